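"""ANI and population-clustering tests, cross-checked against a full
dynamic-programming Smith-Waterman oracle."""

import numpy as np
import pytest

from prophage_census.dereplication import (
    ANIResult,
    cluster_populations,
    compute_ani_matrix,
    dereplicate,
    pairwise_ani,
    select_representatives,
)
from prophage_census.simulate import (
    GeneSpec,
    generate_host_genome,
    generate_prophage_family,
    mutate_nucleotides,
)

from oracles import dp_ani, revcomp


class TestPairwiseANI:
    def test_identical_sequences(self):
        seq = generate_host_genome(10_000, 0.5, seed=1)
        r = pairwise_ani(seq, seq)
        assert (r.ani, r.aligned_fraction) == (100.0, 100.0)

    def test_three_percent_divergence(self, rng):
        seq = generate_host_genome(20_000, 0.5, seed=2)
        other = mutate_nucleotides(seq, 0.03, rng)
        r = pairwise_ani(seq, other)
        assert 96.0 <= r.ani <= 98.0
        assert r.aligned_fraction >= 95.0
        # agree with the full-DP oracle
        ani_o, af_o = dp_ani(seq, other)
        assert abs(r.ani - ani_o) < 0.5
        assert abs(r.aligned_fraction - af_o) < 1e-9

    def test_unrelated_sequences_do_not_qualify(self):
        a = generate_host_genome(10_000, 0.5, seed=3)
        b = generate_host_genome(10_000, 0.5, seed=4)
        r = pairwise_ani(a, b)
        assert r.aligned_fraction < 85.0
        _, af_o = dp_ani(a, b)
        assert af_o < 85.0

    def test_reverse_complement_detected(self, rng):
        seq = generate_host_genome(12_000, 0.5, seed=5)
        flipped = revcomp(mutate_nucleotides(seq, 0.02, rng))
        r = pairwise_ani(seq, flipped)
        assert r.ani > 95.0 and r.aligned_fraction > 95.0

    def test_symmetry_exact(self, rng):
        a = generate_host_genome(9000, 0.5, seed=6)
        b = mutate_nucleotides(a, 0.04, rng)[:8000]
        r1 = pairwise_ani(a, b, id_a="x", id_b="y")
        r2 = pairwise_ani(b, a, id_a="y", id_b="x")
        assert r1.ani == r2.ani
        assert r1.aligned_fraction == r2.aligned_fraction
        # equal lengths: tie broken by id, still symmetric
        c = mutate_nucleotides(a, 0.04, rng)
        r3 = pairwise_ani(a, c, id_a="x", id_b="y")
        r4 = pairwise_ani(c, a, id_a="y", id_b="x")
        assert r3.ani == r4.ani

    def test_short_sequence_rejected(self):
        seq = generate_host_genome(10_000, 0.5, seed=7)
        with pytest.raises(ValueError):
            pairwise_ani(seq[:4000], seq)


class TestClustering:
    def test_three_clones_one_population(self):
        ids = ["a", "b", "c"]
        results = [
            ANIResult("a", "b", 99.0, 100.0),
            ANIResult("a", "c", 99.0, 100.0),
            ANIResult("b", "c", 99.0, 100.0),
        ]
        pops = cluster_populations(ids, results)
        assert len(pops) == 1 and pops[0].members == ["a", "b", "c"]

    def test_ani_threshold_strict(self):
        """ANI exactly 95 (not above) keeps the pair apart; 94 certainly."""
        for ani in (94.0, 95.0):
            pops = cluster_populations(
                ["a", "b"], [ANIResult("a", "b", ani, 99.0)]
            )
            assert len(pops) == 2

    def test_aligned_fraction_inclusive(self):
        pops = cluster_populations(["a", "b"], [ANIResult("a", "b", 96.0, 85.0)])
        assert len(pops) == 1

    def test_single_linkage_transitivity(self):
        results = [
            ANIResult("a", "b", 97.0, 90.0),
            ANIResult("b", "c", 97.0, 90.0),
            ANIResult("a", "c", 80.0, 90.0),  # not a qualifying pair
        ]
        pops = cluster_populations(["a", "b", "c"], results)
        assert len(pops) == 1


class TestRepresentatives:
    def test_singleton_is_its_own_representative(self):
        pops = cluster_populations(["a"], [])
        reps = select_representatives(pops[0], {"a": "sp1"}, {"a": 10_000})
        assert reps == ["a"]

    def test_longest_member_wins_within_host(self):
        pops = cluster_populations(["A", "B"], [ANIResult("A", "B", 99.0, 95.0)])
        reps = select_representatives(
            pops[0], {"A": "sp1", "B": "sp1"}, {"A": 30_000, "B": 25_000}
        )
        assert reps == ["A"]

    def test_multi_host_population_keeps_one_per_species(self):
        pops = cluster_populations(
            ["A", "B", "C"],
            [ANIResult("A", "B", 99.0, 95.0), ANIResult("B", "C", 99.0, 95.0)],
        )
        reps = select_representatives(
            pops[0],
            {"A": "sp1", "B": "sp2", "C": "sp1"},
            {"A": 30_000, "B": 25_000, "C": 31_000},
        )
        assert reps == ["B", "C"]

    def test_missing_host_rejected(self):
        pops = cluster_populations(["a"], [])
        with pytest.raises(KeyError):
            select_representatives(pops[0], {}, {"a": 10_000})


def _family_regions(n_families, n_members, mu, seed, length=8000):
    regions, truth = {}, {}
    for f in range(n_families):
        fam = generate_prophage_family(
            length, n_members, mu, [GeneSpec("g", 100)], seed=seed + f,
            family_id=f"fam{f}",
        )
        for i, m in enumerate(fam.members):
            rid = f"fam{f}_m{i}"
            regions[rid] = m.sequence
            truth[rid] = f
    return regions, truth


def test_family_recovery_small():
    """Clustering recovers planted families exactly at mu = 0.02."""
    regions, truth = _family_regions(3, 3, 0.02, seed=11)
    hosts = {rid: "sp1" for rid in regions}
    pops, _, summary = dereplicate(regions, hosts)
    assert summary.n_populations == 3 and summary.n_singletons == 0
    for p in pops:
        assert len({truth[m] for m in p.members}) == 1
        assert len(p.representatives) == 1


def test_representative_count_identity():
    """representatives = singletons + sum over clusters of host species."""
    regions, _ = _family_regions(2, 3, 0.02, seed=21)
    extra = {"lone": generate_host_genome(8000, 0.5, seed=99)}
    regions.update(extra)
    hosts = {rid: ("sp2" if rid.endswith("m0") else "sp1") for rid in regions}
    pops, _, summary = dereplicate(regions, hosts)
    expected = sum(
        1 if p.is_singleton else len({hosts[m] for m in p.members}) for p in pops
    )
    assert summary.n_representatives == expected
    assert summary.n_singletons == 1
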