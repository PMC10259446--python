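"""Generator tests: determinism, divergence calibration, planting."""

import numpy as np
import pytest

import biotite.sequence as bseq
import biotite.sequence.align as balign

from prophage_census.simulate import (
    GeneSpec,
    GenomeRecord,
    PhageInsert,
    RefSpec,
    default_config,
    derive_reference_protein,
    emit_detector_evidence,
    generate_host_genome,
    generate_prophage_family,
    generate_reference_set,
    plant_prophages,
    simulate,
)


def _global_identity(a: str, b: str) -> float:
    """DP global-alignment identity oracle for protein pairs."""
    m = balign.SubstitutionMatrix.std_protein_matrix()
    ali = balign.align_optimal(
        bseq.ProteinSequence(a), bseq.ProteinSequence(b), m,
        gap_penalty=(-11, -1), local=False, max_number=1,
    )[0]
    return balign.get_sequence_identity(ali, mode="all")


class TestHostGenome:
    def test_deterministic(self):
        a = generate_host_genome(100_000, 0.35, seed=7)
        b = generate_host_genome(100_000, 0.35, seed=7)
        assert a == b

    def test_gc_calibration(self):
        seq = generate_host_genome(1_000_000, 0.35, seed=7)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.35) < 0.01

    @pytest.mark.parametrize("length", [0, -5])
    def test_nonpositive_length_rejected(self, length):
        with pytest.raises(ValueError):
            generate_host_genome(length, 0.5, seed=1)


class TestProphageFamily:
    def test_mu_zero_members_identical(self):
        fam = generate_prophage_family(6000, 3, 0.0, [GeneSpec("g", 100)], seed=1)
        assert all(m.sequence == fam.ancestor for m in fam.members)
        assert all(m.proteins == fam.ancestor_proteins for m in fam.members)

    def test_pairwise_identity_matches_substitution_model(self):
        # each member diverges independently: P(match) = (1-mu)^2 + mu^2/3
        fam = generate_prophage_family(20_000, 2, 0.03, [], seed=5)
        a, b = fam.members
        ident = np.mean([x == y for x, y in zip(a.sequence, b.sequence)]) * 100
        assert abs(ident - 94.1) < 0.6

    def test_layout_carried_through(self):
        layout = [
            GeneSpec("terminase", 200, hallmark="terminase large subunit"),
            GeneSpec("portal", 180, hallmark="portal protein"),
            GeneSpec("capsid", 200, hallmark="major capsid protein"),
            GeneSpec("integrase", 190, integrase=True),
        ]
        fam = generate_prophage_family(6000, 2, 0.02, layout, seed=2)
        assert [g.label for g in fam.layout] == [
            "terminase", "portal", "capsid", "integrase",
        ]
        assert len(fam.gene_coords) == 4
        # substitution-only model: coordinates identical in every member
        for g0, g1 in fam.gene_coords:
            assert 0 <= g0 < g1 <= 6000

    def test_layout_exceeding_ancestor_rejected(self):
        with pytest.raises(ValueError):
            generate_prophage_family(5000, 1, 0.0, [GeneSpec("big", 2000)], seed=1)


class TestPlanting:
    def _family(self, length=20_000, n=1):
        return generate_prophage_family(length, n, 0.0, [GeneSpec("g", 100)], seed=3)

    def test_length_conservation_and_roundtrip(self, rng):
        genome = GenomeRecord("g1", "sp", generate_host_genome(1_000_000, 0.35, rng))
        fam = self._family()
        out, truth = plant_prophages(genome, [PhageInsert(fam, 0)], rng)
        assert out.length == 1_020_000
        (region,) = truth
        assert region.length == 20_000
        assert out.sequence[region.start:region.end] == fam.members[0].sequence

    def test_zero_phages_noop(self, rng):
        genome = GenomeRecord("g1", "sp", generate_host_genome(100_000, 0.5, rng))
        out, truth = plant_prophages(genome, [], rng)
        assert out.sequence == genome.sequence and truth == []

    def test_truth_regions_disjoint_and_in_bounds(self, rng):
        genome = GenomeRecord("g1", "sp", generate_host_genome(200_000, 0.5, rng))
        fam = self._family(length=10_000, n=5)
        out, truth = plant_prophages(genome, [PhageInsert(fam, i) for i in range(5)], rng)
        ivals = sorted((r.start, r.end) for r in truth)
        assert all(0 <= s < e <= out.length for s, e in ivals)
        assert all(ivals[i][1] <= ivals[i + 1][0] for i in range(len(ivals) - 1))

    def test_overweight_planting_rejected(self, rng):
        genome = GenomeRecord("g1", "sp", generate_host_genome(100_000, 0.5, rng))
        fam = self._family(length=25_000, n=2)
        with pytest.raises(ValueError):
            plant_prophages(genome, [PhageInsert(fam, 0), PhageInsert(fam, 1)], rng)


class TestDetectorEvidence:
    def test_clean_evidence_mirrors_truth(self):
        cfg = default_config(seed=4)
        from prophage_census.simulate import DetectorNoise, SimConfig

        clean = SimConfig(
            seed=4, species=cfg.species, phages=cfg.phages,
            noise=DetectorNoise(band_fraction=0.0, decoys_per_genome=0, flank_prob=0.0),
            references=cfg.references,
        )
        sim = simulate(clean)
        assert len(sim.evidence) == len(sim.manifest.regions)
        assert (sim.evidence.primary_score >= 0.9).all()
        truth = {(r.genome_id, r.start, r.end) for r in sim.manifest.regions}
        got = {
            (row.genome_id, row.start, row.end) for row in sim.evidence.itertuples()
        }
        assert got == truth

    def test_full_band_with_confirmation_retains_all(self):
        cfg = default_config(seed=4)
        from prophage_census.simulate import DetectorNoise, SimConfig
        from prophage_census.io import candidates_from_evidence
        from prophage_census.calling import call_regions

        banded = SimConfig(
            seed=4, species=cfg.species, phages=cfg.phages,
            noise=DetectorNoise(band_fraction=1.0, confirm_prob=1.0,
                                decoys_per_genome=0, flank_prob=0.0),
            references=cfg.references,
        )
        sim = simulate(banded)
        assert ((sim.evidence.primary_score >= 0.5)
                & (sim.evidence.primary_score < 0.9)).all()
        assert sim.evidence.secondary_confirmed.all()
        regions, counts = call_regions(candidates_from_evidence(sim.evidence))
        assert counts.n_total == len(sim.manifest.regions)
        assert counts.n_high == 0


class TestReferenceSet:
    def _families(self, n_genes=10):
        layout = [GeneSpec(f"g{i}", 150) for i in range(n_genes)]
        fam = generate_prophage_family(10_000, 1, 0.0, layout, seed=6)
        return {"fam0": fam}

    def test_identity_target_100(self, rng):
        fams = self._families()
        refs, tax = generate_reference_set(
            fams, [RefSpec("R", 0, 100.0, 1.0, genus="G")], rng
        )
        assert [s for _, s in refs["R"]] == list(fams["fam0"].ancestor_proteins)
        assert tax.iloc[0]["reference_id"] == "R"

    def test_fraction_split_exact(self, rng):
        fams = self._families(n_genes=10)
        refs, _ = generate_reference_set(fams, [RefSpec("R", 0, 90.0, 0.6)], rng)
        anc = fams["fam0"].ancestor_proteins
        derived = [
            1 for (_, s), a in zip(refs["R"], anc)
            if np.mean([x == y for x, y in zip(s, a)]) > 0.5
        ]
        assert sum(derived) == 6

    def test_realized_identity_near_target(self, rng):
        fams = self._families(n_genes=12)
        refs, _ = generate_reference_set(fams, [RefSpec("R", 0, 55.0, 1.0)], rng)
        anc = fams["fam0"].ancestor_proteins
        idents = [100 * _global_identity(s, a) for (_, s), a in zip(refs["R"], anc)]
        assert abs(np.mean(idents) - 55.0) < 3.0

    def test_empty_family_rejected(self, rng):
        fam = generate_prophage_family(6000, 1, 0.0, [], seed=1)
        with pytest.raises(ValueError):
            generate_reference_set({"fam0": fam}, [RefSpec("R", 0, 50.0, 1.0)], rng)


def test_low_aai_reference_keeps_conserved_motif(rng):
    protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
    derived = derive_reference_protein(protein, 0.15, rng)
    assert derived[:24] == protein[:24]
    ident = np.mean([x == y for x, y in zip(protein, derived)])
    assert abs(ident - 0.15) < 0.06


def test_simulation_fully_deterministic():
    cfg = default_config(seed=9)
    a, b = simulate(cfg), simulate(cfg)
    assert a.manifest.to_json() == b.manifest.to_json()
    assert a.evidence.equals(b.evidence)
    assert {g: r.sequence for g, r in a.genomes.items()} == {
        g: r.sequence for g, r in b.genomes.items()
    }


def test_planted_composition_conserved():
    sim = simulate(default_config(seed=2))
    per_genome = {}
    for r in sim.manifest.regions:
        per_genome[r.genome_id] = per_genome.get(r.genome_id, 0) + r.length
    for gid, meta in sim.manifest.genomes.items():
        expected = 100.0 * per_genome.get(gid, 0) / meta["length"]
        assert abs(expected - meta["planted_composition_pct"]) < 1e-9
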