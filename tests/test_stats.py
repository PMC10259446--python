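"""Survey-statistics tests: summaries, rank tests, Meng z."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from prophage_census.stats import (
    kruskal_wallis,
    meng_z,
    spearman,
    summarize_species,
)

from oracles import kruskal_exact_p, meng_z_reference


def _survey(values, species="sp1"):
    return pd.DataFrame(
        {
            "species": species,
            "n_prophages": values,
            "n_intact": 0,
            "composition_pct": 0.0,
            "intact_composition_pct": 0.0,
        }
    )


class TestSummaries:
    def test_constant_values(self):
        out = summarize_species(_survey([3, 3, 3]))
        row = out.iloc[0]
        assert row["n_prophages_median"] == 3.0 and row["n_prophages_sd"] == 0.0

    def test_hand_computed_median_and_sample_sd(self):
        out = summarize_species(_survey([1, 2, 3, 4]))
        row = out.iloc[0]
        assert row["n_prophages_median"] == 2.5
        assert row["n_prophages_sd"] == pytest.approx(math.sqrt(5 / 3), abs=1e-12)
        assert (row["n_prophages_min"], row["n_prophages_max"]) == (1.0, 4.0)

    def test_single_genome_sd_flagged(self):
        out = summarize_species(_survey([5]))
        row = out.iloc[0]
        assert row["n_prophages_sd"] == 0.0 and not row["sd_defined"]


class TestKruskalWallis:
    def test_symmetric_groups_give_zero(self):
        h, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_closed_form(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, abs=1e-12)
        assert p == pytest.approx(float(sps.chi2.sf(27 / 7, 1)), abs=1e-12)

    def test_matches_scipy_on_tied_data(self):
        groups = [[1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0], [1.0, 4.0]]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_identical_observations(self):
        assert kruskal_wallis([[2, 2], [2, 2]]) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "groups",
        [([1, 2, 3], [4, 5, 6]), ([1, 4, 2], [3, 6]), ([1, 2], [3, 4], [5, 6])],
    )
    def test_exact_p_matches_enumeration_oracle(self, groups):
        _, p = kruskal_wallis(groups, method="exact")
        assert p == pytest.approx(kruskal_exact_p(groups), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        groups = [[0.1, 2.0, 3.5], [1.0, 4.0, 9.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([[math.exp(v) for v in g] for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1], []])


class TestSpearman:
    def test_monotone_relationships(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [math.log(v) for v in x])[0] == 1.0
        assert spearman(x, [-v for v in x])[0] == -1.0

    def test_four_point_worked_example(self):
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestMengZ:
    def test_equal_correlations_give_zero(self):
        cmp_ = meng_z(0.4, 0.4, 0.2, 100)
        assert cmp_.z == 0.0 and cmp_.p == 1.0

    def test_antisymmetric_in_r1_r2(self):
        a = meng_z(0.5, 0.3, 0.4, 100)
        b = meng_z(0.3, 0.5, 0.4, 100)
        assert a.z == pytest.approx(-b.z, abs=1e-15)

    def test_z_grows_with_n(self):
        zs = [abs(meng_z(0.5, 0.3, 0.4, n).z) for n in (10, 50, 200, 1000)]
        assert zs == sorted(zs) and zs[0] < zs[-1]

    def test_matches_reference_transcription(self):
        cmp_ = meng_z(0.5, 0.3, 0.4, 100)
        assert cmp_.z == pytest.approx(meng_z_reference(0.5, 0.3, 0.4, 100), abs=1e-9)

    def test_ci_brackets_the_fisher_z_difference(self):
        cmp_ = meng_z(0.55, 0.34, 0.6, 181)
        dz = math.atanh(0.55) - math.atanh(0.34)
        assert cmp_.ci_low < dz < cmp_.ci_high
        assert cmp_.ci_scale == "fisher_z_difference"

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            meng_z(0.5, 0.3, 1.0, 100)
        with pytest.raises(ValueError):
            meng_z(0.5, 0.3, 0.4, 3)
        with pytest.raises(ValueError):
            meng_z(1.0, 0.3, 0.4, 100)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        r1=st.floats(-0.95, 0.95), r2=st.floats(-0.95, 0.95),
        r_yy=st.floats(-0.9, 0.95), n=st.integers(4, 10_000),
    )
    def test_property_matches_reference_everywhere(self, r1, r2, r_yy, n):
        assert meng_z(r1, r2, r_yy, n).z == pytest.approx(
            meng_z_reference(r1, r2, r_yy, n), abs=1e-9
        )


def test_single_species_survey_skips_group_tests(default_result):
    from prophage_census.stats import run_survey

    sim = default_result.sim
    one_species = {g: "only" for g in sim.hosts}
    lengths = {g: r.length for g, r in sim.genomes.items()}
    with pytest.warns(UserWarning, match="fewer than 2 species"):
        out = run_survey(lengths, one_species, default_result.regions,
                         default_result.intact)
    assert out.tests["kruskal_counts"] is None
    assert not out.per_genome.empty


def test_genome_size_correlates_with_planted_counts(default_result):
    """The default scenario plants more phages into larger-genome species,
    so the size-count Spearman correlation is strongly positive."""
    tests = default_result.survey.tests
    assert tests["spearman_size_count"]["rho"] > 0.9
    assert tests["meng"] is not None
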