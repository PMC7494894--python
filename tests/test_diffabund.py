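"""NB dispersion estimation, Wald testing, the two pairwise frameworks, and
ternary encoding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dysbiotrack.core import CountTable, SampleMetadata
from dysbiotrack.diffabund import (
    Comparison,
    TernaryPattern,
    design_comparisons,
    fit_dispersion,
    framework_patterns,
    run_frameworks,
    ternary_encode,
    wald_test,
)

from conftest import nb_counts, two_group_metadata


def _table(mat, prefix="g", samples=None):
    n_feat, n_samp = mat.shape
    return CountTable(pd.DataFrame(
        mat, index=[f"{prefix}{i}" for i in range(n_feat)],
        columns=samples or [f"s{j}" for j in range(n_samp)]))


class TestFitDispersion:
    def test_poisson_features_hit_near_zero(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(5.0, 0.8, size=150)
        counts = rng.poisson(mu[:, None] * np.ones(40))
        table = _table(counts)
        disp, _ = fit_dispersion(table, pd.Series(1.0, index=table.samples),
                                 shrink_weight=0.0)
        assert float(np.quantile(disp, 0.9)) <= 0.01

    def test_known_dispersion_recovered(self):
        """alpha = 0.5 at n = 40: at least 90% of per-feature estimates land
        in [0.3, 0.8]."""
        rng = np.random.default_rng(4)
        mu = rng.lognormal(5.0, 0.8, size=200)
        counts = nb_counts(rng, mu[:, None] * np.ones(40), 0.5)
        table = _table(counts)
        disp, _ = fit_dispersion(table, pd.Series(1.0, index=table.samples),
                                 shrink_weight=0.0)
        assert float(((disp >= 0.3) & (disp <= 0.8)).mean()) >= 0.9

    def test_constant_feature_at_floor(self):
        mat = np.vstack([np.full(10, 7), np.arange(10) + 1])
        table = _table(mat)
        disp, _ = fit_dispersion(table, pd.Series(1.0, index=table.samples),
                                 shrink_weight=0.0)
        assert disp.iloc[0] <= 1e-6

    def test_too_few_samples_errors(self):
        table = _table(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="4 samples"):
            fit_dispersion(table, pd.Series(1.0, index=table.samples))

    def test_cellwise_means_shield_real_effects(self):
        """A strong two-group mean shift must not inflate dispersion when
        cells are declared."""
        rng = np.random.default_rng(5)
        mu = rng.lognormal(5.0, 0.5, size=100)
        a = nb_counts(rng, mu[:, None] * np.ones(10), 0.05)
        b = nb_counts(rng, (mu * 8)[:, None] * np.ones(10), 0.05)
        table = _table(np.hstack([a, b]))
        sf = pd.Series(1.0, index=table.samples)
        cells = pd.Series(["A"] * 10 + ["B"] * 10, index=table.samples)
        with_cells, _ = fit_dispersion(table, sf, shrink_weight=0.0,
                                       cells=cells)
        without, _ = fit_dispersion(table, sf, shrink_weight=0.0)
        assert with_cells.median() < 0.15
        assert without.median() > 0.5


class TestWaldTest:
    def test_duplicated_groups_give_zero_l2fc(self):
        rng = np.random.default_rng(6)
        half = rng.poisson(50.0, size=(20, 8))
        table = _table(np.hstack([half, half]),
                       samples=[f"naive_m{j}_d8" for j in range(8)]
                       + [f"EAE_m{j}_d8" for j in range(8)])
        meta = two_group_metadata(8)
        sf = pd.Series(1.0, index=table.samples)
        disp = pd.Series(0.1, index=table.features)
        res = wald_test(table, meta, sf, disp,
                        Comparison("cross_treatment", "EAE", "naive", 8))
        assert np.allclose(res.table["l2fc"], 0.0, atol=1e-9)

    def test_swapping_groups_negates_l2fc(self):
        rng = np.random.default_rng(7)
        counts = nb_counts(rng, rng.lognormal(4, 1, size=(30, 1))
                           * np.ones(20), 0.1)
        table = _table(counts, samples=[f"naive_m{j}_d8" for j in range(10)]
                       + [f"EAE_m{j}_d8" for j in range(10)])
        meta = two_group_metadata(10)
        sf = pd.Series(1.0, index=table.samples)
        disp = pd.Series(0.1, index=table.features)
        ab = wald_test(table, meta, sf, disp,
                       Comparison("cross_treatment", "EAE", "naive", 8))
        ba = wald_test(table, meta, sf, disp,
                       Comparison("cross_treatment", "naive", "EAE", 8))
        assert np.allclose(ab.table["l2fc"], -ba.table["l2fc"], atol=1e-9)
        assert np.allclose(ab.table["p"], ba.table["p"], atol=1e-12)

    def test_planted_effect_recovered(self):
        """log2 effect -4 at n=10/group, dispersion 0.2: mean estimate over
        50 replicate features lies in [-5, -3]."""
        rng = np.random.default_rng(8)
        mu = rng.lognormal(5.5, 0.5, size=50)
        eae = nb_counts(rng, (mu * 2.0**-4)[:, None] * np.ones(10), 0.2)
        naive = nb_counts(rng, mu[:, None] * np.ones(10), 0.2)
        table = _table(np.hstack([naive, eae]),
                       samples=[f"naive_m{j}_d8" for j in range(10)]
                       + [f"EAE_m{j}_d8" for j in range(10)])
        meta = two_group_metadata(10)
        sf = pd.Series(1.0, index=table.samples)
        disp, _ = fit_dispersion(table, sf, cells=meta.table["treatment"])
        res = wald_test(table, meta, sf, disp,
                        Comparison("cross_treatment", "EAE", "naive", 8))
        assert -5.0 <= float(res.table["l2fc"].mean()) <= -3.0

    def test_null_z_is_standard_normal(self):
        """2000 null features: KS distance of the Wald z to N(0,1) < 0.05
        and the type-I rate at alpha=0.05 stays within [0.02, 0.09]."""
        rng = np.random.default_rng(42)
        mu = rng.lognormal(4.5, 1.0, size=2000)
        lib = rng.uniform(0.7, 1.4, size=20)
        counts = nb_counts(rng, mu[:, None] * lib[None, :], 0.1)
        table = _table(counts, samples=[f"naive_m{j}_d8" for j in range(10)]
                       + [f"EAE_m{j}_d8" for j in range(10)])
        meta = two_group_metadata(10)
        from dysbiotrack.ordination import size_factors
        sf = size_factors(table)
        disp, _ = fit_dispersion(table, sf, cells=meta.table["treatment"])
        res = wald_test(table, meta, sf, disp,
                        Comparison("cross_treatment", "EAE", "naive", 8))
        z = res.table["stat"].dropna()
        p = res.table["p"].dropna()
        assert stats.kstest(z, "norm").statistic < 0.05
        assert 0.02 <= float((p < 0.05).mean()) <= 0.09

    def test_all_zero_features_excluded(self):
        mat = np.zeros((3, 12), dtype=int)
        mat[0] = 5
        table = _table(mat, samples=[f"naive_m{j}_d8" for j in range(6)]
                       + [f"EAE_m{j}_d8" for j in range(6)])
        meta = two_group_metadata(6)
        res = wald_test(table, meta, pd.Series(1.0, index=table.samples),
                        pd.Series(0.1, index=table.features),
                        Comparison("cross_treatment", "EAE", "naive", 8))
        assert res.table["p"].notna().sum() == 1


class TestFrameworks:
    def test_design_emits_27_comparisons(self):
        comparisons = design_comparisons([-2, 8, 14, 19, 29])
        cross = [c for c in comparisons if c.framework == "cross_treatment"]
        within = [c for c in comparisons if c.framework == "within_treatment"]
        assert (len(cross), len(within)) == (15, 12)

    def test_scenario_emits_27_results(self, scenario_family_results):
        assert len(scenario_family_results) == 27

    def test_degenerate_comparison_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Comparison("cross_treatment", "naive", "naive", 8)
        with pytest.raises(ValueError, match="differ"):
            Comparison("within_treatment", "EAE", "EAE", -2, baseline_dpi=-2)

    def test_depleted_family_significant_after_onset_only(
            self, scenario, scenario_family_results):
        _, _, _, truth = scenario
        dep = truth["scenario"]["depleted_family"]
        for c, res in scenario_family_results.items():
            if c.framework != "cross_treatment":
                continue
            if (c.group_a, c.group_b) != ("EAE", "naive"):
                continue
            row = res.table.loc[dep]
            if c.dpi in (14, 19, 29):
                assert row["p_adj"] < 0.05 and row["l2fc"] < 0, c.label
            elif c.dpi == -2:
                assert not (row["p_adj"] < 0.05), c.label


class TestTernaryEncode:
    def test_significant_increase(self):
        row = pd.Series({"p_adj": 0.01, "l2fc": 2.5})
        assert ternary_encode([row]).digits == (1,)

    def test_boundary_alpha_is_zero(self):
        row = pd.Series({"p_adj": 0.05, "l2fc": 2.5})
        assert ternary_encode([row]).digits == (0,)

    def test_all_null_pattern_label(self):
        rows = [pd.Series({"p_adj": 1.0, "l2fc": 0.5})] * 5
        assert ternary_encode(rows).label == "0,0,0,0,0"

    def test_nan_encodes_zero(self):
        rows = [pd.Series({"p_adj": np.nan, "l2fc": np.nan}),
                pd.Series({"p_adj": 0.001, "l2fc": -3.0})]
        assert ternary_encode(rows).digits == (0, -1)

    def test_invalid_digits_rejected(self):
        with pytest.raises(ValueError):
            TernaryPattern((0, 2, 1))

    def test_scenario_planted_family_signatures(self, scenario,
                                                scenario_family_results):
        _, _, _, truth = scenario
        patterns = framework_patterns(scenario_family_results)["EAE/naive"]
        assert patterns[truth["scenario"]["depleted_family"]] == "0,0,-1,-1,-1"
        assert patterns[truth["scenario"]["expanded_family"]] == "0,1,1,1,1"

    def test_pattern_lengths_per_framework(self, scenario_family_results):
        patterns = framework_patterns(scenario_family_results)
        assert all(len(p.split(",")) == 5
                   for p in patterns["EAE/naive"])
        assert all(len(p.split(",")) == 4
                   for p in patterns["EAE:post/pre"])
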