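"""Signed adjacency, topological overlap (with brute-force oracle), module
detection on planted factors, and eigenfeature-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dysbiotrack.modules import (
    UNASSIGNED,
    detect_modules,
    module_trait,
    signed_adjacency,
    topological_overlap,
)
from dysbiotrack.simulate import default_eae_scenario, generate_functional_table
from dysbiotrack.core import SampleMetadata


def tom_reference(a):
    """Direct triple-loop evaluation of the TOM formula (oracle)."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


@pytest.fixture(scope="module")
def functional_meta():
    _, _, metadata, _ = default_eae_scenario(seed=1, n_mice_per_group=5)
    return metadata


class TestSignedAdjacency:
    def test_perfect_correlation(self):
        x = np.vstack([np.arange(10.0), np.arange(10.0) * 3 + 1])
        adj = signed_adjacency(pd.DataFrame(x), beta=7)
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.vstack([np.arange(10.0), -np.arange(10.0)])
        adj = signed_adjacency(pd.DataFrame(x), beta=7)
        assert adj.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_quarter_at_beta_two(self):
        x = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        adj = signed_adjacency(pd.DataFrame(x), beta=2)
        assert adj.iloc[0, 1] == pytest.approx(0.25)

    def test_constant_feature_dropped(self):
        x = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) ** 2])
        adj = signed_adjacency(pd.DataFrame(x, index=["flat", "a", "b"]),
                               beta=6)
        assert list(adj.index) == ["a", "b"]

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            signed_adjacency(pd.DataFrame(np.eye(3)), beta=0)


class TestTopologicalOverlap:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            raw = rng.uniform(size=(6, 6))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = topological_overlap(pd.DataFrame(a)).to_numpy()
            assert np.allclose(tom, tom_reference(a), atol=1e-12)

    def test_identical_rows_fully_overlap(self):
        a = np.ones((4, 4))
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_disconnected_pair_zero(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.0
        a[2, 3] = a[3, 2] = 0.9
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == 0.0

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(size=(10, 10))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(pd.DataFrame(a))


class TestDetectModules:
    def test_two_planted_factors_recovered(self, functional_meta):
        table, labels = generate_functional_table(
            functional_meta, n_per_module=40, n_noise=0, seed=11)
        tom = topological_overlap(signed_adjacency(table, beta=6))
        modules = detect_modules(tom, table, min_size=30)
        assert len(modules.modules) == 2
        ari = adjusted_rand_score(
            labels.values, modules.membership.reindex(labels.index).values)
        assert ari >= 0.8
        # at least 90% of each planted module lands in one detected module
        for planted in ("mod1", "mod2"):
            members = modules.membership[labels == planted]
            assert members.value_counts().iloc[0] >= 0.9 * len(members)

    def test_duplicate_factor_modules_merged(self, functional_meta):
        rng = np.random.default_rng(2)
        n = len(functional_meta.samples)
        factor = rng.normal(size=n)
        rows = [0.85 * factor + 0.5 * rng.normal(size=n) for _ in range(70)]
        table = pd.DataFrame(rows, index=[f"f{i}" for i in range(70)],
                             columns=functional_meta.samples)
        tom = topological_overlap(signed_adjacency(table, beta=6))
        modules = detect_modules(tom, table, min_size=30)
        assert len(modules.modules) == 1

    def test_min_size_larger_than_features(self, functional_meta):
        table, _ = generate_functional_table(functional_meta,
                                             n_per_module=10, n_noise=0,
                                             seed=3)
        tom = topological_overlap(signed_adjacency(table, beta=6))
        modules = detect_modules(tom, table, min_size=50)
        assert modules.modules == []
        assert (modules.membership == UNASSIGNED).all()

    def test_noise_features_unassigned(self, functional_meta):
        table, labels = generate_functional_table(
            functional_meta, n_per_module=35, n_noise=20, seed=4)
        tom = topological_overlap(signed_adjacency(table, beta=6))
        modules = detect_modules(tom, table, min_size=30)
        noise = modules.membership[labels == "noise"]
        assert (noise == UNASSIGNED).mean() >= 0.8

    def test_eigenfeature_unit_norm_and_top_variance(self, functional_meta):
        table, _ = generate_functional_table(functional_meta,
                                             n_per_module=40, n_noise=0,
                                             seed=5)
        tom = topological_overlap(signed_adjacency(table, beta=6))
        modules = detect_modules(tom, table, min_size=30)
        for m in modules.modules:
            eig = modules.eigenfeatures.loc[m].to_numpy()
            assert np.linalg.norm(eig) == pytest.approx(1.0)
            x = table.loc[modules.members(m)].to_numpy()
            z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
            # projection variance equals the top eigenvalue of z z^T / n
            gram = z @ z.T
            top = np.linalg.eigvalsh(gram).max()
            assert (z @ eig) @ (z @ eig) == pytest.approx(top, rel=1e-8)


class TestModuleTrait:
    def test_eigenfeature_equal_to_score(self, functional_meta):
        score = functional_meta.table["score"].to_numpy(dtype=float)
        eig = (score - score.mean())
        eig = eig / np.linalg.norm(eig)
        from dysbiotrack.modules import ModuleSet
        modules = ModuleSet(
            pd.Series("M1", index=["f1"]),
            pd.DataFrame([eig], index=["M1"],
                         columns=functional_meta.samples))
        out = module_trait(modules, functional_meta).set_index("trait")
        assert out.loc["score", "r"] == pytest.approx(1.0)

    def test_planted_coupling_signs(self, functional_meta):
        """The score-coupled module correlates positively with score; the
        weight-coupled module negatively with score and positively with
        weight (the protective-module signature)."""
        ok = 0
        reps = 30
        for rep in range(reps):
            table, labels = generate_functional_table(
                functional_meta, n_per_module=40, n_noise=0, seed=600 + rep)
            tom = topological_overlap(signed_adjacency(table, beta=6))
            modules = detect_modules(tom, table, min_size=30)
            if len(modules.modules) < 2:
                continue
            traits = module_trait(modules, functional_meta).set_index(
                ["module", "trait"])
            good_a = good_b = False
            for m in modules.modules:
                members = set(modules.members(m))
                frac1 = len(members & set(labels.index[labels == "mod1"])) \
                    / max(len(members), 1)
                r_score = traits.loc[(m, "score"), "r"]
                r_weight = traits.loc[(m, "weight"), "r"]
                if frac1 > 0.5 and r_score > 0:
                    good_a = True
                if frac1 < 0.5 and r_score < 0 and r_weight > 0:
                    good_b = True
            ok += good_a and good_b
        assert ok >= 0.9 * reps

    def test_planted_r_magnitude(self, functional_meta):
        """With trait coupling 0.5 the recovered eigenfeature-score r lands
        in [0.3, 0.7] for the score module in >= 90% of replicates."""
        hits = reps = 0
        for rep in range(40):
            table, labels = generate_functional_table(
                functional_meta, n_per_module=40, n_noise=0, seed=900 + rep)
            tom = topological_overlap(signed_adjacency(table, beta=6))
            modules = detect_modules(tom, table, min_size=30)
            if len(modules.modules) < 2:
                continue
            traits = module_trait(modules, functional_meta).set_index(
                ["module", "trait"])
            for m in modules.modules:
                members = set(modules.members(m))
                frac1 = len(members & set(labels.index[labels == "mod1"])) \
                    / max(len(members), 1)
                if frac1 > 0.5:
                    reps += 1
                    hits += 0.3 <= abs(traits.loc[(m, "score"), "r"]) <= 0.7
        assert reps > 0 and hits >= 0.9 * reps
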