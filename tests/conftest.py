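"""Shared fixtures: the default planted scenario and its framework results
are expensive enough to compute once per session."""

import numpy as np
import pandas as pd
import pytest

from dysbiotrack import default_eae_scenario
from dysbiotrack.core import CountTable, SampleMetadata, TaxonomyTable, RANKS
from dysbiotrack.diffabund import framework_patterns, run_frameworks


@pytest.fixture(scope="session")
def scenario():
    counts, taxonomy, metadata, truth = default_eae_scenario(seed=1)
    return counts, taxonomy, metadata, truth


@pytest.fixture(scope="session")
def scenario_family_results(scenario):
    counts, taxonomy, metadata, _ = scenario
    return run_frameworks(counts, metadata, taxonomy, rank="family")


@pytest.fixture(scope="session")
def scenario_asv_patterns(scenario):
    counts, taxonomy, metadata, _ = scenario
    results = run_frameworks(counts, metadata, taxonomy, rank="ASV")
    return framework_patterns(results)


@pytest.fixture()
def small_counts():
    df = pd.DataFrame(
        [[3, 0, 5], [4, 2, 1], [0, 7, 2]],
        index=["ASV_1", "ASV_2", "ASV_3"],
        columns=["s1", "s2", "s3"],
    )
    return CountTable(df)


def nb_counts(rng, mu, alpha):
    """NB draws with variance mu + alpha mu^2 (gamma-Poisson)."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(1.0 / alpha, alpha * mu))


def two_group_metadata(n_per_group=10, dpi=8):
    samples = [f"naive_m{j}_d{dpi}" for j in range(n_per_group)] + [
        f"EAE_m{j}_d{dpi}" for j in range(n_per_group)
    ]
    return SampleMetadata(pd.DataFrame(
        {"treatment": ["naive"] * n_per_group + ["EAE"] * n_per_group,
         "dpi": dpi, "weight": 20.0, "score": 0.0},
        index=samples,
    ))


def toy_taxonomy(features, fam_size=10):
    """Assign consecutive features to families of ``fam_size``."""
    rows = {}
    for i, a in enumerate(features):
        k = i // fam_size + 1
        rows[a] = {r: f"{r[0]}{k}" for r in RANKS}
        rows[a]["family"] = f"fam{k}"
    return TaxonomyTable(pd.DataFrame(rows).T.rename_axis("asv_id"))


def planted_block_counts(seed, n_feat=30, n_samp=45, block=8, loading=0.9,
                         dispersion=0.1):
    """One-group compositional NB table with one latent-factor block."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(5.0, 1.0, size=n_feat)
    base[:block] *= 0.3  # modest block mass: its factor swings stay local
    factor = rng.normal(0.0, 1.0, size=n_samp)
    logw = np.log(base)[:, None] + np.zeros((n_feat, n_samp))
    logw[:block] += loading * factor
    w = np.exp(logw)
    w /= w.sum(axis=0)
    lib = rng.integers(30_000, 50_000, size=n_samp)
    counts = nb_counts(rng, w * lib, dispersion)
    return CountTable(pd.DataFrame(
        counts, index=[f"A{i:02d}" for i in range(n_feat)],
        columns=[f"s{j:02d}" for j in range(n_samp)],
    ))
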