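"""Synthetic longitudinal 16S-style count data with known ground truth.

The generator emulates the design of a three-group (naive / CFA / EAE) mouse
study sampled at five days relative to immunization (-2, 8, 14, 19, 29):

* counts are negative-binomially distributed (variance = mu + alpha * mu^2)
  around a compositional mean: per-ASV latent weights are multiplied by
  planted group x time effects and then renormalized per sample, so the
  depletion of a dominant family honestly induces apparent expansion of
  everything else;
* planted effects act on member ASVs of a target taxon from a configurable
  onset day onward; a ``heterogeneity_fraction`` of member ASVs are
  non-responders whose *observed relative abundance* is held at baseline
  (they neither receive the direct effect nor the compositional
  renormalization boost), which is what a flat trajectory in a 16S dataset
  looks like;
* blocks of ASVs can load on shared latent Gaussian factors to plant
  co-occurrence structure for network recovery;
* clinical score and body weight trajectories are coupled to the planted
  dysbiosis in the EAE group.

Non-responders are "anchored": for a sample with anchored baseline mass
``A = sum(w0[anchored])`` and effect-adjusted free mass
``S = sum(w0*m*[not anchored])``, the renormalization total solves the fixed
point ``T = S + A*T``, i.e. ``T = S / (1 - A)``, so anchored relative
abundances equal their baseline values exactly while free ASVs share the
compositional boost ``1/T``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    RANKS,
    TREATMENTS,
    DESIGN_DAYS,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
)

# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """A planted multiplicative group x time effect on one taxon.

    ``log2_effect`` multiplies the expected latent abundance of responding
    member ASVs by ``2**log2_effect`` at every design day >= ``onset_dpi``
    in the listed treatment groups. ``heterogeneity_fraction`` of member
    ASVs do not respond (their observed relative abundance stays flat).
    """

    target: str
    rank: str
    groups: tuple[str, ...]
    onset_dpi: int
    log2_effect: float
    heterogeneity_fraction: float = 0.0
    non_responders: tuple[str, ...] | None = None  # explicit override

    def __post_init__(self) -> None:
        if self.rank not in RANKS and self.rank != "ASV":
            raise ValueError(f"unknown rank {self.rank!r}")
        unknown = set(self.groups) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown groups {sorted(unknown)}")
        if abs(self.log2_effect) > 10:
            raise ValueError("|log2_effect| must be <= 10")
        if not 0.0 <= self.heterogeneity_fraction <= 1.0:
            raise ValueError("heterogeneity_fraction must lie in [0, 1]")


@dataclass
class CorrelationBlock:
    """A set of ASVs sharing a latent Gaussian factor with a common loading."""

    asvs: tuple[str, ...]
    loading: float = 0.9


@dataclass
class SimConfig:
    """Study-design and noise parameters for the generator.

    Defaults mirror the emulated study: 3 treatment groups x 5 sampling days,
    10 mice per group, a 2/2/2/2/3/4 taxonomy (16 families of 12 ASVs each,
    192 ASVs), one global NB dispersion of 0.1 and library sizes of
    30k-50k reads.
    """

    n_mice_per_group: int = 10
    days: tuple[int, ...] = DESIGN_DAYS
    n_asv: int = 192
    taxonomy_shape: tuple[int, ...] = (2, 2, 2, 2, 3, 4)
    baseline_logmean_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (30_000, 50_000)
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    trait_coupling: float = 1.0
    na_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group <= 0 or self.n_asv <= 0:
            raise ValueError("all sizes must be positive")
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be sorted")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if len(self.taxonomy_shape) != len(RANKS):
            raise ValueError(f"taxonomy_shape needs {len(RANKS)} branching factors")


# ---------------------------------------------------------------------------
# Taxonomy generation
# ---------------------------------------------------------------------------

_RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o",
                "family": "f", "genus": "g", "species": "s"}


def generate_taxonomy(config: SimConfig) -> TaxonomyTable:
    """Generate a balanced taxonomy from per-rank branching factors.

    Leaves of the branching tree are species; ASVs are assigned to the first
    ``n_asv`` leaves in mixed-radix order, so every ASV carries a full 6-rank
    lineage. ``na_fraction`` of ASVs (an exact, seeded count of
    ``round(na_fraction * n_asv)``) receive a ``"<genus>_NA"`` species
    designation.
    """
    shape = tuple(int(b) for b in config.taxonomy_shape)
    if any(b <= 0 for b in shape):
        raise ValueError("branching factors must be positive")
    total = int(np.prod(shape))
    if total < config.n_asv:
        raise ValueError(
            f"taxonomy shape {shape} yields {total} leaves < n_asv={config.n_asv}"
        )
    rng = np.random.default_rng(config.seed)
    rows = []
    asv_ids = [f"ASV_{i + 1:04d}" for i in range(config.n_asv)]
    for leaf in range(config.n_asv):
        digits = []
        rem = leaf
        for b in reversed(shape):
            digits.append(rem % b)
            rem //= b
        digits = digits[::-1]
        lineage = {}
        node = 0
        for rank, b, d in zip(RANKS, shape, digits):
            node = node * b + d
            lineage[rank] = f"{_RANK_PREFIX[rank]}{node + 1:02d}"
        rows.append(lineage)
    df = pd.DataFrame(rows, index=pd.Index(asv_ids, name="asv_id"))
    n_na = int(round(config.na_fraction * config.n_asv))
    if n_na > 0:
        which = rng.choice(config.n_asv, size=n_na, replace=False)
        df.iloc[which, df.columns.get_loc("species")] = (
            df.iloc[which]["genus"] + "_NA"
        )
    return TaxonomyTable(df)


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, variance = mu + alpha mu^2) via the gamma-Poisson mixture."""
    if alpha < 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


_SCORE_CURVE = {-2: 0.0, 8: 0.2, 14: 2.0, 19: 3.5, 29: 3.0}
_WEIGHT_DROP = {-2: 0.0, 8: 0.0, 14: 1.5, 19: 2.5, 29: 1.8}


def _trait_tables(config: SimConfig, rng: np.random.Generator,
                  samples: list[tuple[str, str, int]]) -> pd.DataFrame:
    rows = []
    for sid, group, day in samples:
        base_weight = 18.0 + 0.05 * (day + 2) + rng.normal(0, 0.4)
        if group == "EAE":
            score = config.trait_coupling * _SCORE_CURVE.get(day, 0.0)
            score = max(0.0, score + rng.normal(0, 0.3) * (score > 0))
            weight = base_weight - config.trait_coupling * _WEIGHT_DROP.get(day, 0.0)
        else:
            score = 0.0
            weight = base_weight
        rows.append({"sample_id": sid, "treatment": group, "dpi": day,
                     "weight": round(weight, 3), "score": round(score, 3)})
    return pd.DataFrame(rows).set_index("sample_id")


def _effect_members(effect: EffectSpec, taxonomy: TaxonomyTable) -> list[str]:
    if effect.rank == "ASV":
        members = [effect.target] if effect.target in taxonomy.asvs else []
    else:
        labels = taxonomy.labels_at(effect.rank)
        members = list(labels.index[labels == effect.target])
    if not members:
        raise ValueError(
            f"effect target {effect.target!r} at rank {effect.rank!r} has no ASVs"
        )
    return members


def _expected_composition(w0: np.ndarray, mult: np.ndarray,
                          anchored: np.ndarray) -> np.ndarray:
    """Renormalized expected composition for one group x day cell."""
    free = ~anchored
    s = float(np.sum(w0[free] * mult[free]))
    a = float(np.sum(w0[anchored]))
    if a >= 1.0:
        raise ValueError("anchored baseline mass must be < 1")
    t = s / (1.0 - a)
    x = np.empty_like(w0)
    x[free] = w0[free] * mult[free] / t
    x[anchored] = w0[anchored]
    return x


def generate_counts(
    config: SimConfig,
    effects: Sequence[EffectSpec] = (),
    taxonomy: TaxonomyTable | None = None,
    baseline_log_weights: np.ndarray | None = None,
) -> tuple[CountTable, SampleMetadata, dict]:
    """Draw an ASV x sample count table under the planted model.

    Returns the counts, sample metadata (with score/weight trajectories
    coupled to the planted EAE dysbiosis), and a ground-truth dict recording
    each ASV's expected composition per design cell, its true per-comparison
    log2 effect on observed relative abundance, responder/non-responder
    status, and correlation-block membership.
    """
    rng = np.random.default_rng(config.seed)
    if taxonomy is None:
        taxonomy = generate_taxonomy(config)
    asvs = taxonomy.asvs
    n = len(asvs)
    asv_index = {a: i for i, a in enumerate(asvs)}

    if baseline_log_weights is None:
        baseline_log_weights = rng.normal(0.0, config.baseline_logmean_sd, size=n)
    w0 = np.exp(np.asarray(baseline_log_weights, dtype=float))
    w0 = w0 / w0.sum()

    days = list(config.days)
    # per-(group, day) direct multiplier (log2) and anchored mask
    mult_log2 = {(g, d): np.zeros(n) for g in TREATMENTS for d in days}
    anchored = {(g, d): np.zeros(n, dtype=bool) for g in TREATMENTS for d in days}

    nonresponder_cache: dict[tuple[str, str], set[str]] = {}
    responders_by_effect = []
    for effect in effects:
        members = _effect_members(effect, taxonomy)
        key = (effect.target, effect.rank)
        if effect.non_responders is not None:
            extra = set(effect.non_responders) - set(members)
            if extra:
                raise ValueError(f"non-responders not in target: {sorted(extra)}")
            nonresponder_cache[key] = set(effect.non_responders)
        elif key not in nonresponder_cache:
            n_nr = int(round(effect.heterogeneity_fraction * len(members)))
            chosen = rng.choice(len(members), size=n_nr, replace=False)
            nonresponder_cache[key] = {members[i] for i in chosen}
        non_responders = nonresponder_cache[key]
        responders = [m for m in members if m not in non_responders]
        responders_by_effect.append(
            {"target": effect.target, "rank": effect.rank,
             "responders": sorted(responders),
             "non_responders": sorted(non_responders)}
        )
        r_idx = [asv_index[m] for m in responders]
        nr_idx = [asv_index[m] for m in non_responders]
        for g in effect.groups:
            for d in days:
                if d >= effect.onset_dpi:
                    mult_log2[(g, d)][r_idx] += effect.log2_effect
                    anchored[(g, d)][nr_idx] = True

    # an ASV directly affected in a cell is never anchored in that cell
    for cell in anchored:
        anchored[cell] &= mult_log2[cell] == 0

    # expected compositions per cell (block factors at their zero mean)
    expected = {}
    for g in TREATMENTS:
        for d in days:
            expected[(g, d)] = _expected_composition(
                w0, np.exp2(mult_log2[(g, d)]), anchored[(g, d)]
            )

    # block loading matrix
    blocks = list(config.correlation_blocks)
    loadings = np.zeros((n, len(blocks)))
    for b, block in enumerate(blocks):
        for a in block.asvs:
            loadings[asv_index[a], b] = block.loading

    samples: list[tuple[str, str, int]] = []
    for g in TREATMENTS:
        for m in range(config.n_mice_per_group):
            for d in days:
                samples.append((f"{g}_m{m + 1:02d}_d{d}", g, d))

    lo, hi = config.library_size_range
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, (sid, g, d) in enumerate(samples):
        factors = rng.normal(0.0, 1.0, size=len(blocks))
        log_block = loadings @ factors if blocks else 0.0
        w = w0 * np.exp2(mult_log2[(g, d)]) * np.exp(log_block)
        anc = anchored[(g, d)]
        free = ~anc
        a_mass = float(w0[anc].sum())
        t = float(w[free].sum()) / (1.0 - a_mass)
        x = np.where(anc, w0, w / t)
        library = rng.integers(lo, hi + 1)
        counts[:, j] = _nb_sample(rng, library * x, config.nb_dispersion)

    count_df = pd.DataFrame(
        counts, index=pd.Index(asvs, name="asv_id"),
        columns=[s[0] for s in samples],
    )
    metadata = SampleMetadata(_trait_tables(config, rng, samples))

    # ground truth: true log2 effects on observed composition
    eps = 1e-300
    cross = {}
    for g in ("CFA", "EAE"):
        for d in days:
            cross[f"{g}/naive@{d}"] = np.log2(
                (expected[(g, d)] + eps) / (expected[("naive", d)] + eps)
            )
    within = {}
    baseline_day = days[0]
    for g in TREATMENTS:
        for d in days[1:]:
            within[f"{g}:{d}/{baseline_day}"] = np.log2(
                (expected[(g, d)] + eps) / (expected[(g, baseline_day)] + eps)
            )
    ground_truth = {
        "asvs": asvs,
        "expected_composition": {
            f"{g}@{d}": expected[(g, d)].tolist() for g in TREATMENTS for d in days
        },
        "true_l2fc_cross": {k: v.tolist() for k, v in cross.items()},
        "true_l2fc_within": {k: v.tolist() for k, v in within.items()},
        "direct_log2_multiplier": {
            f"{g}@{d}": mult_log2[(g, d)].tolist() for g in TREATMENTS for d in days
        },
        "anchored": {
            f"{g}@{d}": anchored[(g, d)].tolist() for g in TREATMENTS for d in days
        },
        "effects": responders_by_effect,
        "blocks": [
            {"asvs": list(b.asvs), "loading": b.loading} for b in blocks
        ],
    }
    return CountTable(count_df, rank="ASV"), metadata, ground_truth


# ---------------------------------------------------------------------------
# Default scenario
# ---------------------------------------------------------------------------


def default_eae_scenario(
    seed: int = 0, n_mice_per_group: int = 10
) -> tuple[CountTable, TaxonomyTable, SampleMetadata, dict]:
    """The default planted-dysbiosis scenario.

    Eight families of 36 ASVs each (288 ASVs). The dominant family ``f01``
    (~35% baseline relative abundance, the share a healthy mouse gut's
    dominant family holds) is depleted (-4 log2) in EAE with 40%
    non-responding ASVs; its responders split by onset — the high-abundance
    strains collapse at 14 dpi, a smaller subset only at peak disease
    (19 dpi) — so the family carries several distinct trajectory patterns,
    as heterogeneous strain responses do in real 16S data. CFA drives a
    weaker (-1.5) depletion of the same responders. A near-absent family
    ``f04`` expands (+10 log2) in EAE from 8 dpi; family ``f02`` expands to
    community dominance at 14 dpi, its effect size solved so the latent
    mass it adds offsets the mass the depleted strains lose. The remaining
    five background families carry heterogeneous per-ASV responses on a
    continuum (uniform +/-2.5 log2 from 8 dpi, shifted to cancel the
    expansion family's added mass; one of them, ``f03``, additionally
    responds to the adjuvant alone). Keeping each design cell's total
    latent mass at baseline means truly unresponsive taxa are also
    observationally stable — the regime in which median-of-ratios
    normalization has a fixed reference. Two correlation blocks of 8 ASVs
    (within families f05 and f06) plant network structure.
    """
    config = SimConfig(seed=seed, n_mice_per_group=n_mice_per_group,
                       taxonomy_shape=(2, 2, 2, 1, 4, 9), n_asv=288)
    taxonomy = generate_taxonomy(config)
    labels = taxonomy.labels_at("family")
    families = sorted(labels.unique())
    rng = np.random.default_rng(seed + 10_007)

    # family baseline mass shares
    mass = {
        families[0]: 0.35,    # dominant, to be depleted (f01)
        families[1]: 0.12,    # expander-to-dominance (f02)
        families[3]: 3.0e-5,  # near-absent expansion family (f04)
    }
    rest = [f for f in families if f not in mass]  # f03, f05..f08
    for f in rest:
        mass[f] = (1.0 - 0.35 - 0.12 - 3.0e-5) / len(rest)

    asv_pos = {a: i for i, a in enumerate(taxonomy.asvs)}
    log_w = np.empty(len(taxonomy.asvs))
    for fam in families:
        members = labels.index[labels == fam]
        idx = [asv_pos[a] for a in members]
        within = rng.lognormal(0.0, config.baseline_logmean_sd, size=len(idx))
        within = within / within.sum() * mass[fam]
        log_w[idx] = np.log(within)
    w0 = np.exp(log_w)
    w0 = w0 / w0.sum()

    # split the depleted family by baseline abundance: the 12 largest
    # strains collapse at onset (14 dpi), the next 10 at peak (19 dpi),
    # and the smallest 14 (40%) do not respond
    dep_members = sorted(labels.index[labels == families[0]],
                         key=lambda a: -w0[asv_pos[a]])
    onset14, onset19 = dep_members[:12], dep_members[12:22]
    anchored = tuple(sorted(dep_members[22:]))
    mass14 = float(sum(w0[asv_pos[a]] for a in onset14))

    effects = [
        EffectSpec(families[0], "family", ("EAE",), 14, -4.0, 0.4,
                   non_responders=anchored + tuple(onset19)),
        EffectSpec(families[0], "family", ("EAE",), 19, -4.0, 0.4,
                   non_responders=anchored + tuple(onset14)),
        EffectSpec(families[0], "family", ("CFA",), 14, -1.5, 0.4,
                   non_responders=anchored + tuple(onset19)),
        EffectSpec(families[2], "family", ("CFA",), 8, 1.5),
        EffectSpec(families[3], "family", ("EAE",), 8, 10.0),
    ]
    # the expander's bloom is strain-concentrated: its four dominant
    # strains alone absorb the latent mass the depleted strains lose (the
    # rest of the family stays flat) — real blooms reduce evenness, so
    # this is what drives the EAE alpha-diversity decline
    exp_members = sorted(labels.index[labels == families[1]])
    w_exp = np.array([w0[asv_pos[a]] for a in exp_members])
    lead = np.argsort(-w_exp)[:4]
    w_lead = float(w_exp[lead].sum())
    e_lead = float(np.log2(1.0 + mass14 * (1.0 - 2.0**-4) / w_lead))
    for i in lead:
        effects.append(EffectSpec(exp_members[i], "ASV", ("EAE",), 14,
                                  float(np.clip(e_lead, -10, 10))))
    # a CFA-depleted family offsets the adjuvant-responsive family's gain,
    # keeping the CFA cells mass-balanced as well
    w_cfa_dn = mass[families[7]]
    gain_cfa = mass[families[2]] * (2.0**1.5 - 1.0)
    d_cfa = float(-np.log2(max(1.0 - gain_cfa / w_cfa_dn, 2.0**-10)))
    effects.append(EffectSpec(families[7], "family", ("CFA",), 8, -d_cfa))
    # heterogeneous per-ASV background responses from 8 dpi, shifted within
    # each family so that family's net latent-mass change cancels its share
    # of the mass the expansion family adds — every family's aggregate
    # stays observationally stable at 8 dpi
    block_parents = (families[4], families[5])
    blocks = []
    block_asvs: set[str] = set()
    for fam in block_parents:
        members = sorted(labels.index[labels == fam])[:8]
        blocks.append(CorrelationBlock(tuple(members), loading=0.9))
        block_asvs.update(members)

    delta = mass[families[3]] * (2.0**10 - 1.0)  # mass the expansion adds
    block_factor = float(np.exp(0.9**2 / 2.0))  # lognormal factor mean
    for fam in rest:
        members = sorted(labels.index[labels == fam])
        w_f = np.array([
            w0[asv_pos[a]] * (block_factor if a in block_asvs else 1.0)
            for a in members
        ])
        n_f = len(members)
        # three response classes per family: a modest expanding minority, a
        # depleted class deep enough to absorb the community's mass gains,
        # and an equally large unresponsive class — the dense stable class
        # keeps the normalization reference pinned in every design cell
        order = rng.permutation(n_f)
        n_up = max(1, round(n_f * 8 / 36))
        n_dn = max(1, round(n_f * 10 / 36))
        up_idx = order[:n_up]
        dn_idx = order[n_up:n_up + n_dn]
        eff = np.zeros(n_f)
        up_eff = rng.uniform(0.3, 1.2, size=n_up)
        mag = rng.uniform(0.5, 2.5, size=n_dn)
        w_dn = float(w_f[dn_idx].sum())
        for _ in range(60):
            gain = float(np.sum(w_f[up_idx] * (2.0**up_eff - 1.0)))
            if gain + delta / len(rest) <= 0.9 * w_dn:
                break
            up_eff *= 0.9
        target_dn = w_dn - gain - delta / len(rest)
        lo, hi = 0.1, 10.0
        for _ in range(50):
            s = (lo + hi) / 2.0
            if float(np.sum(w_f[dn_idx] * 2.0 ** (-s * mag))) > target_dn:
                lo = s
            else:
                hi = s
        eff[up_idx] = up_eff
        eff[dn_idx] = np.clip(-(lo + hi) / 2.0 * mag, -10.0, None)
        for asv, e in zip(members, eff):
            if e != 0.0:
                effects.append(EffectSpec(asv, "ASV", ("EAE",), 8, float(e)))
    config = SimConfig(seed=seed, n_mice_per_group=n_mice_per_group,
                       correlation_blocks=tuple(blocks))

    counts, metadata, truth = generate_counts(
        config, effects, taxonomy=taxonomy, baseline_log_weights=log_w
    )
    truth["scenario"] = {
        "depleted_family": families[0],
        "expanded_family": families[3],
        "dominant_expander": families[1],
        "adjuvant_family": families[2],
        "block_families": list(block_parents),
        "depleted_onset14": list(onset14),
        "depleted_onset19": list(onset19),
        "depleted_non_responders": list(anchored),
    }
    return counts, taxonomy, metadata, truth


# ---------------------------------------------------------------------------
# Synthetic functional features (for module detection)
# ---------------------------------------------------------------------------


def generate_functional_table(
    metadata: SampleMetadata,
    n_per_module: int = 40,
    n_noise: int = 0,
    loading: float = 0.8,
    trait_coupling: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-factor synthetic functional (e.g. pathway x sample) matrix.

    Module ``mod1`` loads on a factor positively coupled to clinical score;
    ``mod2`` loads on a factor negatively coupled to score and positively to
    body weight. Values are on a normalized (Gaussian) scale, ready for
    correlation-network module detection. Returns the matrix and the planted
    feature -> module labels (noise features labelled ``"noise"``).
    """
    rng = np.random.default_rng(seed)
    meta = metadata.table
    n_samples = len(meta)

    def _z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    resid = np.sqrt(max(0.0, 1.0 - trait_coupling ** 2))
    factor1 = trait_coupling * _z(meta["score"]) + resid * rng.normal(size=n_samples)
    factor2 = trait_coupling * _z(meta["weight"]) + resid * rng.normal(size=n_samples)

    rows, labels = [], []
    feat_resid = np.sqrt(max(0.0, 1.0 - loading ** 2)) * noise_sd
    for m, factor in (("mod1", factor1), ("mod2", factor2)):
        for i in range(n_per_module):
            rows.append(loading * factor + feat_resid * rng.normal(size=n_samples))
            labels.append(m)
    for i in range(n_noise):
        rows.append(noise_sd * rng.normal(size=n_samples))
        labels.append("noise")
    n_feat = len(rows)
    ids = [f"EC_{i + 1:04d}" for i in range(n_feat)]
    table = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="feature_id"),
                         columns=meta.index)
    return table, pd.Series(labels, index=table.index, name="module")


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
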