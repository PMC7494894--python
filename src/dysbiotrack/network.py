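"""Permutation-renormalization-bootstrap (ReBoot-style) ensemble inference
of co-occurrence and mutual-exclusion networks, with Louvain communities.

Five association metrics are computed on column-normalized (relative)
abundances: Spearman and Pearson correlation, mutual information
(equal-frequency binning, ``floor(sqrt(n))`` bins), Bray-Curtis and
symmetrized Kullback-Leibler dissimilarity. Candidate edges are the union,
over metrics, of the strongest co-occurrence and strongest exclusion pairs.
For each candidate pair and metric, a bootstrap distribution (resampling
samples with replacement) is compared against a null distribution obtained
by permuting each feature's counts across samples independently and then
re-normalizing columns — the renormalization step retains the compositional
artifacts that drive spurious correlations, which is exactly what the null
must account for. The comparison is a Z-test on the two distribution means
with the distributions' variances summed,

    z = (mean_boot - mean_null) / sqrt(var_boot + var_null),

and two-sided normal p-values are BH-corrected across candidate pairs
within each metric. An edge is retained when at least two metrics are
significant *and* agree in direction; mutual information (unsigned) takes
its direction from Spearman and only votes alongside a significant signed
metric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import CountTable, SampleMetadata, bh_adjust, relative_abundance

logger = logging.getLogger(__name__)

METRICS: tuple[str, ...] = (
    "spearman", "pearson", "mutual_information", "bray_curtis", "kl_divergence"
)
_DISSIMILARITY = {"bray_curtis", "kl_divergence"}
_SIGNED = {"spearman", "pearson"}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class EdgeEvidence:
    """Per-metric evidence for one unordered feature pair."""

    pair: tuple[str, str]
    metrics: pd.DataFrame  # index metric: score, boot_mean, boot_var, null_mean, null_var, z, p, p_adj, direction
    direction: str = ""  # winning direction of the retained edge
    n_supporting: int = 0


@dataclass
class EnsembleNetwork:
    """Retained signed edges for one treatment group."""

    group: str
    nodes: list[str]
    edges: list[EdgeEvidence]

    def subgraph_edges(self, direction: str) -> list[EdgeEvidence]:
        return [e for e in self.edges if e.direction == direction]

    @property
    def positive_subgraph(self) -> nx.Graph:
        return self._graph("co-occurrence")

    @property
    def negative_subgraph(self) -> nx.Graph:
        return self._graph("exclusion")

    def _graph(self, direction: str) -> nx.Graph:
        g = nx.Graph()
        for e in self.subgraph_edges(direction):
            g.add_edge(*e.pair, n_supporting=e.n_supporting)
        return g

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e.pair, direction=e.direction,
                       n_supporting=e.n_supporting)
        return g


@dataclass
class CommunityPartition:
    """Louvain partition of one subgraph with per-community significance."""

    membership: dict[str, int]
    modularity: float
    community_stats: pd.DataFrame  # index community: size, modularity_contribution, p_wilcoxon

    def members(self, community: int) -> set[str]:
        return {n for n, c in self.membership.items() if c == community}

    @property
    def communities(self) -> list[int]:
        return sorted(set(self.membership.values()))


# ---------------------------------------------------------------------------
# Pre-filtering and scoring
# ---------------------------------------------------------------------------


def prefilter(counts: CountTable, min_occ: int = 3) -> CountTable:
    """Drop features observed (nonzero) in fewer than ``min_occ`` samples."""
    occ = (counts.counts > 0).sum(axis=1)
    kept = counts.counts.loc[occ >= min_occ]
    return CountTable(kept.copy(), rank=counts.rank)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, x)


def _corr(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c


def _mutual_information_pairs(
    x: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """MI for the given (i, j) index pairs, equal-frequency binning."""
    p, n = x.shape
    b = max(2, int(np.floor(np.sqrt(n))))
    # equal-frequency bin codes per feature
    order = np.argsort(x, axis=1, kind="stable")
    codes = np.empty((p, n), dtype=np.int64)
    sizes = np.full(b, n // b)
    sizes[: n % b] += 1
    bin_of_pos = np.repeat(np.arange(b), sizes)
    for i in range(p):
        codes[i, order[i]] = bin_of_pos
    xi = codes[pairs[:, 0]]
    xj = codes[pairs[:, 1]]
    joint_codes = xi * b + xj
    m = pairs.shape[0]
    joint = np.zeros((m, b * b), dtype=np.float64)
    row_idx = np.repeat(np.arange(m), n)
    np.add.at(joint, (row_idx, joint_codes.ravel()), 1.0)
    joint /= n
    pi = joint.reshape(m, b, b).sum(axis=2)
    pj = joint.reshape(m, b, b).sum(axis=1)
    outer = pi[:, :, None] * pj[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint.reshape(m, b, b) * np.log(
            joint.reshape(m, b, b) / outer
        )
    return np.nansum(terms, axis=(1, 2))


def _bray_curtis(x: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(x, metric="braycurtis"))


def _sym_kl(x: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    p = x + pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    logp = np.log(p)
    # KL(i||j) = sum_s p_is (log p_is - log p_js)
    self_term = (p * logp).sum(axis=1)
    cross = p @ logp.T
    kl = self_term[:, None] - cross
    return 0.5 * (kl + kl.T)


def edge_scores(
    rel: pd.DataFrame,
    metric: str,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise association scores on a relative-abundance matrix.

    Returns the full symmetric matrix, or a vector if index ``pairs`` are
    given (mutual information is only ever computed pairwise). Constant
    profiles yield NaN under the correlation metrics.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    x = rel.to_numpy(dtype=float)
    if metric == "mutual_information":
        if pairs is None:
            pairs = np.array(
                list(itertools.combinations(range(x.shape[0]), 2)), dtype=np.int64
            )
            mi = _mutual_information_pairs(x, pairs)
            out = np.zeros((x.shape[0],) * 2)
            out[pairs[:, 0], pairs[:, 1]] = mi
            out[pairs[:, 1], pairs[:, 0]] = mi
            return out
        return _mutual_information_pairs(x, pairs)
    if metric == "spearman":
        full = _corr(_rank_rows(x))
    elif metric == "pearson":
        full = _corr(x)
    elif metric == "bray_curtis":
        full = _bray_curtis(x)
    else:
        full = _sym_kl(x)
    if pairs is None:
        return full
    return full[pairs[:, 0], pairs[:, 1]]


def threshold_candidates(
    scores: Mapping[str, np.ndarray],
    features: Sequence[str],
    n_top: int = 1500,
    n_bottom: int = 1500,
) -> list[tuple[str, str]]:
    """Union, over metrics, of the strongest-association (top) and
    weakest/most-exclusive (bottom) pairs.

    Dissimilarities are inverted so "top" always means strongest
    co-occurrence. Ties are broken by lexicographic pair id; NaN scores are
    skipped. If fewer pairs exist than requested, all are taken.
    """
    if n_top < 0 or n_bottom < 0:
        raise ValueError("n_top and n_bottom must be >= 0")
    p = len(features)
    idx_pairs = list(itertools.combinations(range(p), 2))
    name_pairs = [tuple(sorted((features[i], features[j]))) for i, j in idx_pairs]
    selected: set[tuple[str, str]] = set()
    for metric, mat in scores.items():
        vals = np.array([mat[i, j] for i, j in idx_pairs])
        if metric in _DISSIMILARITY:
            vals = -vals
        ok = np.isfinite(vals)
        order = sorted(
            (k for k in range(len(idx_pairs)) if ok[k]),
            key=lambda k: (-vals[k], name_pairs[k]),
        )
        selected.update(name_pairs[k] for k in order[:n_top])
        if n_bottom:
            selected.update(name_pairs[k] for k in order[-n_bottom:])
    return sorted(selected)


# ---------------------------------------------------------------------------
# ReBoot significance
# ---------------------------------------------------------------------------


def _pair_scores(
    rel: np.ndarray, pairs: np.ndarray, metrics: Sequence[str]
) -> dict[str, np.ndarray]:
    frame = pd.DataFrame(rel)
    out = {}
    for metric in metrics:
        out[metric] = edge_scores(frame, metric, pairs=pairs)
    return out


def reboot_significance(
    counts: CountTable,
    candidates: Sequence[tuple[str, str]],
    n_iter: int = 100,
    seed: int = 0,
    metrics: Sequence[str] = METRICS,
    alpha: float = 0.05,
) -> list[EdgeEvidence]:
    """Bootstrap-vs-renormalized-null Z-test per candidate pair and metric.

    Retains an edge when >= 2 metrics have BH-adjusted p < ``alpha`` and
    agree in direction (see module docstring for the mutual-information
    voting rule). Returns evidence for every candidate pair, with
    ``direction``/``n_supporting`` set on retained edges.
    """
    if n_iter < 20:
        raise ValueError("n_iter < 20 yields distributions too coarse to test")
    if not len(candidates):
        raise ValueError("no candidate pairs")
    rng = np.random.default_rng(seed)
    feats = counts.features
    index = {f: i for i, f in enumerate(feats)}
    pairs = np.array(
        [(index[a], index[b]) for a, b in candidates], dtype=np.int64
    )
    raw = counts.counts.to_numpy(dtype=float)
    totals = raw.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("all-zero sample in network input")
    rel = raw / totals
    n = rel.shape[1]

    m = len(candidates)
    boot = {metric: np.empty((n_iter, m)) for metric in metrics}
    null = {metric: np.empty((n_iter, m)) for metric in metrics}
    for it in range(n_iter):
        cols = rng.integers(0, n, size=n)
        sc = _pair_scores(rel[:, cols], pairs, metrics)
        for metric in metrics:
            boot[metric][it] = sc[metric]
    for it in range(n_iter):
        perm = raw.copy()
        for i in range(perm.shape[0]):
            perm[i] = perm[i, rng.permutation(n)]
        perm_totals = perm.sum(axis=0)
        perm_totals[perm_totals == 0] = 1.0
        sc = _pair_scores(perm / perm_totals, pairs, metrics)
        for metric in metrics:
            null[metric][it] = sc[metric]

    evidence: list[EdgeEvidence] = []
    stats_by_metric = {}
    for metric in metrics:
        with np.errstate(invalid="ignore"):
            mb = np.nanmean(boot[metric], axis=0)
            vb = np.nanvar(boot[metric], axis=0, ddof=1)
            mn = np.nanmean(null[metric], axis=0)
            vn = np.nanvar(null[metric], axis=0, ddof=1)
            z = (mb - mn) / np.sqrt(vb + vn)
        p = 2.0 * stats.norm.sf(np.abs(z))
        ok = np.isfinite(p)
        p_adj = np.full(m, np.nan)
        if ok.any():
            p_adj[ok] = bh_adjust(p[ok])
        if metric in _DISSIMILARITY:
            direction = np.where(mb < mn, "co-occurrence", "exclusion")
        elif metric in _SIGNED:
            direction = np.where(mb >= 0, "co-occurrence", "exclusion")
        else:
            direction = np.full(m, "", dtype=object)  # resolved from spearman
        stats_by_metric[metric] = dict(
            score=mb, boot_mean=mb, boot_var=vb, null_mean=mn, null_var=vn,
            z=z, p=p, p_adj=p_adj, direction=direction,
        )
    if "mutual_information" in metrics and "spearman" in metrics:
        sp_dir = stats_by_metric["spearman"]["direction"]
        stats_by_metric["mutual_information"]["direction"] = sp_dir.copy()

    for k, (a, b) in enumerate(candidates):
        table = pd.DataFrame(
            {
                key: [stats_by_metric[metric][key][k] for metric in metrics]
                for key in ("score", "boot_mean", "boot_var", "null_mean",
                            "null_var", "z", "p", "p_adj", "direction")
            },
            index=list(metrics),
        )
        sig = table.index[table["p_adj"] < alpha]
        votes: dict[str, set[str]] = {"co-occurrence": set(), "exclusion": set()}
        for metric in sig:
            d = table.loc[metric, "direction"]
            if d in votes:
                votes[d].add(metric)
        ev = EdgeEvidence((a, b), table)
        for direction, supporters in votes.items():
            signed_support = supporters & _SIGNED
            effective = {
                s for s in supporters
                if s != "mutual_information" or signed_support
            }
            if len(effective) >= 2:
                ev.direction = direction
                ev.n_supporting = len(effective)
                break
        evidence.append(ev)
    return evidence


def build_group_networks(
    counts: CountTable,
    metadata: SampleMetadata,
    min_occ: int = 3,
    n_top: int = 1500,
    n_bottom: int = 1500,
    n_iter: int = 100,
    seed: int = 0,
    metrics: Sequence[str] = METRICS,
) -> dict[str, EnsembleNetwork]:
    """One ensemble network per treatment group, all time points pooled.

    ``n_top``/``n_bottom`` are clipped to the number of available pairs.
    Groups with no samples are skipped with a warning.
    """
    networks: dict[str, EnsembleNetwork] = {}
    for g_idx, group in enumerate(("naive", "CFA", "EAE")):
        samples = metadata.select(treatment=group)
        if not samples:
            logger.warning("group %s missing; skipped", group)
            continue
        sub = prefilter(counts.subset_samples(samples), min_occ=min_occ)
        rel = relative_abundance(sub)
        scores = {metric: edge_scores(rel, metric) for metric in metrics}
        n_pairs = sub.shape[0] * (sub.shape[0] - 1) // 2
        candidates = threshold_candidates(
            scores, sub.features,
            n_top=min(n_top, n_pairs), n_bottom=min(n_bottom, n_pairs),
        )
        evidence = reboot_significance(
            sub, candidates, n_iter=n_iter, seed=seed + 1000 * g_idx,
            metrics=metrics,
        )
        retained = [e for e in evidence if e.direction]
        networks[group] = EnsembleNetwork(group, sub.features, retained)
    return networks


# ---------------------------------------------------------------------------
# Louvain communities
# ---------------------------------------------------------------------------


def louvain_communities(subgraph: nx.Graph, seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximization (resolution 1, unweighted) with
    per-community Wilcoxon rank-sum significance.

    Community significance compares, over member nodes, their
    within-community degree against their out-of-community degree
    (one-sided: within > out). Isolated nodes are excluded.
    """
    nodes = [n for n in subgraph.nodes if subgraph.degree(n) > 0]
    if not nodes or subgraph.number_of_edges() == 0:
        return CommunityPartition({}, 0.0, pd.DataFrame(
            columns=["size", "modularity_contribution", "p_wilcoxon"]))
    g = ig.Graph()
    g.add_vertices(nodes)
    g.add_edges([(a, b) for a, b in subgraph.edges if a in set(nodes)])
    import random as _random

    ig.set_random_number_generator(_random.Random(seed))
    clustering = g.community_multilevel()
    membership = {nodes[i]: int(c) for i, c in enumerate(clustering.membership)}
    modularity = float(clustering.modularity)

    m = subgraph.number_of_edges()
    stats_rows = {}
    for community in sorted(set(membership.values())):
        members = [n for n, c in membership.items() if c == community]
        within = 0
        degree_sum = 0
        win_deg, out_deg = [], []
        member_set = set(members)
        for node in members:
            w = sum(1 for nb in subgraph.neighbors(node) if nb in member_set)
            d = subgraph.degree(node)
            win_deg.append(w)
            out_deg.append(d - w)
            within += w
            degree_sum += d
        within //= 2
        contribution = within / m - (degree_sum / (2 * m)) ** 2
        if len(members) >= 2 and (np.ptp(win_deg) or np.ptp(out_deg)
                                  or win_deg[0] != out_deg[0]):
            p = float(stats.mannwhitneyu(win_deg, out_deg,
                                         alternative="greater").pvalue)
        else:
            p = float("nan")
        stats_rows[community] = {
            "size": len(members),
            "modularity_contribution": contribution,
            "p_wilcoxon": p,
        }
    return CommunityPartition(membership, modularity,
                              pd.DataFrame(stats_rows).T)


def write_graphml(network: EnsembleNetwork, partitions: Mapping[str, CommunityPartition],
                  taxonomy_labels: Mapping[str, Mapping[str, str]] | None, path) -> None:
    """GraphML export with taxonomy/community node attributes."""
    g = network.to_networkx()
    for direction, part in partitions.items():
        for node, community in part.membership.items():
            g.nodes[node][f"community_{direction}"] = int(community)
    if taxonomy_labels:
        for node in g.nodes:
            for rank, label in taxonomy_labels.get(node, {}).items():
                g.nodes[node][rank] = label
    nx.write_graphml(g, path)
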