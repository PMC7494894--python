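"""Taxonomic over-representation of network communities, cross-network
community matching, and community-level PCA against phenotype traits.

Node mode tests each taxon against each eligible community (>= 3 nodes by
default) with a 2x2 table splitting the network's nodes by community and
taxon membership; edge mode does the same for unordered taxon-pair edge
types against the community's induced subgraph. In both modes the BH
denominator is the full scan grid: (#taxa or #edge types) x (#eligible
communities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, SampleMetadata, TaxonomyTable, bh_adjust, fisher_one_sided
from .network import CommunityPartition, EnsembleNetwork
from .ordination import pca, size_factors, trait_correlation, vst
from .diffabund import fit_dispersion

_DEFAULT_MIN_COMMUNITY = 3


@dataclass
class CommunityEnrichment:
    network: str
    community: int
    taxon: str  # a label (node mode) or "A|B" unordered pair (edge mode)
    rank: str
    a: int
    b: int
    c: int
    d: int
    p: float
    p_adj: float = float("nan")


def _eligible(partition: CommunityPartition, min_size: int) -> list[int]:
    sizes = pd.Series(partition.membership).value_counts()
    return sorted(int(c) for c in sizes.index[sizes >= min_size])


def node_ora(
    partition: CommunityPartition,
    taxonomy: TaxonomyTable,
    rank: str,
    network_label: str = "",
    min_community_size: int = _DEFAULT_MIN_COMMUNITY,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Taxon-within-community enrichment against the network's nodes.

    ``universe`` is the network's full node set ("within versus outside a
    community" counts isolated nodes as outside); it defaults to the
    partitioned nodes when not given.
    """
    nodes = set(universe) if universe is not None else set(partition.membership)
    nodes |= set(partition.membership)
    if not nodes:
        return _empty()
    labels = taxonomy.labels_at(rank).reindex(sorted(nodes))
    taxa = {t: set(g) for t, g in labels.groupby(labels).groups.items()}
    eligible = _eligible(partition, min_community_size)
    n_tests = len(taxa) * len(eligible)
    rows = []
    for community in eligible:
        members = partition.members(community)
        for taxon in sorted(taxa):
            t = taxa[taxon]
            a = len(t & members)
            b = len(members - t)
            c = len(t - members)
            d = len(nodes) - a - b - c
            rows.append(CommunityEnrichment(
                network_label, community, str(taxon), rank, a, b, c, d,
                fisher_one_sided(a, b, c, d)))
    return _finalize(rows, n_tests)


def edge_ora(
    network: EnsembleNetwork,
    partition: CommunityPartition,
    taxonomy: TaxonomyTable,
    rank: str,
    direction: str = "co-occurrence",
    min_community_size: int = _DEFAULT_MIN_COMMUNITY,
) -> pd.DataFrame:
    """Taxon-pair edge-type enrichment within each community's subgraph.

    Edge types are enumerated from edges present in the subgraph (self-pairs
    ``A|A`` are valid types); absent types are not tested.
    """
    edges = network.subgraph_edges(direction)
    if not edges:
        return _empty()
    labels = taxonomy.labels_at(rank)
    typed = []
    for e in edges:
        a, b = e.pair
        t = tuple(sorted((str(labels.get(a, "?")), str(labels.get(b, "?")))))
        typed.append((e.pair, "|".join(t)))
    edge_types = sorted({t for _, t in typed})
    eligible = _eligible(partition, min_community_size)
    n_tests = len(edge_types) * len(eligible)
    rows = []
    total = len(typed)
    for community in eligible:
        members = partition.members(community)
        inside = [(pair, t) for pair, t in typed
                  if pair[0] in members and pair[1] in members]
        inside_count = pd.Series([t for _, t in inside]).value_counts()
        all_count = pd.Series([t for _, t in typed]).value_counts()
        n_inside = len(inside)
        for t in edge_types:
            a = int(inside_count.get(t, 0))
            b = n_inside - a
            c = int(all_count.get(t, 0)) - a
            d = total - a - b - c
            rows.append(CommunityEnrichment(
                network.group, community, t, rank, a, b, c, d,
                fisher_one_sided(a, b, c, d)))
    return _finalize(rows, n_tests)


def _empty() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "network", "community", "taxon", "rank", "a", "b", "c", "d", "p", "p_adj"
    ])


def _finalize(rows, n_tests: int) -> pd.DataFrame:
    if not rows:
        return _empty()
    df = pd.DataFrame([vars(r) for r in rows])
    df["p_adj"] = bh_adjust(df["p"].to_numpy(), n_tests=max(n_tests, len(df)))
    return df.sort_values(["p_adj", "p", "community", "taxon"],
                          kind="stable").reset_index(drop=True)


def significance_stars(p_adj: float) -> str:
    """Fig-style significance stars at 0.05 / 0.01 / 0.001 / 0.0001."""
    if not np.isfinite(p_adj):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p_adj <= cut:
            return stars
    return ""


def jaccard_match(
    partitions: Mapping[str, CommunityPartition]
) -> pd.DataFrame:
    """Jaccard index for every cross-network community pair.

    Communities are compared as ASV sets; a row per (network_a, community_a,
    network_b, community_b) with ``jaccard = |A & B| / |A | B|``. Pairs of
    empty communities are skipped.
    """
    rows = []
    names = sorted(partitions)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            pa, pb = partitions[na], partitions[nb]
            for ca in pa.communities:
                sa = pa.members(ca)
                for cb in pb.communities:
                    sb = pb.members(cb)
                    union = sa | sb
                    if not union:
                        continue
                    rows.append({
                        "network_a": na, "community_a": ca,
                        "network_b": nb, "community_b": cb,
                        "jaccard": len(sa & sb) / len(union),
                    })
    return pd.DataFrame(rows, columns=["network_a", "community_a",
                                       "network_b", "community_b", "jaccard"])


def community_trait_pca(
    counts: CountTable,
    community: set[str],
    metadata: SampleMetadata,
    dispersion_trend: tuple[float, float] | None = None,
) -> tuple[pd.Series, pd.DataFrame] | None:
    """PC1 of the community's VST-normalized member profiles, correlated
    against weight, score and dpi.

    Returns ``None`` (skipped) for communities of fewer than 2 members or
    with constant normalized profiles.
    """
    members = sorted(community & set(counts.features))
    if len(members) < 2:
        return None
    sf = size_factors(counts)
    if dispersion_trend is None:
        _, dispersion_trend = fit_dispersion(counts, sf)
    normalized = vst(counts, sf, dispersion_trend)
    sub = normalized.values.loc[members]
    if np.allclose(sub.to_numpy().std(axis=1), 0):
        return None
    scores, _ = pca(sub, n_components=1)
    pc1 = scores["PC1"]
    meta = metadata.table.reindex(pc1.index)
    rows = {}
    for trait in ("weight", "score", "dpi"):
        v = meta[trait].to_numpy(dtype=float)
        if np.std(v) == 0:
            rows[trait] = {"r": np.nan, "p": np.nan}
            continue
        r, p = trait_correlation(pc1.to_numpy(), v)
        rows[trait] = {"r": r, "p": p}
    return pc1, pd.DataFrame(rows).T.rename_axis("trait")
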