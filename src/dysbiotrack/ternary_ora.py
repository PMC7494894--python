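"""Fisher-exact over-representation of ternary trajectory patterns among the
ASVs of each taxon.

For one testing framework, every ASV carries a single ternary pattern; each
(taxon, observed pattern) pair is tested with a one-sided Fisher exact test
on the 2x2 table splitting the ASV universe by taxon membership and pattern
membership. BH correction uses ``n = (#taxa at the rank) x (#observed
patterns)`` as the denominator — the full grid of tests the scan ranges
over, not just the realized ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import TaxonomyTable, bh_adjust, fisher_one_sided


@dataclass
class PatternEnrichment:
    """One taxon x pattern contingency result."""

    taxon: str
    rank: str
    pattern: str
    a: int  # taxon & pattern
    b: int  # taxon only
    c: int  # pattern only
    d: int  # neither
    p: float
    p_adj: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def pattern_census(asv_patterns: Mapping[str, str]) -> dict[str, set[str]]:
    """Partition ASVs by ternary pattern label (one framework)."""
    census: dict[str, set[str]] = {}
    for asv, pattern in asv_patterns.items():
        census.setdefault(pattern, set()).add(asv)
    return census


def enrich(
    taxon_members: set[str],
    pattern_members: set[str],
    universe: set[str],
    taxon: str = "",
    rank: str = "",
    pattern: str = "",
) -> PatternEnrichment:
    """One-sided Fisher enrichment of ``pattern_members`` within
    ``taxon_members`` against ``universe``."""
    if not taxon_members <= universe or not pattern_members <= universe:
        raise ValueError("member sets must be subsets of the universe")
    a = len(taxon_members & pattern_members)
    b = len(taxon_members - pattern_members)
    c = len(pattern_members - taxon_members)
    d = len(universe) - a - b - c
    p = fisher_one_sided(a, b, c, d)
    return PatternEnrichment(taxon, rank, pattern, a, b, c, d, p)


def ora_all(
    asv_patterns: Mapping[str, str],
    taxonomy: TaxonomyTable,
    rank: str,
) -> pd.DataFrame:
    """Test every (taxon at ``rank``) x (observed pattern) pair.

    Only patterns realized by at least one ASV are tested. The BH
    denominator is ``(#taxa at rank among the universe) x (#observed
    patterns)``. Returns a DataFrame sorted by adjusted p-value.
    """
    universe = set(asv_patterns)
    census = pattern_census(asv_patterns)
    labels = taxonomy.labels_at(rank).reindex(sorted(universe))
    taxa = labels.groupby(labels).groups  # label -> ASV index
    n_tests = len(taxa) * len(census)
    rows = []
    for taxon in sorted(taxa):
        members = set(taxa[taxon])
        for pattern in sorted(census):
            e = enrich(members, census[pattern], universe,
                       taxon=taxon, rank=rank, pattern=pattern)
            rows.append(e)
    if not rows:
        return pd.DataFrame(
            columns=["taxon", "rank", "pattern", "a", "b", "c", "d", "p", "p_adj"]
        )
    df = pd.DataFrame([vars(e) for e in rows])
    df["p_adj"] = bh_adjust(df["p"].to_numpy(), n_tests=n_tests)
    return df.sort_values(["p_adj", "p", "taxon", "pattern"],
                          kind="stable").reset_index(drop=True)
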