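"""Domain types, TSV readers/writers, taxonomic agglomeration, and shared
statistical primitives.

The universal currency of the pipeline is the :class:`CountTable`, an integer
feature x sample matrix at a given taxonomic rank (or "ASV"/"functional").
Taxonomy is a 6-rank lineage map (phylum..species) per ASV, with ambiguous
ranks carried as explicit ``<parent>_NA`` designations rather than blanks.

Two statistical primitives used by every over-representation stage live here:
a Benjamini-Hochberg step-up adjustment that accepts a denominator larger
than the number of observed p-values (the pipeline corrects enrichment scans
against taxa x patterns totals, not just the realized tests), and a one-sided
(enrichment) Fisher exact test on 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Taxonomic ranks from coarsest to finest, excluding the ASV level.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

TREATMENTS: tuple[str, ...] = ("naive", "CFA", "EAE")

#: The study design's sampling days relative to immunization.
DESIGN_DAYS: tuple[int, ...] = (-2, 8, 14, 19, 29)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Integer feature x sample abundance matrix with a rank label.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, features as the index, samples as
        columns. Identifiers must be unique on both axes.
    rank
        One of :data:`RANKS`, ``"ASV"``, or ``"functional"``.
    """

    counts: pd.DataFrame
    rank: str = "ASV"

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        if self.counts.shape[0] == 0:
            raise ValueError("no features")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature identifier: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    "non-integer count at row "
                    f"{self.counts.index[bad[0]]!r}, column "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at row {self.counts.index[bad[0]]!r}, "
                f"column {self.counts.columns[bad[1]]!r}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[:, list(samples)].copy(), rank=self.rank)


@dataclass
class TaxonomyTable:
    """Per-ASV lineage map over the six ranks phylum..species.

    Ambiguity at a rank is encoded as ``"<next-available-identifier>_NA"``
    (e.g. an ASV of known family but unknown genus carries genus
    ``"Lactobacillaceae_NA"``); empty strings are invalid.
    """

    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise ValueError(f"taxonomy table missing rank columns: {missing}")
        if self.lineages.index.duplicated().any():
            raise ValueError("duplicate ASV identifier in taxonomy")
        block = self.lineages[list(RANKS)]
        if (block == "").any().any() or block.isna().any().any():
            raise ValueError("empty taxonomy labels are invalid; use '<parent>_NA'")

    @property
    def asvs(self) -> list[str]:
        return list(self.lineages.index)

    def labels_at(self, rank: str) -> pd.Series:
        """Disambiguated taxon label per ASV at ``rank``.

        Taxa are keyed on the full lineage prefix: two ASVs sharing a label at
        ``rank`` but differing at a coarser rank are kept distinct (the
        coarser rank's disambiguated label is prepended with ``';'``).
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        idx = RANKS.index(rank)
        prefix = self.lineages[list(RANKS[: idx + 1])]
        labels = prefix[rank].copy()
        # detect label collisions across distinct lineage prefixes
        tuples = prefix.apply(tuple, axis=1)
        by_label = tuples.groupby(labels)
        for label, group in by_label:
            if group.nunique() > 1:
                parents = prefix.iloc[:, :-1].apply(
                    lambda row: ";".join(row), axis=1
                )
                mask = labels == label
                labels.loc[mask] = parents.loc[mask] + ";" + label
        return labels


@dataclass
class SampleMetadata:
    """Per-sample design covariates: treatment, day post-immunization,
    body weight (g) and clinical score."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"treatment", "dpi", "weight", "score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad = set(self.table["treatment"]) - set(TREATMENTS)
        if bad:
            raise ValueError(f"unknown treatment labels: {sorted(bad)}")
        if (self.table["score"] < 0).any():
            raise ValueError("clinical scores must be >= 0")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample identifier in metadata")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def select(self, treatment: str | None = None, dpi: int | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if treatment is not None:
            mask &= self.table["treatment"] == treatment
        if dpi is not None:
            mask &= self.table["dpi"] == dpi
        return list(self.table.index[mask])


@dataclass
class TestResult:
    """Raw and BH-adjusted p-values with the underlying statistic."""

    p_values: np.ndarray
    adjusted: np.ndarray
    statistic: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        a = np.asarray(self.adjusted, dtype=float)
        ok = np.isfinite(p) & np.isfinite(a)
        if np.any(a[ok] + 1e-12 < p[ok]):
            raise ValueError("adjusted p-values must be >= raw p-values")
        if np.any((a[ok] < 0) | (a[ok] > 1)):
            raise ValueError("adjusted p-values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_INDEX_LABEL = "feature_id"


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    return df


def read_count_table(path, rank: str = "ASV") -> CountTable:
    """Read a tab-separated count matrix (feature ids in column 1, sample ids
    in the header row). ``#`` comment lines are ignored.

    Raises a hard error on duplicate identifiers and on negative or
    non-integer cells, naming the offending row/column.
    """
    try:
        df = _read_tsv(path)
    except pd.errors.EmptyDataError:
        raise ValueError("no features") from None
    if df.shape[0] == 0:
        raise ValueError("no features")
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for row, raw in df[col].items():
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at row {row!r}, column {col!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"negative count {raw!r} at row {row!r}, column {col!r}"
                )
            parsed.at[row, col] = value
    parsed.index.name = _INDEX_LABEL
    return CountTable(parsed.astype(np.int64), rank=rank)


def write_count_table(table: CountTable, path) -> None:
    """Write the canonical TSV dialect (UTF-8, tab-separated, feature ids in
    column 1 under the header ``feature_id``). ``write . read`` is the
    identity on this dialect."""
    df = table.counts.copy()
    df.index.name = _INDEX_LABEL
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    df.index.name = "asv_id"
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    df = taxonomy.lineages.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "sample_id"
    df["dpi"] = df["dpi"].astype(int)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def agglomerate(counts: CountTable, taxonomy: TaxonomyTable, rank: str) -> CountTable:
    """Sum ASV counts sharing a lineage prefix at ``rank``.

    NA-designated labels are taxa in their own right and never merge with the
    unambiguous taxon they derive from. Column (per-sample) totals are
    conserved exactly.
    """
    if counts.rank != "ASV":
        raise ValueError("agglomeration starts from an ASV-rank table")
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    missing = set(counts.features) - set(taxonomy.asvs)
    if missing:
        raise ValueError(
            f"ASVs missing from taxonomy: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    labels = taxonomy.labels_at(rank).reindex(counts.features)
    grouped = counts.counts.groupby(labels, sort=True).sum()
    grouped.index.name = _INDEX_LABEL
    return CountTable(grouped, rank=rank)


def relative_abundance(counts: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1).

    Raises on any all-zero sample, identifying it by name.
    """
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return counts.counts / totals


def bh_adjust(p_values, n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with an explicit test count.

    ``n_tests`` may exceed ``len(p_values)`` — the enrichment stages correct
    against the full grid of (taxa x patterns) or (taxa x communities) tests,
    of which only the realized ones carry p-values. Adjusted values are
    clipped to 1. Ties are broken by a stable sort on input position.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if n_tests is None:
        n_tests = m
    if n_tests < m:
        raise ValueError(f"n_tests ({n_tests}) < number of p-values ({m})")
    if m == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n_tests / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment / upper tail of ``a``) Fisher exact test on the
    2x2 table ``[[a, b], [c, d]]``.

    Returns ``P(X >= a)`` under the hypergeometric distribution with the
    table's margins fixed.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entry {name}={v} must be a non-negative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    total = a + b + c + d
    if total == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, total, a + b, a + c))
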