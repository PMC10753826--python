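"""ASV-table containers, TSV readers/writers, and sample-level preprocessing.

The pipeline starts from a denoised ASV count table (features x samples),
SILVA-style taxonomy strings and a sample-metadata sheet.  Preprocessing
follows the standard amplicon hygiene sequence for host-associated
communities sequenced alongside no-template controls:

1. drop every ASV observed in any no-template control (and the controls),
2. drop every ASV not classified to the Bacteria kingdom,
3. total-sum scaling (TSS) to per-sample proportions,
4. agglomerate ASVs to genus, folding unassigned / placeholder genera
   (``uncultured``, ``metagenome`` ...) into a single ``unassigned`` row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNASSIGNED",
    "RANKS",
    "SAMPLE_TYPES",
    "CLADES",
    "DEFAULT_PLACEHOLDER_TOKENS",
    "AsvCountTable",
    "RelAbundanceTable",
    "TaxonomyTable",
    "SampleMetadata",
    "read_asv_table",
    "read_taxonomy",
    "read_metadata",
    "remove_control_contaminants",
    "filter_nonbacterial",
    "tss_normalize",
    "agglomerate_genus",
    "preprocess",
]

#: Token used for any rank that carries no assignment.
UNASSIGNED = "unassigned"

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

SAMPLE_TYPES = ("mycelium", "sclerotia", "fruiting_body", "control")
CLADES = ("Elata", "Esculenta", "Rufobrunnea", "unknown")

#: Genus tokens that name a sequencing artefact rather than a genus; they are
#: folded into the ``unassigned`` bucket during agglomeration.
DEFAULT_PLACEHOLDER_TOKENS = frozenset(
    {
        UNASSIGNED,
        "uncultured",
        "uncultured bacterium",
        "metagenome",
        "unidentified",
        "unknown",
        "ambiguous_taxa",
    }
)


class ParseError(ValueError):
    """Raised when an input file violates the expected TSV dialect."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class AsvCountTable:
    """Non-negative integer counts, features x samples."""

    counts: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "feature")
        _check_unique(list(self.counts.columns), "sample")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ParseError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            raise ParseError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    def equals(self, other: "AsvCountTable") -> bool:
        return self.counts.equals(other.counts)


@dataclass
class RelAbundanceTable:
    """Per-sample proportions on the same axes as :class:`AsvCountTable`.

    Every sample column sums to 1 (within 1e-9); enforced at construction.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if arr.size:
            if (arr < -1e-12).any() or (arr > 1 + 1e-9).any():
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = arr.sum(axis=0)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                sample = self.values.columns[bad[0]]
                raise ValueError(
                    f"sample {sample!r} does not sum to 1 (got {sums[bad[0]]!r})"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


@dataclass
class TaxonomyTable:
    """feature id -> 7-rank lineage (kingdom .. species).

    Unassigned ranks carry the explicit :data:`UNASSIGNED` token, never an
    empty string.
    """

    ranks: pd.DataFrame  # index = feature ids, columns = RANKS

    def __post_init__(self) -> None:
        missing = [c for c in RANKS if c not in self.ranks.columns]
        if missing:
            raise ParseError(f"taxonomy table missing ranks: {missing}")
        self.ranks = self.ranks.loc[:, list(RANKS)].astype(str)
        self.ranks = self.ranks.where(self.ranks.ne(""), UNASSIGNED)
        _check_unique(list(self.ranks.index), "feature")

    def rank_of(self, feature_id: str, rank: str) -> str:
        if feature_id not in self.ranks.index:
            return UNASSIGNED
        return str(self.ranks.at[feature_id, rank])

    def genus_of(self, feature_id: str) -> str:
        return self.rank_of(feature_id, "genus")

    def to_tsv(self, path: str | Path) -> None:
        lineage = self.ranks.apply(";".join, axis=1)
        out = pd.DataFrame({"feature_id": lineage.index, "lineage": lineage.values})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class SampleMetadata:
    """sample id -> (sample_type, clade, specimen_id)."""

    table: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        for col in ("sample_type", "clade", "specimen_id"):
            if col not in self.table.columns:
                raise ParseError(f"metadata missing column {col!r}")
        _check_unique(list(self.table.index), "sample")
        bad_type = set(self.table["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ParseError(f"unknown sample_type values: {sorted(bad_type)}")
        bad_clade = set(self.table["clade"]) - set(CLADES)
        if bad_clade:
            raise ParseError(f"unknown clade values: {sorted(bad_clade)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def sample_type(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "sample_type"])

    def samples_of_type(self, sample_type: str) -> list[str]:
        mask = self.table["sample_type"] == sample_type
        return list(self.table.index[mask])

    @property
    def control_ids(self) -> list[str]:
        return self.samples_of_type("control")

    def groups(self, column: str = "sample_type") -> pd.Series:
        return self.table[column]

    def covers(self, sample_ids: Iterable[str]) -> bool:
        return set(sample_ids) <= set(self.table.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_asv_table(path: str | Path) -> AsvCountTable:
    """Read a features x samples count TSV (first column = feature id).

    ``#`` comment lines are ignored, so the BIOM "# Constructed from biom
    file" TSV dialect parses unchanged.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a feature-id column plus >=1 sample")
    raw = raw.set_index(raw.columns[0])
    try:
        counts = raw.astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer count ({exc})") from None
    return AsvCountTable(counts)


_LINEAGE_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a semicolon lineage into exactly 7 ranks.

    SILVA ``D_0__``/Greengenes ``k__`` style prefixes are stripped; missing or
    empty trailing ranks become :data:`UNASSIGNED`.
    """
    parts = [p.strip() for p in lineage.split(";")]
    cleaned: list[str] = []
    for p in parts:
        if p.startswith("D_") and "__" in p:
            p = p.split("__", 1)[1]
        else:
            for pref in _LINEAGE_PREFIXES:
                if p.startswith(pref):
                    p = p[len(pref):]
                    break
        cleaned.append(p if p else UNASSIGNED)
    cleaned = cleaned[:7]
    cleaned += [UNASSIGNED] * (7 - len(cleaned))
    return tuple(cleaned)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column (feature id, semicolon lineage) TSV."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected feature-id and lineage columns")
    ids = raw.iloc[:, 0]
    rows = [parse_lineage(s) for s in raw.iloc[:, 1]]
    table = pd.DataFrame(rows, index=list(ids), columns=list(RANKS))
    return TaxonomyTable(table)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a columnar metadata TSV (sample_id, sample_type, clade, specimen_id)."""
    raw = _read_tsv(path)
    if "sample_id" not in raw.columns:
        raise ParseError(f"{path}: metadata must have a 'sample_id' column")
    return SampleMetadata(raw.set_index("sample_id"))


# ---------------------------------------------------------------------------
# preprocessing operations


def remove_control_contaminants(
    table: AsvCountTable,
    meta: SampleMetadata,
    min_count: int = 1,
) -> AsvCountTable:
    """Drop every feature observed in any no-template control, then the controls.

    A feature counts as "represented" in a control when its count is at least
    ``min_count`` (default 1 — a single read in a control removes the ASV).
    With zero control samples the feature set is untouched.
    """
    if not meta.covers(table.sample_ids):
        missing = set(table.sample_ids) - set(meta.sample_ids)
        raise ValueError(f"metadata does not cover samples: {sorted(missing)}")
    controls = [s for s in table.sample_ids if meta.sample_type(s) == "control"]
    counts = table.counts
    if controls:
        contaminated = counts[controls].ge(min_count).any(axis=1)
        counts = counts.loc[~contaminated]
    keep = [s for s in counts.columns if s not in controls]
    return AsvCountTable(counts[keep].copy())


def filter_nonbacterial(table: AsvCountTable, taxonomy: TaxonomyTable) -> AsvCountTable:
    """Keep only features whose kingdom rank is ``Bacteria``.

    Features absent from the taxonomy are treated as unassigned and removed.
    """
    keep = [f for f in table.feature_ids if taxonomy.rank_of(f, "kingdom") == "Bacteria"]
    return AsvCountTable(table.counts.loc[keep].copy())


def tss_normalize(table: AsvCountTable) -> RelAbundanceTable:
    """Total-sum scaling: divide each sample's counts by its library size."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count; cannot TSS-normalize")
    return RelAbundanceTable(table.counts / totals)


def agglomerate_genus(
    rel: RelAbundanceTable,
    taxonomy: TaxonomyTable,
    placeholder_tokens: frozenset[str] | set[str] = DEFAULT_PLACEHOLDER_TOKENS,
) -> RelAbundanceTable:
    """Sum features sharing an assigned genus into one row per genus.

    Features whose genus is unassigned or a placeholder token (case-insensitive
    match against ``placeholder_tokens``) are pooled into a single
    ``unassigned`` row.  Per-sample sums are preserved exactly.
    """
    lowered = {t.lower() for t in placeholder_tokens}

    def key(feature_id: str) -> str:
        genus = taxonomy.genus_of(feature_id)
        return UNASSIGNED if genus.lower() in lowered else genus

    groups = [key(f) for f in rel.feature_ids]
    merged = rel.values.groupby(pd.Index(groups, name="genus"), sort=True).sum()
    # keep "unassigned" last for readability of exported tables
    if UNASSIGNED in merged.index:
        order = [g for g in merged.index if g != UNASSIGNED] + [UNASSIGNED]
        merged = merged.loc[order]
    return RelAbundanceTable(merged)


def preprocess(
    table: AsvCountTable,
    taxonomy: TaxonomyTable,
    meta: SampleMetadata,
    *,
    min_control_count: int = 1,
    genus_level: bool = True,
    placeholder_tokens: frozenset[str] | set[str] = DEFAULT_PLACEHOLDER_TOKENS,
) -> RelAbundanceTable:
    """Full hygiene sequence: controls -> kingdom filter -> TSS -> genus merge."""
    cleaned = remove_control_contaminants(table, meta, min_count=min_control_count)
    cleaned = filter_nonbacterial(cleaned, taxonomy)
    rel = tss_normalize(cleaned)
    if genus_level:
        rel = agglomerate_genus(rel, taxonomy, placeholder_tokens)
    return rel
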