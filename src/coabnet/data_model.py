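"""Feature tables, sample metadata, and the plumbing between them.

A :class:`FeatureTable` is a features x samples matrix of microbial
abundances (species-level relative abundances, pathway read counts,
metabolite intensities, or phenotype measurements) together with the
feature kind and measurement scale.  Samples are aligned to
:class:`SampleMeta` records carrying calf id, treatment group, sampling
day and sequencing depth, which drive subgrouping and count
reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("CON", "RMT", "RFT")
DAYS = (15, 35, 56)

KINDS = ("species", "pathway", "resistance_gene", "virulence_gene", "metabolite", "phenotype")
SCALES = ("relative", "count", "intensity", "raw")

#: tolerance for "relative abundances sum to <= 1" checks
_REL_SUM_TOL = 1e-6


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one stool/blood sample.

    ``total_reads`` is the host-filtered paired-read count used to
    reconstruct predicted read counts from relative abundances.
    """

    sample_id: str
    calf_id: str
    group: str
    day: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for sample {self.sample_id!r}; expected one of {GROUPS}")
        if self.total_reads <= 0:
            raise ValueError(f"total_reads must be positive for sample {self.sample_id!r}")


@dataclass(frozen=True)
class Subgroup:
    """A (treatment group, sampling day) cell of the design."""

    group: str
    day: int
    sample_ids: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return f"{self.group}_d{self.day}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class FeatureTable:
    """Features x samples abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with sample ids as columns.
    kind
        What the rows are: ``species``, ``pathway``, ``metabolite`` ...
    scale
        ``relative`` (fractions in [0, 1]), ``count`` (nonnegative
        integers), ``intensity`` or ``raw``.
    """

    data: pd.DataFrame
    kind: str = "species"
    scale: str = "relative"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("feature table contains negative values")
        if self.scale == "relative" and values.size:
            colsums = np.nansum(values, axis=0)
            if np.any(colsums > 1 + _REL_SUM_TOL):
                bad = self.data.columns[colsums > 1 + _REL_SUM_TOL].tolist()
                raise ValueError(f"relative-abundance columns sum to > 1: {bad}")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(), kind=self.kind, scale=self.scale)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), kind=self.kind, scale=self.scale)

    def write(self, path: str | Path, feature_col: str = "feature_id") -> None:
        """Write as plain feature x sample TSV."""
        out = self.data.copy()
        out.index.name = feature_col
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# reading


def species_leaf(clade: str) -> str:
    """Reduce a MetaPhlAn-style lineage to its terminal clade.

    ``k__Bacteria|...|s__Bacteroides_fragilis`` -> ``s__Bacteroides_fragilis``.
    Plain ids pass through unchanged.
    """
    return clade.split("|")[-1].strip()


def read_feature_table(path: str | Path, kind: str = "species", scale: str | None = None) -> FeatureTable:
    """Read a tab-separated feature x sample table.

    First column holds feature ids; remaining columns are samples.
    Lines starting with ``#`` are treated as comments, except a leading
    ``#``-prefixed header row (the MetaPhlAn merged-table dialect), which
    is used as the header.  For ``kind='species'`` MetaPhlAn lineage
    strings are reduced to their terminal clade.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    # MetaPhlAn merged tables start the header with '#'; other '#' lines are comments
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line.lstrip("#").split("\t")
            if len(fields) > 1:
                header_idx = i
                lines[i] = line.lstrip("#")
                break
            continue
        header_idx = i
        break
    if header_idx is None:
        raise ValueError(f"{path}: no header line found")
    body = [l for l in lines[header_idx:] if l.strip() and not l.startswith("#")]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    if kind == "species":
        df.index = [species_leaf(f) for f in df.index]
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}")
        numeric[col] = converted
    if scale is None:
        vals = numeric.to_numpy(dtype=float)
        colsums = np.nansum(vals, axis=0)
        scale = "relative" if vals.size and np.all(colsums <= 1 + _REL_SUM_TOL) else "count"
        if kind == "metabolite":
            scale = "intensity"
        elif kind == "phenotype":
            scale = "raw"
    return FeatureTable(numeric, kind=kind, scale=scale)


METADATA_COLUMNS = ("sample_id", "calf_id", "group", "day", "total_reads")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV with header ``sample_id calf_id group day total_reads``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "calf_id": str, "group": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    meta = [
        SampleMeta(
            sample_id=row.sample_id,
            calf_id=row.calf_id,
            group=row.group,
            day=int(row.day),
            total_reads=int(row.total_reads),
        )
        for row in df.itertuples()
    ]
    seen: set[tuple[str, int]] = set()
    for m in meta:
        key = (m.calf_id, m.day)
        if key in seen:
            raise ValueError(f"{path}: duplicate (calf_id, day) pair {key}")
        seen.add(key)
    return meta


def write_metadata(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.calf_id, m.group, m.day, m.total_reads) for m in meta],
        columns=list(METADATA_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def meta_by_sample(meta: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


# ---------------------------------------------------------------------------
# operations


def align_samples(table: FeatureTable, meta: Sequence[SampleMeta]) -> tuple[FeatureTable, list[SampleMeta]]:
    """Restrict table and metadata to their shared samples (order of the table).

    Dropped columns are logged as warnings, never an error: the study
    design tolerates missing samples.
    """
    lookup = meta_by_sample(meta)
    shared = [s for s in table.sample_ids if s in lookup]
    dropped_cols = [s for s in table.sample_ids if s not in lookup]
    if dropped_cols:
        logger.warning("dropping %d table samples without metadata: %s", len(dropped_cols), dropped_cols)
    dropped_meta = sorted(set(lookup) - set(shared))
    if dropped_meta:
        logger.warning("metadata samples absent from table: %s", dropped_meta)
    return table.subset_samples(shared), [lookup[s] for s in shared]


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.10) -> FeatureTable:
    """Keep features present (value > 0) in strictly more than ``min_fraction`` of samples.

    The threshold is strict, so a feature present in exactly 10% of
    samples is removed at ``min_fraction=0.10``.  Feature order is
    preserved.  An empty result warns rather than raising.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    vals = table.values
    prevalence = (vals > 0).sum(axis=1) / max(table.n_samples, 1)
    keep = prevalence > min_fraction
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return FeatureTable(table.data.loc[keep].copy(), kind=table.kind, scale=table.scale)


def to_counts(table: FeatureTable, meta: Sequence[SampleMeta]) -> FeatureTable:
    """Reconstruct predicted read counts from relative abundances.

    count[i, j] = round(rel[i, j] * total_reads[j]) with round-half-to-even.
    """
    if table.scale != "relative":
        raise ValueError(f"to_counts expects a relative-scale table, got {table.scale!r}")
    lookup = meta_by_sample(meta)
    missing = [s for s in table.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"no total_reads for samples: {missing}")
    depths = np.array([lookup[s].total_reads for s in table.sample_ids], dtype=float)
    counts = np.rint(table.values * depths[np.newaxis, :])
    return FeatureTable(
        pd.DataFrame(counts, index=table.data.index, columns=table.data.columns),
        kind=table.kind,
        scale="count",
    )


def split_subgroups(table: FeatureTable, meta: Sequence[SampleMeta]) -> list[tuple[Subgroup, FeatureTable]]:
    """Split samples into one sub-table per observed (group, day) pair.

    Every table sample must have metadata; the union of sub-table
    samples equals the input samples.  Ordering follows the canonical
    group order then ascending day.
    """
    lookup = meta_by_sample(meta)
    missing = [s for s in table.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    cells: dict[tuple[str, int], list[str]] = {}
    for s in table.sample_ids:
        m = lookup[s]
        cells.setdefault((m.group, m.day), []).append(s)
    ordered = sorted(cells, key=lambda gd: (GROUPS.index(gd[0]), gd[1]))
    out = []
    for group, day in ordered:
        samples = cells[(group, day)]
        out.append((Subgroup(group=group, day=day, sample_ids=tuple(samples)), table.subset_samples(samples)))
    return out
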