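"""Compositional and rank transforms, plus alpha/beta diversity.

The differential-testing pipeline applies a centered log-ratio (CLR)
transform per sample followed by a rank-based inverse normal transform
per feature.  Diversity measures are the Shannon index (natural log)
and Bray-Curtis dissimilarity, computed at the species level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .data_model import FeatureTable, SampleMeta, Subgroup, meta_by_sample

logger = logging.getLogger(__name__)


@dataclass
class TransformedTable:
    """A feature x sample matrix on an unconstrained (raw) scale."""

    data: pd.DataFrame
    transform_tag: str  # clr | irn | clr_irn

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def default_pseudocount(table: FeatureTable) -> float:
    """Half the smallest nonzero value in the table (standard CLR practice)."""
    vals = table.values
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero values; cannot choose a pseudocount")
    return float(nonzero.min()) / 2.0


def clr(table: FeatureTable, pseudocount: float | None = None) -> TransformedTable:
    """Centered log-ratio transform per sample.

    out[i, j] = log(x[i, j] + eps) - mean_i log(x[i, j] + eps).

    CLR maps each sample's composition to an unconstrained vector whose
    entries sum to zero, removing the unit-sum constraint that induces
    spurious negative correlations between relative abundances.
    """
    eps = default_pseudocount(table) if pseudocount is None else float(pseudocount)
    if eps <= 0:
        raise ValueError("pseudocount must be positive")
    logx = np.log(table.values + eps)
    out = logx - logx.mean(axis=0, keepdims=True)
    return TransformedTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns), "clr")


def inverse_rank(
    table: FeatureTable | TransformedTable,
    offset: Literal["rankit", "blom"] = "rankit",
) -> TransformedTable:
    """Rank-based inverse normal transform, per feature across samples.

    value = Phi^-1((rank - 0.5) / n) with average ranks for ties (the
    rankit offset; Blom's (rank - 3/8)/(n + 1/4) via ``offset``).
    Constant features map to all zeros.
    """
    vals = table.values
    n = vals.shape[1]
    out = np.empty_like(vals, dtype=float)
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.all(row == row[0]):
            logger.info("constant feature %r: inverse-rank output is all zeros", table.data.index[i])
            out[i] = 0.0
            continue
        ranks = stats.rankdata(row, method="average")
        if offset == "rankit":
            q = (ranks - 0.5) / n
        elif offset == "blom":
            q = (ranks - 3.0 / 8.0) / (n + 0.25)
        else:
            raise ValueError(f"unknown offset convention {offset!r}")
        out[i] = stats.norm.ppf(q)
    tag = "clr_irn" if getattr(table, "transform_tag", None) == "clr" else "irn"
    return TransformedTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns), tag)


def clr_inverse_rank(table: FeatureTable, pseudocount: float | None = None) -> TransformedTable:
    """CLR followed by per-feature inverse normal transform."""
    return inverse_rank(clr(table, pseudocount=pseudocount))


def shannon(table: FeatureTable) -> pd.Series:
    """Per-sample Shannon index H = -sum p ln p after renormalizing to sum 1.

    All-zero samples yield NaN with a warning.
    """
    vals = table.values
    totals = vals.sum(axis=0)
    out = np.full(vals.shape[1], np.nan)
    empty = totals <= 0
    if empty.any():
        warnings.warn(f"all-zero samples have undefined Shannon index: "
                      f"{[table.sample_ids[j] for j in np.flatnonzero(empty)]}", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = vals / totals[np.newaxis, :]
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    out[~empty] = -plogp[:, ~empty].sum(axis=0)
    return pd.Series(out, index=table.sample_ids, name="shannon")


def bray_curtis(table: FeatureTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity: sum|a-b| / sum(a+b).

    Symmetric with a zero diagonal; a pair of all-zero samples has an
    undefined (NaN) entry.
    """
    vals = table.values.T  # samples x features
    totals = vals.sum(axis=1)
    dm = squareform(pdist(vals, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    empty = np.flatnonzero(totals <= 0)
    for i in empty:
        for j in empty:
            if i != j:
                dm[i, j] = np.nan
    return pd.DataFrame(dm, index=table.sample_ids, columns=table.sample_ids)


def within_group_dissimilarity(bc: pd.DataFrame, meta: Sequence[SampleMeta]) -> dict[Subgroup, list[float]]:
    """All pairwise Bray-Curtis values among each subgroup's samples.

    Each unordered pair contributes once; subgroups of size < 2 give an
    empty list.  Used to compare inter-calf community variability
    between treatment groups over time.
    """
    lookup = meta_by_sample(meta)
    cells: dict[tuple[str, int], list[str]] = {}
    for s in bc.index:
        if s in lookup:
            m = lookup[s]
            cells.setdefault((m.group, m.day), []).append(s)
    out: dict[Subgroup, list[float]] = {}
    for (group, day), samples in sorted(cells.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        sg = Subgroup(group=group, day=day, sample_ids=tuple(samples))
        vals = []
        for a_idx in range(len(samples)):
            for b_idx in range(a_idx + 1, len(samples)):
                vals.append(float(bc.loc[samples[a_idx], samples[b_idx]]))
        out[sg] = vals
    return out
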