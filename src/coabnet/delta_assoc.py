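"""Within-calf change scores and microbe-trait association screening.

Changes (deltas) between two sampling days are computed per calf for
microbial features (on the CLR scale), metabolites (log intensities)
and phenotypes (raw).  Microbial deltas are screened against trait
deltas with Spearman correlation; the screening rule flags |rho| > 0.7
at P < 0.01, and an association is called specific to a focal group
(default RMT) when it is significant there and every other group is
either non-significant or correlated in the opposite direction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FeatureTable, SampleMeta, meta_by_sample
from .transforms import TransformedTable

logger = logging.getLogger(__name__)


@dataclass
class DeltaTable:
    """Features x calves matrix of value(day_b) - value(day_a)."""

    data: pd.DataFrame  # index: features, columns: calf ids
    interval: tuple[int, int]
    scale_tag: str = "raw"
    group_of: dict[str, str] | None = None  # calf -> group

    @property
    def calves(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DeltaAssociation:
    microbial_feature: str
    trait: str
    interval: tuple[int, int]
    group_scope: str  # pooled | CON | RMT | RFT
    r: float
    p: float
    n: int
    significant: bool
    specific: bool = False


# ---------------------------------------------------------------------------


def compute_deltas(
    table: FeatureTable | TransformedTable,
    meta: Sequence[SampleMeta],
    day_a: int,
    day_b: int,
    scale_tag: str = "raw",
) -> DeltaTable:
    """Per-calf change value(day_b) - value(day_a) for calves observed at both days."""
    if day_a >= day_b:
        raise ValueError("day_a must precede day_b")
    lookup = meta_by_sample(meta)
    at_day: dict[int, dict[str, str]] = {day_a: {}, day_b: {}}
    for s in table.data.columns:
        m = lookup.get(s)
        if m is not None and m.day in at_day:
            at_day[m.day][m.calf_id] = s
    shared = sorted(set(at_day[day_a]) & set(at_day[day_b]))
    skipped = sorted((set(at_day[day_a]) | set(at_day[day_b])) - set(shared))
    if skipped:
        logger.info("calves missing one of days %d/%d excluded from deltas: %s", day_a, day_b, skipped)
    cols_a = [at_day[day_a][c] for c in shared]
    cols_b = [at_day[day_b][c] for c in shared]
    delta = table.data[cols_b].to_numpy(dtype=float) - table.data[cols_a].to_numpy(dtype=float)
    group_of = {c: lookup[at_day[day_a][c]].group for c in shared}
    return DeltaTable(
        data=pd.DataFrame(delta, index=table.data.index, columns=shared),
        interval=(day_a, day_b),
        scale_tag=scale_tag,
        group_of=group_of,
    )


@lru_cache(maxsize=16)
def _exact_spearman_null(n: int) -> np.ndarray:
    """All |rho| values over the n! rank permutations (tie-free null)."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1)
    out = np.empty(math.factorial(n))
    for k, perm in enumerate(itertools.permutations(range(1, n + 1))):
        d2 = np.sum((base - np.asarray(perm, dtype=float)) ** 2)
        out[k] = 1 - 6 * d2 / denom
    return np.abs(out)


def spearman_with_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with an exact permutation p for small tie-free samples.

    For n <= ``exact_max_n`` without ties, the two-sided p is the exact
    fraction of the n! rank permutations with |rho| at least as large as
    observed; otherwise the t-distribution approximation is used.
    """
    n = len(x)
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        return float("nan"), float("nan")
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not has_ties:
        null = _exact_spearman_null(n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
        return float(rho), p
    return float(rho), float(stats.spearmanr(x, y).pvalue)


def spearman_screen(
    micro_deltas: DeltaTable,
    trait_deltas: DeltaTable,
    r_min: float = 0.7,
    p_max: float = 0.01,
    scope: str = "pooled",
) -> list[DeltaAssociation]:
    """Screen every microbial-feature x trait delta pair by Spearman correlation.

    ``scope`` restricts the shared calves to one treatment group (or
    pools all).  The screen requires at least 5 shared calves; the
    ``significant`` flag applies the dual threshold |rho| > r_min and
    p < p_max.  Constant vectors are skipped with missing rho.
    """
    shared = [c for c in micro_deltas.calves if c in set(trait_deltas.calves)]
    if scope != "pooled":
        if micro_deltas.group_of is None:
            raise ValueError("group information required for group-scoped screening")
        shared = [c for c in shared if micro_deltas.group_of.get(c) == scope]
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared calves in scope {scope!r}, have {len(shared)}")
    out: list[DeltaAssociation] = []
    micro = micro_deltas.data[shared].to_numpy(dtype=float)
    traits = trait_deltas.data[shared].to_numpy(dtype=float)
    for i, feat in enumerate(micro_deltas.data.index):
        x = micro[i]
        if np.all(x == x[0]):
            logger.info("constant microbial delta %r skipped", feat)
            continue
        for j, trait in enumerate(trait_deltas.data.index):
            y = traits[j]
            if np.all(y == y[0]):
                continue
            rho, p = spearman_with_p(x, y)
            sig = bool(np.isfinite(rho) and abs(rho) > r_min and p < p_max)
            out.append(
                DeltaAssociation(
                    microbial_feature=str(feat),
                    trait=str(trait),
                    interval=micro_deltas.interval,
                    group_scope=scope,
                    r=rho,
                    p=p,
                    n=len(shared),
                    significant=sig,
                )
            )
    return out


def call_group_specific(
    per_group: dict[str, DeltaAssociation | None],
    focal: str = "RMT",
) -> bool:
    """Is the association specific to the focal group?

    True iff the focal group's association is significant and every
    other group is either not significant or significant with the
    opposite sign.  Missing group estimates count as not significant.
    """
    focal_assoc = per_group.get(focal)
    if focal_assoc is None or not focal_assoc.significant:
        return False
    for g, assoc in per_group.items():
        if g == focal:
            continue
        if assoc is None:
            logger.info("missing estimate for group %s treated as not significant", g)
            continue
        if assoc.significant and np.sign(assoc.r) == np.sign(focal_assoc.r):
            return False
    return True


def screen_all_groups(
    micro_deltas: DeltaTable,
    trait_deltas: DeltaTable,
    groups: Sequence[str] = ("CON", "RMT", "RFT"),
    r_min: float = 0.7,
    p_max: float = 0.01,
    focal: str = "RMT",
) -> pd.DataFrame:
    """Per-group screening plus focal-group specificity calls, as a tidy frame."""
    per_group: dict[str, dict[tuple[str, str], DeltaAssociation]] = {}
    for g in groups:
        try:
            assocs = spearman_screen(micro_deltas, trait_deltas, r_min=r_min, p_max=p_max, scope=g)
        except ValueError as exc:
            logger.warning("group %s skipped: %s", g, exc)
            continue
        per_group[g] = {(a.microbial_feature, a.trait): a for a in assocs}
    keys = sorted({k for d in per_group.values() for k in d})
    rows = []
    for feat, trait in keys:
        by_group = {g: per_group.get(g, {}).get((feat, trait)) for g in groups}
        specific = call_group_specific(by_group, focal=focal)
        row: dict = {"microbial_feature": feat, "trait": trait,
                     "interval": f"{micro_deltas.interval[0]}:{micro_deltas.interval[1]}"}
        for g in groups:
            a = by_group[g]
            row[f"r_{g}"] = a.r if a else np.nan
            row[f"p_{g}"] = a.p if a else np.nan
            row[f"sig_{g}"] = bool(a.significant) if a else False
        row[f"{focal}_specific"] = specific
        rows.append(row)
    return pd.DataFrame(rows)
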