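"""Synthetic longitudinal microbiome datasets with known ground truth.

The generator mirrors the study design every downstream stage assumes:
3 treatment groups (CON, RMT, RFT) x 3 sampling days (15, 35, 56) x 12
calves, compositional count tables arising from a latent log-normal
basis sampled multinomially at a realistic sequencing depth, planted
basis correlations (shared or group-specific), per-day mean shifts for
differential features, and linear microbe -> metabolite -> phenotype
mediation chains on the delta scale.  This is exactly the generative
model under which SparCC is consistent, so parameter-recovery tests on
these data are meaningful.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import DAYS, GROUPS, FeatureTable, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    Defaults reflect the study design (3 groups x 3 days x 12 calves)
    at a desk-scale feature count and depth.
    """

    n_features: int = 30
    n_calves_per_group: int = 12
    groups: tuple[str, ...] = GROUPS
    days: tuple[int, ...] = DAYS
    basis_corr: list[tuple[int, int, float]] = field(default_factory=list)
    group_specific_edges: list[tuple[int, int, dict[str, float]]] = field(default_factory=list)
    temporal_shifts: dict[int, float] = field(default_factory=dict)  # feature idx -> per-day log drift
    mediation_chains: list[tuple[int, int, int, float, float, float]] = field(default_factory=list)
    n_metabolites: int = 5
    n_phenotypes: int = 4
    depth_mean: int = 100_000
    log_mean_sd: float = 1.0  # spread of baseline mean log abundances
    basis_sd: float = 1.0  # log-scale SD of basis abundances
    noise_sd: float = 1.0  # trait noise on the delta scale, ~1 CLR unit
    dropout: int = 0  # samples removed at random to mimic incomplete designs
    seed: int = 0

    def validate(self) -> None:
        for i, j, rho in self.basis_corr:
            if not (-1 < rho < 1):
                raise ValueError(f"planted rho {rho} for pair ({i}, {j}) outside (-1, 1)")
            if not (0 <= i < self.n_features and 0 <= j < self.n_features) or i == j:
                raise ValueError(f"bad planted pair ({i}, {j})")
        for i, j, by_group in self.group_specific_edges:
            for g, rho in by_group.items():
                if g not in self.groups:
                    raise ValueError(f"unknown group {g!r} in group_specific_edges")
                if not (-1 < rho < 1):
                    raise ValueError(f"planted rho {rho} outside (-1, 1)")
        for chain in self.mediation_chains:
            mi, me, ph = chain[:3]
            if not (0 <= mi < self.n_features):
                raise ValueError(f"mediation microbe index {mi} out of range")
            if not (0 <= me < self.n_metabolites):
                raise ValueError(f"mediation metabolite index {me} out of range")
            if not (0 <= ph < self.n_phenotypes):
                raise ValueError(f"mediation phenotype index {ph} out of range")


@dataclass
class GroundTruth:
    """Planted structure, sufficient to score every pipeline stage."""

    basis_corr_by_group: dict[str, list[list[float]]]
    differential_features: list[str]
    specific_edges: list[tuple[str, str, str]]  # (feature_a, feature_b, group)
    mediation_chains: list[dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["specific_edges"] = [tuple(e) for e in d["specific_edges"]]
        return cls(**d)


# ---------------------------------------------------------------------------


def _nearest_pd(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the positive-definite cone (eigen clip)."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() > 1e-8:
        return mat
    logger.warning("planted correlation matrix not positive definite; repairing by eigenvalue clipping")
    vals = np.clip(vals, 1e-6, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _group_corr_matrix(config: SimulationConfig, group: str) -> np.ndarray:
    c = np.eye(config.n_features)
    for i, j, rho in config.basis_corr:
        c[i, j] = c[j, i] = rho
    for i, j, by_group in config.group_specific_edges:
        rho = by_group.get(group, 0.0)
        c[i, j] = c[j, i] = rho
    c = _nearest_pd(c)
    if np.linalg.eigvalsh(c).min() <= 0:
        raise ValueError("planted correlation matrix remains non-PD after repair")
    return c


def feature_names(config: SimulationConfig) -> list[str]:
    """Fake MetaPhlAn-style species ids (for parser-compatible fixtures)."""
    genera = ["Bacteroides", "Alistipes", "Bifidobacterium", "Prevotella", "Clostridium", "Faecalibacterium"]
    return [f"s__{genera[i % len(genera)]}_sp{i:03d}" for i in range(config.n_features)]


def simulate_counts(
    config: SimulationConfig,
) -> tuple[FeatureTable, list[SampleMeta], GroundTruth]:
    """Draw the full count table, metadata, and ground truth.

    Per subgroup the latent log-basis is multivariate normal with the
    group's planted correlation matrix (scaled by ``basis_sd``) around
    feature means shifted per day; counts are multinomial draws of a
    Poisson sequencing depth around ``depth_mean``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    feats = feature_names(config)
    base_means = rng.normal(0.0, config.log_mean_sd, size=config.n_features)
    corr_by_group = {g: _group_corr_matrix(config, g) for g in config.groups}
    chol_by_group = {g: np.linalg.cholesky(c) for g, c in corr_by_group.items()}

    columns: dict[str, np.ndarray] = {}
    meta: list[SampleMeta] = []
    for gi, group in enumerate(config.groups):
        chol = chol_by_group[group]
        for ci in range(config.n_calves_per_group):
            calf = f"{group}{ci + 1:02d}"
            for di, day in enumerate(config.days):
                mu = base_means.copy()
                for idx, drift in config.temporal_shifts.items():
                    mu[idx] += drift * di
                z = chol @ rng.normal(size=config.n_features)
                log_basis = mu + config.basis_sd * z
                basis = np.exp(log_basis)
                fractions = basis / basis.sum()
                depth = max(int(rng.poisson(config.depth_mean)), config.n_features)
                counts = rng.multinomial(depth, fractions)
                sample_id = f"{calf}_d{day}"
                columns[sample_id] = counts
                meta.append(SampleMeta(sample_id=sample_id, calf_id=calf, group=group,
                                       day=day, total_reads=depth))
    if config.dropout:
        drop_idx = rng.choice(len(meta), size=config.dropout, replace=False)
        dropped = {meta[i].sample_id for i in drop_idx}
        meta = [m for m in meta if m.sample_id not in dropped]
        columns = {s: v for s, v in columns.items() if s not in dropped}
        logger.info("dropped %d samples: %s", len(dropped), sorted(dropped))

    data = pd.DataFrame(columns, index=feats, dtype=float)
    table = FeatureTable(data, kind="species", scale="count")
    truth = GroundTruth(
        basis_corr_by_group={g: c.tolist() for g, c in corr_by_group.items()},
        differential_features=[feats[i] for i in sorted(config.temporal_shifts)],
        specific_edges=[
            (*sorted((feats[i], feats[j])), max(by_group, key=lambda g: abs(by_group[g])))
            for i, j, by_group in config.group_specific_edges
        ],
        mediation_chains=[
            {"microbe": feats[mi], "metabolite": f"metab_{me:02d}", "phenotype": f"pheno_{ph:02d}",
             "a": a, "b": b, "c": c}
            for mi, me, ph, a, b, c in config.mediation_chains
        ],
    )
    return table, meta, truth


def to_relative(table: FeatureTable) -> FeatureTable:
    """Normalize a count table to relative abundances (columns sum to 1)."""
    vals = table.values
    totals = vals.sum(axis=0)
    rel = vals / np.where(totals > 0, totals, 1.0)[np.newaxis, :]
    return FeatureTable(pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
                        kind=table.kind, scale="relative")


def simulate_traits(
    config: SimulationConfig,
    counts: FeatureTable,
    meta: Sequence[SampleMeta],
) -> tuple[FeatureTable, FeatureTable]:
    """Phenotype and metabolite tables realized from the mediation chains.

    Per chain, on the day-15 -> later-day delta scale: metabolite delta
    = a * (microbe CLR delta) + noise, phenotype delta = c * (microbe
    delta) + b * (metabolite delta) + noise.  Values are realized as a
    random day-15 baseline plus the accumulated delta; unchained traits
    are independent noise.
    """
    from .transforms import clr

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    rel = to_relative(counts)
    micro_clr = clr(rel, pseudocount=0.5 / config.depth_mean)
    samples = list(counts.data.columns)
    metab_names = [f"metab_{k:02d}" for k in range(config.n_metabolites)]
    pheno_names = [f"pheno_{k:02d}" for k in range(config.n_phenotypes)]
    by_sample = {m.sample_id: m for m in meta}
    base_day = min(config.days)

    # baseline per calf and trait
    calves = sorted({m.calf_id for m in meta})
    metab_base = {c: rng.normal(10.0, 1.0, size=config.n_metabolites) for c in calves}
    pheno_base = {c: rng.normal(0.0, 1.0, size=config.n_phenotypes) for c in calves}
    baseline_clr: dict[str, np.ndarray] = {}
    for s in samples:
        m = by_sample[s]
        if m.day == base_day:
            baseline_clr[m.calf_id] = micro_clr.data[s].to_numpy()

    metab = np.empty((config.n_metabolites, len(samples)))
    pheno = np.empty((config.n_phenotypes, len(samples)))
    for j, s in enumerate(samples):
        m = by_sample[s]
        metab[:, j] = metab_base[m.calf_id] + rng.normal(0, config.noise_sd, config.n_metabolites)
        pheno[:, j] = pheno_base[m.calf_id] + rng.normal(0, config.noise_sd, config.n_phenotypes)
        if m.day == base_day or m.calf_id not in baseline_clr:
            continue
        micro_delta = micro_clr.data[s].to_numpy() - baseline_clr[m.calf_id]
        for mi, me, ph, a, b, c in config.mediation_chains:
            md = a * micro_delta[mi] + rng.normal(0, config.noise_sd)
            metab[me, j] = metab_base[m.calf_id][me] + md
            pheno[ph, j] = pheno_base[m.calf_id][ph] + c * micro_delta[mi] + b * md \
                + rng.normal(0, config.noise_sd)
    metab_table = FeatureTable(pd.DataFrame(np.exp(metab), index=metab_names, columns=samples),
                               kind="metabolite", scale="intensity")
    pheno_table = FeatureTable(pd.DataFrame(pheno - pheno.min() + 1.0, index=pheno_names, columns=samples),
                               kind="phenotype", scale="raw")
    return pheno_table, metab_table
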