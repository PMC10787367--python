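"""Causal mediation analysis on within-calf delta scores.

Triads (microbial change T, metabolite change M, phenotype change Y)
are admitted when the microbe associates with both the metabolite and
the phenotype in the delta screen and the metabolite-phenotype Spearman
p is below 0.01.  Each admitted triad is analysed with the
quasi-Bayesian Monte Carlo estimator for linear mediator and outcome
models:

    M = a0 + a T + e_M
    Y = c0 + c T + b M + e_Y

Parameter vectors are drawn from the asymptotic multivariate normal of
each least-squares fit; per draw the average causal mediation effect is
a*b, the average direct effect is c, and the total effect their sum.
The ACME p value is the two-sided Monte Carlo sign test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .delta_assoc import DeltaAssociation, DeltaTable, spearman_with_p

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MediationTriad:
    treatment: str  # microbial delta feature
    mediator: str  # metabolite delta
    outcome: str  # phenotype delta


@dataclass
class MediationResult:
    triad: MediationTriad
    acme: float
    ade: float
    total: float
    prop_mediated: float
    p_acme: float
    n: int
    n_sims: int
    seed: int
    draws: np.ndarray | None = None  # (n_sims, 3): acme, ade, total


# ---------------------------------------------------------------------------


def gate_triads(
    micro_metabo: list[DeltaAssociation],
    micro_pheno: list[DeltaAssociation],
    metabo_deltas: DeltaTable,
    pheno_deltas: DeltaTable,
    p_gate: float = 0.01,
) -> list[MediationTriad]:
    """Admit triads where the microbe links to both trait kinds and the
    metabolite-phenotype Spearman p < ``p_gate``."""
    met_by_microbe: dict[str, list[str]] = {}
    for a in micro_metabo:
        if a.significant:
            met_by_microbe.setdefault(a.microbial_feature, []).append(a.trait)
    phe_by_microbe: dict[str, list[str]] = {}
    for a in micro_pheno:
        if a.significant:
            phe_by_microbe.setdefault(a.microbial_feature, []).append(a.trait)
    shared_calves = [c for c in metabo_deltas.calves if c in set(pheno_deltas.calves)]
    triads: list[MediationTriad] = []
    gate_cache: dict[tuple[str, str], bool] = {}
    for microbe in sorted(set(met_by_microbe) & set(phe_by_microbe)):
        for metabolite in sorted(set(met_by_microbe[microbe])):
            for phenotype in sorted(set(phe_by_microbe[microbe])):
                key = (metabolite, phenotype)
                if key not in gate_cache:
                    m = metabo_deltas.data.loc[metabolite, shared_calves].to_numpy(dtype=float)
                    y = pheno_deltas.data.loc[phenotype, shared_calves].to_numpy(dtype=float)
                    _, p = spearman_with_p(m, y)
                    gate_cache[key] = bool(np.isfinite(p) and p < p_gate)
                if gate_cache[key]:
                    triads.append(MediationTriad(microbe, metabolite, phenotype))
    return triads


def mediate_arrays(
    t: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_sims: int = 1000,
    seed: int = 0,
    name: str = "",
) -> MediationResult:
    """Quasi-Bayesian mediation for continuous T, M, Y (no interaction).

    Draws (a, b, c) jointly from the two fits' asymptotic normals (the
    fits are independent, so draws are independent across models); the
    ACME per draw is a*b and acme + ade = total holds exactly per draw.
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    if n < 6:
        raise ValueError(f"mediation triad {name!r}: need >= 6 complete triples, have {n}")
    if np.all(t == t[0]):
        raise ValueError(f"mediation triad {name!r}: constant treatment gives a singular design")
    xm = sm.add_constant(t)
    med_fit = sm.OLS(m, xm).fit()
    xy = sm.add_constant(np.column_stack([t, m]))
    out_fit = sm.OLS(y, xy).fit()
    rng = np.random.default_rng(seed)
    med_draws = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), size=n_sims)
    out_draws = rng.multivariate_normal(out_fit.params, out_fit.cov_params(), size=n_sims)
    a = med_draws[:, 1]
    c = out_draws[:, 1]
    b = out_draws[:, 2]
    acme = a * b
    ade = c
    total = acme + ade
    pos = int(np.sum(acme > 0))
    neg = int(np.sum(acme < 0))
    p_acme = max(2.0 * min(pos, neg) / n_sims, 2.0 / n_sims)
    acme_hat = float(acme.mean())
    total_hat = float(total.mean())
    prop = acme_hat / total_hat if total_hat != 0 else float("nan")
    return MediationResult(
        triad=MediationTriad(name, "", ""),
        acme=acme_hat,
        ade=float(ade.mean()),
        total=total_hat,
        prop_mediated=float(prop),
        p_acme=float(min(p_acme, 1.0)),
        n=n,
        n_sims=n_sims,
        seed=seed,
        draws=np.column_stack([acme, ade, total]),
    )


def mediate(
    triad: MediationTriad,
    micro_deltas: DeltaTable,
    metabo_deltas: DeltaTable,
    pheno_deltas: DeltaTable,
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Run the quasi-Bayesian estimator for one admitted triad."""
    calves = [
        c
        for c in micro_deltas.calves
        if c in set(metabo_deltas.calves) and c in set(pheno_deltas.calves)
    ]
    t = micro_deltas.data.loc[triad.treatment, calves].to_numpy(dtype=float)
    m = metabo_deltas.data.loc[triad.mediator, calves].to_numpy(dtype=float)
    y = pheno_deltas.data.loc[triad.outcome, calves].to_numpy(dtype=float)
    res = mediate_arrays(t, m, y, n_sims=n_sims, seed=seed,
                         name=f"{triad.treatment}->{triad.mediator}->{triad.outcome}")
    res.triad = triad
    return res


def mediation_table(results: list[MediationResult], alpha: float = 0.05) -> pd.DataFrame:
    """Linkages with p_acme < alpha, sorted by phenotype then mediator."""
    rows = [
        {
            "treatment": r.triad.treatment,
            "mediator": r.triad.mediator,
            "outcome": r.triad.outcome,
            "acme": r.acme,
            "ade": r.ade,
            "total": r.total,
            "prop_mediated": r.prop_mediated,
            "p": r.p_acme,
            "n": r.n,
        }
        for r in results
        if r.p_acme < alpha
    ]
    df = pd.DataFrame(rows, columns=["treatment", "mediator", "outcome", "acme", "ade",
                                     "total", "prop_mediated", "p", "n"])
    if len(df):
        df = df.sort_values(["outcome", "mediator", "treatment"]).reset_index(drop=True)
    return df
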