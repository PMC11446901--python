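"""Two-step multivariable-MR mediation analysis.

Step 1 estimates beta1 (exposure → mediator) by univariable IVW on the
exposure's instruments.  Step 2 estimates beta2 (mediator → outcome
conditional on the exposure) as the mediator's coefficient in a
multivariable IVW regression over the union of instruments.  With the total
exposure → outcome effect beta from univariable IVW, the decomposition is

    indirect = beta1 * beta2          (delta-method SE)
    direct   = beta - beta1 * beta2   (direct + indirect = beta exactly)
    ratio    = beta1 * beta2 / beta   (mediated proportion; delta-method SE,
                                       Z = ratio/SE, CI = ratio +/- 1.96 SE)

treating (beta1, beta2, beta) as independent — the construction that
reproduces published mediation tables' Z statistics from their printed
ratios and confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .uvmr import EstimationError, MREstimate

__all__ = [
    "MVMRInput",
    "MvmrEstimate",
    "MediationDecomposition",
    "CollinearityError",
    "mvmr_ivw",
    "decompose",
    "filter_mediations",
    "reconstruct_z",
    "mediation_table",
    "MEDIATION_TABLE_COLUMNS",
]

MEDIATION_TABLE_COLUMNS = ["Exposure", "Mediator", "Outcome",
                           "Mediation effect ratio", "LCI ratio", "UCI ratio",
                           "Z", "P"]


class CollinearityError(EstimationError):
    """The MVMR design matrix is rank deficient."""


@dataclass
class MVMRInput:
    """Per-variant effects of several exposures plus one outcome."""

    variant_ids: list[str]
    exposures: list[str]
    bx: np.ndarray  # (k, p) exposure effect matrix
    sx: np.ndarray  # (k, p)
    by: np.ndarray
    sy: np.ndarray

    def __post_init__(self):
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        k, p = self.bx.shape
        if len(self.exposures) != p:
            raise ValueError("exposure names must match bx columns")
        if not (len(self.by) == len(self.sy) == len(self.variant_ids) == k):
            raise ValueError("MVMRInput arrays must share one length")


@dataclass
class MvmrEstimate:
    exposures: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    pval: dict[str, float]
    conditional_f: dict[str, float]
    n_snp: int
    q_stat: float
    q_pval: float


def mvmr_ivw(data: MVMRInput) -> MvmrEstimate:
    """Multivariable IVW: weighted no-intercept regression of by on the bx matrix.

    Weights 1/sy²; coefficient SEs carry a multiplicative overdispersion
    factor max(1, sqrt(Q/(k-p))).  All-zero exposure columns get a zero
    coefficient (se NaN); linearly dependent nonzero columns raise
    :class:`CollinearityError` naming the traits.
    """
    k, p = data.bx.shape
    if k <= p:
        raise EstimationError(
            f"MVMR needs more instruments than traits (k={k}, p={p})")
    zero_cols = np.flatnonzero(np.all(data.bx == 0.0, axis=0))
    active = [j for j in range(p) if j not in zero_cols]
    X = data.bx[:, active]
    w = 1.0 / data.sy ** 2
    xtwx = (X.T * w) @ X
    rank = np.linalg.matrix_rank(xtwx)
    if rank < len(active):
        corr = np.corrcoef(X.T)
        pairs = [(data.exposures[active[i]], data.exposures[active[j]])
                 for i in range(len(active)) for j in range(i + 1, len(active))
                 if abs(corr[i, j]) > 1.0 - 1e-10]
        raise CollinearityError(f"collinear exposure effects: {pairs or 'rank deficient'}")
    cov_u = np.linalg.inv(xtwx)
    coef = cov_u @ (X.T * w) @ data.by
    resid = data.by - X @ coef
    q = float(np.sum(w * resid ** 2))
    dof = k - len(active)
    q_pval = float(stats.chi2.sf(q, dof))
    scale = max(1.0, math.sqrt(q / dof))
    ses = np.sqrt(np.diag(cov_u)) * scale

    beta_d, se_d, lo_d, hi_d, p_d, f_d = {}, {}, {}, {}, {}, {}
    for pos, j in enumerate(active):
        name = data.exposures[j]
        b, s = float(coef[pos]), float(ses[pos])
        z = b / s
        beta_d[name], se_d[name] = b, s
        lo_d[name], hi_d[name] = b - 1.96 * s, b + 1.96 * s
        p_d[name] = float(2.0 * stats.norm.sf(abs(z)))
        # conditional instrument strength: how much of this trait's signal
        # survives regressing it (weighted) on the other traits
        others = [q2 for q2 in range(X.shape[1]) if q2 != pos]
        xt = X[:, pos]
        if others:
            Xo = X[:, others]
            go = np.linalg.lstsq((Xo.T * w) @ Xo, (Xo.T * w) @ xt, rcond=None)[0]
            e = xt - Xo @ go
        else:
            e = xt
        sx_t = np.maximum(data.sx[:, j], 1e-12)
        f_d[name] = float(np.sum(e ** 2 / sx_t ** 2) / max(k - len(active), 1))
    for j in zero_cols:
        name = data.exposures[j]
        beta_d[name], se_d[name] = 0.0, float("nan")
        lo_d[name] = hi_d[name] = 0.0
        p_d[name] = float("nan")
        f_d[name] = 0.0
    return MvmrEstimate(exposures=list(data.exposures), beta=beta_d, se=se_d,
                        ci_low=lo_d, ci_high=hi_d, pval=p_d,
                        conditional_f=f_d, n_snp=k, q_stat=q, q_pval=q_pval)


@dataclass
class MediationDecomposition:
    """Decomposition of a total effect into mediated and direct components."""

    exposure: str
    mediator: str
    outcome: str
    total: float
    total_se: float
    step1: float          # beta1: exposure -> mediator
    step1_se: float
    step2: float          # beta2: mediator -> outcome | exposure
    step2_se: float
    indirect: float = field(init=False)
    indirect_se: float = field(init=False)
    direct: float = field(init=False)
    ratio: float = field(init=False)
    ratio_se: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    z: float = field(init=False)
    pval: float = field(init=False)

    def __post_init__(self):
        b, b1, b2 = self.total, self.step1, self.step2
        s, s1, s2 = self.total_se, self.step1_se, self.step2_se
        if b == 0.0:
            raise EstimationError("total effect is zero; mediated proportion undefined")
        self.indirect = b1 * b2
        self.indirect_se = math.sqrt(b1 ** 2 * s2 ** 2 + b2 ** 2 * s1 ** 2)
        self.direct = b - self.indirect
        self.ratio = self.indirect / b
        # first-order delta method on (b1, b2, b) treated as independent
        self.ratio_se = math.sqrt((b2 / b) ** 2 * s1 ** 2
                                  + (b1 / b) ** 2 * s2 ** 2
                                  + (b1 * b2 / b ** 2) ** 2 * s ** 2)
        self.ci_low = self.ratio - 1.96 * self.ratio_se
        self.ci_high = self.ratio + 1.96 * self.ratio_se
        self.z = self.ratio / self.ratio_se if self.ratio_se > 0 else float("inf")
        self.pval = float(2.0 * stats.norm.sf(abs(self.z)))


def decompose(total: MREstimate, step1: MREstimate,
              step2_beta: float, step2_se: float,
              exposure: str = "exposure", mediator: str = "mediator",
              outcome: str = "outcome") -> MediationDecomposition:
    """Combine total effect, step-1 and step-2 estimates into a decomposition."""
    return MediationDecomposition(
        exposure=exposure, mediator=mediator, outcome=outcome,
        total=total.beta, total_se=total.se,
        step1=step1.beta, step1_se=step1.se,
        step2=step2_beta, step2_se=step2_se)


def reconstruct_z(ratio: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Back out (SE, Z) from a mediated proportion and its symmetric 95% CI.

    SE = (UCI - LCI) / 3.92 and Z = ratio / SE — the internal-consistency
    check a reader can apply to any published mediation table row.
    """
    se = (ci_high - ci_low) / 3.92
    if se <= 0:
        raise ValueError("confidence interval must have positive width")
    return se, ratio / se


def filter_mediations(decomps: list[MediationDecomposition],
                      alpha: float = 0.05) -> tuple[list[MediationDecomposition],
                                                    dict[str, int]]:
    """Keep decompositions with a positive mediated proportion and P <= alpha."""
    kept, n_neg, n_ns = [], 0, 0
    for d in decomps:
        if d.ratio <= 0:
            n_neg += 1
        elif d.pval > alpha:
            n_ns += 1
        else:
            kept.append(d)
    attrition = {"input": len(decomps), "negative_ratio": n_neg,
                 "not_significant": n_ns, "retained": len(kept)}
    return kept, attrition


def mediation_table(decomps: list[MediationDecomposition]) -> pd.DataFrame:
    """Tidy mediation table (exposure, mediator, outcome, ratio, CI, Z, P)."""
    rows = [{
        "Exposure": d.exposure, "Mediator": d.mediator, "Outcome": d.outcome,
        "Mediation effect ratio": d.ratio, "LCI ratio": d.ci_low,
        "UCI ratio": d.ci_high, "Z": d.z, "P": d.pval,
    } for d in decomps]
    return pd.DataFrame(rows, columns=MEDIATION_TABLE_COLUMNS)
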