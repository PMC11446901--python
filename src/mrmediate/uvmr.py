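"""Univariable two-sample MR estimators and pleiotropy diagnostics.

All estimators consume per-variant summary associations: exposure effects
``bx`` with standard errors ``sx`` and outcome effects ``by`` with ``sy``
for a set of independent instruments.  The battery covers:

* IVW (fixed and multiplicative-random-effects), with robust (MM-type,
  Tukey biweight) and penalized-weight variants;
* MR-Egger regression (slope + average-pleiotropy intercept) in plain,
  penalized, robust and penalized-robust forms;
* profile maximum likelihood accounting for exposure measurement error;
* debiased IVW (consistent under many weak instruments);
* the contamination-mixture model (valid instruments as the largest
  coherent subset);
* Bayesian weighted MR via variational EM with per-SNP outlier weights.

For a binary outcome all effects are on the log-odds scale; ``or_value``
exposes exp(beta).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MRInput",
    "MREstimate",
    "PleiotropyReport",
    "EstimationError",
    "ivw",
    "ivw_robust",
    "ivw_penalized",
    "egger",
    "max_likelihood",
    "debiased_ivw",
    "contamination_mixture",
    "bwmr",
    "run_battery",
    "BatterySettings",
    "BatteryResult",
]

log = logging.getLogger(__name__)

_Z975 = stats.norm.ppf(0.975)
_TUKEY_C = 4.685  # 95% efficiency at the normal model


class EstimationError(RuntimeError):
    """An estimator could not produce a valid estimate."""


@dataclass
class MRInput:
    """Harmonized per-variant effects for one exposure-outcome pair."""

    variant_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray

    def __post_init__(self):
        self.bx, self.sx, self.by, self.sy = (
            np.asarray(a, dtype=float) for a in (self.bx, self.sx, self.by, self.sy))
        k = len(self.bx)
        if not (len(self.sx) == len(self.by) == len(self.sy) == len(self.variant_ids) == k):
            raise ValueError("MRInput arrays must share one length")
        if np.any(self.sy <= 0) or np.any(self.sx < 0):
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.bx)

    def drop_zero_bx(self) -> "MRInput":
        keep = self.bx != 0.0
        if not keep.all():
            log.warning("excluding %d variants with zero exposure effect",
                        int((~keep).sum()))
        if not keep.any():
            raise EstimationError("all exposure effects are zero")
        return self.subset(np.flatnonzero(keep))

    def subset(self, idx) -> "MRInput":
        idx = np.asarray(idx)
        return MRInput(
            variant_ids=[self.variant_ids[i] for i in idx],
            bx=self.bx[idx], sx=self.sx[idx], by=self.by[idx], sy=self.sy[idx])


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_pval: float | None = None
    extra: dict | None = None

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class PleiotropyReport:
    """Egger-intercept results (average directional pleiotropy) per variant."""

    entries: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, variant: str, egger_intercept: float, intercept_se: float,
            intercept_pval: float) -> None:
        self.entries[variant] = {
            "egger_intercept": egger_intercept, "intercept_se": intercept_se,
            "intercept_pval": intercept_pval}

    def intercept_pval(self, variant: str = "plain") -> float:
        return self.entries[variant]["intercept_pval"]


def _wald(method, beta, se, k, q=None, q_p=None, extra=None) -> MREstimate:
    z = beta / se if se > 0 else math.inf * np.sign(beta)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - _Z975 * se),
                      ci_high=float(beta + _Z975 * se),
                      pval=p, n_snp=int(k), q_stat=q, q_pval=q_p, extra=extra)


def cochran_q(data: MRInput, beta: float) -> tuple[float, float]:
    """Cochran's Q of the per-SNP ratio estimates about ``beta``."""
    nz = data.bx != 0
    w = data.bx[nz] ** 2 / data.sy[nz] ** 2
    q = float(np.sum(w * (data.by[nz] / data.bx[nz] - beta) ** 2))
    df = int(nz.sum()) - 1
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, q_p


def ivw(data: MRInput, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2); fixed-effects SE is
    1/sqrt(sum(bx^2/sy^2)); the multiplicative random-effects model scales
    the SE by max(1, sqrt(Q/(k-1))).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    data = data.drop_zero_bx()
    k = len(data)
    if k < 1 or (effects_model == "multiplicative_random" and k < 2):
        raise EstimationError(f"IVW ({effects_model}) needs more instruments (k={k})")
    wx = data.bx ** 2 / data.sy ** 2
    beta = float(np.sum(data.bx * data.by / data.sy ** 2) / np.sum(wx))
    se_fixed = float(1.0 / math.sqrt(np.sum(wx)))
    q = float(np.sum(wx * (data.by / data.bx - beta) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else float("nan")
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / (k - 1)))
        name = "IVW (random effects)"
    else:
        se = se_fixed
        name = "IVW (fixed effects)"
    return _wald(name, beta, se, k, q, q_p)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def _rlm_fit(endog, exog, start):
    import statsmodels.api as sm
    model = sm.RLM(endog, exog, M=sm.robust.norms.TukeyBiweight(c=_TUKEY_C))
    start = np.atleast_1d(start)
    if start.size < 2:  # statsmodels squeezes start_params, breaking p=1
        return model.fit(maxiter=200)
    return model.fit(start_params=start, maxiter=200)


def ivw_robust(data: MRInput, weights: np.ndarray | None = None,
               method_name: str = "Robust IVW") -> MREstimate:
    """MM-type robust IVW: Tukey-biweight regression of by on bx, weights 1/sy²."""
    data = data.drop_zero_bx()
    k = len(data)
    if k < 3:
        raise EstimationError(f"robust IVW needs >= 3 instruments (k={k})")
    w = (weights if weights is not None else np.ones(k)) / data.sy ** 2
    sw = np.sqrt(w)
    u, v = data.bx * sw, data.by * sw
    start = _weighted_median(data.by / data.bx, data.bx ** 2 / data.sy ** 2)
    resid = v - start * u
    scale = np.median(np.abs(resid - np.median(resid)))
    if scale < 1e-12 * max(1.0, float(np.max(np.abs(v)))):
        # exact fit at the robust start: robust = least squares
        est = ivw(data, "fixed")
        q, q_p = est.q_stat, est.q_pval
        return _wald(method_name, est.beta, est.se, k, q, q_p)
    try:
        fit = _rlm_fit(v, u[:, None], start)
    except Exception as exc:  # pragma: no cover - statsmodels failure paths
        raise EstimationError(f"robust IVW did not converge: {exc}") from exc
    beta = float(fit.params[0])
    se = float(np.sqrt(fit.bcov_scaled[0, 0]))
    q = float(np.sum((data.bx ** 2 / data.sy ** 2)
                     * (data.by / data.bx - beta) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    return _wald(method_name, beta, se, k, q, q_p)


def _penalty_weights(data: MRInput, penalty: float) -> np.ndarray:
    est = ivw(data, "fixed")
    w = data.bx ** 2 / data.sy ** 2
    q_j = w * (data.by / data.bx - est.beta) ** 2
    p_j = stats.chi2.sf(q_j, 1)
    return np.minimum(1.0, penalty * p_j)


def ivw_penalized(data: MRInput, robust: bool = False,
                  penalty: float = 20.0,
                  effects_model: str = "multiplicative_random") -> MREstimate:
    """Penalized(-robust) IVW: heterogeneity-outlier weights min(1, penalty·p_j)."""
    data = data.drop_zero_bx()
    k = len(data)
    if k < 3:
        raise EstimationError(f"penalized IVW needs >= 3 instruments (k={k})")
    pen = _penalty_weights(data, penalty)
    if robust:
        return ivw_robust(data, weights=pen, method_name="Penalized robust IVW")
    w = pen / data.sy ** 2
    sxx = float(np.sum(w * data.bx ** 2))
    if sxx <= 0:
        raise EstimationError("all instruments fully penalized")
    beta = float(np.sum(w * data.bx * data.by) / sxx)
    se_fixed = 1.0 / math.sqrt(sxx)
    dof = max(1, int(round(pen.sum())) - 1)
    q = float(np.sum(w * data.bx ** 2 * (data.by / data.bx - beta) ** 2))
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / dof))
    else:
        se = se_fixed
    q_full, q_p = cochran_q(data, beta)
    return _wald("Penalized IVW", beta, se, k, q_full, q_p)


def egger(data: MRInput, variant: str = "plain",
          penalty: float = 20.0) -> tuple[MREstimate, dict[str, float]]:
    """MR-Egger regression: slope = causal effect, intercept = mean pleiotropy.

    Exposure effects are oriented non-negative first (Egger regression is not
    orientation invariant).  Returns the slope estimate and an intercept
    entry ``{egger_intercept, intercept_se, intercept_pval}``; the intercept
    test uses a t distribution with k-2 degrees of freedom.
    """
    if variant not in ("plain", "penalized", "robust", "penalized_robust"):
        raise ValueError(f"unknown Egger variant {variant!r}")
    data = data.drop_zero_bx()
    k = len(data)
    if k < 3:
        raise EstimationError(f"MR-Egger needs >= 3 instruments (k={k})")
    sign = np.where(data.bx < 0, -1.0, 1.0)
    bx, by = data.bx * sign, data.by * sign
    if np.ptp(bx) < 1e-14 * max(1.0, float(np.max(np.abs(bx)))):
        raise EstimationError("exposure effects collinear after orientation")

    base_w = np.ones(k)
    if variant in ("penalized", "penalized_robust"):
        # penalize on heterogeneity about the plain Egger fit
        slope0, int0, *_ = _egger_wls(bx, by, data.sy, np.ones(k))
        q_j = (by - int0 - slope0 * bx) ** 2 / data.sy ** 2
        base_w = np.minimum(1.0, penalty * stats.chi2.sf(q_j, 1))

    if variant in ("robust", "penalized_robust"):
        w = base_w / data.sy ** 2
        sw = np.sqrt(w)
        exog = np.column_stack([sw, bx * sw])
        slope0, int0, *_ = _egger_wls(bx, by, data.sy, base_w)
        resid = by * sw - exog @ np.array([int0, slope0])
        scale = np.median(np.abs(resid - np.median(resid)))
        if scale < 1e-12:
            slope, icpt, se_s, se_i = slope0, int0, *_egger_wls(
                bx, by, data.sy, base_w)[2:4]
        else:
            try:
                fit = _rlm_fit(by * sw, exog, np.array([int0, slope0]))
            except Exception as exc:  # pragma: no cover
                raise EstimationError(f"robust Egger did not converge: {exc}") from exc
            icpt, slope = (float(p) for p in fit.params)
            se_i, se_s = (float(s) for s in np.sqrt(np.diag(fit.bcov_scaled)))
    else:
        slope, icpt, se_s, se_i = _egger_wls(bx, by, data.sy, base_w)

    names = {"plain": "MR-Egger", "penalized": "Penalized MR-Egger",
             "robust": "Robust MR-Egger",
             "penalized_robust": "Penalized robust MR-Egger"}
    q, q_p = cochran_q(data, slope)
    est = _wald(names[variant], slope, se_s, k, q, q_p)
    t_int = icpt / se_i
    p_int = float(2.0 * stats.t.sf(abs(t_int), k - 2))
    intercept = {"egger_intercept": float(icpt), "intercept_se": float(se_i),
                 "intercept_pval": p_int}
    return est, intercept


def _egger_wls(bx, by, sy, base_w):
    """Weighted with-intercept regression; SEs with multiplicative RE scaling."""
    w = base_w / sy ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    try:
        cov_u = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("Egger design matrix is singular") from exc
    params = cov_u @ (XtW @ by)
    icpt, slope = (float(p) for p in params)
    k = len(bx)
    rss = float(np.sum(w * (by - X @ params) ** 2))
    scale = max(1.0, rss / max(k - 2, 1))
    se_i, se_s = (float(s) for s in np.sqrt(np.diag(cov_u) * scale))
    return slope, icpt, se_s, se_i


def max_likelihood(data: MRInput) -> MREstimate:
    """Profile maximum likelihood allowing exposure measurement error.

    Model: bx_j ~ N(gamma_j, sx_j²), by_j ~ N(theta·gamma_j, sy_j²); profiling
    out gamma gives the objective sum (by - theta·bx)² / (sy² + theta²·sx²),
    minimized numerically from the IVW start.  SE from the observed
    information of the profile log-likelihood.
    """
    data = data.drop_zero_bx()
    k = len(data)
    if k < 2:
        raise EstimationError(f"maximum likelihood needs >= 2 instruments (k={k})")

    def nll(theta):
        denom = data.sy ** 2 + theta ** 2 * data.sx ** 2
        return 0.5 * float(np.sum((data.by - theta * data.bx) ** 2 / denom))

    start = ivw(data, "fixed").beta
    span = 10.0 * (abs(start) + 1.0)
    res = optimize.minimize_scalar(nll, bounds=(start - span, start + span),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise EstimationError(f"ML optimization failed: {res.message}")
    theta = float(res.x)
    h = 1e-5 * (abs(theta) + 1.0)
    d2 = (nll(theta + h) - 2.0 * nll(theta) + nll(theta - h)) / h ** 2
    if d2 <= 0:
        raise EstimationError("ML information non-positive at the optimum")
    se = 1.0 / math.sqrt(d2)
    q, q_p = cochran_q(data, theta)
    return _wald("Maximum likelihood", theta, se, k, q, q_p)


def debiased_ivw(data: MRInput) -> MREstimate:
    """Debiased IVW, consistent under many weak instruments.

    theta = sum(bx·by/sy²) / sum((bx² - sx²)/sy²); the denominator subtracts
    the expected weak-instrument inflation E[bx²] - gamma² = sx².  SE by the
    delta method on numerator - theta·denominator.
    """
    k = len(data)
    if k < 1:
        raise EstimationError("debiased IVW needs at least 1 instrument")
    sy2 = data.sy ** 2
    a = float(np.sum(data.bx * data.by / sy2))
    b = float(np.sum((data.bx ** 2 - data.sx ** 2) / sy2))
    if b <= 0:
        raise EstimationError(
            "debiased denominator <= 0: weak-instrument noise overwhelms signal")
    theta = a / b
    mu2 = np.maximum(data.bx ** 2 - data.sx ** 2, 0.0)
    var_t = (mu2 * sy2 + data.sx ** 2 * sy2
             + theta ** 2 * mu2 * data.sx ** 2 + 2.0 * theta ** 2 * data.sx ** 4)
    se = math.sqrt(float(np.sum(var_t / sy2 ** 2))) / abs(b)
    nz = data.bx != 0
    q = float(np.sum((data.bx[nz] ** 2 / sy2[nz])
                     * (data.by[nz] / data.bx[nz] - theta) ** 2))
    q_p = float(stats.chi2.sf(q, int(nz.sum()) - 1)) if nz.sum() > 1 else float("nan")
    return _wald("Debiased IVW", theta, se, k, q, q_p)


def contamination_mixture(data: MRInput, psi: float | None = None,
                          grid: np.ndarray | None = None) -> MREstimate:
    """Contamination-mixture estimate: valid IVs are the largest coherent subset.

    Each SNP's ratio estimate contributes the larger of a valid-model density
    N(theta, se_ratio²) and an invalid-model density N(0, se_ratio² + psi²);
    theta maximizes the profile log-likelihood over a grid, with a CI of grid
    points within chi²₁(0.95)/2 of the maximum.
    """
    data = data.drop_zero_bx()
    k = len(data)
    if k < 3:
        raise EstimationError(f"contamination mixture needs >= 3 instruments (k={k})")
    r = data.by / data.bx
    se_r = data.sy / np.abs(data.bx)
    if psi is None:
        psi = 1.5 * float(np.std(r))
        if psi <= 0:
            psi = float(np.mean(se_r))
    if grid is None:
        lim = 3.0 * float(np.max(np.abs(r)))
        grid = np.linspace(-lim, lim, 500)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("contamination-mixture grid is empty")
    ll_valid = stats.norm.logpdf(r[None, :], grid[:, None], se_r[None, :])
    ll_invalid = stats.norm.logpdf(r, 0.0, np.sqrt(se_r ** 2 + psi ** 2))
    ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)
    best = int(np.argmax(ll))
    theta = float(grid[best])
    cutoff = ll[best] - stats.chi2.ppf(0.95, 1) / 2.0
    inside = grid[ll >= cutoff]
    ci_low, ci_high = float(inside.min()), float(inside.max())
    se = (ci_high - ci_low) / (2.0 * _Z975)
    if se <= 0:
        se = float(grid[1] - grid[0]) if grid.size > 1 else 1e-12
    z = theta / se
    q, q_p = cochran_q(data, theta)
    return MREstimate(method="Contamination mixture", beta=theta, se=se,
                      ci_low=ci_low, ci_high=ci_high,
                      pval=float(2.0 * stats.norm.sf(abs(z))), n_snp=k,
                      q_stat=q, q_pval=q_p,
                      extra={"psi": float(psi), "n_valid": int(
                          np.sum(ll_valid[best] >= ll_invalid))})


def bwmr(data: MRInput, nu: float = 4.0, max_iter: int = 3000,
         tol: float = 1e-6) -> MREstimate:
    """Bayesian weighted MR by coordinate-ascent variational EM.

    Hierarchical model per SNP j:
        gamma_j ~ N(0, sigma_g²)           (polygenic instrument effects)
        w_j ~ Gamma(nu/2, nu/2)            (Student-t outlier weights)
        bx_j | gamma_j ~ N(gamma_j, sx_j²)
        by_j | gamma_j, w_j ~ N(theta·gamma_j, (sy_j² + tau²)/w_j)

    Variational posteriors q(gamma_j) Gaussian and q(w_j) Gamma; theta,
    sigma_g² and the overdispersion tau² are updated by exact M-steps, so the
    ELBO is non-decreasing.  Posterior mean weights E[w_j] expose outliers
    (smaller = more discrepant).
    """
    data = data.drop_zero_bx()
    k = len(data)
    if k < 3:
        raise EstimationError(f"BWMR needs >= 3 instruments (k={k})")
    x, y = data.bx, data.by
    sx2 = np.maximum(data.sx ** 2, 1e-12)
    sy2 = data.sy ** 2

    theta = ivw(data, "fixed").beta
    tau2 = 0.0
    sg2 = float(np.mean(x ** 2))
    m, v = x.copy(), sx2.copy()
    a = np.full(k, (nu + 1.0) / 2.0)
    b = np.full(k, (nu + 1.0) / 2.0)  # E[w] = 1 initially

    def elbo(theta, tau2, sg2, m, v, a, b):
        s2 = sy2 + tau2
        ew = a / b
        elw = special.digamma(a) - np.log(b)
        e2 = (y - theta * m) ** 2 + theta ** 2 * v
        ll_x = -0.5 * np.log(sx2) - ((x - m) ** 2 + v) / (2.0 * sx2)
        ll_y = 0.5 * elw - 0.5 * np.log(s2) - ew * e2 / (2.0 * s2)
        lp_g = -0.5 * math.log(sg2) - (m ** 2 + v) / (2.0 * sg2)
        lp_w = ((nu / 2.0) * math.log(nu / 2.0) - special.gammaln(nu / 2.0)
                + (nu / 2.0 - 1.0) * elw - (nu / 2.0) * ew)
        h_g = 0.5 * np.log(v)
        h_w = a - np.log(b) + special.gammaln(a) + (1.0 - a) * special.digamma(a)
        return float(np.sum(ll_x + ll_y + lp_g + lp_w + h_g + h_w))

    trace = [elbo(theta, tau2, sg2, m, v, a, b)]
    for _ in range(max_iter):
        s2 = sy2 + tau2
        ew = a / b
        # q(gamma)
        prec = 1.0 / sg2 + 1.0 / sx2 + ew * theta ** 2 / s2
        v = 1.0 / prec
        m = (x / sx2 + ew * theta * y / s2) * v
        # q(w)
        e2 = (y - theta * m) ** 2 + theta ** 2 * v
        a = np.full(k, (nu + 1.0) / 2.0)
        b = nu / 2.0 + e2 / (2.0 * s2)
        ew = a / b
        # M-steps
        theta = float(np.sum(ew * y * m / s2) / np.sum(ew * (m ** 2 + v) / s2))
        sg2 = float(np.mean(m ** 2 + v))
        e2 = (y - theta * m) ** 2 + theta ** 2 * v

        def neg_tau_obj(t2):
            s2t = sy2 + t2
            return -float(np.sum(-0.5 * np.log(s2t) - ew * e2 / (2.0 * s2t)))

        upper = 10.0 * float(np.max(sy2) + np.var(y))
        res = optimize.minimize_scalar(neg_tau_obj, bounds=(0.0, upper),
                                       method="bounded",
                                       options={"xatol": 1e-12})
        cand = float(res.x)
        if neg_tau_obj(cand) <= neg_tau_obj(tau2):
            tau2 = cand
        trace.append(elbo(theta, tau2, sg2, m, v, a, b))
        if abs(trace[-1] - trace[-2]) < tol:
            break
    else:
        if trace[-1] < trace[-2] - 1e-6:
            raise EstimationError("BWMR ELBO failed to stabilize")

    ew = a / b
    s2m = sy2 + tau2 + theta ** 2 * sx2

    def marg_nll(t):
        s2t = sy2 + tau2 + t ** 2 * sx2
        return 0.5 * float(np.sum(ew * ((y - t * x) ** 2 / s2t + np.log(s2t))))

    h = 1e-5 * (abs(theta) + 1.0)
    d2 = (marg_nll(theta + h) - 2.0 * marg_nll(theta) + marg_nll(theta - h)) / h ** 2
    se = 1.0 / math.sqrt(d2) if d2 > 0 else float(
        1.0 / math.sqrt(np.sum(ew * x ** 2 / s2m)))
    q, q_p = cochran_q(data, theta)
    return _wald("BWMR", theta, se, k, q, q_p,
                 extra={"weights": dict(zip(data.variant_ids, ew)),
                        "tau2": tau2, "sigma_g2": sg2, "elbo": trace})


@dataclass
class BatterySettings:
    effects_model: str = "multiplicative_random"
    penalty: float = 20.0
    conmix_psi: float | None = None
    conmix_grid: np.ndarray | None = None
    bwmr_nu: float = 4.0
    bwmr_max_iter: int = 3000
    bwmr_tol: float = 1e-6
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    seed: int = 0
    run_presso: bool = True


@dataclass
class BatteryResult:
    estimates: list[MREstimate]
    pleiotropy: PleiotropyReport
    presso: object | None
    failures: dict[str, str] = field(default_factory=dict)

    def get(self, method: str) -> MREstimate | None:
        for e in self.estimates:
            if e.method == method:
                return e
        return None

    def table(self):
        import pandas as pd
        rows = []
        for e in self.estimates:
            rows.append({
                "method": e.method, "beta": e.beta, "se": e.se,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "pval": e.pval,
                "or": e.or_value, "n_snp": e.n_snp,
                "q_stat": e.q_stat, "q_pval": e.q_pval})
        return pd.DataFrame(rows, columns=["method", "beta", "se", "ci_low",
                                           "ci_high", "pval", "or", "n_snp",
                                           "q_stat", "q_pval"])

    def pval_row(self) -> dict[str, float]:
        """method -> p-value mapping (one column of the battery heatmap)."""
        row = {e.method: e.pval for e in self.estimates}
        for variant, entry in self.pleiotropy.entries.items():
            row[f"Egger intercept ({variant})"] = entry["intercept_pval"]
        if self.presso is not None:
            row["MR-PRESSO global"] = self.presso.global_pval
        return row


def run_battery(data: MRInput,
                settings: BatterySettings | None = None) -> BatteryResult:
    """Run every UVMR estimator plus MR-PRESSO; failures are recorded, not fatal."""
    settings = settings or BatterySettings()
    estimates: list[MREstimate] = []
    failures: dict[str, str] = {}
    pleio = PleiotropyReport()

    def attempt(name, fn):
        try:
            estimates.append(fn())
        except (EstimationError, ValueError) as exc:
            failures[name] = str(exc)
            log.warning("battery method %s unavailable: %s", name, exc)

    attempt("IVW (fixed effects)", lambda: ivw(data, "fixed"))
    attempt("IVW (random effects)", lambda: ivw(data, "multiplicative_random"))
    attempt("Robust IVW", lambda: ivw_robust(data))
    attempt("Penalized IVW",
            lambda: ivw_penalized(data, robust=False, penalty=settings.penalty,
                                  effects_model=settings.effects_model))
    attempt("Penalized robust IVW",
            lambda: ivw_penalized(data, robust=True, penalty=settings.penalty))
    for variant in ("plain", "penalized", "robust", "penalized_robust"):
        name = f"MR-Egger ({variant})"
        try:
            est, intercept = egger(data, variant, penalty=settings.penalty)
            estimates.append(est)
            pleio.add(variant, **intercept)
        except (EstimationError, ValueError) as exc:
            failures[name] = str(exc)
            log.warning("battery method %s unavailable: %s", name, exc)
    attempt("Maximum likelihood", lambda: max_likelihood(data))
    attempt("Debiased IVW", lambda: debiased_ivw(data))
    attempt("Contamination mixture",
            lambda: contamination_mixture(data, psi=settings.conmix_psi,
                                          grid=settings.conmix_grid))
    attempt("BWMR", lambda: bwmr(data, nu=settings.bwmr_nu,
                                 max_iter=settings.bwmr_max_iter,
                                 tol=settings.bwmr_tol))

    presso_result = None
    if settings.run_presso:
        from .presso import presso as run_presso
        try:
            presso_result = run_presso(
                data, n_sim=settings.presso_n_sim,
                alpha_outlier=settings.presso_alpha,
                rng=np.random.default_rng(settings.seed))
        except (EstimationError, ValueError) as exc:
            failures["MR-PRESSO"] = str(exc)
            log.warning("battery method MR-PRESSO unavailable: %s", exc)
    return BatteryResult(estimates=estimates, pleiotropy=pleio,
                         presso=presso_result, failures=failures)
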