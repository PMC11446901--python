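"""MR-PRESSO: global pleiotropy test, per-SNP outlier test, distortion test.

The observed residual sum of squares uses leave-one-out fixed-effects IVW
predictions,

    RSS = sum_j (by_j - beta_(-j) * bx_j)^2 / sy_j^2 ,

and its null distribution is built by parametric simulation: draw
by*_j ~ N(beta_(-j)·bx_j, sy_j^2) and bx*_j ~ N(bx_j, sx_j^2), recompute the
leave-one-out RSS on each simulated set.  Per-SNP outlier p-values come from
each residual's simulated distribution (Bonferroni-flagged), the distortion
test compares the outlier-removed estimate against removals of random
same-size subsets, and the corrected estimate is IVW on the outlier-free
instruments.  All Monte-Carlo p-values respect the (1 + #exceed)/(n_sim + 1)
floor and are bit-reproducible under a fixed RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .uvmr import EstimationError, MRInput, MREstimate, ivw

__all__ = ["PressoResult", "presso"]


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str] = field(default_factory=list)
    distortion_pval: float | None = None
    distortion_pct: float | None = None
    corrected: MREstimate | None = None
    n_sim: int = 0


def _loo_rss(bx, by, sy2):
    """Leave-one-out fixed-IVW residuals; returns per-SNP weighted residuals."""
    wxy = bx * by / sy2
    wxx = bx ** 2 / sy2
    sum_wxy = wxy.sum(axis=-1, keepdims=True)
    sum_wxx = wxx.sum(axis=-1, keepdims=True)
    denom = sum_wxx - wxx
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_loo = (sum_wxy - wxy) / denom
    beta_loo = np.where(denom > 0, beta_loo, 0.0)
    return (by - beta_loo * bx) ** 2 / sy2


def presso(data: MRInput, n_sim: int = 1000, alpha_outlier: float = 0.05,
           rng: np.random.Generator | None = None) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Requires at least 4 instruments and ``n_sim`` >= 100.  ``alpha_outlier``
    is the Bonferroni-adjusted per-SNP flagging level.
    """
    k = len(data)
    if k < 4:
        raise EstimationError(f"MR-PRESSO needs >= 4 instruments (k={k})")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = rng or np.random.default_rng()
    if 1.0 / (n_sim + 1) >= alpha_outlier / k:
        import logging
        logging.getLogger(__name__).warning(
            "n_sim=%d cannot resolve the Bonferroni threshold %.2g/%d: the "
            "Monte-Carlo p floor 1/%d makes outlier flagging impossible; "
            "increase n_sim above k/alpha", n_sim, alpha_outlier, k, n_sim + 1)

    bx, by, sy2 = data.bx, data.by, data.sy ** 2
    resid_obs = _loo_rss(bx, by, sy2)
    rss_obs = float(resid_obs.sum())

    # expected value of each by*_j under the leave-one-out fit
    wxy = bx * by / sy2
    wxx = bx ** 2 / sy2
    denom = wxx.sum() - wxx
    beta_loo = np.where(denom > 0, (wxy.sum() - wxy) / denom, 0.0)
    mu_y = beta_loo * bx

    bx_star = rng.normal(bx, data.sx, size=(n_sim, k))
    by_star = rng.normal(mu_y, data.sy, size=(n_sim, k))
    resid_star = _loo_rss(bx_star, by_star, sy2)
    rss_star = resid_star.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    per_snp = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (n_sim + 1)
    outlier_pvals = dict(zip(data.variant_ids, per_snp.astype(float)))
    flagged = [vid for vid, p in outlier_pvals.items()
               if p * k < alpha_outlier]

    result = PressoResult(global_rss=rss_obs, global_pval=global_pval,
                          outlier_pvals=outlier_pvals, outliers=flagged,
                          n_sim=n_sim)
    if not flagged:
        result.corrected = ivw(data)
        return result

    keep_idx = [i for i, vid in enumerate(data.variant_ids) if vid not in flagged]
    if len(keep_idx) < 2:
        raise EstimationError("MR-PRESSO flagged too many instruments to re-estimate")
    corrected = ivw(data.subset(keep_idx))
    full = ivw(data)
    result.corrected = corrected
    obs_dist = 100.0 * (corrected.beta - full.beta) / abs(full.beta) \
        if full.beta != 0 else float("nan")
    result.distortion_pct = obs_dist

    # null distortion: remove random subsets of the same size
    n_out = len(flagged)
    dist_null = np.empty(n_sim)
    idx_all = np.arange(k)
    for s in range(n_sim):
        drop = rng.choice(idx_all, size=n_out, replace=False)
        keep = np.setdiff1d(idx_all, drop, assume_unique=True)
        wxy_s = (bx[keep] * by[keep] / sy2[keep]).sum()
        wxx_s = (bx[keep] ** 2 / sy2[keep]).sum()
        beta_s = wxy_s / wxx_s if wxx_s > 0 else np.nan
        dist_null[s] = 100.0 * (beta_s - full.beta) / abs(full.beta) \
            if full.beta != 0 else np.nan
    exceed = np.sum(np.abs(dist_null) >= abs(obs_dist))
    result.distortion_pval = float((1 + exceed) / (n_sim + 1))
    return result
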