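"""Synthetic GWAS summary statistics under a known structural causal model.

The generator emulates the three summary-statistic sets a two-sample MR
mediation study consumes — exposure (a gut-microbial taxon abundance),
mediator (a circulating metabolite) and outcome (a binary disease trait on
the log-odds scale) — from one structural model

    M = theta_xm * X + e_M,    Y = theta_my * M + theta_xy_direct * X + e_Y

instrumented by ``n_variants`` exposure SNPs (and optionally
``n_mediator_variants`` mediator-specific SNPs, which MVMR needs for
identification).  Per-variant sampling noise follows the usual large-sample
approximation: for a quantitative trait with unit phenotypic variance,
se_j = 1 / sqrt(2 N p_j (1 - p_j)); the binary outcome uses the effective
sample size N_eff = 4 / (1/n_cases + 1/n_controls) in the same formula.

Horizontal pleiotropy (per-variant direct effects on the outcome) can be
balanced, directional, or correlated with instrument strength, and a chosen
number of gross outlier instruments can be planted; everything is recorded
in a :class:`GroundTruth` so downstream estimators can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_summary_stats",
    "simulate_study",
    "write_sumstats",
    "write_ground_truth",
    "read_ground_truth",
    "SUMSTAT_COLUMNS",
    "effective_n",
]

#: fixed on-disk column order for summary-statistic tables
SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

# ordered (effect, other) allele pairs; palindromic pairs (A/T, C/G) are
# opt-in because strand-ambiguous variants near EAF 0.5 are dropped during
# harmonization and most tests want a deterministic instrument count.
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("T", "C"), ("C", "T"), ("T", "G"), ("G", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigurationError(ValueError):
    """A simulation configuration field is invalid."""


def effective_n(n_cases: int, n_controls: int) -> float:
    """Effective sample size of a case-control GWAS, 4/(1/n1 + 1/n0)."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic exposure→mediator→outcome study.

    Sample-size defaults match the real study scale this generator stands in
    for: a 5,959-sample microbiota GWAS, a 136,016-sample metabolite GWAS and
    an ovarian-cancer GWAS with 23,564 cases / 40,138 controls.
    """

    n_variants: int = 30
    n_exposure: int = 5959
    n_mediator: int = 136016
    n_cases: int = 23564
    n_controls: int = 40138
    theta_xm: float = 0.0          # structural effect exposure -> mediator
    theta_my: float = 0.0          # structural effect mediator -> outcome (log-odds)
    theta_xy_direct: float = 0.0   # direct effect exposure -> outcome (log-odds)
    instrument_h2: float = 0.1     # exposure variance explained by instruments
    n_mediator_variants: int = 0   # mediator-specific instruments (for MVMR)
    mediator_h2: float = 0.1       # mediator variance from its own instruments
    pleiotropy_mode: str = "none"  # none | balanced | directional | correlated
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.05  # mean alpha in directional mode
    pleiotropy_cor: float = 0.6    # cor(alpha, gamma) in correlated mode
    n_outliers: int = 0
    outlier_scale: float = 10.0    # outlier pleiotropy, in units of the base scale
    ld_block_size: int = 1
    ld_r2: float = 0.8             # pairwise r^2 within an LD block
    allow_palindromic: bool = False
    seed: int = 0
    variant_prefix: str = "rs"

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ConfigurationError("n_variants must be >= 1")
        for fname in ("n_exposure", "n_mediator", "n_cases", "n_controls"):
            if getattr(self, fname) <= 0:
                raise ConfigurationError(f"{fname} must be > 0")
        if not 0.0 < self.instrument_h2 < 1.0:
            raise ConfigurationError("instrument_h2 must lie in (0, 1)")
        if self.n_mediator_variants and not 0.0 < self.mediator_h2 < 1.0:
            raise ConfigurationError("mediator_h2 must lie in (0, 1)")
        if self.n_mediator_variants < 0:
            raise ConfigurationError("n_mediator_variants must be >= 0")
        if self.pleiotropy_mode not in {"none", "balanced", "directional", "correlated"}:
            raise ConfigurationError(
                f"pleiotropy_mode {self.pleiotropy_mode!r} not one of "
                "none/balanced/directional/correlated")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if not -1.0 <= self.pleiotropy_cor <= 1.0:
            raise ConfigurationError("pleiotropy_cor must lie in [-1, 1]")
        if not 0 <= self.n_outliers <= self.n_variants:
            raise ConfigurationError("n_outliers must lie in [0, n_variants]")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not 0.0 <= self.ld_r2 < 1.0:
            raise ConfigurationError("ld_r2 must lie in [0, 1)")

    @property
    def n_eff_outcome(self) -> float:
        return effective_n(self.n_cases, self.n_controls)


@dataclass
class GroundTruth:
    """Everything the generator knew: per-variant effects and structural targets."""

    variant_id: list[str]
    gamma: np.ndarray          # true instrument effects on the exposure
    delta: np.ndarray          # true mediator-specific instrument effects
    alpha: np.ndarray          # per-variant pleiotropic effects on the outcome
    theta_xm: float
    theta_my: float
    theta_xy_direct: float
    outlier_ids: list[str] = field(default_factory=list)
    block_of: dict[str, int] = field(default_factory=dict)
    ld_r2: float = 0.0

    @property
    def total_effect(self) -> float:
        """Implied total exposure→outcome effect, direct + indirect."""
        return self.theta_xy_direct + self.theta_xm * self.theta_my

    @property
    def mediation_ratio(self) -> float | None:
        """Implied mediated proportion theta_xm*theta_my / total, or None."""
        total = self.total_effect
        if total == 0.0:
            return None
        return self.theta_xm * self.theta_my / total


def _sumstat_frame(ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    return pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pval": pval,
        "n": np.full(len(ids), n, dtype=int),
    })[SUMSTAT_COLUMNS]


def _scaled_effects(rng, eaf, h2, blocks, ld_r2):
    """Draw per-variant true effects whose lead-variant variance sums to h2."""
    n = len(eaf)
    lead = np.zeros(n, dtype=bool)
    raw = np.zeros(n)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        lead[idx[0]] = True
        g = rng.standard_normal()
        raw[idx[0]] = g
        raw[idx[1:]] = math.sqrt(ld_r2) * g  # marginal effect of a tag SNP
    var_per = 2.0 * eaf * (1.0 - eaf) * raw ** 2
    total = var_per[lead].sum()
    scale = math.sqrt(h2 / total) if total > 0 else 0.0
    return raw * scale, lead


def _block_noise(rng, blocks, ld_r2, size):
    """Standard-normal noise with within-block correlation sqrt(ld_r2)."""
    z = rng.standard_normal(size)
    if ld_r2 <= 0:
        return z
    c = ld_r2 ** 0.25  # shared loading c gives corr c^2 = sqrt(ld_r2)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        if len(idx) > 1:
            shared = rng.standard_normal()
            z[idx] = c * shared + math.sqrt(1.0 - c * c) * z[idx]
    return z


def _pleiotropy(rng, config, gamma):
    n = len(gamma)
    mode = config.pleiotropy_mode
    sd = config.pleiotropy_sd
    if mode == "none":
        alpha = np.zeros(n)
    elif mode == "balanced":
        alpha = rng.normal(0.0, sd, n)
    elif mode == "directional":
        alpha = rng.normal(config.pleiotropy_mean, sd, n)
    else:  # correlated: alpha tracks instrument strength (InSIDE violation)
        gs = np.abs(gamma) / (np.std(gamma) + 1e-30)
        rho = config.pleiotropy_cor
        alpha = sd * (rho * gs + math.sqrt(max(0.0, 1.0 - rho * rho))
                      * rng.standard_normal(n))
    return alpha


def simulate_summary_stats(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate exposure, mediator and outcome summary-statistic tables.

    Returns the three tables (each covering all simulated variants, in the
    fixed :data:`SUMSTAT_COLUMNS` order) and the :class:`GroundTruth`.
    Deterministic under a fixed ``config.seed``: one seed sequence is spawned
    into per-purpose child streams.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_x, rng_m, rng_y = (np.random.default_rng(s) for s in ss.spawn(4))

    m = config.n_variants
    mm = config.n_mediator_variants
    total = m + mm
    ids = [f"{config.variant_prefix}{i + 1:06d}" for i in range(total)]
    eaf = rng_struct.uniform(0.05, 0.95, total)

    pairs = _NONPALINDROMIC_PAIRS + (_PALINDROMIC_PAIRS if config.allow_palindromic else [])
    pick = rng_struct.integers(0, len(pairs), total)
    ea = np.array([pairs[i][0] for i in pick])
    oa = np.array([pairs[i][1] for i in pick])

    # LD blocks cover the exposure instruments; mediator instruments independent
    blocks = np.arange(total)
    blocks[:m] = np.arange(m) // config.ld_block_size
    blocks[m:] = np.arange(mm) + m  # unique singleton blocks
    chrom = np.array([(b % 22) + 1 for b in blocks]).astype(str)
    pos = np.zeros(total, dtype=int)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        base = 1_000_000 + (b // 22) * 50_000_000
        pos[idx] = base + 5_000 * np.arange(len(idx))

    gamma = np.zeros(total)
    gamma[:m], _ = _scaled_effects(rng_struct, eaf[:m], config.instrument_h2,
                                   blocks[:m], config.ld_r2)
    delta = np.zeros(total)
    if mm:
        delta[m:], _ = _scaled_effects(rng_struct, eaf[m:], config.mediator_h2,
                                       np.arange(mm), 0.0)

    alpha = _pleiotropy(rng_struct, config, gamma)
    outlier_ids: list[str] = []
    if config.n_outliers:
        base_scale = config.pleiotropy_sd
        if base_scale == 0.0:
            # no background pleiotropy: anchor the shift to the outcome SE scale
            se_y_mean = float(np.mean(
                1.0 / np.sqrt(2.0 * config.n_eff_outcome * eaf[:m] * (1 - eaf[:m]))))
            base_scale = se_y_mean
        which = rng_struct.choice(m, size=config.n_outliers, replace=False)
        signs = rng_struct.choice([-1.0, 1.0], size=config.n_outliers)
        alpha[which] = alpha[which] + signs * config.outlier_scale * base_scale
        outlier_ids = [ids[i] for i in sorted(which)]

    het = 2.0 * eaf * (1.0 - eaf)
    se_x = 1.0 / np.sqrt(config.n_exposure * het)
    se_m = 1.0 / np.sqrt(config.n_mediator * het)
    se_y = 1.0 / np.sqrt(config.n_eff_outcome * het)

    true_x = gamma
    true_m = config.theta_xm * gamma + delta
    # pleiotropy is defined w.r.t. the exposure-increasing allele, so its
    # outcome contribution carries the sign of the instrument effect
    # (directional pleiotropy stays directional after Egger orientation)
    orient = np.where(gamma < 0, -1.0, 1.0)
    true_y = ((config.theta_xy_direct + config.theta_xm * config.theta_my) * gamma
              + config.theta_my * delta + orient * alpha)

    bx = true_x + _block_noise(rng_x, blocks, config.ld_r2, total) * se_x
    bm = true_m + _block_noise(rng_m, blocks, config.ld_r2, total) * se_m
    by = true_y + _block_noise(rng_y, blocks, config.ld_r2, total) * se_y

    exposure = _sumstat_frame(ids, chrom, pos, ea, oa, eaf, bx, se_x, config.n_exposure)
    mediator = _sumstat_frame(ids, chrom, pos, ea, oa, eaf, bm, se_m, config.n_mediator)
    outcome = _sumstat_frame(ids, chrom, pos, ea, oa, eaf, by, se_y,
                             config.n_cases + config.n_controls)

    truth = GroundTruth(
        variant_id=ids, gamma=gamma, delta=delta, alpha=alpha,
        theta_xm=config.theta_xm, theta_my=config.theta_my,
        theta_xy_direct=config.theta_xy_direct,
        outlier_ids=outlier_ids,
        block_of={v: int(b) for v, b in zip(ids, blocks)},
        ld_r2=config.ld_r2 if config.ld_block_size > 1 else 0.0,
    )
    return exposure, mediator, outcome, truth


def simulate_study(
    n_exposures: int,
    n_mediators: int,
    causal_exposure: int = 0,
    causal_mediator: int = 0,
    theta_xm: float = 0.4,
    theta_my: float = 0.5,
    theta_xy_direct: float = 0.1,
    base: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], pd.DataFrame,
           GroundTruth, dict[str, int]]:
    """Simulate a multi-trait screening study over a shared variant universe.

    ``n_exposures`` exposures each get their own instrument set and
    ``n_mediators`` mediators likewise; exactly one (exposure, mediator) pair
    carries the causal chain with the given structural effects, all other
    traits are null.  Every returned table covers the union of variants, so
    any exposure can be tested against any mediator and the single outcome.

    Returns (exposures, mediators, outcome, truth-for-causal-pair, block map).
    """
    if not (0 <= causal_exposure < n_exposures and 0 <= causal_mediator < n_mediators):
        raise ConfigurationError("causal indices out of range")
    cfg = base or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    m = cfg.n_variants
    mm = cfg.n_mediator_variants or cfg.n_variants
    total = n_exposures * m + n_mediators * mm
    ids = [f"{cfg.variant_prefix}{i + 1:06d}" for i in range(total)]
    eaf = rng.uniform(0.05, 0.95, total)
    pairs = _NONPALINDROMIC_PAIRS
    pick = rng.integers(0, len(pairs), total)
    ea = np.array([pairs[i][0] for i in pick])
    oa = np.array([pairs[i][1] for i in pick])
    chrom = np.array([(i % 22) + 1 for i in range(total)]).astype(str)
    pos = 1_000_000 + 50_000_000 * (np.arange(total) // 22)

    own = {}  # trait -> slice of its own instruments
    k = 0
    for e in range(n_exposures):
        own[f"exposure_{e}"] = slice(k, k + m); k += m
    for d in range(n_mediators):
        own[f"mediator_{d}"] = slice(k, k + mm); k += mm

    gamma = {}
    for name, sl in own.items():
        h2 = cfg.instrument_h2 if name.startswith("exposure") else cfg.mediator_h2
        g = np.zeros(total)
        g[sl], _ = _scaled_effects(rng, eaf[sl], h2, np.arange(sl.stop - sl.start), 0.0)
        gamma[name] = g

    het = 2.0 * eaf * (1.0 - eaf)
    se_x = 1.0 / np.sqrt(cfg.n_exposure * het)
    se_m = 1.0 / np.sqrt(cfg.n_mediator * het)
    se_y = 1.0 / np.sqrt(cfg.n_eff_outcome * het)

    ce = f"exposure_{causal_exposure}"
    cm = f"mediator_{causal_mediator}"

    exposures = {}
    for e in range(n_exposures):
        name = f"exposure_{e}"
        bx = gamma[name] + rng.standard_normal(total) * se_x
        exposures[name] = _sumstat_frame(ids, chrom, pos, ea, oa, eaf, bx,
                                         se_x, cfg.n_exposure)
    mediators = {}
    for d in range(n_mediators):
        name = f"mediator_{d}"
        true = gamma[name].copy()
        if name == cm:
            true = true + theta_xm * gamma[ce]
        bm = true + rng.standard_normal(total) * se_m
        mediators[name] = _sumstat_frame(ids, chrom, pos, ea, oa, eaf, bm,
                                         se_m, cfg.n_mediator)

    true_y = ((theta_xy_direct + theta_xm * theta_my) * gamma[ce]
              + theta_my * gamma[cm])
    by = true_y + rng.standard_normal(total) * se_y
    outcome = _sumstat_frame(ids, chrom, pos, ea, oa, eaf, by, se_y,
                             cfg.n_cases + cfg.n_controls)

    truth = GroundTruth(
        variant_id=ids, gamma=gamma[ce], delta=gamma[cm],
        alpha=np.zeros(total), theta_xm=theta_xm, theta_my=theta_my,
        theta_xy_direct=theta_xy_direct,
        block_of={v: i for i, v in enumerate(ids)}, ld_r2=0.0,
    )
    block_map = {v: i for i, v in enumerate(ids)}
    return exposures, mediators, outcome, truth, block_map


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistic table as tab-delimited text (fixed column order)."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    table[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize a GroundTruth as a key: value text sidecar."""
    lines = [
        f"theta_xm: {truth.theta_xm!r}",
        f"theta_my: {truth.theta_my!r}",
        f"theta_xy_direct: {truth.theta_xy_direct!r}",
        f"total_effect: {truth.total_effect!r}",
        f"mediation_ratio: {truth.mediation_ratio!r}",
        f"ld_r2: {truth.ld_r2!r}",
        "outlier_ids: " + ",".join(truth.outlier_ids),
        "variant_id: " + ",".join(truth.variant_id),
        "gamma: " + ",".join(repr(float(g)) for g in truth.gamma),
        "delta: " + ",".join(repr(float(d)) for d in truth.delta),
        "alpha: " + ",".join(repr(float(a)) for a in truth.alpha),
        "block_of: " + ",".join(f"{v}={b}" for v, b in truth.block_of.items()),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read a GroundTruth sidecar written by :func:`write_ground_truth`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        key, _, val = line.partition(":")
        kv[key.strip()] = val.strip()

    def floats(key):
        return np.array([float(x) for x in kv[key].split(",")] if kv[key] else [])

    ids = kv["variant_id"].split(",") if kv["variant_id"] else []
    block_of = {}
    if kv.get("block_of"):
        for item in kv["block_of"].split(","):
            v, _, b = item.partition("=")
            block_of[v] = int(b)
    return GroundTruth(
        variant_id=ids, gamma=floats("gamma"), delta=floats("delta"),
        alpha=floats("alpha"),
        theta_xm=float(kv["theta_xm"]), theta_my=float(kv["theta_my"]),
        theta_xy_direct=float(kv["theta_xy_direct"]),
        outlier_ids=kv["outlier_ids"].split(",") if kv["outlier_ids"] else [],
        block_of=block_of, ld_r2=float(kv["ld_r2"]),
    )


def config_to_mapping(config: SimulationConfig) -> Mapping[str, object]:
    """Plain-dict view of a config (for logging / config files)."""
    return asdict(config)
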