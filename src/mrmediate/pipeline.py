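"""Study orchestration: screening, battery, mediation, report export.

Stage order mirrors the two-step design:

1. UVMR of each exposure on the outcome; an exposure passes screening when
   its IVW p < alpha, the MR-Egger intercept shows no directional pleiotropy
   (p > alpha), and the MR-PRESSO outlier-corrected estimate is
   sign-consistent with IVW (each part configurable).
2. UVMR of each retained exposure on each mediator; links with p < alpha
   give beta1.
3. MVMR of {exposure, mediator} on the outcome over the union of both
   instrument sets, re-clumped jointly; mediator coefficients with
   p < alpha give beta2.
4. Delta-method decomposition and filtering (positive mediated proportion,
   p <= alpha).

Every stage logs attrition counts; per-pair failures are recorded and the
pipeline continues.  All randomness is seeded from the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import instruments as instr
from . import mediation as med
from . import sumstats
from . import synthdata
from . import uvmr

__all__ = ["PipelineConfig", "ScreeningSettings", "StudyReport", "run_study",
           "run_study_from_config", "export_report"]

log = logging.getLogger(__name__)


@dataclass
class ScreeningSettings:
    alpha: float = 0.05
    require_egger_intercept: bool = True   # intercept p must exceed alpha
    require_presso_sign: bool = True       # corrected estimate sign-consistent
    mediation_alpha: float = 0.05
    bh_correction: bool = False            # optional Benjamini-Hochberg on links


@dataclass
class PipelineConfig:
    exposure_paths: dict[str, str] = field(default_factory=dict)
    mediator_paths: dict[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    simulation: dict | None = None          # synthdata study block instead of paths
    criteria: instr.InstrumentCriteria = field(default_factory=instr.InstrumentCriteria)
    battery: uvmr.BatterySettings = field(default_factory=uvmr.BatterySettings)
    screening: ScreeningSettings = field(default_factory=ScreeningSettings)
    ld_matrix_path: str | None = None
    seed: int = 0
    output_dir: str = "mr_report"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        cfg.exposure_paths = dict(raw.get("exposures", {}))
        cfg.mediator_paths = dict(raw.get("mediators", {}))
        cfg.outcome_path = raw.get("outcome")
        cfg.simulation = raw.get("simulation")
        if (cfg.simulation is not None) == bool(cfg.exposure_paths):
            raise ValueError(
                "provide exactly one of file paths or a simulation block")
        for key, val in raw.get("criteria", {}).items():
            setattr(cfg.criteria, key, val)
        for key, val in raw.get("battery", {}).items():
            setattr(cfg.battery, key, val)
        for key, val in raw.get("screening", {}).items():
            setattr(cfg.screening, key, val)
        cfg.ld_matrix_path = raw.get("ld_matrix")
        cfg.seed = int(raw.get("seed", 0))
        cfg.output_dir = raw.get("output_dir", "mr_report")
        return cfg


@dataclass
class StudyReport:
    battery_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    pleiotropy: dict[str, uvmr.PleiotropyReport] = field(default_factory=dict)
    presso: dict[str, object] = field(default_factory=dict)
    verdicts: dict[str, bool] = field(default_factory=dict)
    heatmap: pd.DataFrame | None = None
    volcano: pd.DataFrame | None = None          # exposure x mediator links
    mediator_forest: pd.DataFrame | None = None  # MVMR mediator -> outcome
    decompositions: list[med.MediationDecomposition] = field(default_factory=list)
    mediation: pd.DataFrame | None = None
    attrition: list[dict] = field(default_factory=list)

    def log_stage(self, stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        self.attrition.append(entry)
        log.info("stage %s: %s", stage, counts)


def _screen_exposure(name: str, battery: uvmr.BatteryResult,
                     settings: ScreeningSettings) -> bool:
    ivw_est = battery.get("IVW (random effects)") or battery.get("IVW (fixed effects)")
    if ivw_est is None or ivw_est.pval >= settings.alpha:
        return False
    if settings.require_egger_intercept:
        entry = battery.pleiotropy.entries.get("plain")
        if entry is None or entry["intercept_pval"] <= settings.alpha:
            return False
    if settings.require_presso_sign:
        pr = battery.presso
        if pr is None or pr.corrected is None:
            return False
        if np.sign(pr.corrected.beta) != np.sign(ivw_est.beta):
            return False
    return True


def run_study(exposures: Mapping[str, pd.DataFrame],
              mediators: Mapping[str, pd.DataFrame],
              outcome: pd.DataFrame,
              ld: instr.LDSource | None = None,
              criteria: instr.InstrumentCriteria | None = None,
              battery_settings: uvmr.BatterySettings | None = None,
              screening: ScreeningSettings | None = None,
              seed: int = 0) -> StudyReport:
    """Run the full two-step mediation study over in-memory tables."""
    ld = ld or instr.IndependentLD()
    criteria = criteria or instr.InstrumentCriteria()
    battery_settings = battery_settings or uvmr.BatterySettings()
    screening = screening or ScreeningSettings()
    report = StudyReport()

    # stage 1: exposure -> outcome screening
    retained: dict[str, tuple[instr.InstrumentSet, uvmr.MREstimate]] = {}
    heat_rows = {}
    for i, (name, exp_df) in enumerate(exposures.items()):
        try:
            hs = sumstats.harmonize(exp_df, {"outcome": outcome},
                                    primary_name="exposure")
            iset = instr.select_instruments(hs, ld, criteria)
            bset = replace(battery_settings, seed=seed + i)
            battery = uvmr.run_battery(iset.mr_input("outcome"), bset)
        except (sumstats.HarmonizationError, instr.EmptyInstrumentError,
                uvmr.EstimationError) as exc:
            report.log_stage("uvmr_exposure_outcome", exposure=name,
                             failed=1, reason=str(exc))
            report.verdicts[name] = False
            continue
        report.battery_tables[name] = battery.table()
        report.pleiotropy[name] = battery.pleiotropy
        report.presso[name] = battery.presso
        heat_rows[name] = battery.pval_row()
        verdict = _screen_exposure(name, battery, screening)
        report.verdicts[name] = verdict
        if verdict:
            ivw_est = (battery.get("IVW (random effects)")
                       or battery.get("IVW (fixed effects)"))
            retained[name] = (iset, ivw_est)
    report.heatmap = pd.DataFrame(heat_rows).T if heat_rows else pd.DataFrame()
    report.log_stage("screening", n_exposures=len(exposures),
                     retained=len(retained),
                     excluded=len(exposures) - len(retained))

    # stage 2: retained exposure -> each mediator (beta1)
    volcano_rows = []
    links: list[tuple[str, str, uvmr.MREstimate, instr.InstrumentSet]] = []
    for ename, (iset, total_est) in retained.items():
        exp_df = exposures[ename]
        for mname, med_df in mediators.items():
            try:
                hs = sumstats.harmonize(exp_df, {"mediator": med_df},
                                        primary_name="exposure")
                iset_m = instr.select_instruments(hs, ld, criteria)
                est1 = uvmr.ivw(iset_m.mr_input("mediator"),
                                battery_settings.effects_model)
            except (sumstats.HarmonizationError, instr.EmptyInstrumentError,
                    uvmr.EstimationError) as exc:
                report.log_stage("uvmr_exposure_mediator", exposure=ename,
                                 mediator=mname, failed=1, reason=str(exc))
                continue
            volcano_rows.append({"exposure": ename, "mediator": mname,
                                 "beta": est1.beta, "se": est1.se,
                                 "pval": est1.pval, "n_snp": est1.n_snp})
            if est1.pval < screening.alpha:
                links.append((ename, mname, est1, iset))
    report.volcano = pd.DataFrame(
        volcano_rows, columns=["exposure", "mediator", "beta", "se", "pval",
                               "n_snp"])
    report.log_stage("exposure_mediator_links",
                     tested=len(volcano_rows), retained=len(links))

    # stage 3: MVMR {exposure, mediator} -> outcome (beta2)
    forest_rows = []
    decomps = []
    for ename, mname, est1, iset in links:
        try:
            med_df = mediators[mname]
            # mediator's own instruments
            hs_m = sumstats.harmonize(med_df, {"outcome": outcome},
                                      primary_name="exposure")
            iset_med = instr.select_instruments(hs_m, ld, criteria)
            union_ids = sorted(set(iset.variant_ids) | set(iset_med.variant_ids))
            hs_all = sumstats.harmonize(
                exposures[ename][exposures[ename]["variant_id"].isin(union_ids)],
                {"mediator": med_df, "outcome": outcome},
                primary_name="exposure")
            # re-clump the union jointly on exposure significance order
            joint_criteria = instr.InstrumentCriteria(
                pval_threshold=1.0 - 1e-12, clump_r2=criteria.clump_r2,
                clump_window_kb=criteria.clump_window_kb, f_min=0.0)
            kept = instr.clump(hs_all, ld, joint_criteria)
            hs_all = hs_all.subset(kept)
            t = hs_all.table
            mv = med.mvmr_ivw(med.MVMRInput(
                variant_ids=list(t["variant_id"]),
                exposures=[ename, mname],
                bx=np.column_stack([t["beta_exposure"], t["beta_mediator"]]),
                sx=np.column_stack([t["se_exposure"], t["se_mediator"]]),
                by=t["beta_outcome"].to_numpy(dtype=float),
                sy=t["se_outcome"].to_numpy(dtype=float)))
        except (sumstats.HarmonizationError, instr.EmptyInstrumentError,
                uvmr.EstimationError) as exc:
            report.log_stage("mvmr", exposure=ename, mediator=mname,
                             failed=1, reason=str(exc))
            continue
        beta2, se2 = mv.beta[mname], mv.se[mname]
        forest_rows.append({
            "exposure": ename, "mediator": mname, "beta2": beta2, "se": se2,
            "ci_low": mv.ci_low[mname], "ci_high": mv.ci_high[mname],
            "or": float(np.exp(beta2)), "pval": mv.pval[mname],
            "n_snp": mv.n_snp, "conditional_f": mv.conditional_f[mname]})
        if mv.pval[mname] < screening.alpha:
            total_est = retained[ename][1]
            try:
                decomps.append(med.decompose(
                    total_est, est1, beta2, se2,
                    exposure=ename, mediator=mname, outcome="outcome"))
            except uvmr.EstimationError as exc:
                report.log_stage("decompose", exposure=ename, mediator=mname,
                                 failed=1, reason=str(exc))
    report.mediator_forest = pd.DataFrame(
        forest_rows, columns=["exposure", "mediator", "beta2", "se", "ci_low",
                              "ci_high", "or", "pval", "n_snp",
                              "conditional_f"])
    report.log_stage("mvmr", tested=len(links), retained=len(decomps))

    # stage 4: decomposition filter
    kept, attr = med.filter_mediations(decomps, screening.mediation_alpha)
    report.decompositions = kept
    report.mediation = med.mediation_table(kept)
    report.log_stage("mediation_filter", **attr)
    return report


def run_study_from_config(config: PipelineConfig) -> StudyReport:
    """Resolve a config (files or simulation block) and run the study."""
    ld: instr.LDSource = instr.IndependentLD()
    if config.simulation is not None:
        sim = dict(config.simulation)
        n_exp = int(sim.pop("n_exposures", 1))
        n_med = int(sim.pop("n_mediators", 1))
        causal = {k: sim.pop(k) for k in ("causal_exposure", "causal_mediator",
                                          "theta_xm", "theta_my",
                                          "theta_xy_direct") if k in sim}
        base = synthdata.SimulationConfig(**sim)
        exposures, mediators, outcome, _, block_map = synthdata.simulate_study(
            n_exp, n_med, base=base, seed=config.seed, **causal)
        ld = instr.BlockLD(block_map, base.ld_r2)
    else:
        exposures = {name: sumstats.read_sumstats(p)
                     for name, p in config.exposure_paths.items()}
        mediators = {name: sumstats.read_sumstats(p)
                     for name, p in config.mediator_paths.items()}
        if config.outcome_path is None:
            raise ValueError("outcome path required when not simulating")
        outcome = sumstats.read_sumstats(config.outcome_path)
        if config.ld_matrix_path:
            ld = instr.MatrixLD.from_file(config.ld_matrix_path)
    return run_study(exposures, mediators, outcome, ld=ld,
                     criteria=config.criteria,
                     battery_settings=config.battery,
                     screening=config.screening, seed=config.seed)


def export_report(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the report as tab-delimited tables; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    forest_rows = []
    for name, table in report.battery_tables.items():
        t = table.copy()
        t.insert(0, "exposure", name)
        forest_rows.append(t)
    forest = (pd.concat(forest_rows, ignore_index=True) if forest_rows
              else pd.DataFrame(columns=["exposure", "method", "beta", "se",
                                         "ci_low", "ci_high", "pval", "or",
                                         "n_snp", "q_stat", "q_pval"]))
    for fname, df in [
        ("forest_table.tsv", forest),
        ("heatmap_table.tsv",
         report.heatmap if report.heatmap is not None else pd.DataFrame()),
        ("volcano_table.tsv",
         report.volcano if report.volcano is not None
         else pd.DataFrame(columns=["exposure", "mediator", "beta", "se",
                                    "pval", "n_snp"])),
        ("mediator_forest_table.tsv",
         report.mediator_forest if report.mediator_forest is not None
         else pd.DataFrame()),
        ("mediation_table.tsv",
         report.mediation if report.mediation is not None
         else pd.DataFrame(columns=med.MEDIATION_TABLE_COLUMNS)),
    ]:
        path = outdir / fname
        df.to_csv(path, sep="\t",
                  index=fname == "heatmap_table.tsv")
        written.append(path)
    attr = pd.DataFrame(report.attrition)
    path = outdir / "attrition_log.tsv"
    attr.to_csv(path, sep="\t", index=False)
    written.append(path)
    return written
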