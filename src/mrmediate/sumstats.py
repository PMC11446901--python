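"""Reading, validation and cross-trait harmonization of GWAS summary statistics.

Two-sample MR needs per-variant effects from several GWAS expressed for the
same effect allele.  :func:`harmonize` intersects variant sets, flips swapped
alleles (negating beta, reflecting EAF), resolves strand flips through allele
complements, and drops strand-ambiguous palindromic variants whose allele
frequency is too close to 0.5 to infer the strand.  Variants are matched by
ID; coordinates are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synthdata import SUMSTAT_COLUMNS

__all__ = [
    "SchemaError",
    "HarmonizationError",
    "HarmonizedSet",
    "read_sumstats",
    "harmonize",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NUMERIC = ["pos", "eaf", "beta", "se", "pval", "n"]


class SchemaError(ValueError):
    """Input file lacks a required column or is unusable as a whole."""


class HarmonizationError(ValueError):
    """Harmonization produced no usable variants."""


def read_sumstats(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-delimited summary-statistic file into the standard schema.

    ``column_map`` maps standard names (``variant_id`` ... ``n``) to the
    file's header names for non-standard dialects.  Rows violating the
    per-variant invariants (se > 0, eaf in [0,1], pval in (0,1], n > 0,
    distinct alleles) are rejected and counted; the count is logged and
    stored in ``df.attrs["n_rejected"]``.  More than 50% rejected rows is a
    file-level error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {v: k for k, v in (column_map or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df[SUMSTAT_COLUMNS].copy()
    if df.empty:
        log.warning("%s: header-only file, returning empty set", path)
        df = df.astype({c: float for c in _NUMERIC} | {"pos": int, "n": int},
                       errors="ignore")
        df.attrs["n_rejected"] = 0
        return df

    n_in = len(df)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()
    ok = (
        df[_NUMERIC].notna().all(axis=1)
        & (df["se"] > 0)
        & df["eaf"].between(0.0, 1.0)
        & (df["pval"] > 0) & (df["pval"] <= 1.0)
        & (df["n"] > 0)
        & (df["effect_allele"] != df["other_allele"])
        & df["effect_allele"].str.fullmatch("[ACGT]+")
        & df["other_allele"].str.fullmatch("[ACGT]+")
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%s: rejected %d/%d invalid rows", path, n_bad, n_in)
    if n_bad > 0.5 * n_in:
        raise SchemaError(f"{path}: {n_bad}/{n_in} rows rejected (>50%)")
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)
    df.attrs["n_rejected"] = n_bad
    return df


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _COMPLEMENT.get(ea) == oa


@dataclass
class HarmonizedSet:
    """Variants with per-trait effects aligned to a common effect allele.

    ``table`` is wide: variant_id, chrom, pos, effect_allele, other_allele,
    then beta_<trait>, se_<trait>, eaf_<trait>, pval_<trait>, n_<trait> and a
    flipped_<trait> provenance flag for every trait.
    """

    traits: list[str]
    table: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def trait_table(self, trait: str) -> pd.DataFrame:
        """Project one trait back to the standard summary-statistic schema."""
        if trait not in self.traits:
            raise KeyError(trait)
        t = self.table
        out = pd.DataFrame({
            "variant_id": t["variant_id"], "chrom": t["chrom"], "pos": t["pos"],
            "effect_allele": t["effect_allele"], "other_allele": t["other_allele"],
            "eaf": t[f"eaf_{trait}"], "beta": t[f"beta_{trait}"],
            "se": t[f"se_{trait}"], "pval": t[f"pval_{trait}"],
            "n": t[f"n_{trait}"],
        })
        return out.reset_index(drop=True)

    def subset(self, variant_ids) -> "HarmonizedSet":
        keep = self.table["variant_id"].isin(set(variant_ids))
        return HarmonizedSet(traits=list(self.traits),
                             table=self.table.loc[keep].reset_index(drop=True),
                             dropped=dict(self.dropped))


def harmonize(primary: pd.DataFrame,
              others: Mapping[str, pd.DataFrame],
              palindromic_eaf_window: float = 0.08,
              primary_name: str = "exposure") -> HarmonizedSet:
    """Align one or more trait tables to the primary table's effect alleles.

    For each variant present in every table: matching alleles are kept;
    swapped alleles flip the sign of beta and reflect EAF; strand flips are
    resolved via complements; palindromic (A/T, C/G) variants are dropped
    when any trait's EAF lies within ``palindromic_eaf_window`` of 0.5,
    otherwise their orientation is inferred from allele frequency.
    Unresolvable allele pairs are dropped.  Raises
    :class:`HarmonizationError` when nothing survives.
    """
    traits = [primary_name, *others.keys()]
    idx_p = primary.set_index("variant_id")
    common = set(idx_p.index)
    for df in others.values():
        common &= set(df["variant_id"])
    dropped = {"missing": len(idx_p) - len(common), "palindromic": 0,
               "unresolvable": 0}
    if not common:
        raise HarmonizationError(
            f"empty variant intersection across traits (primary has {len(idx_p)})")

    order = [v for v in primary["variant_id"] if v in common]
    base = idx_p.loc[order]
    out = {
        "variant_id": order,
        "chrom": base["chrom"].to_numpy(),
        "pos": base["pos"].to_numpy(),
        "effect_allele": base["effect_allele"].to_numpy(),
        "other_allele": base["other_allele"].to_numpy(),
    }
    for col in ("beta", "se", "eaf", "pval", "n"):
        out[f"{col}_{primary_name}"] = base[col].to_numpy()
    out[f"flipped_{primary_name}"] = np.zeros(len(order), dtype=bool)

    keep = np.ones(len(order), dtype=bool)
    for name, df in others.items():
        o = df.set_index("variant_id").loc[order]
        beta = o["beta"].to_numpy(dtype=float).copy()
        eaf = o["eaf"].to_numpy(dtype=float).copy()
        flipped = np.zeros(len(order), dtype=bool)
        for i, vid in enumerate(order):
            ea_p, oa_p = out["effect_allele"][i], out["other_allele"][i]
            ea_o, oa_o = o["effect_allele"].iloc[i], o["other_allele"].iloc[i]
            if _is_palindromic(ea_p, oa_p):
                if ea_o not in (ea_p, oa_p) or oa_o not in (ea_p, oa_p):
                    dropped["unresolvable"] += 1
                    keep[i] = False
                    continue
                eaf_p = out[f"eaf_{primary_name}"][i]
                near_half = (abs(eaf_p - 0.5) < palindromic_eaf_window
                             or abs(eaf[i] - 0.5) < palindromic_eaf_window)
                if near_half:
                    dropped["palindromic"] += 1
                    keep[i] = False
                    continue
                same_label = (ea_o == ea_p)
                # infer strand: aligned frequencies sit on the same side of 0.5
                same_freq_side = (eaf_p - 0.5) * (eaf[i] - 0.5) > 0
                if same_label != same_freq_side:
                    beta[i] = -beta[i]
                    eaf[i] = 1.0 - eaf[i]
                    flipped[i] = True
                continue
            if (ea_o, oa_o) == (ea_p, oa_p):
                continue
            if (ea_o, oa_o) == (oa_p, ea_p):
                beta[i] = -beta[i]
                eaf[i] = 1.0 - eaf[i]
                flipped[i] = True
                continue
            cea = _COMPLEMENT.get(ea_o, "?") if len(ea_o) == 1 else "?"
            coa = _COMPLEMENT.get(oa_o, "?") if len(oa_o) == 1 else "?"
            if (cea, coa) == (ea_p, oa_p):
                continue  # pure strand flip, orientation already matches
            if (cea, coa) == (oa_p, ea_p):
                beta[i] = -beta[i]
                eaf[i] = 1.0 - eaf[i]
                flipped[i] = True
                continue
            dropped["unresolvable"] += 1
            keep[i] = False
        out[f"beta_{name}"] = beta
        out[f"eaf_{name}"] = eaf
        out[f"se_{name}"] = o["se"].to_numpy(dtype=float)
        out[f"pval_{name}"] = o["pval"].to_numpy(dtype=float)
        out[f"n_{name}"] = o["n"].to_numpy()
        out[f"flipped_{name}"] = flipped

    table = pd.DataFrame(out).loc[keep].reset_index(drop=True)
    if table.empty:
        raise HarmonizationError(
            f"no variants survive harmonization; dropped counts: {dropped}")
    log.info("harmonized %d variants across %s (dropped: %s)",
             len(table), traits, dropped)
    return HarmonizedSet(traits=traits, table=table, dropped=dropped)
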