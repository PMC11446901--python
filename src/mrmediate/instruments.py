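"""Instrument selection: significance screen, LD clumping, strength filter.

Candidate instruments must pass, in order, (a) an exposure significance
threshold (default P < 1e-5, the conventional relaxed threshold for
microbial-taxon GWAS), (b) greedy LD clumping at pairwise r² < 0.001 within
a 10,000 kb window, and (c) a per-variant instrument-strength filter that
keeps only F > 10, where

    r² = 2β²p(1-p) / (2β²p(1-p) + se²·2N·p(1-p))      (variance explained)
    F  = r²(N - 1 - k) / ((1 - r²)·k)

with N the per-association sample size and k the number of SNPs (k = 1 for
the per-variant screen; a set-level F over the summed r² is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol

import numpy as np
import pandas as pd

from .sumstats import HarmonizedSet

__all__ = [
    "InstrumentCriteria",
    "InstrumentSet",
    "EmptyInstrumentError",
    "IndependentLD",
    "BlockLD",
    "MatrixLD",
    "variance_explained",
    "f_statistic",
    "clump",
    "select_instruments",
]


class EmptyInstrumentError(ValueError):
    """No variant survives instrument selection; carries attrition counts."""

    def __init__(self, attrition: Mapping[str, int]):
        self.attrition = dict(attrition)
        super().__init__(f"no instruments survive selection; attrition: {self.attrition}")


@dataclass
class InstrumentCriteria:
    pval_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10000.0
    f_min: float = 10.0

    def validate(self) -> None:
        if not 0.0 < self.pval_threshold < 1.0:
            raise ValueError("pval_threshold must lie in (0, 1)")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")
        if self.f_min < 0:
            raise ValueError("f_min must be >= 0")


class LDSource(Protocol):
    """Pairwise LD lookup; unknown pairs are treated as r² = 0."""

    def r2(self, a: str, b: str) -> float: ...


class IndependentLD:
    """All variants mutually independent (r² = 0)."""

    def r2(self, a: str, b: str) -> float:
        return 0.0


class BlockLD:
    """Block-diagonal LD: constant r² within a block, zero across blocks."""

    def __init__(self, block_of: Mapping[str, int], within_r2: float):
        self.block_of = dict(block_of)
        self.within_r2 = float(within_r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ba, bb = self.block_of.get(a), self.block_of.get(b)
        if ba is None or bb is None or ba != bb:
            return 0.0
        return self.within_r2


class MatrixLD:
    """Dense LD r² matrix keyed by variant_id."""

    def __init__(self, matrix: pd.DataFrame):
        if list(matrix.index) != list(matrix.columns):
            raise ValueError("LD matrix must be square with matching labels")
        self.matrix = matrix

    @classmethod
    def from_file(cls, path: str | Path) -> "MatrixLD":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self.matrix.at[a, b])
        except KeyError:
            return 0.0


def variance_explained(beta, se, eaf, n):
    """Per-variant phenotypic variance explained (vectorized).

    r² = 2β²p(1-p) / (2β²p(1-p) + se²·2N·p(1-p)); defined for 0 < eaf < 1,
    se > 0 and n > 1.
    """
    beta, se, eaf, n = (np.asarray(x, dtype=float) for x in (beta, se, eaf, n))
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise ValueError("eaf must lie strictly inside (0, 1)")
    if np.any(se <= 0.0):
        raise ValueError("se must be > 0")
    if np.any(n <= 1):
        raise ValueError("n must be > 1")
    het = 2.0 * eaf * (1.0 - eaf)
    num = beta ** 2 * het
    out = num / (num + se ** 2 * n * het)
    return out if out.ndim else float(out)


def f_statistic(r2, n, k=1):
    """Instrument-strength F = r²(N-1-k) / ((1-r²)k)."""
    r2, n, k = (np.asarray(x, dtype=float) for x in (r2, n, k))
    if np.any((r2 < 0.0) | (r2 >= 1.0)):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(k < 1):
        raise ValueError("k must be >= 1")
    if np.any(n <= k + 1):
        raise ValueError("n must exceed k + 1")
    out = r2 * (n - 1.0 - k) / ((1.0 - r2) * k)
    return out if out.ndim else float(out)


@dataclass
class InstrumentSet:
    """Selected instruments with per-variant and set-level strength metrics."""

    harmonized: HarmonizedSet
    exposure: str
    r2: pd.Series          # per-variant variance explained, indexed by variant_id
    f: pd.Series           # per-variant F (k = 1)
    total_r2: float
    overall_f: float
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        return self.harmonized.table

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def __len__(self) -> int:
        return len(self.table)

    def mr_input(self, outcome: str):
        from .uvmr import MRInput
        t = self.table
        return MRInput(
            variant_ids=list(t["variant_id"]),
            bx=t[f"beta_{self.exposure}"].to_numpy(dtype=float),
            sx=t[f"se_{self.exposure}"].to_numpy(dtype=float),
            by=t[f"beta_{outcome}"].to_numpy(dtype=float),
            sy=t[f"se_{outcome}"].to_numpy(dtype=float),
        )


def clump(candidates: HarmonizedSet, ld: LDSource,
          criteria: InstrumentCriteria | None = None,
          exposure: str = "exposure") -> list[str]:
    """Greedy LD clumping; returns retained variant_ids.

    Variants are visited by ascending exposure p-value (ties broken by
    variant_id so the result is independent of input row order); a variant is
    accepted iff its r² with every already-accepted variant on the same
    chromosome within the window is below ``clump_r2``.
    """
    criteria = criteria or InstrumentCriteria()
    criteria.validate()
    t = candidates.table
    order = t.sort_values([f"pval_{exposure}", "variant_id"], kind="mergesort")
    window_bp = criteria.clump_window_kb * 1000.0
    accepted: list[tuple[str, str, int]] = []  # (id, chrom, pos)
    for _, row in order.iterrows():
        vid, chrom, pos = row["variant_id"], row["chrom"], row["pos"]
        ok = True
        for aid, achrom, apos in accepted:
            if str(achrom) == str(chrom) and abs(int(apos) - int(pos)) <= window_bp:
                if ld.r2(vid, aid) >= criteria.clump_r2:
                    ok = False
                    break
        if ok:
            accepted.append((vid, chrom, pos))
    return [a[0] for a in accepted]


def select_instruments(harmonized: HarmonizedSet, ld: LDSource,
                       criteria: InstrumentCriteria | None = None,
                       exposure: str = "exposure") -> InstrumentSet:
    """Apply significance threshold, LD clumping and the F > f_min filter.

    Raises :class:`EmptyInstrumentError` (with stage-by-stage attrition
    counts) when nothing survives.
    """
    criteria = criteria or InstrumentCriteria()
    criteria.validate()
    t = harmonized.table
    attrition = {"input": len(t)}

    sig = t[t[f"pval_{exposure}"] < criteria.pval_threshold]
    attrition["significant"] = len(sig)
    if sig.empty:
        raise EmptyInstrumentError(attrition)

    sig_set = HarmonizedSet(traits=harmonized.traits,
                            table=sig.reset_index(drop=True))
    kept_ids = clump(sig_set, ld, criteria, exposure)
    attrition["clumped"] = len(kept_ids)
    clumped = sig_set.subset(kept_ids)

    ct = clumped.table
    r2 = variance_explained(ct[f"beta_{exposure}"], ct[f"se_{exposure}"],
                            ct[f"eaf_{exposure}"], ct[f"n_{exposure}"])
    f = f_statistic(r2, ct[f"n_{exposure}"].to_numpy(dtype=float), 1)
    strong = np.asarray(f) > criteria.f_min  # F <= f_min are weak, excluded
    attrition["strong"] = int(strong.sum())
    if not strong.any():
        raise EmptyInstrumentError(attrition)

    final = clumped.subset(ct.loc[strong, "variant_id"])
    ids = final.table["variant_id"]
    r2_s = pd.Series(np.asarray(r2)[strong], index=ids, name="r2")
    f_s = pd.Series(np.asarray(f)[strong], index=ids, name="f")
    total_r2 = float(r2_s.sum())
    n_mean = float(final.table[f"n_{exposure}"].mean())
    k = len(final.table)
    overall_f = f_statistic(min(total_r2, 1.0 - 1e-12), n_mean, k) \
        if n_mean > k + 1 else float("nan")
    return InstrumentSet(harmonized=final, exposure=exposure, r2=r2_s, f=f_s,
                         total_r2=total_r2, overall_f=overall_f,
                         attrition=attrition)
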