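"""Plasmid copy number and mRNA fold changes from qPCR crossing points.

The genetic tug-of-war (gTOW) technique drives a target gene to a high
plasmid copy number; the copy number is read out by real-time qPCR of the
plasmid-borne ``leu2d`` marker against the single-copy genomic ``LEU3``
locus. mRNA fold changes use the standard relative-quantification (ddCp)
scheme against ``ACT1``, generalized to per-primer amplification
efficiencies (Pfaffl form); the default efficiency 2.0 is perfect
per-cycle doubling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CpRecord",
    "CopyNumberEstimate",
    "plasmid_copy_number",
    "mrna_fold_change",
    "copy_numbers_from_table",
    "mrna_folds_from_table",
    "CP_COLUMNS",
]

PRIMER_TARGETS = ("leu2d", "LEU3", "TAP", "ACT1")
CP_COLUMNS = ["sample_id", "primer_target", "cp", "efficiency", "replicate", "condition"]


@dataclass(frozen=True)
class CpRecord:
    """One qPCR crossing-point measurement."""

    sample_id: str
    primer_target: str
    cp: float
    efficiency: float = 2.0
    replicate: int = 1
    condition: str = "single"

    def __post_init__(self) -> None:
        if self.primer_target not in PRIMER_TARGETS:
            raise ValueError(f"unknown primer target {self.primer_target!r}")
        if self.cp <= 0:
            raise ValueError("Cp must be positive")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    copies: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.copies < 0 or self.sd < 0 or self.n < 1:
            raise ValueError("invalid copy-number aggregate")


def plasmid_copy_number(
    cp_leu2d: float,
    cp_leu3: float,
    eff_leu2d: float = 2.0,
    eff_leu3: float = 2.0,
) -> float:
    """Plasmid copies per cell relative to the single-copy LEU3 locus.

    Efficiency-corrected relative quantification:
    ``eff_leu3 ** cp_leu3 / eff_leu2d ** cp_leu2d``, which reduces to
    ``2 ** (cp_leu3 - cp_leu2d)`` at perfect efficiency. The marker
    amplifying one cycle earlier than the reference means twice as many
    template copies.
    """
    for cp, eff in ((cp_leu2d, eff_leu2d), (cp_leu3, eff_leu3)):
        if cp is None or np.isnan(cp):
            raise ValueError("missing Cp value")
        if not (1.0 < eff <= 2.0):
            raise ValueError("efficiency must lie in (1, 2]")
    return float(eff_leu3**cp_leu3 / eff_leu2d**cp_leu2d)


def mrna_fold_change(
    cp_target_multi: float,
    cp_ref_multi: float,
    cp_target_single: float,
    cp_ref_single: float,
    eff_target: float = 2.0,
    eff_ref: float = 2.0,
) -> float:
    """Multi/Single mRNA fold change by reference-normalized ddCp.

    ``eff_target ** (cp_target_single - cp_target_multi)`` divided by
    ``eff_ref ** (cp_ref_single - cp_ref_multi)``; with both efficiencies
    at 2 this is ``2 ** -[(Cp_t,m - Cp_r,m) - (Cp_t,s - Cp_r,s)]``.
    Adding a constant to all four Cp values (a plate shift) cancels.
    """
    vals = (cp_target_multi, cp_ref_multi, cp_target_single, cp_ref_single)
    if any(v is None or np.isnan(v) for v in vals):
        raise ValueError("missing Cp value")
    num = eff_target ** (cp_target_single - cp_target_multi)
    den = eff_ref ** (cp_ref_single - cp_ref_multi)
    return float(num / den)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns: {missing}")


def copy_numbers_from_table(cps: pd.DataFrame) -> list[CopyNumberEstimate]:
    """Per-sample gTOW copy numbers, mean ± s.d. over replicates.

    The table follows ``CP_COLUMNS``; each replicate must contain one
    leu2d and one LEU3 row per sample.
    """
    _require_columns(cps, ["sample_id", "primer_target", "cp", "replicate"], "Cp")
    eff = cps["efficiency"] if "efficiency" in cps.columns else 2.0
    cps = cps.assign(efficiency=eff)
    out: list[CopyNumberEstimate] = []
    for sample, sg in cps.groupby("sample_id", sort=True):
        estimates = []
        for rep, rg in sg.groupby("replicate", sort=True):
            rows = {t: rg[rg["primer_target"] == t] for t in ("leu2d", "LEU3")}
            for t, sel in rows.items():
                if len(sel) != 1:
                    raise ValueError(
                        f"sample {sample} replicate {rep}: expected one {t} row, "
                        f"found {len(sel)}"
                    )
            d, r = rows["leu2d"].iloc[0], rows["LEU3"].iloc[0]
            estimates.append(
                plasmid_copy_number(
                    float(d["cp"]), float(r["cp"]),
                    float(d["efficiency"]), float(r["efficiency"]),
                )
            )
        arr = np.asarray(estimates)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(CopyNumberEstimate(str(sample), float(arr.mean()), sd, arr.size))
    return out


def mrna_folds_from_table(
    cps: pd.DataFrame,
    *,
    target: str = "TAP",
    reference: str = "ACT1",
) -> pd.DataFrame:
    """Per-sample Multi/Single mRNA fold changes from an RT-qPCR Cp table.

    Requires target and reference Cp rows in both conditions for each
    replicate; replicate fold changes aggregate as mean ± sample s.d.
    """
    _require_columns(
        cps, ["sample_id", "primer_target", "cp", "replicate", "condition"], "Cp"
    )
    eff = cps["efficiency"] if "efficiency" in cps.columns else 2.0
    cps = cps.assign(efficiency=eff)
    records = []
    for sample, sg in cps.groupby("sample_id", sort=True):
        folds = []
        for rep, rg in sg.groupby("replicate", sort=True):
            cells = {}
            for t in (target, reference):
                for cond in ("single", "multi"):
                    sel = rg[(rg["primer_target"] == t) & (rg["condition"] == cond)]
                    if len(sel) != 1:
                        raise ValueError(
                            f"sample {sample} replicate {rep}: expected one "
                            f"{t}/{cond} row, found {len(sel)}"
                        )
                    cells[(t, cond)] = sel.iloc[0]
            folds.append(
                mrna_fold_change(
                    float(cells[(target, "multi")]["cp"]),
                    float(cells[(reference, "multi")]["cp"]),
                    float(cells[(target, "single")]["cp"]),
                    float(cells[(reference, "single")]["cp"]),
                    float(cells[(target, "single")]["efficiency"]),
                    float(cells[(reference, "single")]["efficiency"]),
                )
            )
        arr = np.asarray(folds)
        records.append(
            {
                "gene": sample,
                "kind": "mrna",
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n": int(arr.size),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["gene", "kind", "mean", "sd", "n"]
    )
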