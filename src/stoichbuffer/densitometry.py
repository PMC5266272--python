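"""Quantitative densitometry: band intensities to fold-change statistics.

Western-blot and stained-gel band intensities (arbitrary units, background
already measured per band by the imaging software) are turned into the
fold-change quantities used throughout the screen:

* **protein fold change** — the Multi/Single ratio of the tagged-protein
  (WB) signal divided by the Multi/Single ratio of the loading-control
  (total-protein gel) signal, so that loading differences cancel;
* **per-copy fold change** — total fold change divided by the gene copy
  number, the natural scale for a tagged-on-plasmid design where the
  Single condition carries exactly one copy;
* **ubiquitination level** — poly-ubiquitin smear intensity normalized by
  the immunoprecipitated loading amount;
* **CHX decay series** — loading-normalized target levels relative to the
  time of translation shutoff, with a log-linear half-life estimate.

Saturated bands poison any ratio they enter: saturation is carried as an
input flag and raises rather than silently clipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandMeasurement",
    "FoldChange",
    "DecaySeries",
    "net_intensity",
    "linearity_check",
    "protein_fold_change",
    "per_copy_fold_change",
    "ubiquitination_level",
    "chx_series",
    "estimate_half_life",
    "fold_changes_from_table",
    "BAND_COLUMNS",
]

BAND_ROLES = ("target", "loading", "ubiquitin_smear", "ip_loading")
CONDITIONS = ("single", "multi")

#: Column order of the band-intensity exchange table.
BAND_COLUMNS = [
    "sample_id",
    "lane_id",
    "band_role",
    "condition",
    "replicate",
    "raw_intensity",
    "background",
    "dilution",
    "saturated",
]


@dataclass(frozen=True)
class BandMeasurement:
    """One quantified band from a blot or stained gel."""

    sample_id: str
    lane_id: str
    band_role: str
    condition: str
    replicate: int
    raw_intensity: float
    background: float
    dilution: float = 1.0
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.band_role not in BAND_ROLES:
            raise ValueError(f"unknown band_role {self.band_role!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.raw_intensity < 0 or self.background < 0:
            raise ValueError("intensities must be nonnegative")
        if self.dilution <= 0:
            raise ValueError("dilution must be positive")

    @property
    def net(self) -> float:
        return net_intensity(self.raw_intensity, self.background)


@dataclass(frozen=True)
class FoldChange:
    """Replicate-aggregated fold change (mean ± sample s.d.)."""

    gene: str
    kind: str  # protein | protein_per_copy | mrna | ubiquitination | complex
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class DecaySeries:
    """Loading-normalized decay curve relative to time 0.

    ``half_life`` is in hours; ``None`` means no decay was detectable
    (non-negative fitted slope).
    """

    times: tuple[float, ...]
    relative_levels: tuple[float, ...]
    half_life: float | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.relative_levels):
            raise ValueError("times and relative_levels differ in length")
        if self.times and self.times[0] != 0:
            raise ValueError("time series must start at 0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.relative_levels and not math.isclose(self.relative_levels[0], 1.0):
            raise ValueError("relative level at time 0 must be 1")


def net_intensity(raw: float, background: float) -> float:
    """Background-subtracted band intensity.

    Raises if the background exceeds the raw signal — an invalid
    background region, never clipped to zero.
    """
    if raw < 0 or background < 0:
        raise ValueError("intensities must be nonnegative")
    if background > raw:
        raise ValueError(
            f"background {background} exceeds raw intensity {raw}: "
            "invalid background region"
        )
    return raw - background


def linearity_check(
    dilutions: Sequence[float],
    nets: Sequence[float],
    *,
    threshold: float = 0.95,
    saturated: Sequence[bool] | None = None,
) -> dict:
    """Dilution-series linearity of net intensity.

    Fits an ordinary least-squares line of net intensity against loaded
    amount and reports the squared Pearson correlation. A series passes
    (``in_linear_range``) when ``r_squared >= threshold`` and no point is
    flagged saturated. Zero variance in the responses (the fully
    saturated case) is defined as ``r_squared = 0`` and fails the flag.
    """
    dil = np.asarray(dilutions, dtype=float)
    net = np.asarray(nets, dtype=float)
    if dil.size < 3 or net.size != dil.size:
        raise ValueError("need >= 3 matched dilution points")
    d = np.diff(dil)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("dilutions must be strictly ordered")
    any_saturated = bool(saturated is not None and any(saturated))
    if np.ptp(net) == 0 or np.ptp(dil) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(dil, net)[0, 1] ** 2)
    return {
        "r_squared": r2,
        "in_linear_range": bool(r2 >= threshold and not any_saturated),
    }


def protein_fold_change(
    target_single: float,
    target_multi: float,
    loading_single: float,
    loading_multi: float,
    *,
    saturated: Sequence[bool] | None = None,
) -> float:
    """Loading-normalized Multi/Single protein fold change.

    The WB fold change (target_multi / target_single) is divided by the
    total-protein gel fold change (loading_multi / loading_single).
    All four net intensities must come from unsaturated bands.
    """
    vals = (target_single, target_multi, loading_single, loading_multi)
    if any(v <= 0 for v in vals):
        raise ValueError("all net intensities must be positive")
    if saturated is not None and any(saturated):
        raise ValueError("saturated band in fold-change computation")
    return (target_multi / target_single) / (loading_multi / loading_single)


def per_copy_fold_change(fc_total: float, copies_multi: float) -> float:
    """Fold change per gene copy for the tagged-on-plasmid design."""
    if fc_total < 0:
        raise ValueError("fold change must be nonnegative")
    if copies_multi < 1:
        raise ValueError("copy number must be >= 1")
    return fc_total / copies_multi


def ubiquitination_level(ub_smear: float, ip_loading: float) -> float:
    """Poly-ubiquitin smear intensity normalized by IP loading amount."""
    if ip_loading <= 0:
        raise ValueError("IP loading amount must be positive")
    if ub_smear < 0:
        raise ValueError("smear intensity must be nonnegative")
    return ub_smear / ip_loading


def estimate_half_life(times: Sequence[float], levels: Sequence[float]) -> float | None:
    """Half-life (h) from a log-linear OLS fit of ln(level) on time.

    Returns ``None`` when the fitted slope is non-negative (no decay).
    Refuses fits with fewer than 3 timepoints.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.size < 3:
        raise ValueError("half-life fit needs >= 3 timepoints")
    if np.any(y <= 0):
        raise ValueError("levels must be positive for a log-linear fit")
    slope = np.polyfit(t, np.log(y), 1)[0]
    if slope >= 0:
        return None
    return float(math.log(2) / abs(slope))


def chx_series(
    times: Sequence[float],
    target_nets: Sequence[float],
    loading_nets: Sequence[float],
) -> DecaySeries:
    """Cycloheximide-chase decay series.

    Each level is the target net intensity divided by the loading-control
    net intensity, expressed relative to the time-0 ratio. Half-life is
    estimated by log-linear OLS when at least three timepoints exist.
    """
    t = np.asarray(times, dtype=float)
    tgt = np.asarray(target_nets, dtype=float)
    ld = np.asarray(loading_nets, dtype=float)
    if not (t.size == tgt.size == ld.size):
        raise ValueError("times, target and loading vectors must match")
    if t.size == 0 or t[0] != 0:
        raise ValueError("time series must start at 0")
    if np.any(tgt <= 0) or np.any(ld <= 0):
        raise ValueError("net intensities must be positive")
    ratio = tgt / ld
    rel = ratio / ratio[0]
    half = estimate_half_life(t, rel) if t.size >= 3 else None
    return DecaySeries(tuple(t.tolist()), tuple(rel.tolist()), half)


def _replicate_fold(group: pd.DataFrame) -> float:
    """Protein fold change for one replicate's four-band lane set."""

    def pick(role: str, condition: str) -> pd.Series:
        sel = group[(group["band_role"] == role) & (group["condition"] == condition)]
        if len(sel) != 1:
            raise ValueError(
                f"expected exactly one {role}/{condition} band per replicate, "
                f"found {len(sel)}"
            )
        return sel.iloc[0]

    rows = {
        (role, cond): pick(role, cond)
        for role in ("target", "loading")
        for cond in CONDITIONS
    }
    if any(bool(r["saturated"]) for r in rows.values()):
        raise ValueError("saturated band in fold-change computation")
    nets = {
        key: net_intensity(float(r["raw_intensity"]), float(r["background"]))
        for key, r in rows.items()
    }
    return protein_fold_change(
        nets[("target", "single")],
        nets[("target", "multi")],
        nets[("loading", "single")],
        nets[("loading", "multi")],
    )


def fold_changes_from_table(
    bands: pd.DataFrame,
    *,
    copies: dict[str, float] | None = None,
) -> list[FoldChange]:
    """Aggregate a band-intensity table into FoldChange rows.

    Expects the ``BAND_COLUMNS`` schema with one target and one loading
    band per (sample, condition, replicate). Per-replicate fold changes
    are averaged as mean ± sample s.d. When ``copies`` maps a sample to a
    Multi-condition copy number, a per-copy fold change (normalized per
    replicate, then averaged) is emitted alongside the total one.
    """
    missing = [c for c in BAND_COLUMNS if c not in bands.columns]
    if missing:
        raise ValueError(f"band table missing columns: {missing}")
    out: list[FoldChange] = []
    for sample, sgroup in bands.groupby("sample_id", sort=True):
        folds = [
            _replicate_fold(rgroup)
            for _, rgroup in sgroup.groupby("replicate", sort=True)
        ]
        arr = np.asarray(folds)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(FoldChange(str(sample), "protein", float(arr.mean()), sd, arr.size))
        if copies and sample in copies:
            per = np.array([per_copy_fold_change(f, copies[sample]) for f in folds])
            psd = float(per.std(ddof=1)) if per.size > 1 else 0.0
            out.append(
                FoldChange(
                    str(sample), "protein_per_copy", float(per.mean()), psd, per.size
                )
            )
    return out
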