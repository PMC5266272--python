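"""Screen classification and statistics for dosage compensation.

A gene is called *compensated* when its tagged endogenous protein drops
well below the Single-condition level while its endogenous mRNA stays
flat — i.e. the reduction is post-transcriptional. Genes whose protein
does not drop are *uncompensated*; genes whose protein drops but whose
mRNA also moved are *indeterminate* (the reduction could be
transcriptional). The statistical toolkit matches the small-sample
designs of such screens: an exact one-tailed Mann–Whitney U test by
complete enumeration, and a 2x2 Pearson chi-square for enrichment of
compensated genes among complex subunits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScreenRecord",
    "ComplexReport",
    "classify",
    "mann_whitney_exact",
    "chi2_2x2",
    "summarize_complexes",
    "DEFAULT_PROTEIN_THRESHOLD",
    "DEFAULT_MRNA_BAND",
]

#: Protein mean fold change at or below which a gene counts as reduced.
DEFAULT_PROTEIN_THRESHOLD = 0.7
#: mRNA mean fold-change band treated as "unchanged".
DEFAULT_MRNA_BAND = (0.7, 1.4)

CLASSIFICATIONS = ("compensated", "uncompensated", "indeterminate")


@dataclass
class ScreenRecord:
    """Per-gene screen measurements and (assigned) classification."""

    gene: str
    protein_folds: list[float]
    mrna_folds: list[float] = field(default_factory=list)
    complex_id: str | None = None
    copies: float | None = None
    classification: str | None = None


@dataclass(frozen=True)
class ComplexReport:
    """One row of a complex-membership table."""

    complex_id: str
    n_subunits: int
    n_tested: int
    n_compensated: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_compensated <= self.n_tested <= self.n_subunits):
            raise ValueError(
                f"{self.complex_id}: need compensated <= tested <= subunits"
            )


def classify(
    record: ScreenRecord,
    protein_threshold: float = DEFAULT_PROTEIN_THRESHOLD,
    mrna_band: tuple[float, float] = DEFAULT_MRNA_BAND,
) -> str:
    """Classify a screen record; stores and returns the label.

    compensated: mean protein fold <= threshold AND mean mRNA fold inside
    the unchanged band. uncompensated: mean protein fold > threshold.
    indeterminate: protein reduced but the mRNA criterion fails.
    """
    if not record.protein_folds:
        raise ValueError(f"{record.gene}: no protein replicates to classify")
    if len(record.protein_folds) < 2:
        raise ValueError(f"{record.gene}: need >= 2 protein replicates")
    p_mean = float(np.mean(record.protein_folds))
    if p_mean > protein_threshold:
        label = "uncompensated"
    else:
        lo, hi = mrna_band
        m_mean = float(np.mean(record.mrna_folds)) if record.mrna_folds else math.nan
        if lo <= m_mean <= hi:
            label = "compensated"
        else:
            label = "indeterminate"
    record.classification = label
    return label


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann–Whitney U of y over x: pairs (xi, yj) with yj > xi (+0.5 ties)."""
    xa = np.asarray(x, dtype=float)[:, None]
    ya = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(ya > xa) + 0.5 * np.sum(ya == xa))


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "y_greater",
) -> float:
    """One-tailed Mann–Whitney U p-value, exact for small samples.

    For ``n_x + n_y <= 12`` the p-value is computed by complete
    enumeration of all C(n_x+n_y, n_x) assignments of the observed
    values to the two groups (the permutation null), so ties are handled
    by permuting the values themselves, not by mid-rank approximations.
    Larger designs fall back to the normal approximation with tie
    correction.

    ``alternative`` is ``"y_greater"`` (values in y tend to exceed x) or
    ``"x_greater"``.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("y_greater", "x_greater"):
        raise ValueError("alternative must be 'y_greater' or 'x_greater'")
    if alternative == "x_greater":
        x, y = y, x  # U(y over x) with swapped roles
    n = len(x) + len(y)
    if n <= 12:
        observed = _u_statistic(x, y)
        pooled = x + y
        idx = range(n)
        hits = 0
        total = 0
        for xs in combinations(idx, len(x)):
            xset = set(xs)
            px = [pooled[i] for i in xs]
            py = [pooled[i] for i in idx if i not in xset]
            total += 1
            if _u_statistic(px, py) >= observed - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(
        y, x, alternative="greater", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def chi2_2x2(
    a: float, b: float, c: float, d: float, *, yates: bool = False
) -> dict:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default (``yates=True`` enables it).
    Raises on a zero row or column marginal.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if table.sum() <= 0:
        raise ValueError("empty table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return {"statistic": float(stat), "p": float(p)}


def summarize_complexes(
    records: Sequence[ScreenRecord],
    table: Sequence[ComplexReport],
) -> dict:
    """Aggregate classified records over a complex-membership table.

    Per-complex tested/compensated counts are derived from the classified
    records naming that complex; a table row whose complex has no records
    contributes its own printed counts (so already-tabulated rows can be
    totalled directly). Returns per-complex counts, totals, and the
    overall compensated percentage as ``floor(100 * compensated /
    tested)``. Records without a complex are ignored; a record naming an
    unknown complex is an error.
    """
    known = {t.complex_id for t in table}
    per: dict[str, dict] = {
        t.complex_id: {
            "n_subunits": t.n_subunits,
            "n_tested": t.n_tested,
            "n_compensated": t.n_compensated,
        }
        for t in table
    }
    counted: dict[str, dict[str, int]] = {}
    for rec in records:
        if rec.complex_id is None:
            continue
        if rec.complex_id not in known:
            raise ValueError(f"record {rec.gene}: unknown complex {rec.complex_id!r}")
        if rec.classification is None:
            raise ValueError(f"record {rec.gene}: not classified")
        slot = counted.setdefault(rec.complex_id, {"tested": 0, "compensated": 0})
        slot["tested"] += 1
        if rec.classification == "compensated":
            slot["compensated"] += 1
    for cid, slot in counted.items():
        per[cid]["n_tested"] = slot["tested"]
        per[cid]["n_compensated"] = slot["compensated"]
    for cid, v in per.items():
        if v["n_compensated"] > v["n_tested"]:
            raise ValueError(f"{cid}: more compensated than tested")
    n_tested = sum(v["n_tested"] for v in per.values())
    n_comp = sum(v["n_compensated"] for v in per.values())
    pct = math.floor(100 * n_comp / n_tested) if n_tested else 0
    return {
        "complexes": per,
        "total_tested": n_tested,
        "total_compensated": n_comp,
        "percent_compensated": pct,
    }
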