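"""Ribosome-profiling and RNA-seq counting and translational efficiency.

Footprint reads are assigned to the ribosomal A-site codon by a
length-dependent 5'-end offset (13–17 nt for 26–30 nt footprints, linear
in read length; 15 nt for 22–51 nt mRNA fragments). Reads are counted
inside a trimmed CDS window excluding the first 15 codons and the last 5
codons, avoiding initiation/termination ramp artifacts. Per-sample
library depth is normalized by median-of-ratios size factors; the
translational efficiency (TE) of a gene is footprint density (counts per
countable CDS nucleotide) divided by its mRNA level, and TE fold changes
between conditions are replicate-mean ratios in which the length terms
cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "CdsAnnotation",
    "RiboCounts",
    "asite_offset",
    "countable_window",
    "count_gene",
    "count_table",
    "size_factors",
    "te_fold_change",
]

READ_CLASSES = ("footprint", "mrna_fragment")

#: Codons trimmed from the CDS 5' and 3' ends before counting.
HEAD_CODONS = 15
TAIL_CODONS = 5

FOOTPRINT_LENGTHS = range(26, 31)
MRNA_LENGTHS = range(22, 52)
MRNA_OFFSET = 15


@dataclass(frozen=True)
class ReadRecord:
    """One transcript-mapped read (0-based 5' coordinate)."""

    transcript_id: str
    five_prime: int
    length: int
    read_class: str

    def __post_init__(self) -> None:
        if self.five_prime < 0 or self.length <= 0:
            raise ValueError("invalid read coordinates")
        if self.read_class not in READ_CLASSES:
            raise ValueError(f"unknown read_class {self.read_class!r}")


@dataclass(frozen=True)
class CdsAnnotation:
    """CDS interval on a transcript, 0-based half-open, in-frame."""

    transcript_id: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        length = self.cds_end - self.cds_start
        if self.cds_start < 0 or length <= 0:
            raise ValueError(f"{self.transcript_id}: invalid CDS interval")
        if length % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not divisible by 3")
        if length < 3 * (HEAD_CODONS + TAIL_CODONS + 1):
            raise ValueError(
                f"{self.transcript_id}: CDS too short to count "
                f"(needs > {HEAD_CODONS + TAIL_CODONS} codons)"
            )

    @property
    def effective_length(self) -> int:
        lo, hi = countable_window(self)
        return hi - lo


@dataclass
class RiboCounts:
    """Gene x sample count matrix with normalization metadata."""

    counts: pd.DataFrame  # genes x samples, integers
    size_factors: pd.Series | None = None
    effective_lengths: pd.Series | None = None

    def normalized(self) -> pd.DataFrame:
        sf = self.size_factors
        if sf is None:
            sf = size_factors(self.counts)
        return self.counts / sf


def asite_offset(length: int, read_class: str) -> int | None:
    """5'-end to A-site offset for a read length, or None if rejected.

    Footprints of 26–30 nt map linearly to offsets 13–17 (offset =
    length − 13); mRNA fragments of 22–51 nt use a fixed offset of 15.
    Other lengths are rejected, not errors.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if read_class == "footprint":
        return length - 13 if length in FOOTPRINT_LENGTHS else None
    if read_class == "mrna_fragment":
        return MRNA_OFFSET if length in MRNA_LENGTHS else None
    raise ValueError(f"unknown read_class {read_class!r}")


def countable_window(cds: CdsAnnotation) -> tuple[int, int]:
    """Half-open nt interval in which A-sites are counted."""
    return cds.cds_start + 3 * HEAD_CODONS, cds.cds_end - 3 * TAIL_CODONS


def count_gene(
    reads, cds: CdsAnnotation, offsets: dict[int, int] | None = None
) -> int:
    """A-site count of reads inside the trimmed CDS window.

    ``offsets`` optionally overrides the length→offset map for
    footprints (empirically calibrated tables). Reads whose length is
    rejected contribute nothing; reads on other transcripts are ignored.
    """
    lo, hi = countable_window(cds)
    n = 0
    for read in reads:
        if read.transcript_id != cds.transcript_id:
            continue
        if offsets is not None and read.read_class == "footprint":
            off = offsets.get(read.length)
        else:
            off = asite_offset(read.length, read.read_class)
        if off is None:
            continue
        if lo <= read.five_prime + off < hi:
            n += 1
    return n


def count_table(
    reads: pd.DataFrame,
    annotations: dict[str, CdsAnnotation],
    offsets: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Gene x sample count matrix from a read-level table.

    ``reads`` columns: transcript_id, five_prime, length, read_class,
    sample.
    """
    required = ["transcript_id", "five_prime", "length", "read_class", "sample"]
    missing = [c for c in required if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    genes = sorted(annotations)
    samples = sorted(reads["sample"].unique())
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for (tid, sample), group in reads.groupby(["transcript_id", "sample"], sort=False):
        if tid not in annotations:
            continue
        recs = [
            ReadRecord(str(r.transcript_id), int(r.five_prime), int(r.length), str(r.read_class))
            for r in group.itertuples(index=False)
        ]
        mat.loc[tid, sample] = count_gene(recs, annotations[tid], offsets)
    return mat


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each gene nonzero in every sample, the ratio of its count to its
    across-sample geometric mean is formed; a sample's factor is the
    median of these ratios. A single-sample matrix gets factor 1.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    allpos = np.all(mat > 0, axis=1)
    if not np.any(allpos):
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[allpos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns)


def te_fold_change(
    fp: RiboCounts,
    rna: RiboCounts,
    condition_map: dict[str, tuple[str, int]],
) -> pd.DataFrame:
    """Per-gene Multi/Single mRNA and TE fold changes.

    ``condition_map`` maps each sample name to ``(condition,
    replicate)`` with condition in {"single", "multi"}; replicate pairs
    are matched by replicate index across the two conditions and assays.
    For each pair, mrna_fold is the normalized RNA ratio, the footprint
    density is the normalized footprint count per countable CDS nt, and
    te_fold = density_fold / mrna_fold (effective lengths cancel).
    Reported values are means across replicate pairs.

    A gene with a zero count in any Single-condition sample is flagged
    (``zero_single``) and given NaN folds rather than dropped.
    """
    for name, rc in (("footprint", fp), ("rna", rna)):
        unknown = [s for s in rc.counts.columns if s not in condition_map]
        if unknown:
            raise ValueError(f"{name} samples missing from condition map: {unknown}")
    genes = fp.counts.index.intersection(rna.counts.index)
    if genes.empty:
        raise ValueError("no genes shared between footprint and RNA matrices")

    def by_rep(rc: RiboCounts) -> dict[tuple[str, int], pd.Series]:
        norm = rc.normalized()
        return {
            condition_map[s]: norm[s].loc[genes] for s in rc.counts.columns
        }

    fp_n, rna_n = by_rep(fp), by_rep(rna)
    reps = sorted(
        {r for (cond, r) in fp_n if cond == "multi"}
        & {r for (cond, r) in fp_n if cond == "single"}
        & {r for (cond, r) in rna_n if cond == "multi"}
        & {r for (cond, r) in rna_n if cond == "single"}
    )
    if not reps:
        raise ValueError("no matched single/multi replicate pairs")
    mrna_folds, te_folds = [], []
    zero_single = pd.Series(False, index=genes)
    for r in reps:
        rna_s, rna_m = rna_n[("single", r)], rna_n[("multi", r)]
        fp_s, fp_m = fp_n[("single", r)], fp_n[("multi", r)]
        zero_single |= (rna_s == 0) | (fp_s == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mf = rna_m / rna_s
            df_ = fp_m / fp_s  # density fold: effective lengths cancel
            tf = df_ / mf
        mrna_folds.append(mf)
        te_folds.append(tf)
    mrna_mean = pd.concat(mrna_folds, axis=1).mean(axis=1)
    te_mean = pd.concat(te_folds, axis=1).mean(axis=1)
    mrna_mean[zero_single] = np.nan
    te_mean[zero_single] = np.nan
    return pd.DataFrame(
        {
            "mrna_fold": mrna_mean,
            "te_fold": te_mean,
            "zero_single": zero_single,
        },
        index=genes,
    )
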