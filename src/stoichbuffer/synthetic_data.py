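"""Seeded synthetic-data generators with ground truth.

Every pipeline input can be generated here with known programmed truth:
blot intensity tables (multiplicative lognormal lane noise, additive
background, optional saturation ceiling), qPCR crossing points (additive
Gaussian Cp noise), a chromosome-scale screen with a compensated subset,
footprint/mRNA count matrices or read-level tables with programmed
translational efficiency (negative-binomial counts), and
cycloheximide-chase decay curves. Identical seed and parameters give
identical tables; each generator returns ``(data, truth)`` where the
truth dictionary echoes the programmed parameters for round-trip tests.

Defaults mirror the study conditions the generators emulate: a 54-gene
screen with 5 compensated genes in 3 replicates, plasmid copy numbers
near 20, chase sampling at 0/1/2/4/6 h, and two profiling replicates
with one gene carrying a 20x mRNA increase at unchanged TE.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .densitometry import BAND_COLUMNS
from .riboprof import CdsAnnotation, asite_offset, countable_window
from .screen import ScreenRecord

__all__ = [
    "gen_blot",
    "gen_qpcr",
    "gen_screen",
    "gen_ribo",
    "gen_chx",
    "CHX_COLUMNS",
]

CHX_COLUMNS = [
    "sample_id",
    "replicate",
    "time_h",
    "target_raw",
    "target_background",
    "loading_raw",
    "loading_background",
]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factor with unit mean and the given CV."""
    if cv < 0:
        raise ValueError("noise CV must be nonnegative")
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def gen_blot(
    true_fold: float = 0.3,
    *,
    n_replicates: int = 3,
    background_mean: float = 20.0,
    noise_cv: float = 0.03,
    saturation_ceiling: float | None = None,
    dilution_series: Sequence[float] = (1.0,),
    gain: float = 1000.0,
    sample_id: str = "GENE1",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Band-intensity table for a Single/Multi blot with programmed fold.

    The tagged-target level is 1 in Single and ``true_fold`` in Multi;
    the loading control is equal in both conditions. Each band's
    intensity is ``background + gain * level * dilution * noise`` with
    lognormal noise of the given CV; intensities above the saturation
    ceiling are clipped and flagged.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    rng = np.random.default_rng(seed)
    levels = {"target": {"single": 1.0, "multi": true_fold},
              "loading": {"single": 1.0, "multi": 1.0}}
    rows = []
    for rep in range(1, n_replicates + 1):
        for role in ("target", "loading"):
            for cond in ("single", "multi"):
                for dil in dilution_series:
                    noise = _lognormal_noise(rng, noise_cv, None)
                    signal = gain * levels[role][cond] * dil * noise
                    raw = background_mean + signal
                    saturated = False
                    if saturation_ceiling is not None and raw > saturation_ceiling:
                        raw = saturation_ceiling
                        saturated = True
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "lane_id": f"{role}_{cond}_d{dil:g}_r{rep}",
                            "band_role": role,
                            "condition": cond,
                            "replicate": rep,
                            "raw_intensity": raw,
                            "background": background_mean,
                            "dilution": dil,
                            "saturated": saturated,
                        }
                    )
    truth = {
        "true_fold": true_fold,
        "gain": gain,
        "background_mean": background_mean,
        "noise_cv": noise_cv,
        "seed": seed,
    }
    return pd.DataFrame(rows, columns=BAND_COLUMNS), truth


def gen_qpcr(
    true_copies: float | None = None,
    true_fold: float | None = None,
    *,
    efficiency: float = 2.0,
    cp_noise_sd: float = 0.1,
    n_replicates: int = 4,
    sample_id: str = "GENE1",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Cp table for gTOW copy number or for an RT-qPCR mRNA fold change.

    Exactly one of ``true_copies`` (leu2d vs LEU3 rows) or ``true_fold``
    (TAP vs ACT1 rows in both conditions) must be given. Ideal Cp values
    follow the relative-quantification model for the stated efficiency,
    plus Gaussian noise of sd ``cp_noise_sd`` cycles.
    """
    if (true_copies is None) == (true_fold is None):
        raise ValueError("give exactly one of true_copies or true_fold")
    rng = np.random.default_rng(seed)
    log_e = math.log(efficiency)
    rows = []
    if true_copies is not None:
        if true_copies <= 0:
            raise ValueError("true_copies must be positive")
        base = 20.0  # LEU3 single-copy reference Cp
        for rep in range(1, n_replicates + 1):
            cp_leu3 = base + rng.normal(0, cp_noise_sd)
            cp_leu2d = base - math.log(true_copies) / log_e + rng.normal(0, cp_noise_sd)
            rows += [
                dict(sample_id=sample_id, primer_target="LEU3", cp=cp_leu3,
                     efficiency=efficiency, replicate=rep, condition="multi"),
                dict(sample_id=sample_id, primer_target="leu2d", cp=cp_leu2d,
                     efficiency=efficiency, replicate=rep, condition="multi"),
            ]
        truth = {"true_copies": true_copies}
    else:
        if true_fold <= 0:
            raise ValueError("true_fold must be positive")
        cp_t, cp_r = 22.0, 16.0  # target and reference baseline Cp
        for rep in range(1, n_replicates + 1):
            vals = {
                ("TAP", "single"): cp_t,
                ("TAP", "multi"): cp_t - math.log(true_fold) / log_e,
                ("ACT1", "single"): cp_r,
                ("ACT1", "multi"): cp_r,
            }
            for (target, cond), cp in vals.items():
                rows.append(
                    dict(sample_id=sample_id, primer_target=target,
                         cp=cp + rng.normal(0, cp_noise_sd),
                         efficiency=efficiency, replicate=rep, condition=cond)
                )
        truth = {"true_fold": true_fold}
    truth.update({"efficiency": efficiency, "cp_noise_sd": cp_noise_sd, "seed": seed})
    return pd.DataFrame(rows), truth


def gen_screen(
    n_genes: int = 54,
    n_compensated: int = 5,
    *,
    n_replicates: int = 3,
    compensated_median: float = 0.4,
    uncompensated_median: float = 1.0,
    protein_sigma: float = 0.15,
    mrna_sigma: float = 0.1,
    true_copies: float = 20.0,
    seed: int = 0,
) -> tuple[list[ScreenRecord], pd.DataFrame]:
    """Screen-shaped dataset: per-gene replicate folds plus truth labels.

    The first ``n_compensated`` genes draw protein folds from a
    lognormal centered at ``compensated_median`` (strong reduction), the
    rest near 1; mRNA folds sit near 1 for everyone — the compensation
    is post-transcriptional by construction. Compensated genes are
    assigned complex memberships; truth carries the programmed label per
    gene.
    """
    if not (0 <= n_compensated <= n_genes):
        raise ValueError("need 0 <= n_compensated <= n_genes")
    rng = np.random.default_rng(seed)
    records: list[ScreenRecord] = []
    truth_rows = []
    for i in range(n_genes):
        compensated = i < n_compensated
        gene = f"GENE{i + 1:03d}"
        median = compensated_median if compensated else uncompensated_median
        protein = median * np.exp(rng.normal(0, protein_sigma, n_replicates))
        mrna = np.exp(rng.normal(0, mrna_sigma, n_replicates))
        complex_id = f"CPLX{i + 1}" if compensated else None
        records.append(
            ScreenRecord(
                gene=gene,
                protein_folds=[float(v) for v in protein],
                mrna_folds=[float(v) for v in mrna],
                complex_id=complex_id,
                copies=true_copies,
            )
        )
        truth_rows.append(
            {
                "gene": gene,
                "true_label": "compensated" if compensated else "uncompensated",
                "complex_id": complex_id if complex_id else "",
                "true_protein_fold": median,
            }
        )
    return records, pd.DataFrame(truth_rows)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts; dispersion 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_ribo(
    n_genes: int = 100,
    *,
    designated_gene: int = 0,
    designated_mrna_fold: float = 20.0,
    designated_te_fold: float = 1.0,
    n_replicates: int = 2,
    library_size: float = 200_000.0,
    dispersion: float = 0.002,
    mean_expression: float = 100.0,
    read_level: bool = False,
    seed: int = 0,
):
    """Footprint/RNA counts with one gene carrying a programmed pattern.

    All genes keep mRNA and TE at 1x between conditions except the
    designated gene, whose Multi-condition mRNA and TE are scaled by the
    programmed folds (defaults emulate a strong multicopy mRNA increase
    with unchanged TE). Counts are negative-binomial around
    ``library_size``-scaled expected abundances; the designated gene is
    pinned to a typical expression share so the programmed pattern is
    measured at ordinary coverage rather than left to a random draw. The
    default dispersion (0.002, ~4.5% replicate CV at high coverage)
    emulates tightly agreeing biological replicates of deeply sequenced
    libraries.

    With ``read_level=True`` the same per-gene counts (same seed, same
    draws) are expanded into transcript-relative reads with valid
    lengths and A-site positions inside the countable window, plus the
    CDS annotations; matrix- and read-level routes agree exactly.

    Returns ``(fp_counts, rna_counts, truth)`` or, read-level,
    ``(reads_df, annotations, truth)``.
    """
    rng = np.random.default_rng(seed)
    base = mean_expression * np.exp(rng.normal(0, 0.5, n_genes))
    base[designated_gene] = mean_expression  # typical, well-covered gene
    base /= base.sum()
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    mrna_fold = np.ones(n_genes)
    te_fold = np.ones(n_genes)
    mrna_fold[designated_gene] = designated_mrna_fold
    te_fold[designated_gene] = designated_te_fold
    samples, fp_cols, rna_cols = [], {}, {}
    for cond, m_scale, t_scale in (
        ("single", np.ones(n_genes), np.ones(n_genes)),
        ("multi", mrna_fold, te_fold),
    ):
        for rep in range(1, n_replicates + 1):
            name = f"{cond}_{rep}"
            samples.append(name)
            rna_mean = library_size * base * m_scale
            fp_mean = rna_mean * t_scale
            rna_cols[name] = _nb_counts(rng, rna_mean, dispersion)
            fp_cols[name] = _nb_counts(rng, fp_mean, dispersion)
    fp_counts = pd.DataFrame(fp_cols, index=genes)
    rna_counts = pd.DataFrame(rna_cols, index=genes)
    truth = {
        "designated_gene": genes[designated_gene],
        "mrna_fold": designated_mrna_fold,
        "te_fold": designated_te_fold,
        "dispersion": dispersion,
        "n_replicates": n_replicates,
        "condition_map": {
            s: (s.rsplit("_", 1)[0], int(s.rsplit("_", 1)[1])) for s in samples
        },
        "seed": seed,
    }
    if not read_level:
        return fp_counts, rna_counts, truth

    cds_start = 30  # leave a 5' UTR so five_prime coordinates stay valid
    n_codons = 120
    annotations = {
        g: CdsAnnotation(g, cds_start, cds_start + 3 * n_codons) for g in genes
    }
    rows = []
    for g in genes:
        lo, hi = countable_window(annotations[g])
        for sample in samples:
            for read_class, mat in (("footprint", fp_counts), ("mrna_fragment", rna_counts)):
                count = int(mat.loc[g, sample])
                if count == 0:
                    continue
                if read_class == "footprint":
                    lengths = rng.integers(26, 31, size=count)
                else:
                    lengths = rng.integers(22, 52, size=count)
                asites = rng.integers(lo, hi, size=count)
                for length, asite in zip(lengths, asites):
                    off = asite_offset(int(length), read_class)
                    rows.append(
                        {
                            "transcript_id": g,
                            "five_prime": int(asite) - off,
                            "length": int(length),
                            "read_class": read_class,
                            "sample": sample,
                        }
                    )
    reads = pd.DataFrame(
        rows, columns=["transcript_id", "five_prime", "length", "read_class", "sample"]
    )
    return reads, annotations, truth


def gen_chx(
    half_life: float = 2.0,
    *,
    times: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 6.0),
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    gain: float = 1000.0,
    background_mean: float = 20.0,
    sample_id: str = "GENE1",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Chase time-series table with a programmed half-life.

    The target decays exponentially with the given half-life (``inf``
    for a stable protein); the loading control is constant. Both
    channels carry lognormal noise of the given CV on top of an additive
    background.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive (use inf for stable)")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    decay = np.ones_like(t) if math.isinf(half_life) else np.exp(-math.log(2) * t / half_life)
    rows = []
    for rep in range(1, n_replicates + 1):
        tgt = gain * decay * _lognormal_noise(rng, noise_cv, t.size)
        ld = gain * _lognormal_noise(rng, noise_cv, t.size)
        for ti, tv, lv in zip(t, tgt, ld):
            rows.append(
                {
                    "sample_id": sample_id,
                    "replicate": rep,
                    "time_h": ti,
                    "target_raw": background_mean + tv,
                    "target_background": background_mean,
                    "loading_raw": background_mean + lv,
                    "loading_background": background_mean,
                }
            )
    truth = {"half_life": half_life, "noise_cv": noise_cv, "seed": seed}
    return pd.DataFrame(rows, columns=CHX_COLUMNS), truth
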