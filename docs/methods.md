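# Methods

## Quantification of band intensities

Each band is recorded with a locally measured background (the
image-software convention); net intensity is `raw − background`, and a
background exceeding the signal is treated as an operator error, never
clipped. Protein fold change between the Single (one genomic gene copy)
and Multi (genomic copy + multicopy plasmid) conditions is the ratio of
target (WB) fold change to loading-control (total-protein gel) fold
change, which cancels loading and exposure differences; the invariance
of this ratio under rescaling either condition's exposure is asserted to
1e-12 in the tests. Saturation is an input flag: any saturated band
aborts a fold-change computation with an error, because a clipped
numerator or denominator biases the ratio in an unknowable direction.
Dilution-series linearity is summarized by the squared Pearson
correlation of net intensity against loaded amount; a zero-variance
response (full saturation) is defined as R² = 0 and fails the linearity
flag. Replicates aggregate as arithmetic mean ± sample s.d. of
per-replicate fold changes. Per-copy fold changes are normalized per
replicate and then averaged; since the copy-number estimate is common to
all replicates the two orders give identical means, and per-replicate
normalization keeps the replicate s.d. on the per-copy scale.

Chase curves normalize the target by the loading channel at each
timepoint and express levels relative to t = 0. Half-life comes from an
ordinary least-squares fit of ln(level) on time, `t½ = ln 2 / |slope|`,
refusing fits with fewer than three points and returning "undefined" for
non-negative slopes. A log-linear fit is the right model for a
single-exponential decay and degrades gracefully for the two-pool decays
simulated by the kinetics module (which are bi-exponential; the fitted
value is then an effective half-life, used only for comparison between
conditions).

## Copy number and mRNA levels from qPCR

Plasmid copy number per cell is efficiency-corrected relative
quantification of the plasmid marker against a single-copy genomic
locus: `E_ref^Cp_ref / E_marker^Cp_marker`, reducing to
`2^(Cp_ref − Cp_marker)` at perfect efficiency. Host strains carry the
marker only on the plasmid, so the marker:locus abundance ratio *is* the
plasmid copy number. No correction is applied for the subpopulation that
may have lost the plasmid; under selective growth that fraction is small
and no correction factor is available, so the estimate is a lower bound
in the worst case. mRNA fold changes use the ΔΔCp scheme against a
reference transcript, generalized to per-primer efficiencies (Pfaffl
form); adding a constant to all four Cp values (a plate shift) cancels
exactly. Default efficiency is 2.0 (ideal doubling), overridable per
primer; replicates aggregate as mean ± s.d.

## Screen classification and statistics

A gene is *compensated* when its mean protein fold change is at or below
0.7 **and** its mean mRNA fold change lies in [0.7, 1.4] — i.e. the
protein drop is post-transcriptional. Genes above the protein threshold
are *uncompensated*; genes below it whose mRNA also moved are
*indeterminate*. The cutoffs are tunable: 0.7 separates the observed
compensated range (≤ 0.6×) from unchanged expression with headroom for
replicate noise, and the mRNA band brackets "unchanged" symmetrically on
the log scale (1/1.4 ≈ 0.71). Classification requires at least two
protein replicates.

The Mann–Whitney U test is exact for the n = 3–6 group sizes these
experiments use: the one-tailed p-value is the fraction of all
C(n₁+n₂, n₁) assignments of the observed values to the two groups whose
U statistic is at least the observed one. Ties are handled by permuting
the values themselves (with the usual ½-count for equal pairs), not by
mid-rank normal corrections; with all values tied every assignment is
equally extreme and p = 1. Beyond a total of 12 observations the
enumeration hands over to the normal approximation with tie correction.
The 2×2 chi-square is Pearson's without continuity correction by
default (df = 1), with Yates' correction as a flag; the operation takes
raw counts and does not construct contingency tables itself. Complex
aggregation counts tested and compensated subunits per complex from
classified records, accepts already-tabulated rows for complexes
without record-level data, and reports the overall percentage as
`floor(100·compensated/tested)`.

## The two-pool heterodimer model

The model realizes, as minimal mass-action kinetics, the hypothesis that
a subunit is unstable as a free monomer and stable once assembled:

    dA/dt = N_A s_A − d_free_A·A − k_on·A·B + k_off·C
    dB/dt = N_B s_B − d_free_B·B − k_on·A·B + k_off·C
    dC/dt = k_on·A·B − k_off·C − d_complex·C

Parameters (arbitrary concentration units, reciprocal hours): per-copy
synthesis fluxes `s_A, s_B`; gene copy numbers `N_A, N_B`; free-monomer
degradation rates `d_free_*`; complex degradation rate `d_complex`;
association/dissociation `k_on, k_off`. The modeled biology has
`d_free ≥ d_complex`; the package permits the inverted ordering for
limit tests. Degradation is first-order from each pool — no explicit
ubiquitin-chain or proteasome dynamics. Cotranslational assembly and
translation-rate feedback are out of scope; a synthesis-scaling hook
(`s_A` itself) exists for the translational-deceleration alternative but
no mechanism is modeled, consistent with the profiling result that TE
does not change.

A genomically tagged copy is kinetically identical to untagged protein,
so tagged levels are the `tagged_copies_A / N_A` share of totals — no
separate tagged ODEs. Observables: `tagged_total_A` (denaturing blot,
free + complexed), `tagged_complex` (native gel), `total_A`.

**Steady states.** Eliminating C via the effective association rate
`k_eff = k_on·d_complex / (k_off + d_complex)` and using the difference
of the two monomer balances reduces the system to one quadratic in free
B; the nonnegative root is taken and the residual fluxes are checked to
a relative tolerance of 1e-9 (absolute 1e-10). Degenerate corners (zero
free-degradation with excess synthesis, `d_complex = 0` with tight
binding) fall back to ODE relaxation (LSODA over ~50 slowest time
constants) and error out with the residuals if no steady state exists.
All-zero synthesis returns the empty cell exactly.

**Perturbations.** `multicopy_self(N)` / `multicopy_partner(N)` set a
copy number (the tagged genomic copy count stays 1, so the tagged share
drops to 1/N under self-multicopy — exactly what a blot against the
tagged endogenous protein sees). `partner_deletion` zeroes the partner
synthesis flux. `proteasome_defect(f)` interpolates both free-pool rates
toward the complex rate, `d_free ← d_complex + f(d_free − d_complex)`;
`f = 0` is a complete defect, under which total protein obeys a single
linear birth–death law and the multicopy-self fold is exactly 1 (the
no-compensation limit); the partial-defect strength is left free because
residual degradation activity is not quantified.

**Default calibration** (`data/default_model.yaml`): `s_A = 1.5,
s_B = 1.0, d_free = 5.0, d_complex = 1.0, k_on = 100, k_off = 0`, with
perturbation copy number 20. The moderate synthesis excess of A, a 5×
stability difference, and near-tight binding place the three predicted
folds at 0.377 (multicopy self), 0.333 (partner deletion) and 1.649
(multicopy partner) — inside the experimentally observed windows
(0.2–0.6×, <0.5×, >1.3× respectively) while keeping all pools
well-conditioned for the solver. `k_off = 0` models a tight dimer;
nonzero `k_off` is supported and covered by flux-balance tests.

**Analytic oracle.** In the `k_on → ∞`, `k_off = 0` limit with A in
synthesis excess, complex formation consumes the entire partner flux and
the tagged-total fold has the closed form

    fold(N) = [s_B/(N·d_c) + (N·s_A − s_B)/(N·d_f)] / [s_B/d_c + (s_A − s_B)/d_f]

The numeric solver at `k_on = 1e6` is required to agree within 2% over a
27-point grid — an independent check that the quadratic and the physics
agree.

**Chase simulation** starts from the steady state, zeroes both synthesis
fluxes and integrates the decay (LSODA, rtol 1e-10). **Parameter
fitting** estimates any of `s_A/s_B`, `d_free/d_complex` and `k_on` from
observed perturbation folds by least squares in log-fold space,
multi-started from a fixed 3-point grid per parameter; an
under-determined system (fewer observations than free parameters) is
refused up front.

## Ribosome profiling and translational efficiency

Footprints of 26–30 nt are assigned to the ribosomal A-site at offset
`length − 13` from the 5′ end (26→13 … 30→17); mRNA fragments of
22–51 nt use a fixed offset of 15 nt. Other lengths are rejected (a
return state, not an error). The linear map is the default; an explicit
length→offset table can override it where offsets are calibrated
empirically per dataset. Counting covers the half-open window
`[cds_start + 45, cds_end − 15)` — the CDS minus the first 15 and last
5 codons — so initiation and termination ramps do not distort density.
Ribosome density is footprint count per countable CDS nucleotide; the
length term cancels in TE fold changes, which is asserted by perturbing
the lengths. Size factors are median-of-ratios over genes expressed in
every sample (a single-sample matrix gets factor 1). TE fold change per
replicate pair is the normalized footprint ratio divided by the
normalized mRNA ratio; the report is the mean over replicate pairs.
Genes with a zero count in any Single-condition sample get NaN folds and
an explicit flag instead of being dropped; no pseudocounts are added by
default. Differential testing (dispersion shrinkage etc.) is not
implemented — the pipeline's claims are fold-change statements, and only
size-factor normalization enters them.

## Synthetic data

Noise models are the standard minimal choices per assay: multiplicative
lognormal (unit mean, specified CV) for band intensities on top of an
additive background with optional saturation clipping; additive Gaussian
noise on qPCR crossing points; negative-binomial counts (Poisson at
dispersion 0) for sequencing. Generators are deterministic in
(seed, parameters) — identical calls give byte-identical tables — and
every generator returns the programmed truth alongside the data.

Defaults encode the study conditions the generators emulate: a 54-gene
screen with 5 compensated genes (compensated protein folds lognormal
around 0.4, uncompensated around 1.0, mRNA near 1 for both, 3
replicates); plasmid copy numbers near 20 with 0.1-cycle Cp noise over 4
replicates; blot noise CV 3% (the precision a good dilution-controlled
densitometry series achieves); chase sampling at 0/1/2/4/6 h with 5%
noise; two profiling replicates per condition with one designated gene
carrying a 20× mRNA increase at unchanged TE. The profiling generator
uses dispersion 0.002 (≈4.5% replicate CV at high coverage, the scale of
tightly agreeing biological replicates of deeply sequenced yeast
libraries) and ~2×10⁵ reads over 100 genes, i.e. realistic per-gene
coverage in a gene count scaled down for test speed; the designated gene
is pinned to a typical expression share so the programmed pattern is
measured at ordinary coverage rather than left to a random draw.
Read-level mode expands the very same count draws into reads with valid
lengths and A-site positions, so matrix- and read-level routes agree
exactly by construction.

What the generators do *not* emulate — and hence what passing round-trip
tests cannot show about real data: spatial gel artifacts and smear
overlap, antibody nonlinearity beyond a hard saturation ceiling, qPCR
inhibitors or melt-curve failures, positional bias of footprints within
the countable window, multimapping ambiguity, and batch structure across
replicates. Real-data use should treat the round trips as verifying the
arithmetic of the pipeline, not the assay physics.

## Numerical conventions

Zero-variance linearity series define R² = 0; negative net intensities
are errors, not clipped; steady-state tolerance 1e-10 absolute / 1e-9
relative residual; half-life fits require ≥3 points and positive levels;
exact Mann–Whitney enumeration up to 12 total observations, asymptotic
with tie correction beyond; chi-square marginals must be positive;
classification requires ≥2 protein replicates. Exchange format is
header-rowed UTF-8 TSV with '.' decimals throughout; CLI runs write a
`provenance.json` (tool version, command, resolved parameters) beside
their outputs, and all randomness descends from the single `--seed`.

## Known limitations

The kinetic model covers heterodimers only — no higher-order complexes,
RNA subunits, stochastic kinetics, or explicit ubiquitin-chain
dynamics. The per-copy fold change assumes the Single condition carries
exactly one gene copy. Copy-number estimates ignore plasmid loss. The
exact rank test's p-values are discrete (multiples of 1/C(n₁+n₂,n₁)), so
attainable significance levels are coarse at n = 3. Half-life estimates
on two-pool decays are effective values, not pool-specific rates.
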