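# Methods

## Steady-state model

For each gene, the mRNA amount RA (molecules/cell) in an exponentially
growing culture obeys

    dRA/dt = TR − (kd + μ) · RA,      kd = ln2 / t½,   μ = ln2 / T_gen

with TR the synthesis rate (molecules/min), kd the degradation rate and μ
the dilution rate from the continuous doubling of cell volume. At steady
state TR = RA·(kd + μ). The *indirect* TR computed this way from measured
RA and t½ reflects only transcription that delivers a mature cytoplasmic
mRNA; the *nascent* TR measured by run-on counts every elongating
polymerase and converts density to rate via the elongation speed:
TR = density (molecules/kb) × v (kb/min). Dilution is included because
stability measurements are made in non-growing cells and therefore miss it;
for the average gene it contributes ~8–15% of the TR, but for stable,
abundant transcripts it dominates.

Key constants (`KineticConstants`), all overridable:

| constant | default | unit | role |
|---|---|---|---|
| doubling_time_min | 113 | min | dilution rate, events per cycle |
| total_mrna_per_cell | 26000 | molecules | turnover denominator |
| elongation_nt_per_s | 25 | nt/s | density ↔ rate conversion (1.5 kb/min) |
| s_phase_fraction | 0.27 | — | histone-gene phase adjustment |
| nucleosome_footprint_bp | 147 | bp | transit-time arithmetic |
| genome_gene_count | 5796 | genes | extrapolation of sums |

## Synthetic data

The simulator draws true TRs and half-lives log-normally
(log10 TR ~ N(−0.92, 0.34) molecules/min, i.e. median ≈ 7 mRNAs/h with a
90% range near 2.3–30; log10 t½ ~ N(1.30, 0.25) min), derives densities
(TR/v), steady-state abundances (TR/(kd+μ)), and ORF lengths
(log10 bp ~ N(3.11, 0.26), floored at 150 bp). Probes follow the array
design rule: complete ORF below 3 kb, 3′-terminal 1 kb otherwise.

**Labeling model.** Polymerases sit uniformly at per-nt density d; during
the run-on each labels the next min(δ, L−x) nt (δ = 300 nt by default; the
true extension length is not published and is a free parameter, not a claim
about the original assay). Position y then receives label d·min(δ, y), and
the probe signal is the closed-form integral of this coverage over the
probe. After dividing by the gDNA signal (∝ probe length) this yields
d·δ·(1 − δ/2L) for full-ORF probes — rising with length — and exactly d·δ
for 3′-tail probes: the simplest mechanism reproducing both the 3′ bias
and its regime change at the probe-design boundary. The RPCC expectation is
density × (L/1 kb)^(−0.05), a mild power-law trend.

**Noise.** Signals are positive and heteroscedastic, so noise is
multiplicative lognormal with unit mean: per-value cv 0.2, an array-level
lognormal scale factor (cv 0.2, removed later by median scaling), and 5%
missing spots uniformly at random. Sequencing-based relative abundances get
cv 0.1 — abundance estimates from deep sequencing are substantially more
precise than a single filter hybridization. Half-life measurements reuse
the cv 0.2 array noise. What the generator does **not** emulate: spatial
artifacts within filters, background subtraction errors, cross-hybridizing
probes, correlated (batch) noise between arrays, biological co-regulation
between genes, or deviations from steady state. Passing recovery tests
therefore demonstrates the correctness and stability of the estimation
chain under the assumed error model, not performance on any real dataset.

## Preprocessing

Zero/negative signals are treated as missing (downstream steps are
log-domain). Each array is divided by its gDNA reference (array-wise when
the gDNA shares the array layout, else by the per-gene gDNA mean), then
median-scaled over the genes complete in all arrays, which makes scaling
idempotent. A gene is valid in an experiment when ≥ 1 replicate is
non-missing; genes valid in fewer than 5 of the 8 experiments are dropped.
The agreement filter computes experiment profiles as per-gene means of
log2 replicates (log2 stops a few bright genes from dominating r) and keeps
an experiment iff its *median* pairwise Pearson with the others is ≥ 0.7;
the median is robust to one bad partner. Whether the original threshold
applied to the 24 samples or the 8 experiment means is ambiguous; both are
supported (`qc_level="experiment" | "array"`), default experiment-level.
Averaging is two-stage in linear scale — replicates → experiment mean,
experiment means → gene — matching the 8×3 design; with a balanced
complete design this equals the flat mean.

## Length-bias correction

GRO and RPCC per-gene values are standardized in log2 space. The z-score
uses the population sd (ddof = 0); the convention is fixed by the worked
case (2, 8) → (−1, +1) and is immaterial downstream since the same sd is
used for inversion. Within each length regime (< 3 kb, ≥ 3 kb; 3000 bp
goes to the upper regime, mirroring the probe rule "shorter than 3 kb"),
lowess smoothers of both z-scores versus ORF length are fitted and the
smoother difference subtracted from the GRO z-scores; the corrected values
therefore inherit the (mild) RPCC trend by construction. The
standardization is then reversed; by default the log2 transform is also
undone (`delog=True`) so calibration operates in linear units — the
original description reverses only the standardization, so the delog is
switchable.

**Lowess flavor** (implemented in-package so the definition is exact and
oracle-testable): local *linear* fit, tricube weights over the
k = ⌈span·n⌉ nearest neighbours, bandwidth = distance to the k-th
neighbour, zero robustness iterations, evaluated at the observed x; span
defaults to 0.2. Ties in x share a window and get identical fits; if all k
neighbours coincide with the target the fit falls back to the tie-group
mean; a degenerate weighted design (zero x-variance) falls back to the
weighted mean. The implementation is linear in y, so additive constants in
the GRO z-scores are absorbed exactly by the smoother and the corrected
values are invariant to them. Tests verify agreement with a brute-force
weighted-least-squares oracle to 1e-8 and cross-check against the
statsmodels implementation on tie-free data.

## Calibration

Both absolute calibrations use a median-of-ratios factor: robust,
scale-equivariant, and exactly correct for proportional data (the original
description — "plot against ... to convert into real units" — does not pin
a functional form). Abundances: factor = median of reference/relative over
the 2000 top reference-ranked shared genes. Nascent TR: factor = median of
indTR/AU over the 2000 genes with the highest dilution-corrected indirect
TR (the most confident ones); top-k ties break by gene id for determinism.
Genes missing a half-life are excluded rather than imputed. Rates are
carried internally in molecules/min; mRNAs/hour appears only at
presentation (×60). The dilution percentage 100·RA·μ/TR is computed from
independently estimated quantities and can exceed [0, 100]; it is clamped,
with TR = 0 mapping to 100% (RA > 0) or 0% (RA = 0).

## Snapshot arithmetic

Totals are sums over the rate table multiplied by
genome_gene_count/n_measured (the measured genes are assumed
representative; the extrapolation is a flag). Events per cycle =
(total/h)/60 × T_gen; turnover = events per cycle / total mRNA. Histone
TRs are divided by the S-phase fraction since those genes transcribe only
then. Nucleosome timing at a given TR: interval between successive
polymerases 3600/TR(h⁻¹) s, transit 147/25 s, occupancy 1 − transit/interval
(floored at 0); the occupancy is reported as the exact closed form (66.4%
at 206 mRNAs/h) rather than a rounded intermediate. The polymerase census
divides the elongating-polymerase sum by the hyperphosphorylated pool
(20000 × 0.6) and returns a 1×–2× interval, reflecting that an unknown
share of elongating polymerases never produces a mature mRNA.

## Problem sizes and determinism

The default study — chosen as the package's reference configuration — is
5000 genes × (8×3 GRO + 24 gDNA + 3 RPCC) arrays; a full run takes a few
seconds. All randomness flows from a single integer seed through per-stage
`SeedSequence` spawn keys, so identical seeds give byte-identical output
TSVs. The calibration top-k follows the genome size in
`run_default_study` (40%, i.e. 2000 at the default size) so scaled-down
runs remain coherent.

## Known limitations

* The run-on extension δ and all noise magnitudes are free parameters of
  the simulator, not measurements.
* The corrected GRO keeps the RPCC length trend by design; if the RPCC
  itself were biased, that bias would propagate.
* Steady state is assumed throughout; the machinery does not model
  induction/shut-off transients.
* The indirect/nascent comparison operations are generic: group
  definitions (non-coding-transcript overlap, polymerase-distribution
  classes, functional categories) must be supplied by the user as
  membership tables.
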