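# nascentrates

Absolute nascent transcription rates and RNA polymerase II densities for
yeast genes, from genomic run-on (GRO) and pol II ChIP-on-chip (RPCC)
array signals.

## The problem

The mRNA amount of a gene (RA, molecules/cell) is the balance of synthesis
and loss. In an exponentially growing culture loss has two parts:
degradation, with rate `kd = ln2 / t½`, and dilution by the doubling cell
volume, with rate `ln2 / T_gen`. At steady state

```
TR_indirect = RA · (kd + ln2 / T_gen)        [molecules/min]
```

This *indirect* TR counts only transcription that yields a mature
cytoplasmic mRNA. A run-on assay instead measures the density of
*elongating* polymerases on each gene — the *nascent* TR — which relates to
density through the elongation speed `v` (25 nt/s → 1.5 kb/min):

```
TR_nascent = density [molecules/kb] · v [kb/min]
```

Turning raw GRO filters into absolute nascent TRs requires a chain of
corrections this package implements end to end:

1. **gDNA normalization** — each hybridization divided by the genomic-DNA
   signal of the same filter (probe-amount control), then median scaling.
2. **Replicate QC** — genes need ≥ 5 valid measures across the 8
   experiments (× 3 replicates); experiments must reach a pairwise Pearson
   of 0.7 on log2 profiles; two-stage averaging collapses the 24 arrays to
   one value per gene.
3. **Probe-length bias correction** — run-on label accumulates towards the
   3′ end, and the probe design changes at 3 kb (full ORF below, 3′-terminal
   1 kb above), imprinting a length artifact on GRO but not on RPCC. Both
   datasets are z-scored in log2 space, lowess smoothers (span 20%) versus
   ORF length are fitted separately above and below 3 kb, and the
   GRO−RPCC smoother difference is subtracted before the standardization is
   reversed.
4. **Absolute calibration** — relative abundances are scaled to
   molecules/cell by median-of-ratios against the 2000 most abundant
   reference mRNAs; corrected GRO arbitrary units are scaled to
   molecules/min against the 2000 highest indirect dilution-corrected TRs.
5. **Snapshot arithmetic** — genome totals, transcription events and mRNA
   turnover per cell cycle, S-phase-adjusted rates for histone genes,
   nucleosome transit timing, and the census of elongating versus
   hyperphosphorylated pol II.

Because the original filter images are not redistributable, the package
ships a first-class synthetic-data module that simulates GRO/RPCC/gDNA
arrays and abundance inputs from a known ground truth — including the
3′-labeling bias, its 3 kb regime change, multiplicative lognormal noise
and missing spots — so every stage is testable and the whole pipeline can
be validated by parameter recovery.

## Worked example

```python
from nascentrates.pipeline import run_default_study, recovery_metrics

result = run_default_study(seed=1, n_genes=5000)   # 8x3 GRO arrays, 20% noise
metrics = recovery_metrics(result)

rt = result.rates
print("genes rated:", len(rt))
print("median TR: %.2f mRNAs/h" % (60 * rt["tr_molecules_per_min"].median()))
print("median density: %.4f molecules/kb" % rt["density_molecules_per_kb"].median())
print("events per cycle: %.0f" % result.snapshot.events_per_cycle)
print("turnover per cycle: %.2f" % result.snapshot.turnover_per_cycle)
print("Spearman(tr, true_tr) = %.3f ; median rel. err = %.1f%%"
      % (metrics["tr_spearman"], 100 * metrics["tr_median_rel_err"]))
```

prints

```
genes rated: 4959
median TR: 7.49 mRNAs/h
median density: 0.0832 molecules/kb
events per cycle: 111079
turnover per cycle: 4.27
Spearman(tr, true_tr) = 0.996 ; median rel. err = 5.4%
```

4959 of the 5000 simulated genes survive the validity filters. The median
nascent TR of ~7.5 mRNAs/h corresponds to a median elongating-pol II
density of ~0.08 molecules/kb at 25 nt/s — most genes carry well under one
active polymerase at any instant. Summed over the genome the cell performs
~1.1·10⁵ productive transcription events per 113-min cycle, turning its
26000-molecule mRNA pool over more than four times. The recovery metrics
compare the estimated rates with the simulation's ground truth: rank
agreement of 0.996 with a 5% median relative error shows the normalization,
bias correction and two-step calibration are close to lossless at this
noise level.

The same pipeline is available from a shell:

```sh
nascentrates run --n-genes 5000 --seed 1 --outdir out/
nascentrates snapshot --rates out/rates.tsv --out out/snapshot.tsv
```

and each stage (`simulate`, `preprocess`, `correct-bias`, `rates`,
`compare`, `snapshot`) can be run separately on user-supplied TSV tables.

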