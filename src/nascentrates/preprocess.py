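"""Array preprocessing: gDNA normalization, scaling, QC filters, averaging.

The stages mirror a classical macroarray workflow: each hybridization is
first divided by the genomic-DNA signal of the same filter (probe-amount
normalization), arrays are put on a common scale by median scaling, genes
must be measured in a minimum number of independent experiments, experiments
must agree (pairwise Pearson on log2 profiles), and the surviving replicate
structure is collapsed to one value per gene by a two-stage mean
(replicates -> experiment, experiments -> gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_matrix import SignalMatrix

logger = logging.getLogger(__name__)

REASON_INSUFFICIENT = "insufficient_valid"
REASON_NONPOSITIVE = "nonpositive_signal"


@dataclass
class QCReport:
    """Outcome of the gene and experiment filters.

    ``kept_gene_ids`` and ``dropped_gene_ids`` partition the input genes;
    each dropped gene carries a reason code.  ``pearson`` is the symmetric
    experiment-by-experiment correlation matrix (unit diagonal) used for the
    experiment filter.
    """

    kept_gene_ids: list[str] = field(default_factory=list)
    dropped_gene_ids: dict[str, str] = field(default_factory=dict)
    pearson: pd.DataFrame | None = None
    kept_experiment_ids: list[str] = field(default_factory=list)
    flagged_missing: dict[str, int] = field(default_factory=dict)

    def merge(self, other: "QCReport") -> "QCReport":
        merged = QCReport(
            kept_gene_ids=self.kept_gene_ids or other.kept_gene_ids,
            dropped_gene_ids={**self.dropped_gene_ids, **other.dropped_gene_ids},
            pearson=self.pearson if self.pearson is not None else other.pearson,
            kept_experiment_ids=self.kept_experiment_ids or other.kept_experiment_ids,
            flagged_missing={**self.flagged_missing, **other.flagged_missing},
        )
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "status": "kept", "reason": ""} for g in self.kept_gene_ids]
        rows += [{"gene_id": g, "status": "dropped", "reason": r}
                 for g, r in self.dropped_gene_ids.items()]
        return pd.DataFrame(rows, columns=["gene_id", "status", "reason"])


# ---------------------------------------------------------------------------


def normalize_to_gdna(signal: SignalMatrix, gdna: SignalMatrix) -> tuple[SignalMatrix, QCReport]:
    """Divide each hybridization by its genomic-DNA reference.

    If the gDNA matrix has the same array ids the division is array-wise
    (each filter by its own gDNA hybridization); otherwise each signal array
    is divided by the per-gene mean across the gDNA arrays.  A zero or
    missing gDNA value where the signal is present makes that measurement
    missing and is counted per gene in the report.
    """
    common = signal.values.index.intersection(gdna.values.index)
    if len(common) < signal.n_genes:
        raise ValueError("gdna reference does not cover all signal genes")
    sig = signal.values
    if list(gdna.values.columns) == list(sig.columns):
        ref = gdna.values.loc[sig.index]
    else:
        per_gene = gdna.values.loc[sig.index].mean(axis=1, skipna=True)
        ref = pd.DataFrame({c: per_gene for c in sig.columns})
    ref = ref.where(ref > 0)  # zero/negative reference is unusable
    out = sig / ref
    flagged_mask = sig.notna() & ref.isna()
    counts = flagged_mask.sum(axis=1)
    flagged = {g: int(c) for g, c in counts.items() if c > 0}
    if flagged:
        logger.warning("gDNA normalization flagged %d genes with unusable reference",
                       len(flagged))
    report = QCReport(flagged_missing=flagged)
    return SignalMatrix(out, dict(signal.experiment_of_array)), report


def mask_nonpositive(matrix: SignalMatrix) -> tuple[SignalMatrix, set[str]]:
    """Treat zero/negative signals as missing (log-domain steps need positivity)."""
    vals = matrix.values
    bad = vals.le(0)
    affected = set(vals.index[bad.any(axis=1)])
    if affected:
        logger.info("masked nonpositive signals in %d genes", len(affected))
    return SignalMatrix(vals.where(~bad), dict(matrix.experiment_of_array)), affected


def scale_arrays(matrix: SignalMatrix) -> SignalMatrix:
    """Median-scale each array so inter-array intensities are comparable.

    The median is taken over the genes non-missing in *all* arrays so every
    array is scaled on the same gene set; afterwards each array's median over
    that set is exactly 1, which makes the operation idempotent.
    """
    vals = matrix.values
    complete = vals.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no genes measured in all arrays; cannot median-scale")
    medians = complete.median(axis=0)
    bad = medians.index[(medians <= 0) | medians.isna()]
    if len(bad):
        raise ValueError(f"array(s) without usable values: {list(bad)}")
    return SignalMatrix(vals / medians, dict(matrix.experiment_of_array))


def valid_experiment_counts(matrix: SignalMatrix) -> pd.Series:
    """Per gene, the number of experiments with at least one non-missing replicate."""
    counts = pd.Series(0, index=matrix.values.index, dtype=int)
    for exp in matrix.experiment_ids:
        cols = matrix.arrays_of_experiment(exp)
        counts += matrix.values[cols].notna().any(axis=1).astype(int)
    return counts


def filter_genes(matrix: SignalMatrix, min_valid: int = 5,
                 nonpositive_genes: set[str] | None = None) -> tuple[SignalMatrix, QCReport]:
    """Keep genes measured in at least ``min_valid`` independent experiments.

    A gene counts as measured in an experiment when any of its replicates is
    non-missing.  Dropped genes are reported with ``insufficient_valid``, or
    ``nonpositive_signal`` when the gene lost all its values to the
    nonpositive-signal mask.
    """
    n_exp = len(matrix.experiment_ids)
    if min_valid > n_exp:
        raise ValueError(f"min_valid={min_valid} exceeds the {n_exp} experiments")
    nonpositive_genes = nonpositive_genes or set()
    counts = valid_experiment_counts(matrix)
    keep = counts >= min_valid
    dropped = {}
    for g in matrix.values.index[~keep]:
        if counts[g] == 0 and g in nonpositive_genes:
            dropped[g] = REASON_NONPOSITIVE
        else:
            dropped[g] = REASON_INSUFFICIENT
    kept_ids = list(matrix.values.index[keep])
    logger.info("gene filter: kept %d / %d genes (min_valid=%d)",
                len(kept_ids), matrix.n_genes, min_valid)
    report = QCReport(kept_gene_ids=kept_ids, dropped_gene_ids=dropped)
    return matrix.subset_genes(kept_ids), report


def _experiment_profiles(matrix: SignalMatrix, level: str) -> pd.DataFrame:
    """log2 profiles per experiment (replicate means) or per array."""
    with np.errstate(invalid="ignore", divide="ignore"):
        logged = np.log2(matrix.values.where(matrix.values > 0))
    if level == "array":
        return logged
    profiles = {}
    for exp in matrix.experiment_ids:
        cols = matrix.arrays_of_experiment(exp)
        profiles[exp] = logged[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(profiles)


def qc_experiments(matrix: SignalMatrix, min_pearson: float = 0.7,
                   level: str = "experiment") -> QCReport:
    """Drop experiments that disagree with the rest of the study.

    Each experiment's profile is the per-gene mean of the log2 replicate
    values; pairwise Pearson correlations are computed on genes complete in
    both profiles, and an experiment is kept iff its *median* pairwise
    correlation with the others reaches ``min_pearson``.  ``level='array'``
    applies the same rule to the 24 individual samples instead.
    """
    profiles = _experiment_profiles(matrix, level)
    names = list(profiles.columns)
    if len(names) < 2:
        raise ValueError("experiment QC needs at least 2 experiments")
    pearson = profiles.corr(method="pearson", min_periods=3)
    np.fill_diagonal(pearson.to_numpy(), 1.0)
    kept = []
    for name in names:
        others = [o for o in names if o != name]
        med = float(np.nanmedian(pearson.loc[name, others]))
        if med >= min_pearson:
            kept.append(name)
        else:
            logger.warning("experiment %s dropped: median pairwise Pearson %.3f < %.2f",
                           name, med, min_pearson)
    return QCReport(pearson=pearson, kept_experiment_ids=kept)


def average_experiments(matrix: SignalMatrix, qc: QCReport) -> pd.Series:
    """Two-stage mean: replicates within each kept experiment, then experiments.

    Genes with no value in any kept experiment are absent from the result.
    """
    kept = qc.kept_experiment_ids or matrix.experiment_ids
    if set(kept) <= set(matrix.experiment_ids):
        exp_means = {
            exp: matrix.values[matrix.arrays_of_experiment(exp)].mean(axis=1, skipna=True)
            for exp in kept
        }
    else:  # array-level QC: kept ids are arrays
        exp_means = {a: matrix.values[a] for a in kept if a in matrix.values.columns}
    stacked = pd.DataFrame(exp_means)
    out = stacked.mean(axis=1, skipna=True).dropna()
    out.name = "signal_au"
    return out


def preprocess_signal(signal: SignalMatrix, gdna: SignalMatrix | None = None,
                      min_valid: int = 5, min_pearson: float = 0.7,
                      qc_level: str = "experiment") -> tuple[pd.Series, QCReport]:
    """Full preprocessing of one signal matrix to a per-gene vector (AU)."""
    report = QCReport()
    if gdna is not None:
        signal, norm_report = normalize_to_gdna(signal, gdna)
        report = report.merge(norm_report)
    signal, nonpos = mask_nonpositive(signal)
    signal = scale_arrays(signal)
    signal, gene_report = filter_genes(signal, min_valid=min_valid,
                                       nonpositive_genes=nonpos)
    report = report.merge(gene_report)
    if len(signal.experiment_ids) >= 2:
        exp_report = qc_experiments(signal, min_pearson=min_pearson, level=qc_level)
        report = report.merge(exp_report)
    else:
        report.kept_experiment_ids = signal.experiment_ids
    return average_experiments(signal, report), report
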