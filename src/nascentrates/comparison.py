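"""Comparisons between nascent and indirect TR datasets.

The nascent TR counts every elongating polymerase; the indirect TR counts
only events that yield a mature cytoplasmic mRNA.  Their log-ratio,
corrected for the amplitude-dependent trend by a lowess fit in an MA-style
plot, is the per-gene discrepancy score used for group tests (e.g. genes
overlapping unstable non-coding transcripts).  The module also carries the
generic rank-correlation and distribution summaries used throughout.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .length_bias import lowess

logger = logging.getLogger(__name__)


def ma_lowess_ratio(tr: pd.Series, ind_tr: pd.Series, span: float = 0.2) -> pd.DataFrame:
    """MA-style comparison of nascent versus indirect TR.

    ``m = log2(tr / ind_tr)`` is plotted against ``a = log2(tr + ind_tr)``
    and the amplitude-dependent trend is removed by subtracting the lowess
    fit of m on a (span 20% by default).  Genes with a non-positive value in
    either dataset are dropped (count logged).
    """
    tr = pd.Series(tr).astype(float)
    ind_tr = pd.Series(ind_tr).astype(float)
    common = tr.index.intersection(ind_tr.index)
    t, i = tr.loc[common], ind_tr.loc[common]
    ok = (t > 0) & (i > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("ma_lowess_ratio: dropped %d genes with non-positive TRs", n_dropped)
    t, i = t[ok], i[ok]
    if len(t) < 10:
        raise ValueError("need at least 10 genes with positive nascent and indirect TR")
    m = np.log2(t / i)
    a = np.log2(t + i)
    fit = lowess(a.to_numpy(), m.to_numpy(), span=span)
    return pd.DataFrame(
        {"m": m.to_numpy(), "a": a.to_numpy(), "m_corrected": m.to_numpy() - fit},
        index=t.index,
    )


def group_mean_test(values, group_mask, equal_var: bool = False):
    """Two-sample t-test of a gene group against the rest.

    Welch's unequal-variance test by default (``equal_var=True`` switches to
    the pooled Student's test).  Returns ``(t, two_sided_p, group_mean,
    complement_mean)``.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and group_mask must be aligned")
    group, rest = values[mask], values[~mask]
    if len(group) < 2 or len(rest) < 2:
        raise ValueError("both the group and its complement need at least 2 values")
    t, p = stats.ttest_ind(group, rest, equal_var=equal_var)
    return float(t), float(p), float(group.mean()), float(rest.mean())


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties), pairwise complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    rho, _ = stats.spearmanr(x[ok], y[ok])
    return float(rho)


def transcription_share(tr, top_fraction: float) -> float:
    """Percent of total transcription carried by the top fraction of genes."""
    tr = np.asarray(tr, dtype=float)
    if tr.size == 0:
        raise ValueError("empty input")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    total = tr.sum()
    if total <= 0:
        raise ValueError("total transcription must be positive")
    k = math.ceil(top_fraction * tr.size)
    top = np.sort(tr)[::-1][:k]
    return float(100.0 * top.sum() / total)


def summary_stats(tr) -> dict[str, float]:
    """Median, 5th/95th percentiles (linear interpolation) and mean."""
    tr = np.asarray(tr, dtype=float)
    if tr.size == 0:
        raise ValueError("empty input")
    return {
        "median": float(np.median(tr)),
        "p5": float(np.percentile(tr, 5, method="linear")),
        "p95": float(np.percentile(tr, 95, method="linear")),
        "mean": float(tr.mean()),
    }
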