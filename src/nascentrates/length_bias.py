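"""Probe-length bias removal for run-on signals.

Run-on labeling accumulates towards the 3' end of transcripts, so the
per-probe GRO signal depends on ORF length, with a regime change at the
3 kb boundary where the array probe design switches from full-ORF probes to
3'-terminal 1 kb probes.  The pol II ChIP (RPCC) signal shows only a mild
length trend and serves as the unbiased reference: both datasets are
standardized (z-score of log2 values), independent lowess smoothers versus
ORF length are fitted above and below the 3 kb split, and the difference
between the GRO and RPCC smoothers is subtracted from the GRO z-scores.
The standardization is finally reversed (and optionally de-logged) to
recover corrected arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StandardizationParams:
    """Mean and sd of the log2 values, retained so the z-score can be inverted."""

    mean_log2: float
    sd_log2: float

    def __post_init__(self) -> None:
        if self.sd_log2 <= 0:
            raise ValueError("sd_log2 must be positive")


def log2_zscore(values) -> tuple[np.ndarray, StandardizationParams]:
    """Standardize positive values in log2 space.

    Each value is log2-transformed, the population mean is subtracted and
    the result divided by the population standard deviation (ddof=0, so the
    worked case (2, 8) -> (-1, +1)).  Returns the z-scores and the
    parameters needed to invert the transform.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        ids = _offender_ids(values, bad)
        raise ValueError(f"non-positive values at {ids}; filter them upstream")
    logged = np.log2(arr)
    mean = float(logged.mean())
    sd = float(logged.std(ddof=0))
    if sd == 0:
        raise ValueError("constant input: standard deviation is zero")
    return (logged - mean) / sd, StandardizationParams(mean, sd)


def _offender_ids(values, positions: np.ndarray) -> list:
    index = getattr(values, "index", None)
    if index is not None:
        return [index[i] for i in positions[:10]]
    return positions[:10].tolist()


def invert_zscore(z, params: StandardizationParams, delog: bool = False) -> np.ndarray:
    """Reverse the standardization: z * sd + mean in log2 space, or 2**(that)."""
    logged = np.asarray(z, dtype=float) * params.sd_log2 + params.mean_log2
    return np.exp2(logged) if delog else logged


# ---------------------------------------------------------------------------
# lowess
# ---------------------------------------------------------------------------

def lowess(x, y, span: float = 0.2) -> np.ndarray:
    """Locally weighted linear regression (lowess), fitted at the observed x.

    The canonical flavor: for each point, the ``k = ceil(span * n)`` nearest
    neighbours define the bandwidth (distance to the k-th nearest), weights
    are tricube in the scaled distance, and a weighted straight line is fit;
    no robustness iterations.  Ties in x receive identical fitted values.
    Linear in y, so the fit of ``y + c`` is the fit of ``y`` plus ``c``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError("lowess needs at least 5 points")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = int(math.ceil(span * n))
    if k < 2:
        raise ValueError("span * n must be at least 2")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fit_sorted = np.empty(n)
    left = 0
    for i in range(n):
        # slide the k-point window so it holds the k nearest neighbours of xs[i]
        while left + k < n and xs[i] - xs[left] > xs[left + k] - xs[i]:
            left += 1
        xw = xs[left:left + k]
        yw = ys[left:left + k]
        h = max(xs[i] - xw[0], xw[-1] - xs[i])
        if h <= 0:  # k-th neighbour coincides with the target: average the ties
            tie = xs == xs[i]
            fit_sorted[i] = ys[tie].mean()
            continue
        u = np.abs(xw - xs[i]) / h
        w = np.clip(1.0 - u ** 3, 0.0, None) ** 3
        sw = w.sum()
        xbar = (w @ xw) / sw
        ybar = (w @ yw) / sw
        dx = xw - xbar
        denom = w @ (dx * dx)
        slope = (w @ (dx * yw)) / denom if denom > 0 else 0.0
        fit_sorted[i] = ybar + slope * (xs[i] - xbar)
    fitted = np.empty(n)
    fitted[order] = fit_sorted
    return fitted


def dual_lowess_correct(gro_z, rpcc_z, lengths_bp, split_bp: int = 3000,
                        span: float = 0.2) -> np.ndarray:
    """Subtract the GRO-minus-RPCC length trend, separately above/below 3 kb.

    Within each probe-design regime (length < split_bp, length >= split_bp;
    genes of exactly ``split_bp`` fall in the upper regime, matching the
    probe rule "shorter than 3 kb"), lowess smoothers of the GRO and RPCC
    z-scores versus ORF length are fitted and

        corrected_i = gro_z_i - (fit_gro(length_i) - fit_rpcc(length_i)).
    """
    gro_z = np.asarray(gro_z, dtype=float)
    rpcc_z = np.asarray(rpcc_z, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if not (gro_z.shape == rpcc_z.shape == lengths.shape):
        raise ValueError("gro_z, rpcc_z and lengths_bp must be aligned")
    need = max(5, math.ceil(2.0 / span))
    corrected = np.empty_like(gro_z)
    for name, mask in (("<%d bp" % split_bp, lengths < split_bp),
                       (">=%d bp" % split_bp, lengths >= split_bp)):
        if mask.sum() < need:
            raise ValueError(
                f"regime {name} has only {int(mask.sum())} genes (< {need}); "
                "disable the split and fit a single regime instead"
            )
        fit_gro = lowess(lengths[mask], gro_z[mask], span=span)
        fit_rpcc = lowess(lengths[mask], rpcc_z[mask], span=span)
        corrected[mask] = gro_z[mask] - (fit_gro - fit_rpcc)
    return corrected
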