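"""Steady-state kinetics: absolute calibration, indirect TRs, pol II densities.

Under steady state with exponential growth the synthesis of each mRNA
balances its disappearance, which has two components: degradation
(``kd = ln2 / half-life``) and dilution by the doubling cell volume
(``ln2 / doubling time``).  The indirect transcription rate is therefore

    indTR = RA * (kd + ln2 / T_gen)        [molecules/min]

with the dilution term optional (classical stability measurements are made
in non-growing cells and miss it).  The nascent TR in arbitrary units is
placed on the molecules/min scale by a median-of-ratios match against the
most reliable indirect TRs, and converted into an elongating-polymerase
density through the elongation speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LN2 = math.log(2.0)


@dataclass(frozen=True)
class KineticConstants:
    """Cell-level constants for an exponentially growing yeast culture."""

    doubling_time_min: float = 113.0
    total_mrna_per_cell: float = 26000.0
    elongation_nt_per_s: float = 25.0
    s_phase_fraction: float = 0.27
    nucleosome_footprint_bp: int = 147
    genome_gene_count: int = 5796

    def __post_init__(self) -> None:
        for name in ("doubling_time_min", "total_mrna_per_cell", "elongation_nt_per_s",
                     "s_phase_fraction", "nucleosome_footprint_bp", "genome_gene_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s_phase_fraction > 1:
            raise ValueError("s_phase_fraction must be in (0, 1]")

    @property
    def elongation_kb_per_min(self) -> float:
        """Elongation speed in kb/min (25 nt/s -> 1.5 kb/min)."""
        return self.elongation_nt_per_s * 60.0 / 1000.0

    @property
    def dilution_rate_per_min(self) -> float:
        return LN2 / self.doubling_time_min


def _as_series(x, name: str) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    return pd.Series(np.asarray(x, dtype=float), name=name)


def _top_k_ids(values: pd.Series, k: int) -> pd.Index:
    """Ids of the k largest values, ties broken by gene id for determinism."""
    order = values.sort_index().sort_values(ascending=False, kind="stable")
    return order.index[:k]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_abundance(relative_ra: pd.Series, reference: pd.DataFrame,
                        top_k: int = 2000) -> pd.Series:
    """Scale relative abundances to molecules/cell against an absolute reference.

    The scale factor is the median, over the ``top_k`` reference-ranked genes
    shared by both tables, of ``reference_abundance / relative_ra``; the whole
    relative table is multiplied by it.  Median-of-ratios is exactly correct
    for proportional data and robust to outliers.
    """
    relative_ra = _as_series(relative_ra, "relative_ra")
    if np.any(relative_ra.to_numpy() <= 0):
        raise ValueError("relative abundances must be positive")
    ref = reference.set_index("gene_id")["abundance"] if "gene_id" in getattr(
        reference, "columns", []) else _as_series(reference, "abundance")
    common = relative_ra.index.intersection(ref.index)
    if len(common) < top_k:
        raise ValueError(
            f"only {len(common)} genes shared with the reference; "
            f"need at least top_k={top_k} (use a smaller top_k)"
        )
    chosen = _top_k_ids(ref.loc[common], top_k)
    factor = float(np.median(ref.loc[chosen] / relative_ra.loc[chosen]))
    return relative_ra * factor


def calibrate_nascent(tr_au: pd.Series, ind_tr: pd.Series, top_k: int = 2000) -> pd.Series:
    """Convert nascent TR from arbitrary units to molecules/min.

    Uses the ``top_k`` genes with the highest (most confident) indirect,
    dilution-corrected TR; the factor is the median of ``ind_tr / tr_au``
    over that selection.
    """
    tr_au = _as_series(tr_au, "tr_au")
    ind_tr = _as_series(ind_tr, "ind_tr")
    common = tr_au.index.intersection(ind_tr.index)
    ok = common[(tr_au.loc[common] > 0) & (ind_tr.loc[common] > 0)]
    if len(ok) < top_k:
        raise ValueError(
            f"only {len(ok)} genes with positive nascent and indirect TR; "
            f"need at least top_k={top_k}"
        )
    chosen = _top_k_ids(ind_tr.loc[ok], top_k)
    factor = float(np.median(ind_tr.loc[chosen] / tr_au.loc[chosen]))
    return tr_au * factor


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def degradation_rate(half_life_min):
    """kd = ln2 / half-life (1/min); an infinite half-life gives kd = 0."""
    hl = np.asarray(half_life_min, dtype=float)
    if np.any(hl[~np.isnan(hl)] <= 0):
        raise ValueError("half-lives must be positive")
    out = LN2 / hl
    return out if out.ndim else float(out)


def indirect_tr(ra, half_life_min, constants: KineticConstants,
                include_dilution: bool = True):
    """Steady-state (indirect) TR in molecules/min.

    ``RA * kd`` compensates degradation; with ``include_dilution`` the term
    ``RA * ln2 / doubling_time`` compensating growth dilution is added.
    """
    ra_arr = np.asarray(ra, dtype=float)
    if np.any(ra_arr[~np.isnan(ra_arr)] < 0):
        raise ValueError("abundances must be nonnegative")
    kd = np.asarray(degradation_rate(half_life_min), dtype=float)
    rate = kd + (constants.dilution_rate_per_min if include_dilution else 0.0)
    out = ra_arr * rate
    if isinstance(ra, pd.Series):
        return pd.Series(out, index=ra.index, name="ind_tr")
    return out if out.ndim else float(out)


def pol_density(tr, constants: KineticConstants):
    """Elongating pol II density (molecules/kb) from a TR in molecules/min."""
    out = np.asarray(tr, dtype=float) / constants.elongation_kb_per_min
    if isinstance(tr, pd.Series):
        return pd.Series(out, index=tr.index, name="density_per_kb")
    return out if out.ndim else float(out)


def pols_per_gene(density_per_kb, orf_length_bp):
    """Elongating pol II molecules per gene: density x gene length (kb)."""
    out = np.asarray(density_per_kb, dtype=float) * np.asarray(orf_length_bp, dtype=float) / 1000.0
    if isinstance(density_per_kb, pd.Series):
        return pd.Series(out, index=density_per_kb.index, name="pols_per_gene")
    return out if out.ndim else float(out)


def dilution_fraction(ra, tr, constants: KineticConstants):
    """Percent of the TR devoted to compensating growth dilution, clamped to [0, 100].

    The dilution-compensating TR is computed independently of the nascent TR,
    so the raw ratio can exceed 100%; such values are clamped (100% = the TR
    is dominated by dilution, 0% = dilution negligible).  ``tr = 0`` with
    positive abundance clamps to 100; ``tr = ra = 0`` gives 0.
    """
    ra_arr = np.asarray(ra, dtype=float)
    tr_arr = np.asarray(tr, dtype=float)
    dilution_tr = ra_arr * constants.dilution_rate_per_min
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 100.0 * dilution_tr / tr_arr
    raw = np.where((tr_arr == 0) & (ra_arr > 0), 100.0, raw)
    raw = np.where((tr_arr == 0) & (ra_arr == 0), 0.0, raw)
    out = np.clip(raw, 0.0, 100.0)
    if isinstance(tr, pd.Series):
        return pd.Series(out, index=tr.index, name="dilution_pct")
    return out if out.ndim else float(out)


def build_rate_table(gene_ids, orf_length_bp, tr_au, tr, ind_tr_nodil, ind_tr,
                     ra, half_life_min, constants: KineticConstants) -> pd.DataFrame:
    """Assemble the per-gene rate table with unit-suffixed column names.

    Series inputs are aligned on gene id; plain sequences are taken
    positionally in ``gene_ids`` order.
    """
    idx = pd.Index(gene_ids, name="gene_id")

    def aligned(x) -> np.ndarray:
        if isinstance(x, pd.Series):
            return x.loc[idx].to_numpy(dtype=float)
        arr = np.asarray(x, dtype=float)
        if arr.shape != (len(idx),):
            raise ValueError("positional input length does not match gene_ids")
        return arr

    tr_arr = aligned(tr)
    dens = pol_density(tr_arr, constants)
    table = pd.DataFrame(
        {
            "gene_id": idx,
            "orf_length_bp": np.asarray(orf_length_bp),
            "tr_au": aligned(tr_au),
            "tr_molecules_per_min": tr_arr,
            "ind_tr_nodil_molecules_per_min": aligned(ind_tr_nodil),
            "ind_tr_molecules_per_min": aligned(ind_tr),
            "ra_molecules_per_cell": aligned(ra),
            "half_life_min": aligned(half_life_min),
            "density_molecules_per_kb": dens,
        }
    )
    table["pols_per_gene"] = pols_per_gene(
        table["density_molecules_per_kb"], table["orf_length_bp"]
    ).to_numpy()
    table["dilution_pct"] = dilution_fraction(
        table["ra_molecules_per_cell"].to_numpy(),
        table["tr_molecules_per_min"].to_numpy(), constants)
    return table.reset_index(drop=True)
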