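"""Genome-wide transcriptional bookkeeping ("snapshot" arithmetic).

From the per-gene rate table and a handful of cell-level constants this
module derives the whole-cell picture: total productive transcription,
events and mRNA-pool turnover per cell cycle, S-phase-adjusted rates for
replication-coupled genes, the timing of polymerase passage through a
nucleosome, and the census of elongating polymerases against the
hyperphosphorylated pol II pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticConstants


@dataclass(frozen=True)
class SnapshotParams:
    """Published cell-biology inputs for the polymerase census."""

    total_polII_per_cell: float = 20000.0
    hyperphosphorylated_fraction: float = 0.6
    chromatin_bound_fraction_low: float = 0.6
    chromatin_bound_fraction_high: float = 0.8

    def __post_init__(self) -> None:
        if self.total_polII_per_cell <= 0:
            raise ValueError("total_polII_per_cell must be positive")
        for f in (self.hyperphosphorylated_fraction,
                  self.chromatin_bound_fraction_low, self.chromatin_bound_fraction_high):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.chromatin_bound_fraction_low > self.chromatin_bound_fraction_high:
            raise ValueError("chromatin-bound fraction interval inverted")


@dataclass
class SnapshotSummary:
    """Whole-cell totals extrapolated to the full genome."""

    total_tr_per_hour: float
    events_per_min: float
    events_per_cycle: float
    turnover_per_cycle: float
    elongating_pols: float
    n_measured: int
    extrapolation_factor: float

    def to_dict(self) -> dict[str, float]:
        return {
            "total_tr_mrnas_per_hour": self.total_tr_per_hour,
            "events_per_min": self.events_per_min,
            "events_per_cycle": self.events_per_cycle,
            "turnover_per_cycle": self.turnover_per_cycle,
            "elongating_pols": self.elongating_pols,
            "n_measured": self.n_measured,
            "extrapolation_factor": self.extrapolation_factor,
        }


def genome_totals(rates: pd.DataFrame, constants: KineticConstants,
                  extrapolate: bool = True) -> SnapshotSummary:
    """Sum the rate table and extrapolate to the whole genome.

    Measured genes are assumed representative of all ORF-containing genes,
    so sums are multiplied by ``genome_gene_count / n_measured`` (disable
    with ``extrapolate=False``).  Events per cycle and the turnover of the
    mRNA pool follow directly from the doubling time and the total mRNA
    content.
    """
    if len(rates) == 0:
        raise ValueError("empty rate table")
    n = len(rates)
    factor = constants.genome_gene_count / n if extrapolate else 1.0
    total_per_hour = float(rates["tr_molecules_per_min"].sum()) * 60.0 * factor
    events_per_min = total_per_hour / 60.0
    events_per_cycle = events_per_min * constants.doubling_time_min
    turnover = events_per_cycle / constants.total_mrna_per_cell
    elongating = float(rates["pols_per_gene"].sum()) * factor if "pols_per_gene" in rates else float("nan")
    return SnapshotSummary(
        total_tr_per_hour=total_per_hour,
        events_per_min=events_per_min,
        events_per_cycle=events_per_cycle,
        turnover_per_cycle=turnover,
        elongating_pols=elongating,
        n_measured=n,
        extrapolation_factor=factor,
    )


def phase_adjust(tr, phase_fraction: float):
    """Population-average TR -> TR while the gene is actually active.

    Replication-coupled genes (histones) transcribe only during S phase;
    dividing the population average by the phase fraction gives the rate in
    the cells that are transcribing.
    """
    if not 0 < phase_fraction <= 1:
        raise ValueError("phase_fraction must be in (0, 1]")
    out = np.asarray(tr, dtype=float) / phase_fraction
    return out if out.ndim else float(out)


def nucleosome_timing(tr_per_hour: float, constants: KineticConstants
                      ) -> tuple[float, float, float]:
    """Timing of polymerase passage through one nucleosome at a given TR.

    Returns ``(interval_s, transit_s, occupancy_fraction)``: the time between
    successive polymerases at any position (3600 / TR per hour), the time one
    polymerase needs to read the nucleosome footprint, and the fraction of
    time the nucleosome could stay DNA-associated (zero-floored).
    """
    if tr_per_hour <= 0:
        raise ValueError("tr_per_hour must be positive")
    interval_s = 3600.0 / tr_per_hour
    transit_s = constants.nucleosome_footprint_bp / constants.elongation_nt_per_s
    occupancy = max(0.0, 1.0 - transit_s / interval_s)
    return interval_s, transit_s, occupancy


def active_pol_census(summary: SnapshotSummary, params: SnapshotParams
                      ) -> tuple[float, float]:
    """Fraction of gene-associated hyperphosphorylated pol II actually elongating.

    The denominator is ``total_polII x hyperphosphorylated_fraction`` (the
    gene-associated hyperphosphorylated pool).  Because an unknown share of
    elongating polymerases never yields a mature mRNA, the numerator is
    uncertain by up to 2x; the returned interval is
    ``[elongating, 2 x elongating] / pool`` as fractions.
    """
    if summary.elongating_pols < 0 or not np.isfinite(summary.elongating_pols):
        raise ValueError("elongating_pols must be a nonnegative finite number")
    pool = params.total_polII_per_cell * params.hyperphosphorylated_fraction
    if pool <= 0:
        raise ValueError("hyperphosphorylated pol II pool is zero")
    low = summary.elongating_pols / pool
    return low, 2.0 * low
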