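"""Synthetic GRO / RPCC / gDNA / abundance data with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for a budding-yeast macroarray study:

* log-normal true transcription rates (TR, molecules/min) and mRNA
  half-lives (min);
* steady-state abundances ``RA = TR / (kd + ln2/T_gen)`` where the second
  denominator term is the growth-dilution rate;
* a run-on 3' labeling bias: an elongating polymerase at position ``x``
  labels the next ``min(delta, L - x)`` nucleotides, so the expected
  per-position label is ``d * min(delta, y)`` with ``d`` the per-nt
  polymerase density and ``y`` the distance from the ORF start.  Integrated
  over the probe this produces a signal that, after genomic-DNA
  normalization, rises with ORF length below the 3 kb probe-design boundary
  (full-ORF probes) and is flat above it (3'-terminal 1 kb probes);
* a milder power-law length trend in the pol II ChIP (RPCC) signal;
* multiplicative log-normal noise, array-level scale factors, and
  uniformly-at-random missing values.

Every simulator op is reproducible: the same seed yields byte-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticConstants
from .signal_matrix import SignalMatrix

LN2 = math.log(2.0)

#: ORF length (bp) at which the array probe design switches from the
#: complete ORF to the 3'-terminal kilobase.
PROBE_DESIGN_SPLIT_BP = 3000
PROBE_TAIL_BP = 1000
MIN_ORF_BP = 150

# independent RNG streams per simulator op, all derived from config.seed
_STREAM_CATALOG = 0
_STREAM_KINETICS = 1
_STREAM_GRO = 2
_STREAM_RPCC = 3
_STREAM_GDNA = 4
_STREAM_REF_RA = 5
_STREAM_REL_RA = 6
_STREAM_HALFLIFE = 7


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError("noise cv must be nonnegative")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults reproduce an exponentially growing yeast culture profiled on
    8 GRO experiments x 3 replicates: the TR distribution is centred on the
    observed median of ~0.12 molecules/min with a spread matching the
    reported 90% range (2.33-29.7 mRNAs/h), half-lives on ~20 min, and ORF
    lengths on ~1.3 kb.
    """

    n_genes: int = 5000
    seed: int = 0
    tr_log10_mean: float = -0.92      # log10 molecules/min; 10**-0.92 ~ 0.12
    tr_log10_sd: float = 0.34
    halflife_log10_mean: float = 1.30  # log10 min; ~20 min
    halflife_log10_sd: float = 0.25
    length_log10_mean: float = 3.11    # log10 bp; ~1.3 kb
    length_log10_sd: float = 0.26
    runon_extension_nt: int = 300
    noise_cv: float = 0.2
    array_scale_cv: float = 0.2
    rnaseq_noise_cv: float = 0.1   # sequencing-based abundances are more precise

    missing_rate: float = 0.05
    rpcc_length_bias_exponent: float = -0.05
    n_experiments: int = 8
    reps_per_experiment: int = 3

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if self.runon_extension_nt <= 0:
            raise ValueError("runon_extension_nt must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_cv < 0 or self.array_scale_cv < 0 or self.rnaseq_noise_cv < 0:
            raise ValueError("noise coefficients of variation must be nonnegative")
        if self.tr_log10_sd <= 0 or self.halflife_log10_sd <= 0 or self.length_log10_sd <= 0:
            raise ValueError("log10 scale parameters must be positive")
        if self.n_experiments < 1 or self.reps_per_experiment < 1:
            raise ValueError("need at least one experiment and one replicate")


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------

def probe_interval(orf_length_bp: int, split_bp: int = PROBE_DESIGN_SPLIT_BP,
                   tail_bp: int = PROBE_TAIL_BP) -> tuple[int, int]:
    """Probe coordinates for one ORF (0-based half-open, relative to the ORF start).

    Genes shorter than ``split_bp`` are covered by a full-ORF probe; longer
    genes by their 3'-terminal ``tail_bp``.
    """
    L = int(orf_length_bp)
    if L <= 0:
        raise ValueError("orf_length_bp must be positive")
    if L < split_bp:
        return 0, L
    return L - tail_bp, L


def generate_gene_catalog(n_genes: int, seed: int,
                          length_log10_mean: float = 3.11,
                          length_log10_sd: float = 0.26) -> pd.DataFrame:
    """Draw a gene catalog with log-normal ORF lengths and the probe-design rule.

    Returns a DataFrame with columns ``gene_id``, ``orf_length_bp``,
    ``probe_start_bp``, ``probe_end_bp`` (and an empty ``group_label``).
    Lengths are floored at 150 bp so every probe interval is valid.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be nonnegative")
    if not (np.isfinite(length_log10_mean) and np.isfinite(length_log10_sd)):
        raise ValueError("length distribution parameters must be finite")
    rng = _rng(seed, _STREAM_CATALOG)
    lengths = np.round(10.0 ** rng.normal(length_log10_mean, length_log10_sd, n_genes))
    lengths = np.maximum(lengths, MIN_ORF_BP).astype(int)
    starts = np.empty(n_genes, dtype=int)
    ends = np.empty(n_genes, dtype=int)
    for i, L in enumerate(lengths):
        starts[i], ends[i] = probe_interval(L)
    width = max(5, len(str(max(n_genes, 1))))
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(1, n_genes + 1)],
            "orf_length_bp": lengths,
            "probe_start_bp": starts,
            "probe_end_bp": ends,
            "group_label": [""] * n_genes,
        }
    )


# ---------------------------------------------------------------------------
# ground-truth kinetics
# ---------------------------------------------------------------------------

def generate_true_kinetics(catalog: pd.DataFrame, constants: KineticConstants,
                           config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth TR, half-life, degradation rate, density and steady-state RA.

    The polymerase density is tied to the TR through the elongation speed
    (``density = TR / v`` with ``v`` in kb/min) and RA follows from steady
    state with growth dilution: ``RA = TR / (kd + ln2 / T_gen)``.
    """
    if len(catalog) == 0:
        raise ValueError("catalog must be non-empty")
    rng = _rng(config.seed, _STREAM_KINETICS)
    n = len(catalog)
    true_tr = 10.0 ** rng.normal(config.tr_log10_mean, config.tr_log10_sd, n)
    half_life = 10.0 ** rng.normal(config.halflife_log10_mean, config.halflife_log10_sd, n)
    kd = LN2 / half_life
    dilution = LN2 / constants.doubling_time_min
    ra_true = true_tr / (kd + dilution)
    true_density = true_tr / constants.elongation_kb_per_min
    return pd.DataFrame(
        {
            "gene_id": catalog["gene_id"].to_numpy(),
            "true_density": true_density,   # molecules per kb
            "true_tr": true_tr,             # molecules per min
            "half_life_min": half_life,
            "kd": kd,                       # 1/min
            "ra_true": ra_true,             # molecules per cell
        }
    )


# ---------------------------------------------------------------------------
# expected array signals (closed forms)
# ---------------------------------------------------------------------------

def _labeling_antiderivative(t: np.ndarray, delta: float) -> np.ndarray:
    # F(t) = integral_0^t min(delta, y) dy
    t = np.asarray(t, dtype=float)
    return np.where(t <= delta, 0.5 * t * t, 0.5 * delta * delta + delta * (t - delta))


def expected_gro_signal(catalog: pd.DataFrame, density_per_kb: np.ndarray,
                        extension_nt: float) -> np.ndarray:
    """Expected run-on label (nt equivalents) overlapping each gene's probe.

    Polymerases sit uniformly at per-nt density ``d = density_per_kb/1000``;
    each labels the next ``min(delta, L - x)`` nt, so position ``y`` receives
    label from the polymerases within ``delta`` upstream: coverage
    ``d * min(delta, y)``.  The probe signal is the integral of that coverage
    over the probe interval.
    """
    if extension_nt <= 0:
        raise ValueError("run-on extension must be positive")
    d_nt = np.asarray(density_per_kb, dtype=float) / 1000.0
    a = catalog["probe_start_bp"].to_numpy(dtype=float)
    b = catalog["probe_end_bp"].to_numpy(dtype=float)
    return d_nt * (_labeling_antiderivative(b, extension_nt)
                   - _labeling_antiderivative(a, extension_nt))


def expected_rpcc_signal(catalog: pd.DataFrame, density_per_kb: np.ndarray,
                         length_bias_exponent: float) -> np.ndarray:
    """Expected pol II ChIP enrichment: density with a mild power-law length trend."""
    L_kb = catalog["orf_length_bp"].to_numpy(dtype=float) / 1000.0
    return np.asarray(density_per_kb, dtype=float) * L_kb ** length_bias_exponent


def expected_gdna_signal(catalog: pd.DataFrame) -> np.ndarray:
    """Expected genomic-DNA hybridization signal: proportional to probe length."""
    return (catalog["probe_end_bp"] - catalog["probe_start_bp"]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# simulated array matrices
# ---------------------------------------------------------------------------

def _noisy_matrix(expected: np.ndarray, rng: np.random.Generator,
                  array_ids: list[str], noise_cv: float, array_scale_cv: float,
                  missing_rate: float, gene_ids: np.ndarray) -> SignalMatrix:
    n = expected.size
    cols = {}
    for array_id in array_ids:
        scale = _lognormal_factors(rng, array_scale_cv, 1)[0]
        vals = expected * scale * _lognormal_factors(rng, noise_cv, n)
        if missing_rate > 0:
            vals = np.where(rng.random(n) < missing_rate, np.nan, vals)
        cols[array_id] = vals
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return SignalMatrix(values)


def _check_alignment(truth: pd.DataFrame, catalog: pd.DataFrame) -> None:
    if not np.array_equal(truth["gene_id"].to_numpy(), catalog["gene_id"].to_numpy()):
        raise ValueError("truth and catalog must be aligned on gene_id")


def gro_array_ids(config: SimulationConfig) -> list[str]:
    return [
        f"exp{e}_rep{r}"
        for e in range(1, config.n_experiments + 1)
        for r in range(1, config.reps_per_experiment + 1)
    ]


def simulate_gro_arrays(truth: pd.DataFrame, catalog: pd.DataFrame,
                        config: SimulationConfig) -> SignalMatrix:
    """Run-on arrays: 3'-biased labeling signal with noise and missing spots."""
    _check_alignment(truth, catalog)
    expected = expected_gro_signal(catalog, truth["true_density"].to_numpy(),
                                   config.runon_extension_nt)
    rng = _rng(config.seed, _STREAM_GRO)
    return _noisy_matrix(expected, rng, gro_array_ids(config), config.noise_cv,
                         config.array_scale_cv, config.missing_rate,
                         catalog["gene_id"].to_numpy())


def simulate_rpcc_arrays(truth: pd.DataFrame, catalog: pd.DataFrame,
                         config: SimulationConfig) -> SignalMatrix:
    """Pol II ChIP arrays in triplicate (each replicate its own experiment)."""
    _check_alignment(truth, catalog)
    expected = expected_rpcc_signal(catalog, truth["true_density"].to_numpy(),
                                    config.rpcc_length_bias_exponent)
    rng = _rng(config.seed, _STREAM_RPCC)
    ids = [f"rpcc{r}_rep1" for r in range(1, 4)]
    return _noisy_matrix(expected, rng, ids, config.noise_cv,
                         config.array_scale_cv, config.missing_rate,
                         catalog["gene_id"].to_numpy())


def simulate_gdna_reference(catalog: pd.DataFrame, config: SimulationConfig) -> SignalMatrix:
    """Genomic-DNA hybridizations of the same filters used for the GRO arrays.

    One gDNA reference per GRO array (same array ids), signal proportional to
    probe length with multiplicative noise; never missing, strictly positive.
    """
    if len(catalog) == 0:
        raise ValueError("catalog must be non-empty")
    expected = expected_gdna_signal(catalog)
    rng = _rng(config.seed, _STREAM_GDNA)
    return _noisy_matrix(expected, rng, gro_array_ids(config), config.noise_cv,
                         config.array_scale_cv, 0.0, catalog["gene_id"].to_numpy())


# ---------------------------------------------------------------------------
# abundance and half-life inputs
# ---------------------------------------------------------------------------

def simulate_reference_abundances(truth: pd.DataFrame, n_ref: int,
                                  noise_cv: float, seed: int) -> pd.DataFrame:
    """Absolute-abundance reference (competitive-PCR-like) for the most abundant genes.

    Returns the ``n_ref`` genes with the highest true steady-state abundance,
    measured with multiplicative log-normal noise.
    """
    if n_ref <= 0 or n_ref > len(truth):
        raise ValueError(f"n_ref must be in [1, {len(truth)}]")
    rng = _rng(seed, _STREAM_REF_RA)
    top = truth.sort_values(["ra_true", "gene_id"], ascending=[False, True]).head(n_ref)
    abundance = top["ra_true"].to_numpy() * _lognormal_factors(rng, noise_cv, n_ref)
    return pd.DataFrame({"gene_id": top["gene_id"].to_numpy(),
                         "abundance": abundance})


def simulate_relative_abundances(truth: pd.DataFrame, noise_cv: float, seed: int,
                                 scale: float = 1e-3) -> pd.Series:
    """Relative mRNA abundances (RNA-Seq-like): true RA in arbitrary units plus noise."""
    rng = _rng(seed, _STREAM_REL_RA)
    vals = truth["ra_true"].to_numpy() * scale * _lognormal_factors(rng, noise_cv, len(truth))
    return pd.Series(vals, index=pd.Index(truth["gene_id"], name="gene_id"),
                     name="relative_ra")


def simulate_measured_half_lives(truth: pd.DataFrame, noise_cv: float, seed: int) -> pd.Series:
    """Measured mRNA half-lives (min): ground truth with multiplicative noise."""
    rng = _rng(seed, _STREAM_HALFLIFE)
    vals = truth["half_life_min"].to_numpy() * _lognormal_factors(rng, noise_cv, len(truth))
    return pd.Series(vals, index=pd.Index(truth["gene_id"], name="gene_id"),
                     name="half_life_min")
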