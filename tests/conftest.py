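import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nascentrates.kinetics import KineticConstants
from nascentrates.synthetic import (SimulationConfig, generate_gene_catalog,
                                    generate_true_kinetics)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants() -> KineticConstants:
    return KineticConstants()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=300, seed=7)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return generate_gene_catalog(small_config.n_genes, small_config.seed,
                                 small_config.length_log10_mean,
                                 small_config.length_log10_sd)


@pytest.fixture(scope="session")
def small_truth(small_catalog, constants, small_config):
    return generate_true_kinetics(small_catalog, constants, small_config)


def make_catalog(lengths: list[int]) -> pd.DataFrame:
    """Catalog for explicit ORF lengths, probe rule applied."""
    from nascentrates.synthetic import probe_interval

    rows = []
    for i, L in enumerate(lengths, start=1):
        a, b = probe_interval(L)
        rows.append({"gene_id": f"g{i:05d}", "orf_length_bp": L,
                     "probe_start_bp": a, "probe_end_bp": b, "group_label": ""})
    return pd.DataFrame(rows)


def make_truth(catalog: pd.DataFrame, density_per_kb, constants: KineticConstants,
               half_life_min=20.0) -> pd.DataFrame:
    """Truth table with prescribed densities (TR derived via elongation speed)."""
    density = np.broadcast_to(np.asarray(density_per_kb, dtype=float), (len(catalog),))
    tr = density * constants.elongation_kb_per_min
    hl = np.broadcast_to(np.asarray(half_life_min, dtype=float), (len(catalog),))
    kd = np.log(2) / hl
    ra = tr / (kd + np.log(2) / constants.doubling_time_min)
    return pd.DataFrame({"gene_id": catalog["gene_id"].to_numpy(),
                         "true_density": density, "true_tr": tr,
                         "half_life_min": hl, "kd": kd, "ra_true": ra})
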