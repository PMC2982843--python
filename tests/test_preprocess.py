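"""Normalization, scaling, replicate filters and averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nascentrates.kinetics import KineticConstants
from nascentrates.preprocess import (REASON_INSUFFICIENT, average_experiments,
                                     filter_genes, normalize_to_gdna,
                                     preprocess_signal, qc_experiments,
                                     scale_arrays)
from nascentrates.signal_matrix import SignalMatrix
from nascentrates.synthetic import (SimulationConfig, expected_gro_signal,
                                    generate_gene_catalog, generate_true_kinetics,
                                    simulate_gdna_reference, simulate_gro_arrays)

from conftest import make_catalog, make_truth


def matrix_from(values: dict, genes: list[str]) -> SignalMatrix:
    return SignalMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id")))


class TestNormalizeToGdna:
    def test_elementwise_division(self):
        sig = matrix_from({"exp1_rep1": [10.0, 6.0]}, ["a", "b"])
        gdna = matrix_from({"exp1_rep1": [2.0, 3.0]}, ["a", "b"])
        out, report = normalize_to_gdna(sig, gdna)
        np.testing.assert_allclose(out.values["exp1_rep1"], [5.0, 2.0])
        assert report.flagged_missing == {}

    def test_zero_gdna_flags_missing(self):
        sig = matrix_from({"exp1_rep1": [10.0, 6.0]}, ["a", "b"])
        gdna = matrix_from({"exp1_rep1": [0.0, 3.0]}, ["a", "b"])
        out, report = normalize_to_gdna(sig, gdna)
        assert np.isnan(out.values.loc["a", "exp1_rep1"])
        assert report.flagged_missing == {"a": 1}

    def test_constant_gdna_preserves_ranks(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(20, 2))
        genes = [f"g{i}" for i in range(20)]
        sig = matrix_from({"exp1_rep1": vals[:, 0], "exp1_rep2": vals[:, 1]}, genes)
        gdna = matrix_from({"exp1_rep1": np.full(20, 4.0),
                            "exp1_rep2": np.full(20, 4.0)}, genes)
        out, _ = normalize_to_gdna(sig, gdna)
        for col in sig.array_ids:
            assert (out.values[col].rank() == sig.values[col].rank()).all()

    def test_noise_free_long_genes_recover_density_times_extension(self, constants):
        """After gDNA normalization a >=3 kb gene reads d_per_nt * delta exactly."""
        cat = make_catalog([4000, 6000, 9000])
        truth = make_truth(cat, density_per_kb=np.array([0.3, 0.9, 1.5]),
                           constants=constants)
        cfg = SimulationConfig(n_genes=3, seed=2, noise_cv=0.0, array_scale_cv=0.0,
                               missing_rate=0.0, n_experiments=1, reps_per_experiment=1)
        gro = simulate_gro_arrays(truth, cat, cfg)
        gdna = simulate_gdna_reference(cat, cfg)
        out, _ = normalize_to_gdna(gro, gdna)
        expected = truth["true_density"].to_numpy() / 1000.0 * cfg.runon_extension_nt
        np.testing.assert_allclose(out.values["exp1_rep1"], expected, rtol=1e-9)


class TestScaleArrays:
    def test_unit_median_after_scaling(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(31)]
        mat = matrix_from({"exp1_rep1": rng.lognormal(size=31),
                           "exp2_rep1": rng.lognormal(size=31)}, genes)
        out = scale_arrays(mat)
        np.testing.assert_allclose(out.values.median(axis=0), 1.0)

    def test_proportional_arrays_collapse(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        mat = matrix_from({"exp1_rep1": base, "exp2_rep1": 3 * base},
                          ["a", "b", "c", "d"])
        out = scale_arrays(mat)
        np.testing.assert_allclose(out.values["exp1_rep1"], out.values["exp2_rep1"])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(size=(15, 3))
        genes = [f"g{i}" for i in range(15)]
        mat = matrix_from({f"exp{j}_rep1": vals[:, j] for j in range(3)}, genes)
        once = scale_arrays(mat)
        twice = scale_arrays(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_unusable_array_named_in_error(self):
        mat = matrix_from({"exp1_rep1": [1.0, 2.0], "exp2_rep1": [np.nan, np.nan]},
                          ["a", "b"])
        with pytest.raises(ValueError, match="no genes measured in all arrays"):
            scale_arrays(mat)


class TestFilterGenes:
    def _matrix(self, present_experiments: int) -> SignalMatrix:
        cols = {}
        for e in range(1, 9):
            for r in (1, 2, 3):
                value = 1.0 if e <= present_experiments else np.nan
                cols[f"exp{e}_rep{r}"] = [value, 2.0]
        return matrix_from(cols, ["sparse", "full"])

    def test_gene_in_all_experiments_kept(self):
        out, report = filter_genes(self._matrix(8), min_valid=5)
        assert "sparse" in report.kept_gene_ids

    def test_boundary_four_of_eight_dropped(self):
        out, report = filter_genes(self._matrix(4), min_valid=5)
        assert report.dropped_gene_ids == {"sparse": REASON_INSUFFICIENT}
        assert out.gene_ids == ["full"]

    def test_disabled_filter_keeps_everything(self):
        out, report = filter_genes(self._matrix(0), min_valid=0)
        assert report.dropped_gene_ids == {}

    def test_min_valid_above_experiment_count(self):
        with pytest.raises(ValueError):
            filter_genes(self._matrix(8), min_valid=9)

    def test_partition_is_exact(self):
        mat = self._matrix(4)
        _, report = filter_genes(mat, min_valid=5)
        assert set(report.kept_gene_ids) | set(report.dropped_gene_ids) == set(mat.gene_ids)
        assert set(report.kept_gene_ids) & set(report.dropped_gene_ids) == set()


class TestQcExperiments:
    def test_duplicate_experiments_all_kept(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(size=40)
        genes = [f"g{i}" for i in range(40)]
        mat = matrix_from({f"exp{e}_rep1": base for e in range(1, 4)}, genes)
        report = qc_experiments(mat)
        assert report.kept_experiment_ids == ["exp1", "exp2", "exp3"]
        np.testing.assert_allclose(report.pearson.to_numpy(), 1.0)

    def test_outlier_experiment_dropped(self):
        rng = np.random.default_rng(42)
        n = 2000
        signal = rng.normal(size=n)
        genes = [f"g{i}" for i in range(n)]
        cols = {}
        for e in range(1, 5):
            cols[f"exp{e}_rep1"] = np.exp2(signal + rng.normal(scale=0.33, size=n))
        cols["exp5_rep1"] = np.exp2(rng.normal(size=n))  # independent noise
        report = qc_experiments(matrix_from(cols, genes), min_pearson=0.7)
        assert "exp5" not in report.kept_experiment_ids
        assert set(report.kept_experiment_ids) == {"exp1", "exp2", "exp3", "exp4"}

    def test_disabled_threshold_keeps_all(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        cols = {f"exp{e}_rep1": rng.lognormal(size=30) for e in range(1, 4)}
        report = qc_experiments(matrix_from(cols, genes), min_pearson=-1)
        assert len(report.kept_experiment_ids) == 3

    def test_single_experiment_rejected(self):
        mat = matrix_from({"exp1_rep1": [1.0, 2.0, 3.0]}, ["a", "b", "c"])
        with pytest.raises(ValueError):
            qc_experiments(mat)


class TestAverageExperiments:
    def test_two_stage_hand_computation(self):
        # replicates (2, 4) in exp1 and (6) in exp2 -> (3 + 6) / 2 = 4.5
        mat = matrix_from({"exp1_rep1": [2.0], "exp1_rep2": [4.0],
                           "exp2_rep1": [6.0]}, ["a"])
        from nascentrates.preprocess import QCReport

        avg = average_experiments(mat, QCReport(kept_experiment_ids=["exp1", "exp2"]))
        assert avg["a"] == pytest.approx(4.5)

    def test_identity_for_single_replicate(self):
        from nascentrates.preprocess import QCReport

        mat = matrix_from({"exp1_rep1": [1.5, 2.5]}, ["a", "b"])
        avg = average_experiments(mat, QCReport(kept_experiment_ids=["exp1"]))
        np.testing.assert_allclose(avg, [1.5, 2.5])

    def test_balanced_design_equals_flat_mean(self):
        from nascentrates.preprocess import QCReport

        rng = np.random.default_rng(4)
        vals = rng.lognormal(size=(10, 6))
        genes = [f"g{i}" for i in range(10)]
        cols = {f"exp{e}_rep{r}": vals[:, 2 * (e - 1) + (r - 1)]
                for e in (1, 2, 3) for r in (1, 2)}
        mat = matrix_from(cols, genes)
        avg = average_experiments(mat, QCReport(kept_experiment_ids=["exp1", "exp2", "exp3"]))
        np.testing.assert_allclose(avg, vals.mean(axis=1))

    def test_average_tracks_expected_signal(self, constants):
        """Full preprocessing of a noisy 24-array study ranks genes correctly."""
        from scipy.stats import spearmanr

        cfg = SimulationConfig(n_genes=5000, seed=9, noise_cv=0.2)
        cat = generate_gene_catalog(5000, 9)
        truth = generate_true_kinetics(cat, constants, cfg)
        gro = simulate_gro_arrays(truth, cat, cfg)
        gdna = simulate_gdna_reference(cat, cfg)
        norm, _ = normalize_to_gdna(gro, gdna)
        avg, report = preprocess_signal(norm)
        expected = expected_gro_signal(cat, truth["true_density"].to_numpy(),
                                       cfg.runon_extension_nt)
        exp_series = pd.Series(expected, index=cat["gene_id"]).loc[avg.index]
        probe_len = (cat.set_index("gene_id")["probe_end_bp"]
                     - cat.set_index("gene_id")["probe_start_bp"]).loc[avg.index]
        rho, _ = spearmanr(avg, exp_series / probe_len)
        assert rho >= 0.95


class TestPermutationEquivariance:
    def test_gene_order_does_not_matter(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(25)]
        sig = matrix_from({"exp1_rep1": rng.lognormal(size=25),
                           "exp2_rep1": rng.lognormal(size=25)}, genes)
        gdna = matrix_from({"exp1_rep1": rng.lognormal(size=25) + 0.5,
                            "exp2_rep1": rng.lognormal(size=25) + 0.5}, genes)
        out1, _ = normalize_to_gdna(sig, gdna)
        out1 = scale_arrays(out1)
        perm = rng.permutation(25)
        sig_p = SignalMatrix(sig.values.iloc[perm])
        gdna_p = SignalMatrix(gdna.values.iloc[perm])
        out2, _ = normalize_to_gdna(sig_p, gdna_p)
        out2 = scale_arrays(out2)
        pd.testing.assert_frame_equal(out2.values.sort_index(), out1.values.sort_index())
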