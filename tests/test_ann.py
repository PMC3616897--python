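"""Linear feed-forward network calibration and its LM training loop."""

import numpy as np
import pytest

from triquant.ann import (
    AnnHyper,
    AnnModel,
    CalibrationDataset,
    mean_center,
    predict,
    rmsep,
    train,
)
from triquant.design import TRAINING, VALIDATION, split, table1_design
from triquant.simulate import NoiseModel, default_library, make_dataset


def _dataset(library, sd=0.0, seed=0):
    design = split(table1_design(), n_train=16)
    noise = NoiseModel(sd_au=sd, seed=seed) if sd > 0 else None
    spectra, conc = make_dataset(design, library, noise=noise)
    return CalibrationDataset.from_spectra(spectra, conc, design.partition)


@pytest.fixture(scope="module")
def noiseless(library):
    return _dataset(library)


@pytest.fixture(scope="module")
def noiseless_model(noiseless):
    return train(noiseless, seed=1)


class TestDatasetAndCentering:
    def test_window_gives_110_inputs(self, noiseless):
        assert noiseless.spectra_matrix.shape == (25, 110)
        assert noiseless.wavelengths_nm[0] == 230.0
        assert noiseless.wavelengths_nm[-1] == 339.0

    def test_centered_training_columns_have_zero_mean(self, noiseless):
        centered, _, _ = mean_center(noiseless)
        tr = centered.mask(TRAINING)
        np.testing.assert_allclose(centered.spectra_matrix[tr].mean(axis=0),
                                   0.0, atol=1e-12)
        np.testing.assert_allclose(centered.targets[tr].mean(axis=0),
                                   0.0, atol=1e-12)

    def test_centering_then_uncentering_is_identity(self, noiseless):
        centered, xc, yc = mean_center(noiseless)
        np.testing.assert_allclose(centered.spectra_matrix + xc,
                                   noiseless.spectra_matrix, atol=1e-12)
        np.testing.assert_allclose(centered.targets + yc,
                                   noiseless.targets, atol=1e-12)

    def test_validation_rows_use_training_means_only(self):
        """Centering a 2+2-row toy set must subtract the training means
        from the validation rows, not their own means."""
        x = np.array([[1.0, 2.0], [3.0, 4.0], [10.0, 20.0], [30.0, 40.0]])
        y = np.array([[1.0], [3.0], [10.0], [30.0]])
        part = np.array([TRAINING, TRAINING, VALIDATION, VALIDATION],
                        dtype=object)
        ds = CalibrationDataset(x, y, part, np.array([0.0, 1.0]), ("A",))
        centered, xc, yc = mean_center(ds)
        np.testing.assert_allclose(xc, [2.0, 3.0])
        np.testing.assert_allclose(centered.spectra_matrix[2], [8.0, 17.0])
        np.testing.assert_allclose(centered.targets[2], [8.0])


class TestRmsep:
    def test_zero_for_perfect_prediction(self):
        x = np.arange(12.0).reshape(4, 3)
        overall, per = rmsep(x, x)
        assert overall == 0.0 and np.all(per == 0.0)

    def test_plus_minus_one_errors_give_one(self):
        overall, _ = rmsep(np.array([[1.0], [-1.0]]), np.array([[0.0], [0.0]]))
        assert overall == 1.0

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        p, a = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        overall, per = rmsep(p, a)
        acc = 0.0
        for i in range(9):
            for j in range(3):
                acc += (p[i, j] - a[i, j]) ** 2
        assert overall == pytest.approx(np.sqrt(acc / 27), rel=1e-12)
        for j in range(3):
            col = sum((p[i, j] - a[i, j]) ** 2 for i in range(9))
            assert per[j] == pytest.approx(np.sqrt(col / 9), rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rmsep(np.empty((0, 3)), np.empty((0, 3)))


class TestTraining:
    def test_noiseless_training_converges_to_exact_fit(self, noiseless,
                                                       noiseless_model):
        tr = noiseless.mask(TRAINING)
        overall, _ = rmsep(noiseless_model.predict(noiseless.spectra_matrix[tr]),
                           noiseless.targets[tr])
        assert overall <= 1e-6

    def test_training_samples_predict_their_own_targets(self, noiseless,
                                                        noiseless_model):
        tr = noiseless.mask(TRAINING)
        np.testing.assert_allclose(
            noiseless_model.predict(noiseless.spectra_matrix[tr]),
            noiseless.targets[tr], atol=1e-6)

    def test_matches_least_squares_oracle(self, library):
        """With linear transfers the converged network is an affine map;
        its predictions must match multivariate OLS (normal equations /
        pseudoinverse) on the same centered data to 1e-4 ug/mL.  With
        fewer training samples than wavelengths the least-squares fit is
        only determined on the span of the training inputs, so noiseless
        data (which lies in the three-component span everywhere) is
        compared on all rows and noisy data on the training rows."""
        converged = AnnHyper(early_stopping=False, max_iter=500)
        for sd, seed in ((0.0, 3), (0.002, 9), (0.002, 21)):
            ds = _dataset(library, sd=sd, seed=seed)
            model = train(ds, hyper=converged, seed=seed)
            centered, _, yc = mean_center(ds)
            tr = ds.mask(TRAINING)
            w = np.linalg.pinv(centered.spectra_matrix[tr]) @ centered.targets[tr]
            mask = slice(None) if sd == 0.0 else tr
            ols = centered.spectra_matrix[mask] @ w + yc
            ann = model.predict(ds.spectra_matrix[mask])
            assert np.abs(ann - ols).max() < 1e-4

    def test_early_stopping_returns_best_validation_iterate(self, library):
        ds = _dataset(library, sd=0.002, seed=21)
        model = train(ds, seed=21)
        trace = model.trace["val_rmsep"]
        va = ds.mask(VALIDATION)
        returned, _ = rmsep(model.predict(ds.spectra_matrix[va]),
                            ds.targets[va])
        assert returned <= min(trace) * (1 + 1e-9)
        assert returned <= trace[-1] * (1 + 1e-9)

    def test_seed_determinism(self, library):
        ds = _dataset(library, sd=0.002, seed=4)
        m1, m2 = train(ds, seed=13), train(ds, seed=13)
        assert np.array_equal(m1.w_in, m2.w_in)
        assert np.array_equal(m1.w_out, m2.w_out)
        np.testing.assert_array_equal(m1.predict(ds.spectra_matrix),
                                      m2.predict(ds.spectra_matrix))

    def test_empty_partition_rejected(self, noiseless):
        bad = CalibrationDataset(noiseless.spectra_matrix, noiseless.targets,
                                 np.array([TRAINING] * 25, dtype=object),
                                 noiseless.wavelengths_nm, noiseless.analytes)
        with pytest.raises(ValueError):
            train(bad)

    def test_validation_recovery_monte_carlo(self, library):
        """16/9 split at sd 0.002 over 50 seeds: mean validation recovery
        per analyte must stay within 98-103%."""
        sums = None
        count = 0
        for seed in range(50):
            ds = _dataset(library, sd=0.002, seed=seed)
            model = train(ds, seed=seed)
            va = ds.mask(VALIDATION)
            rec = 100.0 * model.predict(ds.spectra_matrix[va]) / ds.targets[va]
            sums = rec.sum(axis=0) if sums is None else sums + rec.sum(axis=0)
            count += rec.shape[0]
        means = sums / count
        for analyte, mean in zip(ds.analytes, means):
            assert 98.0 < mean < 103.0, analyte

    def test_predicted_vs_true_regression_on_validation(self, library):
        """Predicted-against-known regression on the nine validation
        mixtures: slope near 1 and r above 0.999."""
        from scipy import stats
        ds = _dataset(library, sd=0.002, seed=77)
        model = train(ds, seed=77)
        va = ds.mask(VALIDATION)
        pred = model.predict(ds.spectra_matrix[va])
        for j, analyte in enumerate(ds.analytes):
            fit = stats.linregress(ds.targets[va][:, j], pred[:, j])
            assert 0.97 < fit.slope < 1.03, analyte
            assert fit.rvalue >= 0.999, analyte


class TestPredictAndPersistence:
    def test_zero_centered_input_maps_through_biases(self, noiseless_model):
        x = noiseless_model.x_center[None, :]
        expected = (noiseless_model.b_hidden @ noiseless_model.w_out
                    + noiseless_model.b_out + noiseless_model.y_center)
        np.testing.assert_allclose(predict(noiseless_model, x)[0], expected,
                                   atol=1e-12)

    def test_window_mismatch_rejected(self, noiseless_model):
        with pytest.raises(ValueError):
            predict(noiseless_model, np.zeros((1, 50)))

    def test_predict_does_not_mutate_model(self, noiseless, noiseless_model):
        before = noiseless_model.w_in.copy()
        predict(noiseless_model, noiseless.spectra_matrix)
        assert np.array_equal(noiseless_model.w_in, before)

    def test_json_round_trip(self, tmp_path, noiseless, noiseless_model):
        path = tmp_path / "model.json"
        noiseless_model.save(path)
        back = AnnModel.load(path)
        np.testing.assert_allclose(back.predict(noiseless.spectra_matrix),
                                   noiseless_model.predict(noiseless.spectra_matrix),
                                   atol=1e-12)
        assert back.hyper == noiseless_model.hyper

    def test_architecture_matches_110_10_3(self, noiseless_model):
        assert noiseless_model.w_in.shape == (110, 10)
        assert noiseless_model.w_out.shape == (10, 3)


class TestHyper:
    @pytest.mark.parametrize("kwargs", [
        {"hidden_units": 0}, {"lc": 0.0}, {"lci": 0.5},
        {"hidden_transfer": "relu"},
    ])
    def test_invalid_hyper_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnnHyper(**kwargs)

    def test_tansig_hidden_transfer_trains(self, library):
        """The optional nonlinear hidden transfer still fits the linear
        data acceptably (it contains the linear regime)."""
        ds = _dataset(library)
        model = train(ds, hyper=AnnHyper(hidden_transfer="tansig",
                                         init_scale=0.01), seed=2)
        tr = ds.mask(TRAINING)
        overall, _ = rmsep(model.predict(ds.spectra_matrix[tr]), ds.targets[tr])
        assert overall < 0.5
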