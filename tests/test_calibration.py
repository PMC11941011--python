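"""Variable matrix, correction/transform fits, PCA basis and reconstruction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import savehsi as sh
from savehsi.calibration import (
    TERM_LABELS_ORDER3,
    reconstruct_spectra,
)
from savehsi.colorimetry import ContractError
from tests.conftest import build_rig


class TestVariableMatrix:
    def test_zero_rgb_leaves_only_constant(self):
        v = sh.build_variable_matrix([(0.0, 0.0, 0.0)], order=3)
        assert v.matrix[:-1].sum() == 0.0
        assert v.matrix[-1, 0] == 1.0

    def test_pure_red_activates_red_powers_only(self):
        v = sh.build_variable_matrix([(1.0, 0.0, 0.0)], order=3)
        active = {t for t, val in zip(v.terms, v.matrix[:, 0]) if val != 0.0}
        assert active == {"R", "R2", "R3", "1"}

    def test_term_count_matches_monomial_enumeration(self):
        # brute-force: all monomials of degree <= 3 in 3 variables
        count = sum(
            1
            for i, j, k in itertools.product(range(4), repeat=3)
            if 1 <= i + j + k <= 3
        )
        v = sh.build_variable_matrix([(0.2, 0.3, 0.4)], order=3)
        assert len(v.terms) == count + 1 == 20  # + constant dark term
        assert v.terms == TERM_LABELS_ORDER3

    def test_rows_match_independent_monomial_evaluation(self):
        rng = np.random.default_rng(0)
        rgb = rng.uniform(0, 1.3, (5, 3))
        v = sh.build_variable_matrix(rgb, order=3)
        powers = {  # label -> exponents of (R, G, B)
            "R": (1, 0, 0), "G": (0, 1, 0), "B": (0, 0, 1),
            "R2": (2, 0, 0), "G2": (0, 2, 0), "B2": (0, 0, 2),
            "RG": (1, 1, 0), "GB": (0, 1, 1), "RB": (1, 0, 1),
            "R3": (3, 0, 0), "G3": (0, 3, 0), "B3": (0, 0, 3),
            "R2G": (2, 1, 0), "R2B": (2, 0, 1), "G2R": (1, 2, 0),
            "G2B": (0, 2, 1), "B2R": (1, 0, 2), "B2G": (0, 1, 2),
            "RGB": (1, 1, 1), "1": (0, 0, 0),
        }
        for row, label in enumerate(v.terms):
            i, j, k = powers[label]
            expected = rgb[:, 0] ** i * rgb[:, 1] ** j * rgb[:, 2] ** k
            assert np.allclose(v.matrix[row], expected)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1.3), min_size=3, max_size=3))
    def test_first_order_rows_equal_raw_rgb(self, rgb):
        v = sh.build_variable_matrix([tuple(rgb)], order=3)
        assert np.allclose(v.matrix[:3, 0], rgb)

    def test_invalid_order_rejected(self):
        with pytest.raises(ContractError):
            sh.build_variable_matrix([(0.1, 0.2, 0.3)], order=4)


class TestCorrectionMatrix:
    def test_exact_linear_camera_is_reproduced(self):
        rng = np.random.default_rng(1)
        rgb = rng.uniform(0.05, 0.95, (24, 3))
        A = rng.uniform(0, 1, (3, 3))
        xyz = rgb @ A.T
        v = sh.build_variable_matrix(rgb, order=3)
        c = sh.fit_correction_matrix(xyz, v)
        assert np.max(np.abs(sh.apply_correction(c, v) - xyz)) < 1e-8

    def test_duplicated_patches_give_identical_fit(self):
        rng = np.random.default_rng(2)
        rgb = rng.uniform(0.05, 0.95, (24, 3))
        xyz = rng.uniform(5, 95, (24, 3))
        v24 = sh.build_variable_matrix(rgb, order=3)
        v48 = sh.build_variable_matrix(np.vstack([rgb, rgb]), order=3)
        c24 = sh.fit_correction_matrix(xyz, v24)
        c48 = sh.fit_correction_matrix(np.vstack([xyz, xyz]), v48)
        assert np.allclose(c24.matrix, c48.matrix, atol=1e-9)

    def test_ground_truth_recovery(self):
        # XYZ generated exactly by a random C*; enough independent columns
        rng = np.random.default_rng(3)
        rgb = rng.uniform(0, 1, (60, 3))
        v = sh.build_variable_matrix(rgb, order=3)
        c_star = rng.normal(size=(3, 20))
        xyz = (c_star @ v.matrix).T
        c = sh.fit_correction_matrix(xyz, v)
        assert np.max(np.abs(c.matrix - c_star)) < 1e-6

    def test_apply_correction_oracle_and_contracts(self):
        rng = np.random.default_rng(4)
        v = sh.build_variable_matrix(rng.uniform(0, 1, (5, 3)), order=2)
        C = rng.normal(size=(3, len(v.terms)))
        out = sh.apply_correction(sh.CorrectionMatrix(C), v)
        # naive triple loop
        expected = np.zeros((5, 3))
        for s in range(5):
            for i in range(3):
                for t in range(len(v.terms)):
                    expected[s, i] += C[i, t] * v.matrix[t, s]
        assert np.allclose(out, expected, atol=1e-12)
        assert np.all(sh.apply_correction(sh.CorrectionMatrix(np.zeros_like(C)), v) == 0)
        with pytest.raises(ContractError):
            sh.apply_correction(sh.CorrectionMatrix(np.zeros((3, 7))), v)


class TestPCABasis:
    def test_rank_six_data_fully_explained(self, grid):
        rng = np.random.default_rng(5)
        loadings, _ = np.linalg.qr(rng.normal(size=(grid.n_bands, 6)))
        scores = rng.normal(scale=0.05, size=(24, 6))
        spectra = np.clip(0.5 + scores @ loadings.T, 0, 1)
        basis = sh.fit_pca_basis(spectra, grid, n_components=6)
        assert basis.explained_fraction == pytest.approx(1.0, abs=1e-9)
        recon = basis.reconstruct(basis.scores(spectra))
        assert np.max(np.abs(recon - spectra)) < 1e-9

    def test_components_orthonormal(self, checker, grid):
        basis = sh.fit_pca_basis(checker.reflectances, grid, 6)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)

    def test_eigenvalues_match_gram_matrix_oracle(self, checker, grid):
        X = checker.reflectances
        Xc = X - X.mean(axis=0)
        gram_eigs = np.sort(np.linalg.eigvalsh(Xc @ Xc.T / (X.shape[0] - 1)))[::-1]
        basis = sh.fit_pca_basis(X, grid, 6)
        assert np.allclose(basis.eigenvalues, gram_eigs[:6], rtol=1e-8)

    def test_explained_fraction_nondecreasing_and_full_rank_exact(self, checker, grid):
        fracs = [
            sh.fit_pca_basis(checker.reflectances, grid, k).explained_fraction
            for k in range(1, 12)
        ]
        assert np.all(np.diff(fracs) >= -1e-12)
        basis23 = sh.fit_pca_basis(checker.reflectances, grid, 23)
        recon = basis23.reconstruct(basis23.scores(checker.reflectances))
        assert np.max(np.abs(recon - checker.reflectances)) < 1e-8

    def test_too_few_spectra_rejected(self, grid):
        with pytest.raises(ContractError):
            sh.fit_pca_basis(np.ones((5, grid.n_bands)) * 0.5, grid, n_components=6)


class TestTransformMatrix:
    def _rig_linear_scores(self, grid, seed=6):
        # model-class data: scores an exactly linear function of V terms
        rng = np.random.default_rng(seed)
        rgb = rng.uniform(0.05, 0.95, (24, 3))
        v = sh.build_variable_matrix(rgb, order=3)
        m_star = rng.normal(scale=0.05, size=(6, 20))
        scores = m_star @ v.matrix
        return rgb, v, m_star, scores

    def test_ground_truth_recovery(self, grid):
        rng = np.random.default_rng(7)
        rgb = rng.uniform(0, 1, (60, 3))
        v = sh.build_variable_matrix(rgb, order=3)
        m_star = rng.normal(size=(6, 20))
        m = sh.fit_transform_matrix(m_star @ v.matrix, v)
        assert np.max(np.abs(m.matrix - m_star)) < 1e-6

    def test_zero_scores_give_zero_matrix(self, grid):
        _, v, _, _ = self._rig_linear_scores(grid)
        m = sh.fit_transform_matrix(np.zeros((6, 24)), v)
        assert np.all(m.matrix == 0)

    def test_noiseless_model_class_reconstruction_is_exact(self, grid, checker):
        rgb, v, m_star, scores = self._rig_linear_scores(grid)
        basis = sh.fit_pca_basis(checker.reflectances, grid, 6)
        m = sh.fit_transform_matrix(scores, v)
        spectra_true = basis.reconstruct(scores)
        recon = reconstruct_spectra(m, basis, v)
        assert np.max(np.abs(recon - spectra_true)) < 1e-8


class TestReconstruction:
    def test_zero_transform_returns_mean_spectrum(self, checker, grid):
        basis = sh.fit_pca_basis(checker.reflectances, grid, 6)
        m = sh.TransformMatrix(np.zeros((6, 20)))
        v = sh.build_variable_matrix([(0.3, 0.4, 0.5)], order=3)
        spec = sh.reconstruct_spectrum(m, basis, v.matrix[:, 0])
        assert np.allclose(spec.values, np.clip(basis.mean_spectrum, 0, 1.2), atol=1e-12)

    def test_matches_termwise_expansion_oracle(self, checker, grid):
        rng = np.random.default_rng(8)
        basis = sh.fit_pca_basis(checker.reflectances, grid, 6)
        m = sh.TransformMatrix(rng.normal(scale=0.01, size=(6, 20)))
        v_col = sh.build_variable_matrix([(0.3, 0.6, 0.2)], order=3).matrix[:, 0]
        spec = sh.reconstruct_spectrum(m, basis, v_col)
        expected = basis.mean_spectrum.copy()
        for k in range(6):
            score_k = float(m.matrix[k] @ v_col)
            expected = expected + score_k * basis.components[k]
        assert np.allclose(spec.values, np.clip(expected, 0, 1.2), atol=1e-10)

    def test_order_monotonicity_of_in_sample_residual(self, grid, rig):
        model = rig["model"]
        resids = []
        for order in (1, 2, 3):
            res = model.fit(order=order)
            resids.append(res.fit_report["mean_rmse"])
        assert resids[2] <= resids[1] + 1e-12
        assert resids[1] <= resids[0] + 1e-12

    def test_noise_monotonicity_of_rmse_and_de00(self, grid):
        # seed-averaged: monotone in expectation, individual draws fluctuate
        seeds = range(90, 95)
        rmses, de00s = [], []
        for sigma in (0.0, 0.001, 0.005, 0.01):
            rs = [
                build_rig(grid, camera_noise=sigma, spectrometer_noise=sigma, seed=s)
                for s in seeds
            ]
            rmses.append(np.mean([r["rmse_vs_truth"].mean() for r in rs]))
            de00s.append(
                np.mean([r["results"].fit_report["mean_de00_reconstruction"] for r in rs])
            )
        assert np.all(np.diff(rmses) >= -1e-12)
        assert np.all(np.diff(de00s) >= -1e-12)

    def test_six_pc_span_loop_recovers_to_small_residual(self, grid, checker):
        # noiseless loop on spectra projected to the chart's own 6-PC span;
        # the RGB bottleneck leaves a small but nonzero residual
        basis = sh.fit_pca_basis(checker.reflectances, grid, 6)
        proj = np.clip(basis.reconstruct(basis.scores(checker.reflectances)), 0, 1)
        cam = sh.default_virtual_camera(grid, noise_sigma=0.0)
        cam.gamma, cam.dark_level = 1.0, 0.0
        rgb = sh.simulate_camera_capture(proj, cam)
        res = sh.SpectralCalibration(rgb, proj, grid).fit()
        recon = res.reconstruct(rgb)
        rmse = [sh.patch_rmse(r, t, grid=grid) for r, t in zip(recon, proj)]
        assert max(rmse) < 2e-2


class TestCubeConversion:
    def test_uniform_image_gives_constant_cube(self, rig, grid):
        res = rig["results"]
        color = rig["camera_rgb"][5]
        img = np.tile(color, (4, 4, 1))
        cube = res.convert_image(img)
        single = res.reconstruct(color[None])[0]
        assert np.allclose(cube.values, np.clip(single, -0.1, 1.3), atol=1e-12)

    def test_vectorization_matches_per_pixel_loop(self, rig, grid):
        res = rig["results"]
        rng = np.random.default_rng(9)
        img = rng.uniform(0.05, 0.9, (2, 2, 3))
        cube = res.convert_image(img)
        for i in range(2):
            for j in range(2):
                v = sh.build_variable_matrix(img[i, j][None], order=3)
                spec = sh.reconstruct_spectrum(res.transform, res.basis, v.matrix[:, 0])
                got = np.clip(cube.values[i, j], 0, 1.2)
                assert np.allclose(got, spec.values, atol=1e-10)

    def test_saturated_pixels_flagged_but_converted(self, rig):
        img = np.full((2, 2, 3), 0.5)
        img[0, 0] = (1.0, 0.5, 0.5)
        cube = rig["results"].convert_image(img)
        assert cube.saturation_mask[0, 0]
        assert not cube.saturation_mask[1, 1]
        assert np.all(np.isfinite(cube.values))


class TestPatchRMSE:
    def test_identical_and_offset(self, grid):
        a = sh.Spectrum(grid, np.full(grid.n_bands, 0.5))
        b = sh.Spectrum(grid, np.full(grid.n_bands, 0.57))
        assert sh.patch_rmse(a, a) == 0.0
        assert sh.patch_rmse(a, b) == pytest.approx(0.07, abs=1e-12)

    def test_matches_elementwise_oracle(self, grid):
        rng = np.random.default_rng(10)
        a = rng.uniform(0, 1, grid.n_bands)
        b = rng.uniform(0, 1, grid.n_bands)
        mask = grid.window_mask(400, 700)
        expected = np.sqrt(np.mean((a[mask] - b[mask]) ** 2))
        assert sh.patch_rmse(a, b, grid=grid) == pytest.approx(expected, abs=1e-12)

    def test_window_is_configurable(self, grid):
        a = np.zeros(grid.n_bands)
        b = np.zeros(grid.n_bands)
        b[-1] = 1.0  # 780 nm, outside the default window
        assert sh.patch_rmse(a, b, grid=grid) == 0.0
        assert sh.patch_rmse(a, b, grid=grid, window=(380, 780)) > 0.0

    def test_grid_mismatch_rejected(self, grid):
        with pytest.raises(ContractError):
            sh.patch_rmse(np.zeros(grid.n_bands), np.zeros(10), grid=grid)


class TestBundlePersistence:
    def test_json_round_trip_preserves_predictions(self, rig, tmp_path):
        res = rig["results"]
        path = str(tmp_path / "bundle.json")
        res.save(path)
        loaded = sh.CalibrationResults.load(path)
        rgb = rig["camera_rgb"]
        assert np.allclose(loaded.reconstruct(rgb), res.reconstruct(rgb), atol=1e-12)
        assert np.allclose(loaded.correct_xyz(rgb), res.correct_xyz(rgb), atol=1e-12)
        assert loaded.grid == res.grid

    def test_summary_mentions_key_diagnostics(self, rig):
        text = rig["results"].summary()
        assert "RMSE" in text and "dE00" in text and "components" in text
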