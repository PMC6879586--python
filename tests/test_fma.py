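import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poreflux import fma, geometry, synthgen
from poreflux.fma import cross_validate, fit_pls_fma, interpolate_mode, pca_modes
from poreflux.synthgen import generate_fma_ensemble


def linear_ensemble(n_frames=200, n_atoms=12, seed=0, noise=0.0):
    """Frames of pure Gaussian coordinates with y exactly linear in them."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(n_frames, n_atoms, 3))
    w = rng.normal(size=3 * n_atoms)
    w /= np.linalg.norm(w)
    y = coords.reshape(n_frames, -1) @ w
    if noise:
        y = y + rng.normal(scale=noise, size=n_frames)
    return coords, y, w


def rank_one_ensemble(n_frames=200, n_atoms=12, seed=0):
    """One noise-free collective mode carries all variance; y = w^T x exactly.

    A single PLS component then reproduces the target exactly.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(size=3 * n_atoms)
    w /= np.linalg.norm(w)
    q = rng.standard_normal(n_frames)
    mean = rng.normal(size=3 * n_atoms)
    X = mean[None, :] + q[:, None] * w[None, :]
    y = X @ w
    return X.reshape(n_frames, n_atoms, 3), y, w


class TestFitPlsFma:
    def test_noiseless_linear_target_perfect_fit_one_component(self):
        coords, y, w = rank_one_ensemble(seed=1)
        mode = fit_pls_fma(coords, y, n_components=1, do_superpose=False)
        assert mode.r_train == pytest.approx(1.0, abs=1e-6)
        assert mode.r_valid == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_linear_target_full_rank(self):
        coords, y, _ = linear_ensemble(seed=1)
        mode = fit_pls_fma(coords, y, n_components=3 * 12, do_superpose=False)
        assert mode.r_train == pytest.approx(1.0, abs=1e-6)
        assert mode.r_valid == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_linear_ewmcm_parallel_to_cw(self):
        coords, y, w = linear_ensemble(seed=2)
        mode = fit_pls_fma(coords, y, n_components=3 * 12, do_superpose=False)
        X = coords.reshape(coords.shape[0], -1)
        half = coords.shape[0] // 2
        Xc = X[:half] - X[:half].mean(axis=0)
        cw = Xc.T @ (Xc @ w) / (half - 1)
        cosine = abs(cw @ mode.ewmcm) / np.linalg.norm(cw)
        assert cosine > 0.999

    def test_constant_target_rejected(self):
        coords, _, _ = linear_ensemble()
        with pytest.raises(ValueError):
            fit_pls_fma(coords, np.ones(coords.shape[0]), n_components=1)

    def test_components_reduced_to_rank_with_warning(self):
        coords, y, _ = linear_ensemble(n_frames=40, n_atoms=4)
        with pytest.warns(UserWarning):
            mode = fit_pls_fma(coords, y, n_components=50, do_superpose=False)
        assert mode.n_components <= 12

    def test_planted_mode_recovery_at_r2_092(self):
        r2 = 0.92
        snr = r2 / (1 - r2)
        rng = np.random.default_rng(5)
        planted = rng.normal(size=150)
        planted /= np.linalg.norm(planted)
        r_valids, cosines = [], []
        for seed in range(4):
            coords, target, info = generate_fma_ensemble(
                n_frames=2000, n_atoms=50, planted_mode=planted, snr=snr, seed=seed
            )
            mode = fit_pls_fma(coords, target, n_components=10, do_superpose=False)
            r_valids.append(mode.r_valid)
            cosines.append(abs(mode.ewmcm @ planted))
        assert np.mean(r_valids) == pytest.approx(np.sqrt(r2), abs=0.02)
        assert min(cosines) >= 0.95

    def test_rank_equivalence_with_least_squares_oracle(self):
        # with k = rank(X), PLS equals the ordinary least-squares fit
        rng = np.random.default_rng(7)
        n_frames, n_atoms = 200, 5  # 3M = 15 << frames -> full column rank
        coords = rng.normal(size=(n_frames, n_atoms, 3))
        y = rng.normal(size=n_frames)
        mode = fit_pls_fma(coords, y, n_components=15, do_superpose=False)
        half = n_frames // 2
        X = coords.reshape(n_frames, -1)
        Xc = X[:half] - X[:half].mean(axis=0)
        yc = y[:half] - y[:half].mean()
        beta_ols, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        assert np.allclose(mode.beta, beta_ols, atol=1e-8)

    def test_sign_convention_projection_increases_target(self):
        coords, y, _ = linear_ensemble(seed=9, noise=0.1)
        mode = fit_pls_fma(coords, y, n_components=5, do_superpose=False)
        X = coords.reshape(coords.shape[0], -1)
        proj = (X - mode.mean_structure.reshape(-1)) @ mode.ewmcm
        assert np.corrcoef(proj, y)[0, 1] > 0

    def test_rigid_motion_invariance_up_to_sign(self):
        # the mode is expressed in the superposed frame; align the mean
        # structures before comparing the vectors
        coords, y, _ = linear_ensemble(seed=11, noise=0.05)
        mode_a = fit_pls_fma(coords, y, n_components=5)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 1.0])
        mode_b = fit_pls_fma(moved, y, n_components=5)
        r_align, _ = geometry.kabsch(mode_b.mean_structure, mode_a.mean_structure)
        ew_b = (mode_b.ewmcm.reshape(-1, 3) @ r_align.T).reshape(-1)
        assert abs(abs(mode_a.ewmcm @ ew_b) - 1.0) < 1e-2
        assert mode_a.r_valid == pytest.approx(mode_b.r_valid, abs=1e-6)


class TestCrossValidate:
    def test_matches_fit_diagnostics(self):
        coords, y, _ = linear_ensemble(seed=3, noise=0.2)
        mode = fit_pls_fma(coords, y, n_components=5)
        r_train, r_valid = cross_validate(mode, coords, y)
        assert r_train == pytest.approx(mode.r_train, abs=1e-9)
        assert r_valid == pytest.approx(mode.r_valid, abs=1e-9)

    def test_null_target_small_validation_correlation(self):
        fails = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            coords = rng.normal(size=(400, 10, 3))
            y = rng.normal(size=400)
            mode = fit_pls_fma(coords, y, n_components=3, do_superpose=False)
            if abs(mode.r_valid) >= 3 / np.sqrt(200):
                fails += 1
        assert fails <= 3  # |r_valid| < 3/sqrt(n) with >=95% probability

    def test_overfitting_direction(self):
        bad = 0
        for seed in range(10):
            coords, target, _ = generate_fma_ensemble(
                n_frames=400, n_atoms=20,
                planted_mode=np.eye(60)[0], snr=3.0, seed=seed,
            )
            mode = fit_pls_fma(coords, target, n_components=10, do_superpose=False)
            if not mode.r_train >= mode.r_valid - 0.05:
                bad += 1
        assert bad == 0

    def test_too_few_frames(self):
        coords, y, _ = linear_ensemble(n_frames=12)
        with pytest.raises(ValueError):
            fit_pls_fma(coords, y, n_components=2)


class TestInterpolateMode:
    @pytest.fixture()
    def mode(self):
        coords, y, _ = linear_ensemble(seed=4, noise=0.1)
        return fit_pls_fma(coords, y, n_components=3, do_superpose=False)

    def test_two_structures_are_extremes(self, mode):
        out = interpolate_mode(mode, 2)
        flat = out.reshape(2, -1) - mode.mean_structure.reshape(-1)
        assert flat[0] @ mode.ewmcm == pytest.approx(mode.proj_min, abs=1e-9)
        assert flat[1] @ mode.ewmcm == pytest.approx(mode.proj_max, abs=1e-9)

    def test_three_structures_midpoint(self, mode):
        out = interpolate_mode(mode, 3)
        assert np.allclose(out[1], (out[0] + out[2]) / 2, atol=1e-12)

    def test_minimum_count(self, mode):
        with pytest.raises(ValueError):
            interpolate_mode(mode, 1)


class TestPcaModes:
    def test_planted_dominant_mode(self):
        rng = np.random.default_rng(0)
        planted = rng.normal(size=30)
        planted /= np.linalg.norm(planted)
        coords, _, _ = generate_fma_ensemble(
            n_frames=3000, n_atoms=10, planted_mode=planted, snr=10, seed=0,
            coord_noise=0.05,
        )
        modes, eigvals, _ = pca_modes(coords, n_modes=3, do_superpose=False)
        assert abs(modes[0] @ planted) >= 0.99
        assert np.all(np.diff(eigvals) <= 1e-12)

    def test_isotropic_noise_no_dominant_mode(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(4000, 6, 3))  # frames >> 3M = 18
        _, eigvals, _ = pca_modes(coords, n_modes=2, do_superpose=False)
        assert eigvals[0] / eigvals[1] < 1.5

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(300, 8, 3))
        _, eigvals, _ = pca_modes(coords, n_modes=5, do_superpose=False)
        X = coords.reshape(300, -1)
        total = np.sum(np.var(X, axis=0, ddof=1))
        assert eigvals.sum() == pytest.approx(total, rel=1e-9)

    def test_too_many_modes(self):
        coords = np.zeros((50, 4, 3))
        with pytest.raises(ValueError):
            pca_modes(coords, n_modes=13)


class TestChannelCoupling:
    def test_ewmcm_amplitude_on_planted_moving_atoms(self):
        # gate motion drives the filter spread; the mode must localise on
        # the atoms the generator actually moves with the opening
        spec = synthgen.SynthSpec(
            n_frames=1200, n_replicas=1, seed=23, gate_jitter=0.08,
            sigma_xyz=0.01, n_ions=0, n_cavity_waters=0, n_site_waters=0,
        )
        ens, ann, _ = synthgen.generate_ensemble(spec)
        target = geometry.cross_distance_series(ens, ann, "T_CA", "opposite")
        mode = fit_pls_fma(ens, target, n_components=10)
        coords = ens.replicas[0].coords
        moving = np.flatnonzero(coords.std(axis=0).max(axis=1) > 0.02)
        amp = mode.ewmcm.reshape(-1, 3)
        frac = np.sum(amp[moving] ** 2) / np.sum(amp**2)
        assert frac >= 0.70
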