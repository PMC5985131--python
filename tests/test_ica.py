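"""Unit and property tests for centring, whitening and the FastICA core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fetalica import (
    IcaConfig,
    MultichannelRecording,
    RankDeficiencyError,
    ValidationError,
    amari_index,
    center,
    contrast_g,
    conventional_update,
    extract_all,
    extract_component,
    improved_update,
    residual_and_jacobian,
    select_overrelaxation,
    whiten,
)


def angular_distance(u, v):
    """Sign-invariant angle between unit vectors."""
    return np.arccos(min(1.0, abs(float(u @ v))))


# ---------------------------------------------------------------------------
# centring
# ---------------------------------------------------------------------------


class TestCenter:
    def test_small_example(self):
        centered, mean = center(np.array([[1.0, 3.0], [2.0, 2.0]]))
        np.testing.assert_allclose(centered, [[-1.0, 1.0], [0.0, 0.0]])
        np.testing.assert_allclose(mean, [2.0, 2.0])

    def test_zero_matrix_unchanged(self):
        centered, mean = center(np.zeros((3, 10)))
        assert np.all(centered == 0) and np.all(mean == 0)

    def test_row_means_vanish(self):
        rng = np.random.default_rng(0)
        centered, _ = center(rng.normal(5.0, 2.0, size=(4, 10_000)))
        assert np.abs(centered.mean(axis=1)).max() < 1e-10

    def test_rejects_non_finite(self):
        bad = np.ones((2, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError):
            center(bad)

    def test_accepts_recording(self):
        rec = MultichannelRecording(np.arange(12.0).reshape(2, 6), fs=10.0)
        centered, mean = center(rec)
        assert np.abs(centered.mean(axis=1)).max() < 1e-12


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------


def sample_cov(z):
    return z @ z.T / z.shape[1]


class TestWhiten:
    def test_already_white_input(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 50_000))
        x -= x.mean(axis=1, keepdims=True)
        # orthogonalize exactly so the sample covariance is I
        x = np.linalg.solve(np.linalg.cholesky(sample_cov(x)), x)
        z, model = whiten(x)
        np.testing.assert_allclose(sample_cov(z), np.eye(3), atol=1e-6)
        np.testing.assert_allclose(
            model.transform @ model.transform.T, np.eye(3), atol=1e-5
        )

    def test_correlated_gaussian(self):
        rng = np.random.default_rng(2)
        a = np.array([[2.0, 0.5], [0.3, 1.0]])
        x = a @ rng.standard_normal((2, 20_000))
        xc, _ = center(x)
        z, model = whiten(xc)
        np.testing.assert_allclose(sample_cov(z), np.eye(2), atol=1e-6)
        assert np.allclose(model.E.T @ model.E, np.eye(2), atol=1e-8)
        assert np.all(model.D > 0)

    def test_duplicated_channel_raises(self):
        rng = np.random.default_rng(3)
        row = rng.standard_normal(1000)
        x = np.vstack([row, row, rng.standard_normal(1000)])
        xc, _ = center(x)
        with pytest.raises(RankDeficiencyError):
            whiten(xc)

    def test_requires_zero_mean(self):
        with pytest.raises(ValidationError):
            whiten(np.random.default_rng(4).normal(5.0, 1.0, (2, 100)))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_whitening_contract(self, seed):
        """cov(Z) = I for any full-rank input."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 5))
        a = rng.normal(size=(d, d)) + d * np.eye(d)
        x = a @ rng.laplace(size=(d, 500))
        xc, _ = center(x)
        z, _ = whiten(xc)
        np.testing.assert_allclose(sample_cov(z), np.eye(d), atol=1e-6)


# ---------------------------------------------------------------------------
# contrast and residual
# ---------------------------------------------------------------------------


class TestContrast:
    @pytest.mark.parametrize(
        "u, g, gp",
        [(2.0, 8.0, 12.0), (0.0, 0.0, 0.0)],
    )
    def test_scalar_values(self, u, g, gp):
        got_g, got_gp = contrast_g(np.array([u]))
        assert got_g[0] == g and got_gp[0] == gp

    def test_symmetry(self):
        g, gp = contrast_g(np.array([-1.0, 1.0]))
        np.testing.assert_allclose(g, [-1.0, 1.0])
        np.testing.assert_allclose(gp, [3.0, 3.0])


class TestResidual:
    def test_residual_orthogonal_to_w(self):
        rng = np.random.default_rng(5)
        z = rng.laplace(size=(3, 5000))
        xc, _ = center(z)
        z, _ = whiten(xc)
        w = rng.standard_normal(3)
        w /= np.linalg.norm(w)
        f, _ = residual_and_jacobian(w, z)
        assert abs(float(f @ w)) < 1e-8

    def test_gaussian_residual_small(self):
        # a Gaussian has no negentropy structure: F ~ sampling noise only
        rng = np.random.default_rng(6)
        n = 1_000_000
        z = rng.standard_normal((2, n))
        xc, _ = center(z)
        z, _ = whiten(xc)
        w = np.array([0.6, 0.8])
        f, _ = residual_and_jacobian(w, z)
        assert np.linalg.norm(f) < 5.0 / np.sqrt(n)

    def test_brute_force_two_sample_oracle(self):
        z = np.array([[1.0, -1.0], [1.0, 1.0]]) / np.sqrt(1.0)
        w = np.array([1.0, 0.0])
        # hand-expanded sums, one column at a time
        n = z.shape[1]
        s = [w @ z[:, t] for t in range(n)]
        beta = sum(si * si**3 for si in s) / n
        f_expected = (
            sum(z[:, t] * s[t] ** 3 for t in range(n)) / n - beta * w
        )
        jf_expected = sum(3 * si**2 for si in s) / n - beta
        f, jf = residual_and_jacobian(w, z)
        np.testing.assert_allclose(f, f_expected, atol=1e-12)
        assert jf == pytest.approx(jf_expected, abs=1e-12)


# ---------------------------------------------------------------------------
# updates
# ---------------------------------------------------------------------------


class TestConventionalUpdate:
    def test_output_unit_norm(self, uniform_mixture):
        z, _ = uniform_mixture
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = rng.standard_normal(2)
            w /= np.linalg.norm(w)
            assert np.linalg.norm(conventional_update(w, z)) == pytest.approx(1.0)

    def test_true_direction_is_fixed_point(self, uniform_mixture):
        # the empirical fixed point deviates from the population one by
        # O(1/sqrt(n)); at n = 2e5 an angular step below 5e-3 means the
        # true unmixing direction is stationary up to sampling noise
        z, directions = uniform_mixture
        for i in range(2):
            w = directions[:, i]
            w_next = conventional_update(w, z)
            assert angular_distance(w_next, w) < 5e-3

    def test_repeated_application_converges(self, uniform_mixture):
        z, _ = uniform_mixture
        w = np.random.default_rng(8).standard_normal(2)
        w /= np.linalg.norm(w)
        inner = 0.0
        for _ in range(200):
            w_next = conventional_update(w, z)
            inner = abs(float(w_next @ w))
            w = w_next
            if 1.0 - inner < 1e-10:
                break
        assert 1.0 - inner < 1e-10


class TestSelectOverrelaxation:
    def test_grid_is_1_01_to_1_99(self, uniform_mixture):
        """N=100 candidates are exactly {1.01, ..., 1.99}."""
        z, _ = uniform_mixture
        rng = np.random.default_rng(9)
        w = rng.standard_normal(2)
        w /= np.linalg.norm(w)
        alpha = select_overrelaxation(w, z, 100)
        grid = {round(1.0 + k / 100, 10) for k in range(1, 100)} | {1.0}
        assert round(alpha, 10) in grid

    def test_fallback_at_converged_point(self, uniform_mixture):
        """At a fixed point no α strictly decreases the residual."""
        z, directions = uniform_mixture
        w = directions[:, 0]
        for _ in range(100):  # polish to the empirical fixed point
            w_new = conventional_update(w, z)
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < 1e-12:
                w = w_new
                break
            w = w_new
        assert select_overrelaxation(w, z, 100) == 1.0

    def test_matches_exhaustive_oracle(self, uniform_mixture):
        z, _ = uniform_mixture
        rng = np.random.default_rng(10)
        w = rng.standard_normal(2)
        w /= np.linalg.norm(w)
        f0, jf = residual_and_jacobian(w, z)
        dw = f0 / jf
        best, best_tf = 1.0, np.inf
        for k in range(1, 100):
            ak = 1 + k / 100
            wt = w - ak * dw
            st_ = wt @ z
            beta = np.mean(st_ * st_**3)
            ft = z @ st_**3 / z.shape[1] - beta * wt
            tf = np.linalg.norm(ft)
            if tf**2 < float(f0 @ f0) and tf < best_tf:
                best, best_tf = ak, tf
        assert select_overrelaxation(w, z, 100) == pytest.approx(best)


class TestImprovedUpdate:
    def test_output_unit_norm(self, uniform_mixture):
        z, _ = uniform_mixture
        w = np.array([0.8, -0.6])
        for alpha in (1.0, 1.3, 1.99):
            assert np.linalg.norm(improved_update(w, z, alpha)) == pytest.approx(1.0)

    def test_alpha_range_validated(self, uniform_mixture):
        z, _ = uniform_mixture
        with pytest.raises(ValidationError):
            improved_update(np.array([1.0, 0.0]), z, 2.5)

    def test_converges_to_true_direction(self, uniform_mixture):
        z, directions = uniform_mixture
        cfg = IcaConfig(method="improved", eps=1e-6, seed=11)
        rng = np.random.default_rng(11)
        w0 = rng.standard_normal(2)
        w, n_iter, converged, alpha = extract_component(z, w0, cfg)
        assert converged
        dist = min(
            angular_distance(w, directions[:, 0]),
            angular_distance(w, directions[:, 1]),
        )
        assert dist < 1e-3
        assert 1.0 <= alpha < 2.0

    def test_median_iterations_not_worse_than_conventional(self, uniform_mixture):
        """Paired over shared initial vectors on the same mixture."""
        z, _ = uniform_mixture
        iters = {"improved": [], "conventional": []}
        for seed in range(15):
            for method in iters:
                cfg = IcaConfig(method=method, seed=seed)
                w0 = np.random.default_rng(seed).standard_normal(2)
                _, n, ok, _ = extract_component(z, w0, cfg)
                assert ok
                iters[method].append(n)
        assert np.median(iters["improved"]) <= np.median(iters["conventional"])


class TestExtractComponent:
    def test_existence(self, uniform_mixture):
        z, _ = uniform_mixture
        w0 = np.random.default_rng(12).standard_normal(2)
        w, n_iter, converged, _ = extract_component(z, w0, IcaConfig(seed=12))
        assert converged and n_iter >= 1

    def test_fixed_point_converges_in_one_iteration(self, uniform_mixture):
        z, directions = uniform_mixture
        w = directions[:, 0]
        for _ in range(100):
            w_new = conventional_update(w, z)
            if min(np.linalg.norm(w_new - w), np.linalg.norm(w_new + w)) < 1e-12:
                break
            w = w_new
        _, n_iter, converged, _ = extract_component(
            z, w, IcaConfig(method="conventional")
        )
        assert converged and n_iter == 1

    def test_deterministic_under_fixed_seed(self, uniform_mixture):
        z, _ = uniform_mixture
        w0 = np.random.default_rng(13).standard_normal(2)
        out1 = extract_component(z, w0, IcaConfig(seed=13))
        out2 = extract_component(z, w0, IcaConfig(seed=13))
        assert np.array_equal(out1[0], out2[0]) and out1[1] == out2[1]


class TestExtractAll:
    def test_orthogonal_rows_and_white_sources(self, clean_whitened):
        z, _ = clean_whitened
        res = extract_all(z, 4, IcaConfig(seed=14))
        np.testing.assert_allclose(res.W @ res.W.T, np.eye(4), atol=1e-6)
        np.testing.assert_allclose(
            res.Y @ res.Y.T / z.shape[1], np.eye(4), atol=1e-6
        )
        assert res.total_iterations == sum(res.iterations)

    @pytest.mark.parametrize("method", ["conventional", "improved"])
    def test_recovers_known_mixing(self, clean_record, clean_whitened, method):
        z, model = clean_whitened
        res = extract_all(z, 4, IcaConfig(method=method, seed=15))
        a_white = model.transform @ clean_record.mixing
        assert amari_index(res.W, a_white) < 0.05

    def test_rejects_too_many_components(self, clean_whitened):
        z, _ = clean_whitened
        with pytest.raises(ValidationError):
            extract_all(z, 5, IcaConfig())

    def test_fixed_point_consistency(self, clean_whitened):
        """A converged conventional direction is (within ε) a fixed point."""
        z, _ = clean_whitened
        cfg = IcaConfig(method="conventional", eps=1e-6, seed=16)
        w0 = np.random.default_rng(16).standard_normal(4)
        w, _, converged, _ = extract_component(z, w0, cfg)
        assert converged
        w_next = conventional_update(w, z)
        assert min(np.linalg.norm(w_next - w), np.linalg.norm(w_next + w)) < 1e-6
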