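import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from calimb import (
    BetaParams,
    CalibrationMap,
    DatasetSpec,
    DistortionSpec,
    PlattParams,
    apply_beta,
    apply_map,
    apply_platt,
    distort_scores,
    ece,
    fit_beta,
    fit_map,
    fit_platt,
    fit_spline,
    generate_latent_scores,
    is_monotone,
    load_map,
    make_imbalanced_labels,
    sample_family_scores,
    save_map,
)
from calimb.calibrators import apply_spline
from calimb.exceptions import DegenerateInputError, DegenerateLabelsError, FitError


def latent_sample(n, separability=2.0, seed=0):
    spec = DatasetSpec(n_negative=n // 2, ratio=1.0, seed=seed)
    labels = make_imbalanced_labels(spec)
    probs = generate_latent_scores(labels, separability, rng=seed)
    return labels, probs


class TestApplyPlatt:
    def test_zero_params_give_half(self):
        assert np.allclose(apply_platt(PlattParams(0.0, 0.0), np.array([0.1, 0.9])), 0.5)

    def test_unit_slope_at_zero(self):
        assert apply_platt(PlattParams(0.0, 1.0), np.array([0.0]))[0] == 0.5

    def test_unit_slope_at_one_matches_logistic(self):
        # independent high-precision evaluation of the logistic at 1
        expected = 1.0 / (1.0 + math.exp(-1.0))
        assert apply_platt(PlattParams(0.0, 1.0), np.array([1.0]))[0] == pytest.approx(
            expected, abs=1e-15
        )


class TestFitPlatt:
    def test_generating_model_recovery(self):
        spec = DistortionSpec("platt_family", {"alpha": -2.0, "beta": 4.0})
        sample = sample_family_scores(spec, 50000, rng=42)
        params = fit_platt(sample.scores, sample.labels)
        assert params.alpha == pytest.approx(-2.0, abs=0.15)
        assert params.beta == pytest.approx(4.0, abs=0.3)

    def test_constant_scores_output_smoothed_prevalence(self):
        labels = np.array([0, 1] * 50)
        scores = np.full(100, 0.5)
        with pytest.warns(UserWarning, match="constant"):
            params = fit_platt(scores, labels)
        out = apply_platt(params, np.array([0.0, 0.5, 1.0]))
        expected = 0.5 * ((50 + 1) / (50 + 2) + 1 / (50 + 2))  # mean smoothed target
        assert np.allclose(out, expected)

    def test_independent_labels_flat_map(self, rng):
        import warnings

        n = 20000
        scores = rng.uniform(size=n)
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        with warnings.catch_warnings():
            # a tiny negative fitted slope legitimately warns on pure noise
            warnings.simplefilter("ignore", UserWarning)
            params = fit_platt(scores, labels)
        assert abs(params.beta) < 0.15
        out = apply_platt(params, np.linspace(0.05, 0.95, 10))
        # closed-form intercept-only solution: logit of the mean smoothed target
        n_pos, n_neg = labels.sum(), n - labels.sum()
        t_bar = (labels.mean() * (n_pos + 1) / (n_pos + 2)) + (1 - labels.mean()) / (n_neg + 2)
        assert np.allclose(out, t_bar, atol=0.02)

    def test_one_class_error(self):
        with pytest.raises(DegenerateLabelsError):
            fit_platt(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_too_few_samples(self):
        with pytest.raises(DegenerateInputError):
            fit_platt(np.array([0.5]), np.array([1]))

    def test_negative_slope_warns(self, rng):
        scores = rng.uniform(size=500)
        labels = (scores < 0.3).astype(int)  # anti-oriented
        with pytest.warns(UserWarning, match="beta"):
            fit_platt(scores, labels)

    def test_deterministic(self, rng):
        scores = rng.uniform(size=300)
        labels = (rng.uniform(size=300) < scores).astype(int)
        assert fit_platt(scores, labels) == fit_platt(scores, labels)


class TestApplyBeta:
    def test_identity_member(self):
        assert apply_beta(BetaParams(1.0, 1.0, 0.0), np.array([0.37]))[0] == pytest.approx(
            0.37, abs=1e-9
        )

    def test_symmetric_midpoint(self):
        assert apply_beta(BetaParams(2.0, 2.0, 0.0), np.array([0.5]))[0] == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        # p = (1 + e^{-c} (1-z)^b / z^a)^{-1} at (2, 1, 0), z = 0.25
        expected = 1.0 / (1.0 + 0.75 / 0.0625)
        assert apply_beta(BetaParams(2.0, 1.0, 0.0), np.array([0.25]))[0] == pytest.approx(
            expected, abs=1e-12
        )


class TestFitBeta:
    def test_generating_model_recovery(self):
        labels, probs = latent_sample(50000, separability=2.0, seed=3)
        dist = DistortionSpec("beta_family", {"a": 2.0, "b": 1.0, "c": 0.5})
        scores = distort_scores(probs, dist)
        params = fit_beta(scores, labels)
        assert params.a == pytest.approx(2.0, abs=0.2)
        assert params.b == pytest.approx(1.0, abs=0.2)
        assert params.c == pytest.approx(0.5, abs=0.2)

    def test_identity_neutrality_on_calibrated_scores(self):
        labels, probs = latent_sample(50000, separability=2.0, seed=8)
        params = fit_beta(probs, labels)
        grid = np.linspace(0.01, 0.99, 99)
        assert np.abs(apply_beta(params, grid) - grid).max() < 0.02

    def test_independent_labels_flat_map(self, rng):
        n = 30000
        scores = rng.uniform(size=n)
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        params = fit_beta(scores, labels)
        out = apply_beta(params, np.linspace(0.05, 0.95, 10))
        assert np.allclose(out, labels.mean(), atol=0.03)

    def test_constraints_never_negative(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 200))
            scores = rng.uniform(size=n)
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 4)] = 1
            rng.shuffle(labels)
            params = fit_beta(scores, labels)
            assert params.a >= 0 and params.b >= 0

    def test_anti_oriented_scores_drop_to_subfamily(self, rng):
        scores = rng.uniform(size=2000)
        labels = (rng.uniform(size=2000) < 1 - scores).astype(int)
        params = fit_beta(scores, labels)
        assert params.a == 0.0 and params.b == 0.0

    def test_separated_input_uses_smoothed_targets(self):
        scores = np.concatenate([np.linspace(0.05, 0.4, 20), np.linspace(0.6, 0.95, 20)])
        labels = np.concatenate([np.zeros(20, dtype=int), np.ones(20, dtype=int)])
        params = fit_beta(scores, labels)  # must not diverge
        assert np.isfinite([params.a, params.b, params.c]).all()

    def test_one_class_error(self):
        with pytest.raises(DegenerateLabelsError):
            fit_beta(np.array([0.2, 0.8]), np.array([0, 0]))


class TestFitSpline:
    def test_identity_neutrality_on_calibrated_scores(self):
        labels, probs = latent_sample(50000, separability=2.0, seed=21)
        params = fit_spline(probs, labels, seed=0)
        grid = np.linspace(0.01, 0.99, 99)
        out = apply_spline(params, grid)
        assert np.abs(out - grid).max() < 0.03

    def test_overconfident_distortion_reduces_ece(self):
        labels, probs = latent_sample(20000, separability=2.0, seed=4)
        # temperature-style overconfidence: logit(z) = 2 * logit(p)
        scores = distort_scores(probs, DistortionSpec("beta_family", {"a": 0.5, "b": 0.5, "c": 0.0}))
        params = fit_spline(scores, labels, seed=0)
        calibrated = apply_spline(params, scores)
        assert ece(labels, calibrated) < ece(labels, scores)

    def test_infinite_smoothing_gives_affine_logit_map(self):
        labels, probs = latent_sample(5000, separability=2.0, seed=6)
        params = fit_spline(probs, labels, lambda_grid=np.array([1e9]))
        grid = np.linspace(0.05, 0.95, 200)
        f = np.log(apply_spline(params, grid) / (1 - apply_spline(params, grid)))
        x = np.log(grid / (1 - grid))
        residual = f - np.polyval(np.polyfit(x, f, 1), x)
        assert np.abs(residual).max() < 1e-6

    def test_lambda_selection_trace_recorded(self):
        labels, probs = latent_sample(2000, seed=9)
        grid = np.logspace(-2, 1, 5)
        params = fit_spline(probs, labels, lambda_grid=grid, seed=3)
        assert len(params.selection_trace) == 5
        assert params.lam in grid
        best = max(params.selection_trace, key=lambda pair: pair[1])
        assert params.lam == best[0]

    def test_deterministic_given_seed(self):
        labels, probs = latent_sample(1000, seed=13)
        a = fit_spline(probs, labels, seed=5)
        b = fit_spline(probs, labels, seed=5)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.lam == b.lam

    def test_too_small_n(self):
        with pytest.raises(DegenerateInputError):
            fit_spline(np.linspace(0.1, 0.9, 8), np.array([0, 1] * 4))

    def test_identical_scores_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_spline(np.full(50, 0.5), np.array([0, 1] * 25))

    def test_bad_lambda_grid(self):
        labels, probs = latent_sample(100, seed=0)
        with pytest.raises(FitError):
            fit_spline(probs, labels, lambda_grid=np.array([-1.0, 1.0]))


class TestApplyMap:
    def test_identity_passthrough(self):
        cmap = CalibrationMap("identity")
        scores = np.array([0.1, 0.9])
        assert np.array_equal(apply_map(cmap, scores), scores)

    def test_platt_dispatch(self):
        cmap = CalibrationMap("platt", PlattParams(0.0, 1.0))
        assert apply_map(cmap, np.array([0.0]))[0] == 0.5

    def test_empty_vector(self):
        cmap = CalibrationMap("beta", BetaParams(2.0, 1.0, 0.0))
        assert apply_map(cmap, np.array([])).size == 0

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            apply_map(CalibrationMap("isotonic"), np.array([0.5]))

    def test_fit_map_unknown_method(self):
        with pytest.raises(ValueError):
            fit_map("isotonic", np.array([0.1, 0.9]), np.array([0, 1]))

    @given(
        alpha=st.floats(-5, 5),
        beta=st.floats(-5, 5),
        a=st.floats(0, 4),
        b=st.floats(0, 4),
        c=st.floats(-3, 3),
    )
    def test_range_property(self, alpha, beta, a, b, c):
        grid = np.linspace(0.0, 1.0, 101)
        for cmap in (
            CalibrationMap("platt", PlattParams(alpha, beta)),
            CalibrationMap("beta", BetaParams(a, b, c)),
        ):
            out = apply_map(cmap, grid)
            assert np.all((out >= 0.0) & (out <= 1.0))

    @given(alpha=st.floats(-5, 5), beta=st.floats(0.01, 8))
    def test_platt_monotone_when_beta_positive(self, alpha, beta):
        assert is_monotone(CalibrationMap("platt", PlattParams(alpha, beta)))

    @given(a=st.floats(0, 4), b=st.floats(0, 4), c=st.floats(-3, 3))
    def test_beta_monotone_when_ab_nonnegative(self, a, b, c):
        assert is_monotone(CalibrationMap("beta", BetaParams(a, b, c)))


class TestSerialization:
    @pytest.mark.parametrize("method", ["identity", "platt", "beta", "spline"])
    def test_round_trip_bit_faithful(self, method, tmp_path, rng):
        labels = (rng.uniform(size=500) < 0.5).astype(int)
        scores = np.clip(rng.normal(0.5, 0.2, size=500), 0.01, 0.99)
        cmap = fit_map(method, scores, labels, seed=2)
        path = tmp_path / "map.json"
        save_map(cmap, path)
        loaded = load_map(path)
        assert loaded.method == cmap.method
        assert loaded.fit_n == cmap.fit_n
        if method == "platt":
            assert loaded.params == cmap.params
        elif method == "beta":
            assert loaded.params == cmap.params
        elif method == "spline":
            assert np.array_equal(loaded.params.knots, cmap.params.knots)
            assert np.array_equal(loaded.params.coefficients, cmap.params.coefficients)
            assert loaded.params.lam == cmap.params.lam
            assert loaded.params.selection_trace == cmap.params.selection_trace
        grid = np.linspace(0, 1, 101)
        assert np.array_equal(apply_map(loaded, grid), apply_map(cmap, grid))

    def test_reject_foreign_file(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"something": "else"}')
        with pytest.raises(ValueError):
            load_map(path)
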