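import numpy as np
import pandas as pd
import pytest

from consonance.analysis import (
    SmoothingConfig,
    bootstrap_profile,
    default_grid,
    model_profile,
    nw_smooth,
    smooth_profile,
    split_half_reliability,
    zscore_within_participant,
)


def make_dataset(rng, n_participants=20, n_trials=30, fn=None, noise=0.5):
    fn = fn or (lambda x: np.sin(x))
    rows = []
    for p in range(n_participants):
        x = rng.uniform(0, 15, n_trials)
        y = fn(x) + rng.normal(0, noise, n_trials)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": p,
                    "interval_1": x,
                    "bass_midi": rng.uniform(55, 65, n_trials),
                    "rating": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestZscore:
    def test_two_ratings(self):
        data = pd.DataFrame(
            {"participant_id": [0, 0], "interval_1": [1.0, 2.0], "rating": [1, 7]}
        )
        z = zscore_within_participant(data)
        # sample sd convention (ddof=1): sd([1,7]) = 4.2426
        np.testing.assert_allclose(
            z["rating"].to_numpy(), [-0.7071067811865475, 0.7071067811865475]
        )

    def test_constant_ratings_to_zero(self):
        data = pd.DataFrame(
            {"participant_id": [0, 0, 1, 1], "interval_1": [1, 2, 3, 4.0],
             "rating": [4, 4, 2, 2]}
        )
        assert (zscore_within_participant(data)["rating"] == 0).all()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        data = make_dataset(rng, 5, 20)
        once = zscore_within_participant(data)
        twice = zscore_within_participant(once)
        np.testing.assert_allclose(once["rating"], twice["rating"], atol=1e-12)

    def test_per_participant_moments(self):
        rng = np.random.default_rng(1)
        z = zscore_within_participant(make_dataset(rng, 8, 25))
        for _, g in z.groupby("participant_id"):
            assert g["rating"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["rating"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zscore_within_participant(pd.DataFrame(columns=["participant_id", "rating"]))


class TestSmoothing:
    def test_constant_ratings_constant_profile(self):
        xs = np.linspace(0, 15, 40)
        data = pd.DataFrame(
            {"participant_id": 0, "interval_1": xs, "rating": 2.0}
        )
        prof = smooth_profile(data, default_grid(0, 15, 50))
        assert prof.defined.all()
        np.testing.assert_allclose(prof.mean, 2.0)

    def test_single_rating_constant_profile(self):
        data = pd.DataFrame(
            {"participant_id": [0], "interval_1": [7.0], "rating": [3.0]}
        )
        prof = smooth_profile(data, np.linspace(6.5, 7.5, 11))
        np.testing.assert_allclose(prof.mean, 3.0)

    def test_linear_recovery_matches_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 15, 4000)
        y = x.copy()
        grid = np.linspace(4, 11, 10)
        est, defined = nw_smooth(x, y, grid, 0.2)
        assert defined.all()
        # brute-force weighted mean oracle
        for g, e in zip(grid, est):
            w = np.exp(-0.5 * ((x - g) / 0.2) ** 2)
            assert e == pytest.approx(np.sum(w * y) / np.sum(w), rel=1e-12)
        np.testing.assert_allclose(est, grid, atol=0.05)

    def test_undefined_far_from_support(self):
        data = pd.DataFrame(
            {"participant_id": [0, 0], "interval_1": [1.0, 1.1], "rating": [2.0, 3.0]}
        )
        prof = smooth_profile(data, np.array([1.0, 14.0]))
        assert prof.defined[0]
        assert not prof.defined[1]
        assert np.isnan(prof.mean[1])

    def test_linear_in_ratings_and_order_invariant(self):
        rng = np.random.default_rng(3)
        data = make_dataset(rng, 6, 20)
        grid = default_grid(1, 14, 40)
        a = smooth_profile(data, grid).mean
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = smooth_profile(shuffled, grid).mean
        np.testing.assert_allclose(a, b, atol=1e-10)
        doubled = data.copy()
        doubled["rating"] *= 2
        np.testing.assert_allclose(
            smooth_profile(doubled, grid).mean, 2 * a, atol=1e-10
        )

    def test_2d_product_kernel(self):
        rng = np.random.default_rng(4)
        n = 2000
        data = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(20), 100),
                "interval_1": rng.uniform(0, 15, n),
                "rolloff": rng.uniform(0, 15, n),
                "rating": rng.normal(size=n),
            }
        )
        data["rating"] += data["rolloff"] * 0.2
        grid = np.column_stack([np.full(5, 7.5), np.linspace(2, 12, 5)])
        prof = smooth_profile(data, grid)
        # main effect of roll-off is recovered as an increasing trend
        assert prof.mean[-1] - prof.mean[0] > 1.0
        assert np.corrcoef(grid[:, 1], prof.mean)[0, 1] > 0.9


class TestBootstrap:
    def test_identical_participants_zero_width(self):
        base = pd.DataFrame(
            {"interval_1": np.linspace(0, 15, 30), "rating": np.sin(np.linspace(0, 15, 30))}
        )
        data = pd.concat(
            [base.assign(participant_id=i) for i in range(6)], ignore_index=True
        )
        prof = bootstrap_profile(data, default_grid(0, 15, 30), SmoothingConfig(n_boot=50), seed=0)
        np.testing.assert_allclose(prof.se, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.ci_low, prof.mean, atol=1e-10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        data = make_dataset(rng, 10, 15)
        grid = default_grid(1, 14, 25)
        cfg = SmoothingConfig(n_boot=40)
        a = bootstrap_profile(data, grid, cfg, seed=123)
        b = bootstrap_profile(data, grid, cfg, seed=123)
        np.testing.assert_array_equal(a.se, b.se)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_ci_width_scaling(self):
        # CI width ~ 1/sqrt(N): slope of log width vs log N in [-0.7, -0.3]
        rng = np.random.default_rng(6)
        grid = default_grid(2, 13, 15)
        cfg = SmoothingConfig(n_boot=100)
        widths = []
        ns = [10, 40, 160]
        for n in ns:
            data = make_dataset(rng, n, 20, noise=1.0)
            prof = bootstrap_profile(data, grid, cfg, seed=1)
            widths.append(np.nanmean(prof.ci_high - prof.ci_low))
        slope = np.polyfit(np.log(ns), np.log(widths), 1)[0]
        assert -0.7 < slope < -0.3

    def test_too_few_participants(self):
        data = pd.DataFrame(
            {"participant_id": [0, 0], "interval_1": [1, 2.0], "rating": [1, 2.0]}
        )
        with pytest.raises(ValueError):
            bootstrap_profile(data, default_grid(0, 15, 10))


class TestModelProfile:
    def test_constant_model(self):
        grid = default_grid(0, 15, 100)
        prof = model_profile(np.full(100, 1.3), grid)
        np.testing.assert_allclose(prof.mean, 1.3, atol=1e-12)

    def test_broad_maximum_preserved(self):
        grid = default_grid(0, 15, 500)
        raw = np.exp(-0.5 * ((grid - 6.2) / 1.0) ** 2)
        prof = model_profile(raw, grid, SmoothingConfig(bandwidth_interval=0.2))
        assert abs(grid[np.argmax(prof.mean)] - 6.2) <= 0.1

    def test_delta_kernel_limit(self):
        grid = default_grid(0, 15, 200)
        raw = np.sin(grid)
        prof = model_profile(raw, grid, SmoothingConfig(bandwidth_interval=0.001))
        np.testing.assert_allclose(prof.mean, raw, atol=1e-6)


class TestSplitHalf:
    def test_noise_free_raters_near_one(self):
        rng = np.random.default_rng(7)
        data = make_dataset(rng, 20, 40, noise=0.0)
        out = split_half_reliability(data, default_grid(1, 14, 50), n_perm=20, seed=0)
        assert out["mean_r"] > 0.99

    def test_pure_noise_centered_near_zero(self):
        rng = np.random.default_rng(8)
        data = make_dataset(rng, 20, 40, fn=lambda x: 0.0 * x, noise=1.0)
        out = split_half_reliability(data, default_grid(1, 14, 50), n_perm=50, seed=0)
        assert abs(out["mean_r"]) < 0.3

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        data = make_dataset(rng, 8, 20)
        grid = default_grid(1, 14, 30)
        a = split_half_reliability(data, grid, n_perm=10, seed=5)
        b = split_half_reliability(data, grid, n_perm=10, seed=5)
        assert a == b
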