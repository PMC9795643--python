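"""Sound Level Regression: features, bounds, piecewise fit, threshold rule."""

from __future__ import annotations

import numpy as np
import pytest

from abrkit.io import ABRDataset, N_SAMPLES, get_stimulus_blocks
from abrkit.simulate import SyntheticSpec, generate_dataset
from abrkit.slr import (
    SLRConfig,
    _fold_assignment,
    estimate_thresholds,
    extract_spectral_features,
    fit_piecewise,
    lower_bound,
    predict_sound_levels,
    results_to_frame,
    select_breakpoint,
    threshold_from_fit,
    upper_bound,
    PiecewiseFit,
)


# ---------------------------------------------------------------- features
def brute_force_power_spectrum(x, n_features):
    """O(N^2) direct-summation DFT oracle on the mean-centred signal."""
    x = np.asarray(x, float)
    x = x - x.mean()
    N = len(x)
    out = np.empty(n_features)
    for k in range(1, n_features + 1):
        re = sum(x[n] * np.cos(-2 * np.pi * k * n / N) for n in range(N))
        im = sum(x[n] * np.sin(-2 * np.pi * k * n / N) for n in range(N))
        out[k - 1] = re * re + im * im
    return out


def test_constant_curve_gives_zero_features():
    f = extract_spectral_features(np.ones(N_SAMPLES))
    assert f.shape == (50,)
    assert np.all(f == 0.0)


def test_pure_sinusoid_concentrates_in_its_bin():
    t = np.arange(N_SAMPLES)
    f = extract_spectral_features(np.sin(2 * np.pi * 5 * t / N_SAMPLES))
    assert np.argmax(f) == 4  # bin 5 is feature index 4 (DC excluded)
    assert f[4] > 1e3 * (f.sum() - f[4] + 1e-300)


def test_features_match_brute_force_dft():
    rng = np.random.default_rng(17)
    x = rng.normal(size=N_SAMPLES)
    fast = extract_spectral_features(x, SLRConfig(n_features=8))
    slow = brute_force_power_spectrum(x, 8)
    np.testing.assert_allclose(fast, slow, rtol=1e-8)


# ------------------------------------------------------- fold assignment
def test_fold_assignment_invariant_to_input_order():
    mice = [f"m{i}" for i in range(12)]
    a = _fold_assignment(mice, 5, seed=3)
    b = _fold_assignment(list(reversed(mice)), 5, seed=3)
    assert a == b
    with pytest.raises(ValueError, match="lower n_folds"):
        _fold_assignment(["a", "b"], 5, seed=0)


# -------------------------------------------------- sound level regression
@pytest.fixture(scope="module")
def small_preds():
    """Out-of-fold predictions on a 30-mouse click set, null and strong."""
    out = {}
    for name, kwargs in [
        ("null", dict(amplitude_gain=0.0)),
        ("strong", dict(noise_sd=0.05)),
    ]:
        spec = SyntheticSpec(
            n_mutant_lines=0, mice_per_line=0, n_controls=30, stimuli=("click",),
            seed=19, **kwargs,
        )
        dataset, truth = generate_dataset(spec)
        blocks = get_stimulus_blocks(dataset, "click")
        out[name] = (predict_sound_levels(blocks, seed=0), truth)
    return out


def test_no_signal_gives_no_rank_correlation(small_preds):
    from scipy.stats import spearmanr

    preds, _ = small_preds["null"]
    assert len(preds) >= 500
    rho = spearmanr(preds["sound_level"], preds["predicted"]).statistic
    assert abs(rho) < 0.15


def test_strong_signal_gives_high_supra_threshold_correlation(small_preds):
    from scipy.stats import spearmanr

    preds, truth = small_preds["strong"]
    thr = {r.mouse_id: r.true_threshold for r in truth.itertuples()}
    supra = preds[
        preds.apply(lambda r: r["sound_level"] >= thr[r["mouse_id"]], axis=1)
    ]
    rho = spearmanr(supra["sound_level"], supra["predicted"]).statistic
    assert rho > 0.8


# ------------------------------------------------------------- upper bound
def test_upper_bound_constant_predictions_none():
    grid = np.arange(0, 90, 5.0)
    assert upper_bound(grid, np.full_like(grid, 30.0)) is None


def test_upper_bound_perfect_predictions_hits_largest_testable_level():
    grid = np.arange(0, 90, 5.0)
    actual = np.tile(grid, 5)
    assert upper_bound(actual, actual.copy()) == 70.0  # 75,80,85 above


def test_upper_bound_monte_carlo_recovers_kink():
    grid = np.arange(0, 90, 5.0)
    hits = 0
    for rep in range(100):
        rng = np.random.default_rng(rep)
        actual = np.tile(grid, 3)
        pred = np.where(
            actual <= 40, rng.normal(30, 2, actual.shape),
            actual - 20 + rng.normal(0, 2, actual.shape),
        )
        b = upper_bound(actual, pred)
        hits += b is not None and b >= 35
    assert hits >= 95


# ------------------------------------------------------------- lower bound
def test_lower_bound_cases():
    grid = np.arange(0, 90, 5.0)
    # strictly increasing -> minimum measured level
    assert lower_bound(grid, grid + 3.0) == 0.0
    # constant below 45, increase from 50 -> bound 45
    pred = np.where(grid <= 45, 30.0, 30.0 + (grid - 45))
    assert lower_bound(grid, pred) == 45.0
    # globally constant -> fallback to minimum level
    assert lower_bound(grid, np.full_like(grid, 30.0)) == 0.0


# ------------------------------------------------------------ piecewise fit
def _kink_data():
    grid = np.arange(0, 90, 5.0)
    actual = np.tile(grid, 2)
    pred = np.where(actual <= 40, 20.0, actual - 20.0)
    return actual, pred


def test_fit_piecewise_constant_limit():
    actual = np.tile(np.arange(0, 90, 5.0), 2)
    fit = fit_piecewise(actual, np.full_like(actual, 30.0), breakpoint=40.0, seed=0)
    assert fit.const == pytest.approx(30.0, abs=1e-6)
    assert np.all(np.abs(fit.coeffs) < 1e-6)
    assert fit.cv_error == pytest.approx(0.0, abs=1e-9)


def test_fit_piecewise_recovers_noiseless_kink():
    actual, pred = _kink_data()
    fit = fit_piecewise(actual, pred, breakpoint=40.0, seed=0)
    assert fit.const == pytest.approx(20.0, abs=0.5)
    assert fit.predict(np.array([60.0]))[0] == pytest.approx(40.0, abs=0.5)


def test_wrong_breakpoint_has_larger_cv_error():
    actual, pred = _kink_data()
    right = fit_piecewise(actual, pred, breakpoint=40.0, seed=0)
    wrong = fit_piecewise(actual, pred, breakpoint=20.0, seed=0)
    assert wrong.cv_error > right.cv_error


def test_fit_piecewise_needs_enough_points():
    with pytest.raises(ValueError, match=">= 8"):
        fit_piecewise(np.arange(5.0), np.arange(5.0), 2.0)


# ------------------------------------------------------ breakpoint selection
def test_select_breakpoint_noiseless_kink():
    actual, pred = _kink_data()
    fit, cand, errs = select_breakpoint(actual, pred, 20.0, 60.0, seed=0)
    assert fit.breakpoint in {39.5, 40.0, 40.5}
    assert len(cand) == len(errs) == 9 + 2  # grid candidates + refinements


def test_select_breakpoint_tie_goes_to_larger():
    actual = np.tile(np.arange(0, 90, 5.0), 2)
    pred = np.full_like(actual, 25.0)  # constant: all candidates tie at 0
    fit, _, _ = select_breakpoint(actual, pred, 20.0, 40.0, seed=0)
    assert fit.breakpoint >= 40.0


def test_select_breakpoint_single_candidate_still_refined():
    actual, pred = _kink_data()
    fit, cand, _ = select_breakpoint(actual, pred, 40.0, 40.0, seed=0)
    assert len(cand) == 3  # one candidate + two refinements
    assert fit.breakpoint in {39.5, 40.0, 40.5}

    with pytest.raises(ValueError):
        select_breakpoint(actual, pred, 50.0, 40.0, seed=0)


# ---------------------------------------------------------- threshold rule
def test_threshold_from_fit_linear_case():
    grid = np.arange(0, 90, 5.0)
    fit = PiecewiseFit(breakpoint=40.0, const=20.0,
                       coeffs=np.array([1.0, 0, 0, 0]), cv_error=0.0)
    # deviation exceeds 4 dB just above x = 44 -> snap up to grid level 45
    assert threshold_from_fit(fit, grid) == 45.0


def test_threshold_from_fit_no_deviation_is_non_hearing():
    grid = np.arange(0, 90, 5.0)
    flat = PiecewiseFit(40.0, 20.0, np.zeros(4), 0.0)
    assert threshold_from_fit(flat, grid) == 999.0
    # deviation point beyond the measured range -> 999
    late = PiecewiseFit(83.0, 20.0, np.array([1.0, 0, 0, 0]), 0.0)
    assert threshold_from_fit(late, grid) == 999.0


# ------------------------------------------------------------- end to end
def test_high_snr_recovery(high_snr_run):
    frame = high_snr_run["frame"]
    hearing = frame[frame["true_threshold"] != 999]
    within5 = (hearing["threshold"] - hearing["true_threshold"]).abs() <= 5
    assert within5.mean() >= 0.90


def test_null_data_called_non_hearing(null_run):
    frame = null_run["frame"]
    assert (frame["threshold"] == 999).mean() >= 0.95


def test_bound_sanity_invariant(high_snr_run):
    # the +-0.5 dB refinement may step just outside the [lower, upper] grid
    for r in high_snr_run["results"]:
        if r.threshold != 999 and r.best_fit is not None:
            assert r.lower_bound - 0.5 <= r.best_fit.breakpoint <= r.upper_bound + 0.5
            assert r.threshold >= r.best_fit.breakpoint


def test_amplifying_responses_does_not_raise_threshold():
    # doubling every supra-threshold waveform leaves sub-threshold curves as
    # the only unpredictable ones; the estimate must not move up
    spec = SyntheticSpec(
        n_mutant_lines=0, mice_per_line=0, n_controls=8, stimuli=("click",),
        noise_sd=0.05, seed=29,
    )
    dataset, truth = generate_dataset(spec)
    base = results_to_frame(estimate_thresholds(dataset, seed=1))
    thr = {r.mouse_id: r.true_threshold for r in truth.itertuples()}
    amplified = dataset.samples.copy()
    for i, r in dataset.curves.iterrows():
        if r["sound_level"] >= thr[r["mouse_id"]]:
            amplified[i] *= 2.0
    boosted = ABRDataset(
        curves=dataset.curves, samples=amplified, metadata=dataset.metadata
    )
    after = results_to_frame(estimate_thresholds(boosted, seed=1))
    merged = base.merge(after, on=["mouse_id", "stimulus"], suffixes=("_a", "_b"))
    assert (merged["threshold_b"] <= merged["threshold_a"]).all()


def test_estimation_deterministic_and_label_blind():
    spec = SyntheticSpec(
        n_mutant_lines=0, mice_per_line=0, n_controls=8, stimuli=("click",),
        noise_sd=0.1, seed=23,
    )
    dataset, _ = generate_dataset(spec)
    first = results_to_frame(estimate_thresholds(dataset, seed=4))
    # scramble the manual labels: the self-supervised path must not notice
    scrambled = ABRDataset(
        curves=dataset.curves.assign(threshold=999.0),
        samples=dataset.samples,
        metadata=dataset.metadata,
    )
    second = results_to_frame(estimate_thresholds(scrambled, seed=4))
    assert first.drop(columns=["error"]).equals(second.drop(columns=["error"]))
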