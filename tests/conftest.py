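"""Shared fixtures.

The expensive end-to-end runs (100-mouse screens through SLR and the NN)
are computed once per session and shared between the module tests and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from abrkit.evaluation import (
    ThresholdAssignment,
    constant_method,
    curve_area,
    evaluation_curve,
)
from abrkit.nn import TwoStageNNThresholder
from abrkit.simulate import (
    SyntheticSpec,
    dominance_screen,
    generate_dataset,
    high_snr_screen,
    mutant_screen,
    null_screen,
    sample_thresholds,
    _mouse_table,
)
from abrkit.slr import estimate_thresholds, results_to_frame


@pytest.fixture(scope="session")
def tiny_dataset():
    """Six mice, click only — quick I/O and block tests."""
    spec = SyntheticSpec(
        n_mutant_lines=1, mice_per_line=3, n_controls=3, stimuli=("click",), seed=5
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def high_snr_run():
    """High-SNR 100-mouse screen pushed through SLR."""
    spec = high_snr_screen(seed=11)
    dataset, truth = generate_dataset(spec)
    results = estimate_thresholds(dataset, seed=0)
    frame = results_to_frame(results).merge(truth, on=["mouse_id", "stimulus"])
    return {"dataset": dataset, "truth": truth, "results": results, "frame": frame}


@pytest.fixture(scope="session")
def null_run():
    """Zero-amplitude (pure noise) 100-mouse screen pushed through SLR."""
    spec = null_screen(seed=21)
    dataset, truth = generate_dataset(spec)
    results = estimate_thresholds(dataset, seed=0)
    frame = results_to_frame(results)
    return {"dataset": dataset, "truth": truth, "results": results, "frame": frame}


@pytest.fixture(scope="session")
def nn_run():
    """High-SNR click-only screen with clean labels through the NN pipeline."""
    spec = high_snr_screen(seed=31, stimuli=("click",))
    dataset, truth = generate_dataset(spec)
    est = TwoStageNNThresholder(random_state=0).fit(dataset)
    frame = est.oof_predictions_.merge(truth, on=["mouse_id", "stimulus"])
    return {"dataset": dataset, "truth": truth, "estimator": est, "frame": frame}


@pytest.fixture(scope="session")
def mutant_run():
    """Click screen with six +30 dB lines and ten null lines through SLR."""
    spec = mutant_screen(seed=41)
    dataset, truth = generate_dataset(spec)
    results = estimate_thresholds(dataset, seed=0)
    return {
        "dataset": dataset,
        "truth": truth,
        "thresholds": results_to_frame(results)[["mouse_id", "stimulus", "threshold"]],
        "shifted_lines": {f"line{i:03d}" for i in range(6)},
        "null_lines": {f"line{i:03d}" for i in range(6, 16)},
    }


def _corrupt(tmap: dict, seed: int, frac: float = 0.3) -> dict:
    """Shift all thresholds of a random 30% of mice by +-5 dB."""
    rng = np.random.default_rng(seed)
    out = dict(tmap)
    for mouse in sorted({k[0] for k in tmap}):
        if rng.random() < frac:
            step = 5.0 if rng.random() < 0.5 else -5.0
            for key in out:
                if key[0] == mouse and out[key] != 999:
                    out[key] = float(np.clip(out[key] + step, 0, 85))
    return out


@pytest.fixture(scope="session")
def dominance_stats():
    """Areas and curve heights for truth / corrupted / constant-50 over 100 seeds."""
    rows = []
    for seed in range(100):
        dataset, truth = generate_dataset(dominance_screen(seed=1000 + seed))
        tmap = {
            (r.mouse_id, r.stimulus): r.true_threshold for r in truth.itertuples()
        }
        assignments = {
            "truth": ThresholdAssignment("truth", tmap),
            "corrupted": ThresholdAssignment("corrupted", _corrupt(tmap, seed)),
            "constant": constant_method(dataset),
        }
        row = {}
        for name, asg in assignments.items():
            curve = evaluation_curve(dataset, asg, "click")
            row[f"area_{name}"] = curve_area(curve)
            for frac in (0.25, 0.5):
                i = int(np.searchsorted(curve.fractions, frac))
                row[f"h{frac}_{name}"] = float(curve.values[i])
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_scan_rates():
    """Fraction of p < 0.05 line x stimulus tests on zero-effect screens."""
    rates = []
    for seed in range(20):
        spec = SyntheticSpec(n_mutant_lines=200, mice_per_line=8, n_controls=50, seed=seed)
        rng = np.random.default_rng(seed)
        thr = sample_thresholds(spec, rng).rename(columns={"true_threshold": "threshold"})
        meta = _mouse_table(spec).set_index("mouse_id")
        from abrkit.phenotyping import effect_scan

        eff = effect_scan(thr, meta, "all_controls")
        rates.append(float((eff["p_value"] < 0.05).mean()))
    return rates
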