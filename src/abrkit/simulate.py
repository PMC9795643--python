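"""Synthetic ABR datasets with known ground-truth hearing thresholds.

The generator reproduces the statistical structure the threshold-finding
methods rely on: curves recorded below an animal's hearing threshold are
temporally *incoherent* (pure noise, so cross-curve averages flatten out),
while curves at and above threshold contain a *coherent* evoked waveform
whose amplitude grows and whose peak latencies shrink with stimulus level.
The waveform template is a train of alternating-sign Gaussian peaks between
1 and 7 ms, emulating ABR waves I-V.

True thresholds are drawn per mouse and stimulus from a normal distribution
around a stimulus-specific mean (shifted per mutant line), rounded to the
5 dB recording grid; with a stimulus-specific probability the animal is
non-hearing (sentinel 999) for that stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ABRDataset,
    DEFAULT_GRIDS,
    GRID_STEP,
    N_SAMPLES,
    NON_HEARING,
    STIMULI,
    WINDOW_MS,
)

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "assign_lines",
    "sample_thresholds",
    "high_snr_screen",
    "null_screen",
    "mutant_screen",
    "dominance_screen",
]

#: (latency ms, width ms, relative amplitude) for five alternating peaks
#: within 1-7 ms, a stylised waves I-V morphology.
DEFAULT_PEAK_TEMPLATE: tuple[tuple[float, float, float], ...] = (
    (1.5, 0.25, 1.0),
    (2.3, 0.30, -0.8),
    (3.1, 0.30, 0.9),
    (4.2, 0.35, -0.6),
    (5.3, 0.40, 0.5),
)

#: Typical U-shaped control hearing curve (dB SPL): most sensitive in the
#: low-mid kHz range, less sensitive at the band edges.
DEFAULT_MEAN_THRESHOLD: dict[str, float] = {
    "click": 30.0,
    "6": 45.0,
    "12": 25.0,
    "18": 30.0,
    "24": 40.0,
    "30": 55.0,
}

#: Non-hearing is common mainly at the highest frequencies.
DEFAULT_NON_HEARING_PROB: dict[str, float] = {
    "click": 0.0,
    "6": 0.0,
    "12": 0.0,
    "18": 0.0,
    "24": 0.05,
    "30": 0.10,
}


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated screen.

    Parameters
    ----------
    n_mutant_lines, mice_per_line, n_controls : int
        Cohort layout; mutant cohort size defaults to 8 animals per line.
    stimuli : tuple of str
        Which stimuli to record (default: all six).
    mean_threshold, threshold_sd : per-stimulus mean (dB) and spread (dB)
        of the true-threshold distribution for unaffected animals.
    non_hearing_prob : per-stimulus probability of a 999 threshold.
    line_effect : mapping line name -> {stimulus: dB shift} added to the
        threshold mean for that line's mice.
    noise_sd : float
        Standard deviation of the recording noise (arbitrary voltage units).
    peak_template : evoked waveform as (latency ms, width ms, rel. amplitude).
    amplitude_gain : float
        Waveform amplitude per dB above ``threshold - 5`` (so the curve at
        threshold itself already carries signal, matching the labelling
        convention that the threshold SPL counts as hearing).
    latency_shift : float
        Peak latency reduction in ms per dB above threshold.
    noise_ar : float
        AR(1) coefficient for coloured recording noise (0 = white).
    label_noise_prob : float
        Probability that the manual label is displaced by one grid step,
        emulating human reader variability (default 0: clean labels).
    n_dates : int
        Number of distinct measurement dates cycled over lines/controls.
    seed : int
    """

    n_mutant_lines: int = 2
    mice_per_line: int = 8
    n_controls: int = 8
    stimuli: tuple[str, ...] = STIMULI
    mean_threshold: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_THRESHOLD)
    )
    threshold_sd: float = 7.5
    non_hearing_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NON_HEARING_PROB)
    )
    line_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.5
    peak_template: tuple[tuple[float, float, float], ...] = DEFAULT_PEAK_TEMPLATE
    amplitude_gain: float = 0.2
    latency_shift: float = 0.01
    noise_ar: float = 0.0
    label_noise_prob: float = 0.0
    n_dates: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_mutant_lines, self.mice_per_line, self.n_controls) < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for lat, width, _amp in self.peak_template:
            if width <= 0:
                raise ValueError("peak widths must be > 0")
            if not (0 <= lat <= WINDOW_MS):
                raise ValueError("peak latencies must lie within the 10 ms window")
        for stim in self.stimuli:
            if stim not in STIMULI:
                raise ValueError(f"unknown stimulus {stim!r}")
        if not (0 <= self.noise_ar < 1):
            raise ValueError("noise_ar must be in [0, 1)")


def _mouse_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Mouse ids with line, zygosity and measurement-date assignment."""
    rows = []
    for li in range(spec.n_mutant_lines):
        line = f"line{li:03d}"
        date = f"d{li % spec.n_dates:03d}"
        for m in range(spec.mice_per_line):
            rows.append((f"{line}_m{m:02d}", line, "mutant", date))
    for m in range(spec.n_controls):
        rows.append((f"ctrl_m{m:03d}", "control", "control", f"d{m % spec.n_dates:03d}"))
    return pd.DataFrame(rows, columns=["mouse_id", "line", "zygosity", "measurement_date"])


def sample_thresholds(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw true thresholds per mouse x stimulus.

    Normal around the stimulus mean plus the line effect, rounded to the
    recording grid and clipped to its range; non-hearing (999) with the
    stimulus-specific probability.
    """
    mice = _mouse_table(spec)
    rows = []
    for _, mouse in mice.iterrows():
        for stim in spec.stimuli:
            grid = DEFAULT_GRIDS[stim]
            if rng.random() < spec.non_hearing_prob.get(stim, 0.0):
                theta = float(NON_HEARING)
            else:
                shift = spec.line_effect.get(mouse["line"], {}).get(stim, 0.0)
                raw = rng.normal(spec.mean_threshold[stim] + shift, spec.threshold_sd)
                theta = float(
                    np.clip(round(raw / GRID_STEP) * GRID_STEP, grid[0], grid[-1])
                )
            rows.append((mouse["mouse_id"], stim, theta))
    return pd.DataFrame(rows, columns=["mouse_id", "stimulus", "true_threshold"])


def _template_curve(
    spec: SyntheticSpec, spl: float, theta: float, t_ms: np.ndarray
) -> np.ndarray:
    """Noise-free evoked waveform for a supra-threshold curve."""
    amp = spec.amplitude_gain * (spl - theta + GRID_STEP)
    lat_shift = spec.latency_shift * (spl - theta)
    wave = np.zeros_like(t_ms)
    for lat, width, rel in spec.peak_template:
        wave += rel * amp * np.exp(-0.5 * ((t_ms - (lat - lat_shift)) / width) ** 2)
    return wave


def _noise(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(0.0, spec.noise_sd, size=(n, N_SAMPLES))
    if spec.noise_ar == 0.0:
        return white
    out = np.empty_like(white)
    out[:, 0] = white[:, 0]
    a = spec.noise_ar
    scale = np.sqrt(1 - a * a)  # keep marginal sd = noise_sd
    for j in range(1, N_SAMPLES):
        out[:, j] = a * out[:, j - 1] + scale * white[:, j]
    return out


def generate_dataset(spec: SyntheticSpec) -> tuple[ABRDataset, pd.DataFrame]:
    """Simulate a full screen; returns (dataset, ground-truth table).

    Deterministic given ``spec.seed``.  The manual threshold label column is
    the true threshold, optionally corrupted by one grid step with
    probability ``label_noise_prob``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = sample_thresholds(spec, rng)
    mice = _mouse_table(spec)
    t_ms = np.arange(N_SAMPLES) * (WINDOW_MS / N_SAMPLES)

    curve_rows = []
    sample_blocks = []
    for _, row in truth.iterrows():
        stim = row["stimulus"]
        theta = row["true_threshold"]
        grid = DEFAULT_GRIDS[stim]
        block = _noise(spec, len(grid), rng)
        if theta != NON_HEARING:
            for i, spl in enumerate(grid):
                if spl >= theta:
                    block[i] += _template_curve(spec, spl, theta, t_ms)
        label = theta
        if spec.label_noise_prob > 0 and theta != NON_HEARING:
            if rng.random() < spec.label_noise_prob:
                step = GRID_STEP if rng.random() < 0.5 else -GRID_STEP
                label = float(np.clip(theta + step, grid[0], grid[-1]))
        for i, spl in enumerate(grid):
            curve_rows.append((row["mouse_id"], stim, float(spl), label))
        sample_blocks.append(block)

    curves = pd.DataFrame(
        curve_rows, columns=["mouse_id", "stimulus", "sound_level", "threshold"]
    )
    samples = np.vstack(sample_blocks) if sample_blocks else np.empty((0, N_SAMPLES))
    metadata = mice.set_index("mouse_id")
    metadata["sex"] = ""
    metadata["validation"] = "none"
    dataset = ABRDataset(curves=curves, samples=samples, metadata=metadata)
    return dataset, truth


def high_snr_screen(
    seed: int = 11, stimuli: tuple[str, ...] = ("click", "18")
) -> SyntheticSpec:
    """Benchmark scenario: 100 mice with clearly resolvable evoked responses.

    Recording noise is one tenth of the default, so the waveform at
    threshold + 30 dB is ~70x the noise floor; used to measure how well a
    method recovers known thresholds when the data are clean.
    """
    return SyntheticSpec(
        n_mutant_lines=5,
        mice_per_line=4,
        n_controls=80,
        stimuli=stimuli,
        noise_sd=0.1,
        seed=seed,
    )


def null_screen(
    seed: int = 21, stimuli: tuple[str, ...] = ("click", "18")
) -> SyntheticSpec:
    """Benchmark scenario: 100 mice with zero evoked amplitude everywhere.

    Every curve is pure noise, so the correct call is non-hearing (999) for
    every animal; used to measure the false-response rate.
    """
    return SyntheticSpec(
        n_mutant_lines=5,
        mice_per_line=4,
        n_controls=80,
        stimuli=stimuli,
        amplitude_gain=0.0,
        seed=seed,
    )


def mutant_screen(seed: int = 41) -> SyntheticSpec:
    """Benchmark scenario: click-stimulus screen of 16 lines, 6 truly shifted.

    Six lines carry a +30 dB click-threshold shift (a strong hearing-loss
    phenotype), ten are unaffected; 8 mice per line against 40 controls.
    Used for the end-to-end candidate-gene recovery check.
    """
    return SyntheticSpec(
        n_mutant_lines=16,
        mice_per_line=8,
        n_controls=40,
        stimuli=("click",),
        noise_sd=0.1,
        line_effect={f"line{i:03d}": {"click": 30.0} for i in range(6)},
        seed=seed,
    )


def dominance_screen(seed: int) -> SyntheticSpec:
    """Benchmark scenario for evaluation curves: 40 mice, click stimulus.

    One line with a +30 dB shift and a 10% non-hearing rate spread the true
    thresholds widely, which is the regime the curve statistic is built for
    (a screening population, not a homogeneous colony).
    """
    return SyntheticSpec(
        n_mutant_lines=2,
        mice_per_line=8,
        n_controls=24,
        stimuli=("click",),
        noise_sd=0.3,
        line_effect={"line000": {"click": 30.0}},
        non_hearing_prob={"click": 0.1},
        seed=seed,
    )


def assign_lines(dataset: ABRDataset, spec: SyntheticSpec) -> pd.DataFrame:
    """(Re-)derive the per-mouse line/zygosity metadata from mouse ids.

    Every mouse gets exactly one line label; controls are labelled
    ``control``.  Returns the metadata frame and attaches it to the dataset.
    """
    mice = sorted(dataset.curves["mouse_id"].unique())
    table = _mouse_table(spec).set_index("mouse_id")
    rows = {}
    for mouse in mice:
        if mouse in table.index:
            rows[mouse] = table.loc[mouse]
        else:
            line = mouse.rsplit("_m", 1)[0]
            rows[mouse] = pd.Series(
                {
                    "line": "control" if line.startswith("ctrl") else line,
                    "zygosity": "control" if line.startswith("ctrl") else "mutant",
                    "measurement_date": "",
                }
            )
    meta = pd.DataFrame(rows).T
    meta.index.name = "mouse_id"
    dataset.metadata = meta
    return meta
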