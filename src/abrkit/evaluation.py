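"""Ground-truth-free comparison of threshold assignments via evaluation curves.

Rationale: curves recorded below an animal's true hearing threshold are
temporally incoherent, so the cross-curve average of sub-threshold curves
flattens towards a constant, while supra-threshold curves share an evoked
waveform that survives averaging.  Sorting all curves of one stimulus by the
threshold-normalised sound level l(i) = SPL(i) / threshold(i) and tracking
the temporal variance S^2(n) of the cumulative mean of the first n curves
yields a curve that stays near zero as long as only genuinely sub-threshold
curves are accumulated.  The better a threshold assignment, the longer the
normalised curve S^2(n)/S^2(N) stays near zero as a function of n/N — no
ground truth needed, only relative comparison intended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ABRDataset, NON_HEARING

__all__ = [
    "ThresholdAssignment",
    "EvaluationCurve",
    "normalized_levels",
    "cumulative_temporal_variance",
    "evaluation_curve",
    "constant_method",
    "curve_area",
]


@dataclass
class ThresholdAssignment:
    """A named map (mouse_id, stimulus) -> threshold (grid dB or 999)."""

    method: str
    thresholds: dict[tuple[str, str], float]

    @classmethod
    def from_frame(cls, method: str, frame: pd.DataFrame) -> "ThresholdAssignment":
        return cls(
            method,
            {
                (str(r.mouse_id), str(r.stimulus)): float(r.threshold)
                for r in frame.itertuples()
            },
        )


@dataclass
class EvaluationCurve:
    method: str
    stimulus: str
    fractions: np.ndarray  # n/N, ascending in (0, 1]
    values: np.ndarray  # S^2(n) / S^2(N), last value exactly 1
    degenerate: bool = False


def normalized_levels(
    curves: pd.DataFrame, assignment: ThresholdAssignment
) -> np.ndarray:
    """Deterministic sort order of curve rows by l(i) = SPL / threshold.

    Sentinels: threshold 999 gives a tiny key (sub-threshold by
    construction); threshold 0 sorts after all finite keys, internally by
    SPL.  Remaining ties break by (SPL, mouse_id).  Returns positional
    indices into ``curves``.
    """
    keys = []
    for pos, r in enumerate(curves.itertuples()):
        k = (str(r.mouse_id), str(r.stimulus))
        if k not in assignment.thresholds:
            raise KeyError(f"no threshold assigned for mouse {k[0]} / stimulus {k[1]}")
        thr = assignment.thresholds[k]
        spl = float(r.sound_level)
        if thr == 0:
            keys.append((1, 0.0, spl, str(r.mouse_id), pos))
        else:
            keys.append((0, spl / thr, spl, str(r.mouse_id), pos))
    keys.sort()
    return np.array([k[-1] for k in keys], dtype=int)


def cumulative_temporal_variance(sorted_samples: np.ndarray) -> np.ndarray:
    """S^2(n) for n = 1..N: temporal variance of the mean of the first n curves.

    The cumulative average is the arithmetic mean over exactly the first n
    curves; the variance is the population variance over the 1000 time
    points (time integrals as sample means).
    """
    x = np.asarray(sorted_samples, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("need a non-empty (N, T) curve stack")
    n = np.arange(1, len(x) + 1)[:, None]
    cummean = np.cumsum(x, axis=0) / n
    return cummean.var(axis=1)


def evaluation_curve(
    dataset: ABRDataset,
    assignment: ThresholdAssignment,
    stimulus: str,
) -> EvaluationCurve:
    """Build the normalised evaluation curve for one stimulus."""
    sel = (dataset.curves["stimulus"] == stimulus).to_numpy()
    sub = dataset.curves[sel].reset_index(drop=True)
    samples = dataset.samples[sel]
    if len(sub) == 0:
        raise ValueError(f"no curves for stimulus {stimulus}")
    order = normalized_levels(sub, assignment)
    s2 = cumulative_temporal_variance(samples[order])
    N = len(s2)
    total = s2[-1]
    degenerate = total == 0
    values = s2 / total if not degenerate else np.zeros_like(s2)
    if not degenerate:
        values[-1] = 1.0  # exact by definition
    return EvaluationCurve(
        method=assignment.method,
        stimulus=stimulus,
        fractions=np.arange(1, N + 1) / N,
        values=values,
        degenerate=bool(degenerate),
    )


def constant_method(dataset: ABRDataset, level: float = 50.0) -> ThresholdAssignment:
    """The "always 50 dB" control assignment (assumed worst reasonable method)."""
    pairs = dataset.curves.groupby(["mouse_id", "stimulus"]).groups.keys()
    return ThresholdAssignment(
        method=f"constant-{level:g}",
        thresholds={(str(m), str(s)): float(level) for m, s in pairs},
    )


def curve_area(curve: EvaluationCurve) -> float:
    """Area under the normalised curve (trapezoid); lower = better method."""
    return float(np.trapezoid(curve.values, curve.fractions))


def curves_to_frame(curves: list[EvaluationCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for f, v in zip(c.fractions, c.values):
            rows.append((c.method, c.stimulus, float(f), float(v)))
    return pd.DataFrame(
        rows, columns=["method", "stimulus", "n_over_N", "normalized_variance"]
    )
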