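"""Accuracy evaluation and the mutant-vs-control candidate-gene effect scan.

Accuracy against manual labels is reported at three match levels — exact,
+-5 dB and +-10 dB — reflecting the 5 dB recording granularity and known
human reader variability.  The non-hearing sentinel 999 only ever matches
itself.

The effect scan compares stimulus-specific thresholds of each mutant line
against controls with two distribution-free measures: Cliff's delta
d = P(mutant > control) - P(mutant < control) in [-1, 1] (effect size, with
conventional margins |d| = 0.147 / 0.33 / 0.474 for small / medium / large)
and a Wilcoxon rank-sum p-value (two-sided, tie-corrected; exact
enumeration for small groups).  Candidate lines must pass p < 0.05 and
|d| > 0.474 (strict inequalities); the sign of d gives the direction of the
threshold change.  999 enters all rank statistics as the largest ordinal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import FULL_GRID, NON_HEARING

__all__ = [
    "EFFECT_MARGINS",
    "accuracy",
    "accuracy_report",
    "confusion_matrix",
    "cliffs_delta",
    "wilcoxon_rank_sum",
    "effect_scan",
    "candidate_filter",
    "summarize_hearing_curves",
    "combine_cohorts",
]

#: |d| margins for small / medium / large effects.
EFFECT_MARGINS: dict[str, float] = {"small": 0.147, "medium": 0.33, "large": 0.474}


def effect_class(d: float) -> str:
    a = abs(d)
    if a > EFFECT_MARGINS["large"]:
        return "large"
    if a > EFFECT_MARGINS["medium"]:
        return "medium"
    if a > EFFECT_MARGINS["small"]:
        return "small"
    return "negligible"


def _matches(labels: np.ndarray, preds: np.ndarray, tolerance_db: float) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    preds = np.asarray(preds, dtype=float)
    both_nh = (labels == NON_HEARING) & (preds == NON_HEARING)
    numeric = (labels != NON_HEARING) & (preds != NON_HEARING)
    return both_nh | (numeric & (np.abs(labels - preds) <= tolerance_db))


def accuracy(labels, predictions, tolerance_db: float = 0) -> float:
    """Fraction of matching pairs at the given tolerance.

    A pair matches iff both are 999, or both are numeric within
    ``tolerance_db``; 999 never matches a numeric value.
    """
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if len(labels) == 0:
        raise ValueError("no label/prediction pairs to compare")
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must align")
    return float(_matches(labels, predictions, tolerance_db).mean())


def accuracy_report(
    labels: pd.DataFrame, predictions: pd.DataFrame
) -> pd.DataFrame:
    """Per-stimulus and overall accuracies at tolerances 0 / 5 / 10 dB.

    Both frames need mouse_id, stimulus, threshold columns; pairs are
    matched on (mouse_id, stimulus).
    """
    merged = labels.merge(
        predictions, on=["mouse_id", "stimulus"], suffixes=("_label", "_pred")
    ).dropna(subset=["threshold_label", "threshold_pred"])
    if merged.empty:
        raise ValueError("no overlapping (mouse, stimulus) pairs")
    rows = []
    groups = [("overall", merged)] + [
        (stim, sub) for stim, sub in merged.groupby("stimulus")
    ]
    for name, sub in groups:
        row = {"stimulus": name, "n": len(sub)}
        for tol in (0, 5, 10):
            row[f"acc_{tol}"] = accuracy(
                sub["threshold_label"], sub["threshold_pred"], tol
            )
        rows.append(row)
    return pd.DataFrame(rows)


def confusion_matrix(labels, predictions, grid=None) -> pd.DataFrame:
    """Counts of manual (rows) vs predicted (columns) thresholds.

    Classes are the recording grid plus the 999 sentinel; marginals sum to
    the pair total.
    """
    classes = [float(g) for g in (FULL_GRID if grid is None else grid)] + [
        float(NON_HEARING)
    ]
    ct = pd.crosstab(
        pd.Series(np.asarray(labels, dtype=float), name="manual"),
        pd.Series(np.asarray(predictions, dtype=float), name="predicted"),
    )
    return ct.reindex(index=classes, columns=classes, fill_value=0)


def cliffs_delta(mutant_values, control_values) -> float:
    """Cliff's delta d = (#{m > c} - #{m < c}) / (n_m n_c).

    Direct pair enumeration for n_m * n_c <= 1e6, rank-based equivalent
    (via the Mann-Whitney U with ties counting 1/2) above.  999 sorts as
    the largest ordinal naturally.
    """
    m = np.asarray(mutant_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(m) == 0 or len(c) == 0:
        raise ValueError("both groups must be non-empty")
    if len(m) * len(c) <= 1_000_000:
        diff = m[:, None] - c[None, :]
        return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)
    u = stats.mannwhitneyu(m, c, alternative="two-sided").statistic
    return float(2.0 * u / (len(m) * len(c)) - 1.0)


def _exact_rank_sum_p(m: np.ndarray, c: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of group assignments.

    Uses midranks (tie-aware).  p = fraction of the C(n, n_m) assignments
    whose rank-sum deviates from its mean by at least as much as observed.
    """
    pooled = np.concatenate([m, c])
    ranks = stats.rankdata(pooled)
    n, nm = len(pooled), len(m)
    w_obs = ranks[:nm].sum()
    mean_w = nm * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    hits = 0
    for idx in combinations(range(n), nm):
        if abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-12:
            hits += 1
    return hits / comb(n, nm)


def wilcoxon_rank_sum(mutant_values, control_values) -> float:
    """Two-sided Wilcoxon rank-sum p-value with tie correction.

    Exact enumeration when the pooled sample has at most 12 values,
    tie-corrected normal approximation above.  All values tied gives p = 1.
    """
    m = np.asarray(mutant_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(m) == 0 or len(c) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([m, c])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(m) + len(c) <= 12:
        return float(_exact_rank_sum_p(m, c))
    res = stats.mannwhitneyu(m, c, alternative="two-sided", use_continuity=False)
    return float(res.pvalue)


@dataclass
class EffectResult:
    line: str
    stimulus: str
    cliffs_delta: float
    p_value: float
    n_mutant: int
    n_control: int
    effect: str


def effect_scan(
    thresholds: pd.DataFrame,
    metadata: pd.DataFrame,
    control_policy: str = "all_controls",
) -> pd.DataFrame:
    """Cliff's delta + Wilcoxon p per mutant line x stimulus vs controls.

    ``thresholds``: mouse_id, stimulus, threshold.  ``metadata``: indexed by
    mouse_id with line, zygosity and (for the ``same_day`` policy)
    measurement_date columns.  Mice without a line label and, under
    ``same_day``, lines without matching-date controls are excluded with a
    warning.
    """
    import warnings

    if control_policy not in ("same_day", "all_controls"):
        raise ValueError("control_policy must be same_day|all_controls")
    df = thresholds.merge(
        metadata.reset_index()[
            [c for c in ("mouse_id", "line", "zygosity", "measurement_date")
             if c in metadata.reset_index().columns]
        ],
        on="mouse_id",
        how="left",
    )
    n_unlabelled = int(df["line"].isna().sum())
    if n_unlabelled:
        warnings.warn(f"excluding {n_unlabelled} rows without valid line label")
        df = df.dropna(subset=["line"])
    if control_policy == "same_day" and (
        "measurement_date" not in df.columns or df["measurement_date"].isna().all()
    ):
        warnings.warn("no measurement dates available; falling back to all_controls")
        control_policy = "all_controls"

    controls = df[df["zygosity"] == "control"]
    rows = []
    lines = sorted(l for l in df["line"].unique() if l != "control")
    for line in lines:
        mut = df[df["line"] == line]
        if control_policy == "same_day":
            dates = set(mut["measurement_date"].dropna())
            ctl = controls[controls["measurement_date"].isin(dates)]
            if ctl.empty:
                warnings.warn(f"line {line}: no same-day controls; skipped")
                continue
        else:
            ctl = controls
        for stim in sorted(mut["stimulus"].unique()):
            mv = mut.loc[mut["stimulus"] == stim, "threshold"].dropna().to_numpy()
            cv = ctl.loc[ctl["stimulus"] == stim, "threshold"].dropna().to_numpy()
            if len(mv) == 0 or len(cv) == 0:
                continue
            d = cliffs_delta(mv, cv)
            p = wilcoxon_rank_sum(mv, cv)
            rows.append(
                EffectResult(line, stim, d, p, len(mv), len(cv), effect_class(d))
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def candidate_filter(
    effects: pd.DataFrame, p_max: float = 0.05, d_min: float = EFFECT_MARGINS["large"]
) -> pd.DataFrame:
    """Lines passing p < p_max and |d| > d_min (strict), with direction."""
    if effects.empty:
        return effects.assign(direction=pd.Series(dtype=str))
    keep = (effects["p_value"] < p_max) & (effects["cliffs_delta"].abs() > d_min)
    out = effects[keep].copy()
    out["direction"] = np.where(
        out["cliffs_delta"] > 0, "higher threshold", "lower threshold"
    )
    return out.reset_index(drop=True)


def _ordinal_percentile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile with 999 as the largest ordinal."""
    return float(np.percentile(np.asarray(values, dtype=float), q))


def summarize_hearing_curves(
    thresholds: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Median hearing curves per line x stimulus with IQR and control ribbon.

    Medians and percentiles treat 999 as the largest ordinal; a group whose
    median lands at 999 reports non-hearing.  The control ribbon is the
    [5; 95] percentile range of all control animals (linear interpolation
    between order statistics).
    """
    df = thresholds.merge(
        metadata.reset_index()[["mouse_id", "line", "zygosity"]],
        on="mouse_id",
        how="inner",
    ).dropna(subset=["threshold"])
    controls = df[df["zygosity"] == "control"]
    rows = []
    for (line, stim), sub in df.groupby(["line", "stimulus"]):
        v = sub["threshold"].to_numpy(dtype=float)
        ctl = controls.loc[controls["stimulus"] == stim, "threshold"].to_numpy(dtype=float)
        rows.append(
            {
                "line": line,
                "stimulus": stim,
                "n": len(v),
                "median": _ordinal_percentile(v, 50),
                "q25": _ordinal_percentile(v, 25),
                "q75": _ordinal_percentile(v, 75),
                "control_p5": _ordinal_percentile(ctl, 5) if len(ctl) else np.nan,
                "control_p95": _ordinal_percentile(ctl, 95) if len(ctl) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def combine_cohorts(summaries: list[dict], n_shared_genes: int = 0) -> dict:
    """Combine per-dataset cohort counts into screen-wide totals.

    Each summary carries ``n_mutants``, ``n_controls`` and
    ``n_distinct_genes``; genes present in several datasets are counted
    once via ``n_shared_genes`` (inclusion-exclusion for two sets).
    """
    total_mutants = sum(s["n_mutants"] for s in summaries)
    total_controls = sum(s["n_controls"] for s in summaries)
    distinct = sum(s["n_distinct_genes"] for s in summaries) - n_shared_genes
    return {
        "n_mice": total_mutants + total_controls,
        "n_mutants": total_mutants,
        "n_controls": total_controls,
        "n_distinct_genes": distinct,
    }
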