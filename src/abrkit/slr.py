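"""Self-supervised Sound Level Regression (SLR) hearing-threshold estimation.

The method needs no manual labels.  Per stimulus:

Step A — *sound-level estimation*.  Each averaged curve is mapped to the
power of its lowest 50 Fourier components; a random-forest regressor,
embedded in a five-fold grouped (per-mouse) cross-validation, predicts the
stimulus SPL of every curve from curves of *other* mice.  Below the hearing
threshold the curve carries no information about the stimulus, so predicted
levels fluctuate around a constant; above threshold they track the actual
level.

Step B — *breakpoint search*.  Per mouse, the predicted-vs-actual relation
is fitted with a piecewise model — constant up to a breakpoint b, plus a
quartic polynomial in (x - b) above it — by elastic net with internal
cross-validation.  Candidate breakpoints are the 5 dB grid levels between a
lower bound (first increase of an isotonic fit) and an upper bound (largest
level with significant positive rank correlation above it, Bonferroni
corrected); the candidate with least CV error wins and is refined by
+-0.5 dB.  The threshold is the first recorded grid level at which the
polynomial part exceeds the constant by more than 4 dB; if the correlation
test never fires, or the 4 dB deviation never occurs within the measured
range, the animal is called non-hearing (999).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .io import ABRDataset, GRID_STEP, NON_HEARING, N_SAMPLES, StimulusBlock, get_stimulus_blocks

__all__ = [
    "SLRConfig",
    "PiecewiseFit",
    "SLRResult",
    "extract_spectral_features",
    "predict_sound_levels",
    "upper_bound",
    "lower_bound",
    "fit_piecewise",
    "select_breakpoint",
    "threshold_from_fit",
    "estimate_thresholds",
    "SoundLevelRegressionThresholder",
]


@dataclass
class SLRConfig:
    """Tunable parameters of the SLR pipeline.

    ``n_features``: retained low-frequency power-spectrum components.
    ``include_dc``: include the DC bin as the first feature (default off;
    curves are mean-centred so it would be zero anyway).
    ``upper_bound_rule``: ``significant`` takes the largest level whose
    above-level rank correlation is significantly positive after Bonferroni
    correction; ``nonsignificant`` takes the largest level whose corrected
    p-value exceeds alpha (an alternative reading of the bound).
    """

    n_features: int = 50
    include_dc: bool = False
    n_folds: int = 5
    rf_trees: int = 100
    l1_ratios: tuple[float, ...] = (0.5, 0.99)
    n_alphas: int = 30
    poly_degree: int = 4
    deviation_db: float = 4.0
    refine_offset_db: float = 0.5
    alpha_corr: float = 0.05
    grid_step_db: float = GRID_STEP
    scan_step_db: float = 0.1
    upper_bound_rule: str = "significant"
    min_points: int = 8

    def validate(self) -> None:
        if not (1 <= self.n_features <= 500):
            raise ValueError("n_features must be in [1, 500]")
        if self.deviation_db <= 0:
            raise ValueError("deviation_db must be > 0")
        if self.upper_bound_rule not in ("significant", "nonsignificant"):
            raise ValueError("upper_bound_rule must be significant|nonsignificant")


@dataclass
class PiecewiseFit:
    """Constant-plus-quartic breakpoint model of predicted vs actual SPL.

    f(x) = c for x <= b; f(x) = c + sum_k a_k (x-b)^k for x > b.  Continuous
    at b by construction.  ``cv_error`` is the mean squared cross-validation
    residual of the elastic-net fit (dB^2).
    """

    breakpoint: float
    const: float
    coeffs: np.ndarray
    cv_error: float

    def deviation(self, x: np.ndarray) -> np.ndarray:
        """f(x) - c (zero at and below the breakpoint)."""
        h = np.maximum(np.asarray(x, dtype=float) - self.breakpoint, 0.0)
        return sum(a * h ** (k + 1) for k, a in enumerate(self.coeffs))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.const + self.deviation(x)


@dataclass
class SLRResult:
    mouse_id: str
    stimulus: str
    threshold: float
    lower_bound: float | None = None
    upper_bound: float | None = None
    best_fit: PiecewiseFit | None = None
    candidates: list[float] = field(default_factory=list)
    candidate_cv_errors: list[float] = field(default_factory=list)
    error: str | None = None


def extract_spectral_features(samples: np.ndarray, config: SLRConfig | None = None) -> np.ndarray:
    """Low-frequency power-spectrum features of one curve or a stack.

    The curve is mean-centred, discrete-Fourier transformed, and the squared
    magnitudes of bins 1..n_features (or 0..n_features-1 with
    ``include_dc``) are returned.  An all-constant curve maps to the zero
    vector.
    """
    config = config or SLRConfig()
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[1] != N_SAMPLES:
        raise ValueError(f"curves must have {N_SAMPLES} samples")
    centred = x - x.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(centred, axis=1)) ** 2
    start = 0 if config.include_dc else 1
    out = spec[:, start : start + config.n_features]
    return out[0] if np.asarray(samples).ndim == 1 else out


def _fold_assignment(mouse_ids: Sequence[str], n_folds: int, seed: int) -> dict[str, int]:
    """Deterministic grouped folds: canonical sort, seeded shuffle, round-robin."""
    mice = sorted(set(map(str, mouse_ids)))
    if len(mice) < n_folds:
        raise ValueError(
            f"{len(mice)} mice < {n_folds} folds; lower n_folds to at most {len(mice)}"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(mice))
    return {m: i % n_folds for i, m in enumerate(order)}


def predict_sound_levels(
    blocks: Sequence[StimulusBlock],
    config: SLRConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold SPL predictions for all curves of one stimulus.

    Mice are partitioned into ``n_folds`` groups; each curve's prediction
    comes from a random forest trained only on curves of mice outside its
    group.  Returns a frame with mouse_id, sound_level, predicted, fold.
    """
    config = config or SLRConfig()
    config.validate()
    if not blocks:
        raise ValueError("no blocks given")
    stimuli = {b.stimulus for b in blocks}
    if len(stimuli) > 1:
        raise ValueError(f"blocks span multiple stimuli: {sorted(stimuli)}")
    folds = _fold_assignment([b.mouse_id for b in blocks], config.n_folds, seed)

    feats, spls, mice = [], [], []
    for b in blocks:
        feats.append(extract_spectral_features(b.samples, config))
        spls.append(b.spls)
        mice.extend([b.mouse_id] * len(b))
    X = np.vstack(feats)
    y = np.concatenate(spls)
    mice = np.asarray(mice)
    fold_of = np.asarray([folds[m] for m in mice])

    predicted = np.empty(len(y))
    for k in range(config.n_folds):
        test = fold_of == k
        rf = RandomForestRegressor(
            n_estimators=config.rf_trees, random_state=seed, n_jobs=1
        )
        rf.fit(X[~test], y[~test])
        predicted[test] = rf.predict(X[test])

    return pd.DataFrame(
        {
            "mouse_id": mice,
            "sound_level": y,
            "predicted": predicted,
            "fold": fold_of,
        }
    )


_EXACT_RHO_NULL: dict[int, np.ndarray] = {}


def _spearman_p_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (positive) Spearman p-value.

    The t-approximation degenerates for tiny samples (a perfect ordering of
    three points would give p = 0 although its null probability is 1/6), so
    for n <= 8 without ties the exact permutation distribution of rho is
    used (cached per n); otherwise the usual approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        return 1.0
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        return 1.0
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 8 and tie_free:
        if n not in _EXACT_RHO_NULL:
            from itertools import permutations

            ident = np.arange(n)
            rhos = np.array(
                [
                    1 - 6 * np.sum((np.array(p) - ident) ** 2) / (n * (n * n - 1))
                    for p in permutations(range(n))
                ]
            )
            _EXACT_RHO_NULL[n] = np.sort(rhos)
        null = _EXACT_RHO_NULL[n]
        return float((null >= rho - 1e-12).mean())
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(stats.spearmanr(x, y, alternative="greater").pvalue)


def upper_bound(
    actual: np.ndarray,
    predicted: np.ndarray,
    alpha_corr: float = 0.05,
    rule: str = "significant",
) -> float | None:
    """Upper search bound from above-level rank-correlation tests.

    For every candidate level L with at least three distinct actual levels
    strictly above it, a one-sided Spearman test of positive correlation
    between actual and predicted SPL (restricted to actual > L) is run;
    p-values are Bonferroni-corrected over the candidates tested.  Under the
    default ``significant`` rule the largest significant L is returned;
    None means no candidate fired (non-hearing downstream).
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    levels = np.unique(actual)
    candidates = [L for L in levels if np.unique(actual[actual > L]).size >= 3]
    if not candidates:
        return None
    pvals = {}
    for L in candidates:
        sel = actual > L
        pvals[L] = _spearman_p_greater(actual[sel], predicted[sel])
    m = len(candidates)
    if rule == "significant":
        sig = [L for L in candidates if pvals[L] * m < alpha_corr]
        return max(sig) if sig else None
    nonsig = [L for L in candidates if pvals[L] * m > alpha_corr]
    return max(nonsig) if nonsig else None


def lower_bound(
    actual: np.ndarray,
    predicted: np.ndarray,
    grid_step: float = GRID_STEP,
    tol: float = 1e-9,
) -> float:
    """Conservative lower bound: first increase of an isotonic fit.

    Predictions are mean-aggregated per actual level, fitted with a
    non-decreasing step function; the bound is one grid step below the first
    level whose fitted value strictly exceeds the fitted value at the lowest
    level, floored at the lowest measured level.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    levels = np.unique(actual)
    means = np.array([predicted[actual == L].mean() for L in levels])
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(levels, means)
    rises = np.flatnonzero(fitted > fitted[0] + tol)
    if rises.size == 0:
        return float(levels[0])
    return float(max(levels[rises[0]] - grid_step, levels[0]))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def fit_piecewise(
    actual: np.ndarray,
    predicted: np.ndarray,
    breakpoint: float,
    config: SLRConfig | None = None,
    seed: int = 0,
) -> PiecewiseFit:
    """Elastic-net fit of the constant + quartic breakpoint model.

    Design features h_k(x) = max(x - b, 0)^k, k = 1..4, standardized; the
    unpenalised intercept is the constant part c.  Regularisation strength
    is chosen by internal 5-fold CV over the configured l1 ratios;
    ``cv_error`` is the mean squared CV residual at the chosen setting.
    """
    config = config or SLRConfig()
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(actual) < config.min_points:
        raise ValueError(f"need >= {config.min_points} points for the piecewise fit")
    order = np.lexsort((predicted, actual))
    actual, predicted = actual[order], predicted[order]

    h = np.maximum(actual - breakpoint, 0.0)
    X = np.column_stack([h ** k for k in range(1, config.poly_degree + 1)])
    Xs, mu, sd = _standardize(X)
    cv = KFold(n_splits=5, shuffle=True, random_state=seed % (2 ** 31))
    enet = ElasticNetCV(
        l1_ratio=list(config.l1_ratios),
        alphas=config.n_alphas,
        cv=cv,
        max_iter=20000,
        random_state=seed % (2 ** 31),
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        enet.fit(Xs, predicted)

    l1_list = list(np.atleast_1d(config.l1_ratios))
    if len(l1_list) > 1:
        li = int(np.argmin([abs(l - enet.l1_ratio_) for l in l1_list]))
        alphas = enet.alphas_[li]
        mse = enet.mse_path_[li]
    else:
        alphas = enet.alphas_
        mse = enet.mse_path_
    ai = int(np.argmin(np.abs(alphas - enet.alpha_)))
    cv_error = float(mse[ai].mean())

    coeffs = enet.coef_ / sd
    const = float(enet.intercept_ - np.sum(enet.coef_ * mu / sd))
    return PiecewiseFit(
        breakpoint=float(breakpoint),
        const=const,
        coeffs=np.asarray(coeffs, dtype=float),
        cv_error=cv_error,
    )


def select_breakpoint(
    actual: np.ndarray,
    predicted: np.ndarray,
    lower: float,
    upper: float,
    config: SLRConfig | None = None,
    seed: int = 0,
) -> tuple[PiecewiseFit, list[float], list[float]]:
    """Grid search over 5 dB candidate breakpoints plus +-0.5 dB refinement.

    All grid candidates in [lower, upper] are fitted; the CV-error minimiser
    wins (ties toward the larger breakpoint); then b +- 0.5 dB are fitted and
    whichever of the three has least CV error is adopted.  Returns the best
    fit together with the candidate grid and per-candidate CV errors.
    """
    config = config or SLRConfig()
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    step = config.grid_step_db
    candidates = list(np.arange(lower, upper + step / 2, step))
    if not candidates:
        raise ValueError("empty breakpoint candidate set")
    fits = [fit_piecewise(actual, predicted, b, config, seed) for b in candidates]
    errors = [f.cv_error for f in fits]
    best = max(
        range(len(fits)), key=lambda i: (-errors[i], candidates[i])
    )  # min error, ties -> larger b
    chosen = fits[best]
    tried_b = list(candidates)
    tried_e = list(errors)
    for off in (-config.refine_offset_db, config.refine_offset_db):
        b = chosen.breakpoint + off
        refined = fit_piecewise(actual, predicted, b, config, seed)
        tried_b.append(b)
        tried_e.append(refined.cv_error)
        if refined.cv_error < chosen.cv_error or (
            refined.cv_error == chosen.cv_error and b > chosen.breakpoint
        ):
            chosen = refined
    return chosen, tried_b, tried_e


def threshold_from_fit(
    fit: PiecewiseFit, spl_grid: np.ndarray, config: SLRConfig | None = None
) -> float:
    """Apply the 4 dB deviation rule and snap up to the recorded grid.

    Scans from the breakpoint at 0.1 dB resolution for the first point where
    the polynomial part exceeds the constant by more than ``deviation_db``;
    reports the smallest recorded grid level at or above it, or 999 if the
    deviation never occurs within the measured range.
    """
    config = config or SLRConfig()
    grid = np.asarray(spl_grid, dtype=float)
    xs = np.arange(fit.breakpoint, grid[-1] + config.scan_step_db / 2, config.scan_step_db)
    dev = fit.deviation(xs)
    hit = np.flatnonzero(dev > config.deviation_db)
    if hit.size == 0:
        return float(NON_HEARING)
    x_star = xs[hit[0]]
    at_or_above = grid[grid >= x_star - 1e-9]
    if at_or_above.size == 0:
        return float(NON_HEARING)
    return float(at_or_above[0])


def estimate_thresholds(
    dataset: ABRDataset,
    config: SLRConfig | None = None,
    seed: int = 0,
) -> list[SLRResult]:
    """Run the full SLR pipeline on every stimulus of a dataset.

    Self-supervised: manual threshold labels are never read.  Per-mouse
    failures are returned as flagged results, never abort the batch.
    """
    config = config or SLRConfig()
    config.validate()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    results: list[SLRResult] = []
    for stim in dataset.stimuli:
        blocks = get_stimulus_blocks(dataset, stim)
        preds = predict_sound_levels(blocks, config, seed)
        for block in blocks:
            sub = preds[preds["mouse_id"] == block.mouse_id]
            actual = sub["sound_level"].to_numpy()
            predicted = sub["predicted"].to_numpy()
            try:
                ub = upper_bound(
                    actual, predicted, config.alpha_corr, config.upper_bound_rule
                )
                if ub is None:
                    results.append(
                        SLRResult(block.mouse_id, stim, float(NON_HEARING),
                                  lower_bound=None, upper_bound=None)
                    )
                    continue
                lb = lower_bound(actual, predicted, config.grid_step_db)
                lo, hi = min(lb, ub), max(lb, ub)
                fit, cand, cand_err = select_breakpoint(
                    actual, predicted, lo, hi, config, seed
                )
                thr = threshold_from_fit(fit, block.spls, config)
                results.append(
                    SLRResult(
                        block.mouse_id,
                        stim,
                        thr,
                        lower_bound=lo,
                        upper_bound=hi,
                        best_fit=fit,
                        candidates=cand,
                        candidate_cv_errors=cand_err,
                    )
                )
            except Exception as exc:  # pragma: no cover - defensive batch path
                results.append(
                    SLRResult(
                        block.mouse_id, stim, float("nan"), error=str(exc)
                    )
                )
    return results


def results_to_frame(results: Sequence[SLRResult]) -> pd.DataFrame:
    """Tabulate SLR results (one row per mouse x stimulus)."""
    rows = []
    for r in results:
        rows.append(
            {
                "mouse_id": r.mouse_id,
                "stimulus": r.stimulus,
                "threshold": r.threshold,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "breakpoint": r.best_fit.breakpoint if r.best_fit else np.nan,
                "cv_error": r.best_fit.cv_error if r.best_fit else np.nan,
                "error": r.error,
            }
        )
    return pd.DataFrame(rows)


class SoundLevelRegressionThresholder(BaseEstimator):
    """Sklearn-style estimator wrapping the SLR pipeline.

    ``fit`` runs the self-supervised estimation on an :class:`ABRDataset`
    (labels, if present, are ignored); fitted attributes expose the results.

    Parameters mirror :class:`SLRConfig`; ``random_state`` seeds the fold
    assignment, the random forests and the elastic-net CV splits.
    """

    def __init__(
        self,
        n_features: int = 50,
        include_dc: bool = False,
        n_folds: int = 5,
        rf_trees: int = 100,
        l1_ratios: tuple[float, ...] = (0.5, 0.99),
        n_alphas: int = 30,
        deviation_db: float = 4.0,
        alpha_corr: float = 0.05,
        upper_bound_rule: str = "significant",
        random_state: int = 0,
    ) -> None:
        self.n_features = n_features
        self.include_dc = include_dc
        self.n_folds = n_folds
        self.rf_trees = rf_trees
        self.l1_ratios = l1_ratios
        self.n_alphas = n_alphas
        self.deviation_db = deviation_db
        self.alpha_corr = alpha_corr
        self.upper_bound_rule = upper_bound_rule
        self.random_state = random_state

    def _config(self) -> SLRConfig:
        return SLRConfig(
            n_features=self.n_features,
            include_dc=self.include_dc,
            n_folds=self.n_folds,
            rf_trees=self.rf_trees,
            l1_ratios=tuple(self.l1_ratios),
            n_alphas=self.n_alphas,
            deviation_db=self.deviation_db,
            alpha_corr=self.alpha_corr,
            upper_bound_rule=self.upper_bound_rule,
        )

    def fit(self, dataset: ABRDataset, y=None) -> "SoundLevelRegressionThresholder":
        self.results_ = estimate_thresholds(dataset, self._config(), self.random_state)
        self.thresholds_ = results_to_frame(self.results_)
        return self

    def predict(self, dataset: ABRDataset | None = None) -> pd.DataFrame:
        """Thresholds for a dataset (re-runs the pipeline if one is given)."""
        if dataset is not None:
            return results_to_frame(
                estimate_thresholds(dataset, self._config(), self.random_state)
            )
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("call fit first or pass a dataset")
        return self.thresholds_[["mouse_id", "stimulus", "threshold"]]
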