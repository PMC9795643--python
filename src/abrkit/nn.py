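"""Supervised two-stage neural-network hearing-threshold classification.

Model I is a per-curve classifier: given one 1000-sample averaged curve
(per-curve standardized) it scores whether an evoked response is present.
Its training labels are derived from the manual threshold: curves at or
above the threshold SPL are "response" (1), sub-threshold curves are "no
response" (0); a 999 (non-hearing) threshold labels every curve 0.
Measurements whose label was re-validated with an "agree" verdict are
weighted higher.

Model II is a per-stimulus classifier mapping the stack of Model I class
scores — placed on the full 0-85 dB grid (18 slots, unmeasured slots
masked) — to a threshold class on the grid or 999.

Training and prediction follow a five-fold grouped cross-validation with
mice as groups: mice are split 4:1 into training and test, and the training
mice again 4:1 into training and validation.  No curve of a test mouse ever
enters the training of the fold that scores it.

Both models are small multilayer perceptrons with configurable
architecture (the published architecture is replaceable via
:class:`NNConfig`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neural_network import MLPClassifier

from .io import (
    ABRDataset,
    FULL_GRID,
    GRID_STEP,
    NON_HEARING,
    N_SAMPLES,
    StimulusBlock,
    get_stimulus_blocks,
)

__all__ = [
    "NNConfig",
    "FoldSplit",
    "ScoreVector",
    "derive_curve_labels",
    "make_fold_splits",
    "train_model_I",
    "assemble_score_vectors",
    "train_model_II",
    "predict_thresholds_nn",
    "TwoStageNNThresholder",
]

N_SLOTS = len(FULL_GRID)  # 18
MASK_FILL = -1.0


@dataclass
class NNConfig:
    """Hyperparameters of both models.

    ``model1_hidden``/``model2_hidden`` are MLP hidden-layer sizes;
    ``agree_weight`` up-weights curves whose manual label was re-validated
    with an "agree" verdict (realised by row replication, rounded);
    ``inner_folds`` controls the inner grouped split used to produce
    out-of-fold Model I scores for Model II training.
    """

    model1_hidden: tuple[int, ...] = (32, 16)
    model2_hidden: tuple[int, ...] = (32,)
    model1_max_iter: int = 60
    model2_max_iter: int = 400
    batch_size: int = 128
    learning_rate_init: float = 1e-3
    agree_weight: float = 2.0
    n_folds: int = 5
    inner_folds: int = 3
    model2_scores: str = "out_of_fold"  # or "in_fold"
    seed: int = 0

    def validate(self) -> None:
        if self.model1_max_iter < 1 or self.model2_max_iter < 1:
            raise ValueError("epochs must be >= 1")
        if self.model2_scores not in ("out_of_fold", "in_fold"):
            raise ValueError("model2_scores must be out_of_fold|in_fold")


@dataclass
class FoldSplit:
    """Disjoint mouse-level train/validation/test assignment for one fold."""

    train: list[str]
    validation: list[str]
    test: list[str]

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set.union(*groups)) != total:
            raise ValueError("train/validation/test groups must be disjoint")


@dataclass
class ScoreVector:
    """Model I class scores of one mouse x stimulus on the full 0-85 grid.

    ``scores`` has 18 slots in [0, 1] where measured and the fill value -1
    where not; ``mask`` is 1 for measured slots.
    """

    mouse_id: str
    stimulus: str
    scores: np.ndarray
    mask: np.ndarray

    def features(self) -> np.ndarray:
        """Concatenated (scores, mask) input for Model II (36 values)."""
        return np.concatenate([self.scores, self.mask.astype(float)])


def derive_curve_labels(
    block: StimulusBlock,
    threshold: float,
    validation_flag: str | None = None,
    agree_weight: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-curve response labels and weights from a manual threshold.

    Label 1 iff the curve's SPL is at or above the threshold; a 999
    threshold labels everything 0.  Weight = ``agree_weight`` when the
    measurement was re-validated "agree", else 1.
    """
    if threshold == NON_HEARING:
        labels = np.zeros(len(block), dtype=int)
    else:
        labels = (block.spls >= threshold).astype(int)
    w = agree_weight if validation_flag == "agree" else 1.0
    return labels, np.full(len(block), w)


def make_fold_splits(
    mouse_ids: Sequence[str], seed: int = 0, n_folds: int = 5
) -> list[FoldSplit]:
    """Grouped 5-fold splits: test 1/5 of mice, then validation 1/5 of the rest.

    Deterministic given the seed; every mouse is a test mouse in exactly one
    fold.
    """
    mice = sorted(set(map(str, mouse_ids)))
    if len(mice) < 5 * n_folds:
        raise ValueError(
            f"need >= {5 * n_folds} mice for {n_folds} folds with non-empty "
            f"validation cells, got {len(mice)}"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(mice))
    tests = [order[k::n_folds] for k in range(n_folds)]
    splits = []
    for k in range(n_folds):
        rest = [m for m in order if m not in set(tests[k])]
        rest = list(np.random.default_rng(seed + 1000 + k).permutation(rest))
        n_val = max(1, round(len(rest) / 5))
        splits.append(
            FoldSplit(
                train=sorted(rest[n_val:]),
                validation=sorted(rest[:n_val]),
                test=sorted(tests[k]),
            )
        )
    return splits


def _standardize_curves(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _replicate_by_weight(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    reps = np.maximum(np.round(w).astype(int), 1)
    return np.repeat(X, reps, axis=0), np.repeat(y, reps)


def train_model_I(
    curves: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
    config: NNConfig | None = None,
) -> MLPClassifier:
    """Train the per-curve response-presence classifier.

    ``curves`` is (n, 1000); inputs are per-curve standardized.  Both
    classes must be present.
    """
    config = config or NNConfig()
    config.validate()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("Model I training data contains a single class")
    X = _standardize_curves(curves)
    if weights is not None:
        X, labels = _replicate_by_weight(X, labels, np.asarray(weights))
    clf = MLPClassifier(
        hidden_layer_sizes=config.model1_hidden,
        max_iter=config.model1_max_iter,
        batch_size=config.batch_size,
        learning_rate_init=config.learning_rate_init,
        random_state=config.seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        clf.fit(X, labels)
    return clf


def score_curves(model_I: MLPClassifier, curves: np.ndarray) -> np.ndarray:
    """Class-1 ("response present") scores in [0, 1] for a curve stack."""
    X = _standardize_curves(curves)
    proba = model_I.predict_proba(X)
    one = int(np.flatnonzero(model_I.classes_ == 1)[0])
    return proba[:, one]


def assemble_score_vectors(
    blocks: Sequence[StimulusBlock], model_I: MLPClassifier
) -> list[ScoreVector]:
    """Place Model I scores at their SPL slots on the full 0-85 dB grid.

    Unmeasured slots get fill value -1 with the mask bit cleared; an empty
    block yields a fully masked vector.
    """
    vectors = []
    slot_of = {float(s): i for i, s in enumerate(FULL_GRID)}
    for b in blocks:
        scores = np.full(N_SLOTS, MASK_FILL)
        mask = np.zeros(N_SLOTS, dtype=int)
        if len(b):
            s = score_curves(model_I, b.samples)
            for spl, val in zip(b.spls, s):
                i = slot_of[float(spl)]
                scores[i] = val
                mask[i] = 1
        vectors.append(ScoreVector(b.mouse_id, b.stimulus, scores, mask))
    return vectors


def train_model_II(
    vectors: Sequence[ScoreVector],
    thresholds: Mapping[tuple[str, str], float] | Sequence[float],
    config: NNConfig | None = None,
) -> MLPClassifier:
    """Train the per-stimulus threshold classifier on score vectors.

    Classes are the observed threshold values (grid levels and/or 999).  At
    least two classes must be present.
    """
    config = config or NNConfig()
    config.validate()
    if isinstance(thresholds, Mapping):
        y = np.array([thresholds[(v.mouse_id, v.stimulus)] for v in vectors])
    else:
        y = np.asarray(list(thresholds), dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("Model II training data contains a single class")
    X = np.vstack([v.features() for v in vectors])
    clf = MLPClassifier(
        hidden_layer_sizes=config.model2_hidden,
        max_iter=config.model2_max_iter,
        batch_size=min(config.batch_size, len(y)),
        learning_rate_init=config.learning_rate_init,
        random_state=config.seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        clf.fit(X, y.astype(int))
    return clf


def _collect_curves(
    blocks: Sequence[StimulusBlock], mice: set[str], agree_weight: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack labelled curves of the given mice across blocks."""
    xs, ys, ws = [], [], []
    for b in blocks:
        if b.mouse_id not in mice or b.threshold is None:
            continue
        labels, w = derive_curve_labels(b, b.threshold, b.validation, agree_weight)
        xs.append(b.samples)
        ys.append(labels)
        ws.append(w)
    if not xs:
        return np.empty((0, N_SAMPLES)), np.empty(0, int), np.empty(0)
    return np.vstack(xs), np.concatenate(ys), np.concatenate(ws)


def _fit_fold(
    blocks_by_stim: dict[str, list[StimulusBlock]],
    split: FoldSplit,
    config: NNConfig,
) -> tuple[MLPClassifier, dict[str, MLPClassifier]]:
    """Train Model I on the fold's training mice and Model II per stimulus.

    Model I sees only the training mice.  Model II consumes out-of-fold
    Model I scores: inner grouped-split scores for the training mice plus
    the validation mice scored by the (to them out-of-sample) Model I, so
    its inputs match the test-time distribution.
    """
    all_blocks = [b for bs in blocks_by_stim.values() for b in bs]
    train_mice = sorted(split.train)
    X, y, w = _collect_curves(all_blocks, set(train_mice), config.agree_weight)
    model_I = train_model_I(X, y, w, config)

    score_model_of = {m: model_I for m in split.validation}
    if config.model2_scores == "in_fold":
        score_model_of.update({m: model_I for m in train_mice})
    else:
        rng = np.random.default_rng(config.seed + 7)
        order = list(rng.permutation(train_mice))
        for g in range(config.inner_folds):
            held = set(order[g :: config.inner_folds])
            rest = set(train_mice) - held
            Xg, yg, wg = _collect_curves(all_blocks, rest, config.agree_weight)
            aux = train_model_I(Xg, yg, wg, config)
            for m in held:
                score_model_of[m] = aux

    model_II: dict[str, MLPClassifier] = {}
    for stim, blocks in blocks_by_stim.items():
        vecs, thr = [], []
        for b in blocks:
            if b.mouse_id in score_model_of and b.threshold is not None:
                (v,) = assemble_score_vectors([b], score_model_of[b.mouse_id])
                vecs.append(v)
                thr.append(b.threshold)
        model_II[stim] = train_model_II(vecs, thr, config)
    return model_I, model_II


def predict_thresholds_nn(
    dataset: ABRDataset,
    models: Sequence[tuple[MLPClassifier, dict[str, MLPClassifier]]],
    splits: Sequence[FoldSplit],
) -> pd.DataFrame:
    """Out-of-fold threshold predictions: each mouse by the fold testing it.

    Mice absent from every test set are returned flagged (NaN threshold),
    never silently dropped.
    """
    fold_of = {}
    for k, s in enumerate(splits):
        for m in s.test:
            fold_of[m] = k
    rows = []
    for stim in dataset.stimuli:
        blocks = get_stimulus_blocks(dataset, stim)
        for b in blocks:
            k = fold_of.get(b.mouse_id)
            if k is None:
                rows.append((b.mouse_id, stim, np.nan, "not in any test set"))
                continue
            model_I, model_II = models[k]
            (v,) = assemble_score_vectors([b], model_I)
            pred = float(model_II[stim].predict(v.features()[None, :])[0])
            rows.append((b.mouse_id, stim, pred, None))
    return pd.DataFrame(rows, columns=["mouse_id", "stimulus", "threshold", "flag"])


class TwoStageNNThresholder(BaseEstimator):
    """Sklearn-style estimator for the supervised two-stage pipeline.

    ``fit(dataset)`` trains per-fold Model I / Model II pairs on the
    dataset's manual labels under grouped five-fold cross-validation and
    stores out-of-fold predictions in ``oof_predictions_``.
    ``predict(dataset)`` scores new data with the per-fold models (Model I
    scores averaged, Model II majority vote).
    """

    def __init__(
        self,
        model1_hidden: tuple[int, ...] = (32, 16),
        model2_hidden: tuple[int, ...] = (32,),
        model1_max_iter: int = 60,
        model2_max_iter: int = 400,
        agree_weight: float = 2.0,
        model2_scores: str = "out_of_fold",
        inner_folds: int = 3,
        random_state: int = 0,
    ) -> None:
        self.model1_hidden = model1_hidden
        self.model2_hidden = model2_hidden
        self.model1_max_iter = model1_max_iter
        self.model2_max_iter = model2_max_iter
        self.agree_weight = agree_weight
        self.model2_scores = model2_scores
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _config(self) -> NNConfig:
        return NNConfig(
            model1_hidden=tuple(self.model1_hidden),
            model2_hidden=tuple(self.model2_hidden),
            model1_max_iter=self.model1_max_iter,
            model2_max_iter=self.model2_max_iter,
            agree_weight=self.agree_weight,
            model2_scores=self.model2_scores,
            inner_folds=self.inner_folds,
            seed=self.random_state,
        )

    def fit(self, dataset: ABRDataset, y=None) -> "TwoStageNNThresholder":
        config = self._config()
        config.validate()
        labelled = dataset.labels()
        mice = sorted(labelled["mouse_id"].unique())
        self.splits_ = make_fold_splits(mice, config.seed, config.n_folds)
        blocks_by_stim = {
            stim: get_stimulus_blocks(dataset, stim) for stim in dataset.stimuli
        }
        self.models_ = [
            _fit_fold(blocks_by_stim, split, config) for split in self.splits_
        ]
        self.oof_predictions_ = predict_thresholds_nn(dataset, self.models_, self.splits_)
        return self

    def predict(self, dataset: ABRDataset | None = None) -> pd.DataFrame:
        if not hasattr(self, "models_"):
            raise RuntimeError("call fit first")
        if dataset is None:
            return self.oof_predictions_[["mouse_id", "stimulus", "threshold"]]
        rows = []
        for stim in dataset.stimuli:
            blocks = get_stimulus_blocks(dataset, stim)
            for b in blocks:
                votes = []
                for model_I, model_II in self.models_:
                    if stim not in model_II:
                        continue
                    (v,) = assemble_score_vectors([b], model_I)
                    votes.append(float(model_II[stim].predict(v.features()[None, :])[0]))
                if not votes:
                    rows.append((b.mouse_id, stim, np.nan))
                    continue
                # majority vote; ties broken toward the smaller threshold
                count = Counter(votes)
                best = sorted(count.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
                rows.append((b.mouse_id, stim, best))
        return pd.DataFrame(rows, columns=["mouse_id", "stimulus", "threshold"])
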