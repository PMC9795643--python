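"""Data model and CSV I/O for averaged ABR measurements.

The on-disk dialect is a single CSV with one averaged evoked-response curve
per row: a mouse identifier, the stimulus (broadband click or a tone-pip
frequency in kHz), the stimulus sound pressure level (SPL, dB), an optional
manually assigned hearing threshold, and the 1000-sample time series in
columns ``t0`` .. ``t999`` (a 10 ms window).  The non-hearing sentinel is the
literal value 999.  Optional per-mouse metadata columns (genetic line,
zygosity, sex, measurement date, validation flag) may be carried on each row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STIMULI",
    "NON_HEARING",
    "N_SAMPLES",
    "WINDOW_MS",
    "DEFAULT_GRIDS",
    "FULL_GRID",
    "GRID_STEP",
    "ABRDataset",
    "StimulusBlock",
    "read_abr_csv",
    "write_abr_csv",
    "filter_complete_mice",
    "get_stimulus_blocks",
    "dataset_summary",
]

#: Canonical stimulus names: broadband click plus tone-pip frequencies in kHz.
STIMULI: tuple[str, ...] = ("click", "6", "12", "18", "24", "30")

#: Sentinel threshold meaning "no response at any tested SPL".
NON_HEARING: int = 999

#: Samples per averaged curve and the time window they span.
N_SAMPLES: int = 1000
WINDOW_MS: float = 10.0

GRID_STEP: int = 5

#: Recorded SPL grids per stimulus (dB, 5 dB steps).
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "click": np.arange(0, 90, GRID_STEP),
    "6": np.arange(20, 90, GRID_STEP),
    "12": np.arange(0, 90, GRID_STEP),
    "18": np.arange(0, 90, GRID_STEP),
    "24": np.arange(0, 90, GRID_STEP),
    "30": np.arange(20, 90, GRID_STEP),
}

#: The union of all per-stimulus grids (0-85 dB in 5 dB steps, 18 levels).
FULL_GRID: np.ndarray = np.arange(0, 90, GRID_STEP)

_SAMPLE_COLS = [f"t{i}" for i in range(N_SAMPLES)]
_META_COLS = ["line", "zygosity", "sex", "measurement_date", "validation"]

#: Canonical header names; a schema mapping can rename foreign headers.
CANONICAL_SCHEMA = {
    "mouse_id": "mouse_id",
    "stimulus": "stimulus",
    "sound_level": "sound_level",
    "threshold": "threshold",
}


def canonical_stimulus(value: object) -> str:
    """Normalise a stimulus spelling to one of :data:`STIMULI`.

    Accepts e.g. ``"Click"``, ``"6"``, ``6``, ``"6kHz"``, ``"6 kHz"``.
    """
    s = str(value).strip().lower()
    if s.endswith("khz"):
        s = s[:-3].strip()
    if s == "click":
        return "click"
    try:
        k = int(float(s))
    except ValueError:
        raise ValueError(f"unrecognised stimulus {value!r}") from None
    if str(k) not in STIMULI:
        raise ValueError(f"unrecognised stimulus frequency {value!r}")
    return str(k)


@dataclass
class StimulusBlock:
    """The SPL-ordered stack of curves for one mouse x stimulus.

    This is the unit on which a hearing threshold is decided.
    """

    mouse_id: str
    stimulus: str
    spls: np.ndarray
    samples: np.ndarray
    threshold: float | None = None
    validation: str | None = None

    def __post_init__(self) -> None:
        self.spls = np.asarray(self.spls, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_SAMPLES:
            raise ValueError("samples must be (n_curves, 1000)")
        if len(self.spls) != len(self.samples):
            raise ValueError("spls and samples length mismatch")
        if np.any(np.diff(self.spls) <= 0):
            raise ValueError("SPLs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spls)


@dataclass
class ABRDataset:
    """A collection of averaged ABR curves with optional labels and metadata.

    Parameters
    ----------
    curves : pandas.DataFrame
        One row per curve with columns ``mouse_id``, ``stimulus``,
        ``sound_level`` and (optionally, possibly NaN) ``threshold``.
        Row order is preserved and aligned with `samples`.
    samples : numpy.ndarray
        Array of shape ``(n_curves, 1000)``.
    metadata : pandas.DataFrame or None
        Indexed by ``mouse_id`` with any of the columns ``line``,
        ``zygosity`` (mutant/control), ``sex``, ``measurement_date`` and
        ``validation`` (agree/disagree/undecided/none).
    """

    curves: pd.DataFrame
    samples: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.curves) != len(self.samples):
            raise ValueError("curves and samples must have equal length")
        if len(self.samples) and self.samples.shape[1] != N_SAMPLES:
            raise ValueError(f"samples must have {N_SAMPLES} columns")
        if "threshold" not in self.curves.columns:
            self.curves = self.curves.assign(threshold=np.nan)
        dup = self.curves.duplicated(subset=["mouse_id", "stimulus", "sound_level"])
        if dup.any():
            row = self.curves[dup].iloc[0]
            raise ValueError(
                "duplicate (mouse_id, stimulus, sound_level) key: "
                f"({row.mouse_id}, {row.stimulus}, {row.sound_level})"
            )

    def __len__(self) -> int:
        return len(self.curves)

    @property
    def mice(self) -> list[str]:
        return sorted(self.curves["mouse_id"].unique())

    @property
    def stimuli(self) -> list[str]:
        present = set(self.curves["stimulus"].unique())
        return [s for s in STIMULI if s in present]

    def labels(self) -> pd.DataFrame:
        """Manual threshold labels as a (mouse_id, stimulus, threshold) frame.

        Curves of one mouse x stimulus share the label; NaN rows (unlabelled)
        are dropped.
        """
        lab = (
            self.curves.groupby(["mouse_id", "stimulus"], sort=True)["threshold"]
            .first()
            .dropna()
            .reset_index()
        )
        return lab


def read_abr_csv(
    path,
    schema: Mapping[str, str] | None = None,
    strict: bool = False,
    grids: Mapping[str, np.ndarray] | None = None,
) -> ABRDataset:
    """Read the averaged-ABR CSV dialect.

    Parameters
    ----------
    path : str or path-like
    schema : mapping, optional
        Maps canonical column names (``mouse_id``, ``stimulus``,
        ``sound_level``, ``threshold``) to the file's actual headers, for
        foreign files whose header spelling differs.
    strict : bool
        If True, an SPL off the stimulus grid is an error; otherwise a
        warning is emitted and the row is kept.
    """
    schema = {**CANONICAL_SCHEMA, **(schema or {})}
    grids = grids or DEFAULT_GRIDS
    df = pd.read_csv(path, dtype={schema["mouse_id"]: str})
    for col in _SAMPLE_COLS:
        if col not in df.columns:
            raise ValueError(f"missing time-series column: {col}")
    for key in ("mouse_id", "stimulus", "sound_level"):
        if schema[key] not in df.columns:
            raise ValueError(f"missing required column: {schema[key]}")

    samples = np.empty((len(df), N_SAMPLES), dtype=float)
    block = df[_SAMPLE_COLS]
    for j, col in enumerate(_SAMPLE_COLS):
        vals = pd.to_numeric(block[col], errors="coerce")
        bad = vals.isna() & block[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric sample in column {col} at row {int(np.flatnonzero(bad)[0])}"
            )
        if vals.isna().any():
            raise ValueError(
                f"empty sample in column {col} at row {int(np.flatnonzero(vals.isna())[0])}"
            )
        samples[:, j] = vals.to_numpy()

    curves = pd.DataFrame(
        {
            "mouse_id": df[schema["mouse_id"]].astype(str),
            "stimulus": [canonical_stimulus(s) for s in df[schema["stimulus"]]],
            "sound_level": pd.to_numeric(df[schema["sound_level"]]).astype(float),
        }
    )
    if schema["threshold"] in df.columns:
        curves["threshold"] = pd.to_numeric(
            df[schema["threshold"]], errors="coerce"
        ).astype(float)
    else:
        curves["threshold"] = np.nan

    for stim, sub in curves.groupby("stimulus"):
        grid = np.asarray(grids.get(stim, FULL_GRID))
        off = ~sub["sound_level"].isin(grid)
        if off.any():
            msg = (
                f"{int(off.sum())} curve(s) for stimulus {stim} have SPL off "
                f"the recorded grid"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)

    meta = None
    present = [c for c in _META_COLS if c in df.columns]
    if present:
        meta = (
            df.assign(mouse_id=curves["mouse_id"])[["mouse_id", *present]]
            .groupby("mouse_id", sort=True)
            .first()
        )
    return ABRDataset(curves=curves, samples=samples, metadata=meta)


def write_abr_csv(dataset: ABRDataset, path) -> None:
    """Write a dataset in the averaged-ABR CSV dialect (round-trip safe)."""
    out = dataset.curves[["mouse_id", "stimulus", "sound_level"]].copy()
    thr = dataset.curves["threshold"]
    # 999 and grid values are integers on disk; missing labels stay empty.
    out["threshold"] = thr.map(
        lambda v: "" if pd.isna(v) else (f"{int(v)}" if float(v).is_integer() else f"{v}")
    )
    if dataset.metadata is not None:
        for col in dataset.metadata.columns:
            out[col] = dataset.curves["mouse_id"].map(dataset.metadata[col]).fillna("")
    ts = pd.DataFrame(dataset.samples, columns=_SAMPLE_COLS, index=out.index)
    pd.concat([out, ts], axis=1).to_csv(path, index=False)


def filter_complete_mice(
    dataset: ABRDataset, stimuli: Sequence[str] = STIMULI
) -> ABRDataset:
    """Keep only mice that have data for every required stimulus.

    Mice lacking any of the six stimuli are removed; the removal count is
    reported via a warning so batch logs record it.
    """
    have = dataset.curves.groupby("mouse_id")["stimulus"].agg(set)
    need = set(stimuli)
    complete = have[have.map(lambda s: need.issubset(s))].index
    n_removed = dataset.curves["mouse_id"].nunique() - len(complete)
    if n_removed:
        warnings.warn(
            f"filter_complete_mice: removed {n_removed} mouse/mice without a "
            f"complete set of {len(need)} stimuli",
            stacklevel=2,
        )
    keep = dataset.curves["mouse_id"].isin(complete).to_numpy()
    meta = dataset.metadata
    if meta is not None:
        meta = meta[meta.index.isin(complete)]
    return ABRDataset(
        curves=dataset.curves[keep].reset_index(drop=True),
        samples=dataset.samples[keep],
        metadata=meta,
    )


def get_stimulus_blocks(
    dataset: ABRDataset, stimulus: str | None = None
) -> list[StimulusBlock]:
    """Split a dataset into per-(mouse, stimulus) SPL-ordered blocks.

    Output order is deterministic: sorted by (mouse_id, stimulus).  Duplicate
    (mouse, stimulus, SPL) keys raise (guarded already at dataset build).
    """
    df = dataset.curves
    sel = np.ones(len(df), dtype=bool)
    if stimulus is not None:
        sel = (df["stimulus"] == canonical_stimulus(stimulus)).to_numpy()
    idx = np.flatnonzero(sel)
    sub = df.iloc[idx]
    blocks: list[StimulusBlock] = []
    stim_order = {s: i for i, s in enumerate(STIMULI)}
    keys = sorted(
        sub.groupby(["mouse_id", "stimulus"]).groups.items(),
        key=lambda kv: (kv[0][0], stim_order[kv[0][1]]),
    )
    for (mouse, stim), rows in keys:
        rows = np.asarray(rows)
        spls = df.loc[rows, "sound_level"].to_numpy(dtype=float)
        order = np.argsort(spls, kind="stable")
        thr = df.loc[rows, "threshold"].iloc[0]
        validation = None
        if dataset.metadata is not None and "validation" in dataset.metadata.columns:
            if mouse in dataset.metadata.index:
                validation = dataset.metadata.loc[mouse, "validation"]
        blocks.append(
            StimulusBlock(
                mouse_id=mouse,
                stimulus=stim,
                spls=spls[order],
                samples=dataset.samples[rows[order]],
                threshold=None if pd.isna(thr) else float(thr),
                validation=validation,
            )
        )
    return blocks


def dataset_summary(dataset: ABRDataset) -> dict:
    """Summary used by ``abr validate``: mice, stimuli, grids, label coverage."""
    labels = dataset.labels()
    per_stim = {}
    for stim in dataset.stimuli:
        sub = dataset.curves[dataset.curves["stimulus"] == stim]
        per_stim[stim] = {
            "n_curves": int(len(sub)),
            "n_mice": int(sub["mouse_id"].nunique()),
            "spl_min": float(sub["sound_level"].min()),
            "spl_max": float(sub["sound_level"].max()),
        }
    n_pairs = int(dataset.curves.groupby(["mouse_id", "stimulus"]).ngroups)
    return {
        "n_curves": int(len(dataset)),
        "n_mice": int(dataset.curves["mouse_id"].nunique()),
        "stimuli": per_stim,
        "n_labelled_pairs": int(len(labels)),
        "n_pairs": n_pairs,
        "label_coverage": float(len(labels) / n_pairs) if n_pairs else 0.0,
    }
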