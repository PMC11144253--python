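"""Patient time series -> labeled, windowed, split and balanced datasets.

The raw input is a per-patient table on a strict 5-minute grid with four
channels: blood glucose (mg/dL), heart rate (bpm), step count and calories
burned per sample.  A candidate prediction window at time ``t`` collects the
full 2-hour history of all four channels (lags 0, 5, ..., 120 minutes) and
is labeled by the glucose value at ``t + ph``: hypoglycemia iff it is below
70 mg/dL.  Windows with any missing value — in the history or the target —
are discarded rather than imputed; imputation risks manufacturing the very
excursions the models are meant to detect.

Splitting is stratified 70/30 and the training side is balanced to exactly
50% hypoglycemia by random undersampling of the majority class, so the
accuracy component of the fitness is meaningful.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "PatientSeries",
    "LabeledDataset",
    "SplitSpec",
    "HYPO_THRESHOLD_MGDL",
    "GRID_MINUTES",
    "HISTORY_MINUTES",
    "build_windows",
    "stratified_split",
    "undersample_balance",
    "estimated_average_glucose",
    "summarize_cohort",
    "load_participants",
]

HYPO_THRESHOLD_MGDL = 70.0
GRID_MINUTES = 5
HISTORY_MINUTES = 120
CHANNELS = ("gluc", "hr", "steps", "cal")


@dataclass
class PatientSeries:
    """One patient's multichannel trace on the 5-minute grid.

    ``data`` is indexed by timestamp with columns gluc/hr/steps/cal; missing
    samples are NaN (gap rows may simply be absent — the constructor
    reindexes onto the full grid so spacing is always exactly 5 minutes).
    """

    patient_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in CHANNELS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing channel column(s): {missing_cols}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("data must be indexed by timestamp")
        if len(df) == 0:
            raise ValueError("empty series")
        df = df[list(CHANNELS)].sort_index()
        if df.index.has_duplicates:
            raise ValueError("duplicate timestamps")
        step = pd.Timedelta(minutes=GRID_MINUTES)
        off = (df.index - df.index[0]) % step
        if (off != pd.Timedelta(0)).any():
            raise ValueError("timestamps are not on the 5-minute grid")
        full = pd.date_range(df.index[0], df.index[-1], freq=f"{GRID_MINUTES}min")
        df = df.reindex(full)
        for col in ("gluc", "hr", "cal", "steps"):
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative values in channel {col!r}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "timestamp"
        out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def from_csv(cls, path, patient_id: str | None = None) -> "PatientSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
        pid = patient_id or Path(path).stem
        return cls(patient_id=pid, data=df)


@dataclass
class LabeledDataset:
    """Feature windows plus binary hypoglycemia labels at one horizon.

    ``X`` has one column per lagged variable (``gluc_0`` ... ``cal_120``)
    and is indexed by the prediction timestamp (tagged with the patient id
    when datasets are pooled); ``y`` is True for hypoglycemia.
    """

    X: pd.DataFrame
    y: np.ndarray
    horizon: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=bool)
        if len(self.X) != len(self.y):
            raise ValueError("windows and labels differ in length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def positive_fraction(self) -> float:
        return float(self.y.mean()) if len(self.y) else math.nan

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X.iloc[idx], self.y[np.asarray(idx)], self.horizon)

    def arrays(self) -> dict[str, np.ndarray]:
        """Column arrays for fast vectorised rule evaluation."""
        return {c: self.X[c].to_numpy(dtype=float) for c in self.X.columns}

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["label"] = self.y.astype(int)
        out["horizon"] = self.horizon
        out.index.name = "window"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        df = pd.read_csv(path, index_col="window")
        horizons = df["horizon"].unique()
        if len(horizons) != 1:
            raise ValueError("mixed horizons in one dataset file")
        y = df.pop("label").to_numpy(dtype=bool)
        df = df.drop(columns=["horizon"])
        return cls(X=df, y=y, horizon=int(horizons[0]))

    @staticmethod
    def concat(parts: list["LabeledDataset"]) -> "LabeledDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        horizons = {p.horizon for p in parts}
        if len(horizons) != 1:
            raise ValueError("cannot pool datasets with different horizons")
        X = pd.concat([p.X for p in parts], axis=0)
        y = np.concatenate([p.y for p in parts])
        return LabeledDataset(X=X, y=y, horizon=parts[0].horizon)


@dataclass
class SplitSpec:
    train_fraction: float = 0.70
    stratified: bool = True
    undersample_train: bool = True
    seed: int = 0


def build_windows(series: PatientSeries, ph: int) -> LabeledDataset:
    """All complete 2-hour windows of a series, labeled at horizon ``ph``.

    One candidate window per timestamp ``t`` with a full 2-hour history and
    a glucose value at ``t + ph``; any missing value anywhere in the history
    or at the target drops the window.  Label: gluc(t+ph) < 70 mg/dL.
    """
    if ph <= 0 or ph % GRID_MINUTES != 0:
        raise ValueError(f"horizon {ph} must be a positive multiple of {GRID_MINUTES}")
    df = series.data
    lag_steps = HISTORY_MINUTES // GRID_MINUTES
    ph_steps = ph // GRID_MINUTES
    if len(df) < lag_steps + ph_steps + 1:
        warnings.warn(
            f"series {series.patient_id!r} shorter than "
            f"{HISTORY_MINUTES + ph} minutes; no windows produced",
            stacklevel=2,
        )
        cols = [f"{ch}_{s}" for ch in CHANNELS for s in range(0, HISTORY_MINUTES + 1, GRID_MINUTES)]
        return LabeledDataset(
            X=pd.DataFrame(columns=cols, dtype=float), y=np.zeros(0, bool), horizon=ph
        )
    frames = {}
    for ch in CHANNELS:
        for s in range(0, HISTORY_MINUTES + 1, GRID_MINUTES):
            frames[f"{ch}_{s}"] = df[ch].shift(s // GRID_MINUTES)
    X = pd.DataFrame(frames)
    target = df["gluc"].shift(-ph_steps)
    keep = X.notna().all(axis=1) & target.notna()
    X = X[keep]
    y = (target[keep] < HYPO_THRESHOLD_MGDL).to_numpy()
    return LabeledDataset(X=X, y=y, horizon=ph)


def stratified_split(
    ds: LabeledDataset, spec: SplitSpec | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified 70/30 split preserving the class proportions.

    Disjoint and exhaustive; per-class train counts are rounded so the
    global 70% holds to within one window.  Requires at least two windows
    in each class.
    """
    spec = spec or SplitSpec()
    counts = np.bincount(ds.y.astype(int), minlength=2)
    if counts.min() < 2:
        raise ValueError(
            "cannot stratify: each class needs at least 2 windows, got "
            f"{counts[1]} positive / {counts[0]} negative"
        )
    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=ds.y if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    train_idx.sort()
    test_idx.sort()
    return ds.subset(train_idx), ds.subset(test_idx)


def undersample_balance(train: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Random majority-class undersampling to exactly 50% hypoglycemia.

    Every minority window is kept; majority windows are subsampled without
    replacement down to the minority count.  No window is synthesised.
    """
    pos = np.flatnonzero(train.y)
    neg = np.flatnonzero(~train.y)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if len(pos) < len(neg):
        keep_neg = rng.choice(neg, size=len(pos), replace=False)
        idx = np.sort(np.concatenate([pos, keep_neg]))
    elif len(neg) < len(pos):
        keep_pos = rng.choice(pos, size=len(neg), replace=False)
        idx = np.sort(np.concatenate([keep_pos, neg]))
    else:
        idx = np.arange(len(train))
    return train.subset(idx)


def estimated_average_glucose(hba1c: float) -> int:
    """ADAG linear HbA1c -> mean glucose conversion: 28.7*HbA1c - 46.7 mg/dL.

    Rounded to the nearest integer (ties to even).  Valid for HbA1c in
    (3, 20) percent.
    """
    if not (3.0 < hba1c < 20.0):
        raise ValueError(f"HbA1c {hba1c}% outside the plausible range (3, 20)")
    return int(round(28.7 * hba1c - 46.7))


REQUIRED_METADATA = ("id", "gender", "age", "bmi", "hba1c", "treatment", "t1dm_years")


def summarize_cohort(table: pd.DataFrame, t1dm_threshold: float = 10.0) -> dict:
    """Deterministic cohort summary of a patient metadata table."""
    cols = {c.lower() for c in table.columns}
    missing = [c for c in REQUIRED_METADATA if c not in cols]
    if missing:
        raise ValueError(f"metadata table missing column(s): {missing}")
    t = table.rename(columns=str.lower)
    return {
        "n_patients": int(len(t)),
        "n_female": int((t["gender"] == "F").sum()),
        "n_male": int((t["gender"] == "M").sum()),
        "treatment_counts": t["treatment"].value_counts().to_dict(),
        "age_range": (float(t["age"].min()), float(t["age"].max())),
        "age_mean": float(t["age"].mean()),
        "age_std": float(t["age"].std()),
        "hba1c_range": (float(t["hba1c"].min()), float(t["hba1c"].max())),
        "hba1c_mean": float(t["hba1c"].mean()),
        "bmi_range": (float(t["bmi"].min()), float(t["bmi"].max())),
        "t1dm_years_range": (
            float(t["t1dm_years"].min()),
            float(t["t1dm_years"].max()),
        ),
        "n_t1dm_over_threshold": int((t["t1dm_years"] > t1dm_threshold).sum()),
        "t1dm_threshold": float(t1dm_threshold),
    }


def load_participants() -> pd.DataFrame:
    """The packaged 24-patient study metadata table."""
    with resources.files("hypoge.data").joinpath("participants.csv").open() as fh:
        return pd.read_csv(fh)
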