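"""Data model for HD-FMG recordings and canonical CSV round-tripping.

An FMG recording is a wide table: one row per 10 Hz sample, one column per
FSR channel, plus ``repetition``, ``gesture`` and ``time_s`` metadata
columns.  Raw sensor values are the classifier features directly (no
feature extraction), so "channel selection" and "feature selection" are the
same operation throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The six-grip vocabulary: neutral poses plus grips central to activities
#: of daily living.
GESTURES = ("relax", "open", "force", "tripod", "point", "key")

#: Accepted spellings on read, canonicalized to the vocabulary above.
_GESTURE_ALIASES = {
    "finger point": "point",
    "finger_point": "point",
    "fingerpoint": "point",
}

_META_COLUMNS = ("repetition", "gesture", "time_s")


class ValidationError(ValueError):
    """Raised when a dataset violates the FMG data-model invariants."""


def canonical_gesture(label: str) -> str:
    """Map a raw gesture label to the canonical six-grip vocabulary.

    Labels are case-insensitive; ``"finger point"`` and ``"point"`` both
    map to ``point``.  Unknown labels raise :class:`ValidationError`.
    """
    low = str(label).strip().lower()
    low = _GESTURE_ALIASES.get(low, low)
    if low not in GESTURES:
        raise ValidationError(
            f"unknown gesture label {label!r}; expected one of {GESTURES}"
        )
    return low


@dataclass(frozen=True)
class FMGDataset:
    """A labeled multichannel FSR sample matrix with repetition structure.

    Attributes
    ----------
    values
        float array, shape ``(n_samples, n_channels)``; raw FSR readings in
        arbitrary force units, finite and nonnegative.
    gesture
        per-sample grip label from :data:`GESTURES`.
    repetition
        per-sample integer repetition id (1-based protocol repetitions).
    time_s
        per-sample timestamps (metadata only; never resampled).
    channel_ids
        stable string names, one per column — the external handle a
        prosthetist uses to identify a physical sensor (e.g. ``s03_c07``).
    sample_rate_hz
        nominal acquisition rate, 10 Hz in the study protocol.
    protocol
        ``"static"`` (stationary arm) or ``"dynamic"`` (circular arm motion).
    """

    values: np.ndarray
    gesture: np.ndarray
    repetition: np.ndarray
    time_s: np.ndarray
    channel_ids: tuple[str, ...]
    sample_rate_hz: float = 10.0
    protocol: str = "static"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        gesture = np.asarray(self.gesture, dtype=object)
        repetition = np.asarray(self.repetition, dtype=int)
        time_s = np.asarray(self.time_s, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gesture", gesture)
        object.__setattr__(self, "repetition", repetition)
        object.__setattr__(self, "time_s", time_s)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))
        self._validate()

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D sample × channel matrix")
        n, d = self.values.shape
        if d == 0:
            raise ValidationError("dataset must contain at least one channel")
        if n == 0:
            raise ValidationError("dataset must contain at least one sample")
        if len(self.channel_ids) != d:
            raise ValidationError(
                f"{len(self.channel_ids)} channel_ids for {d} value columns"
            )
        if len(set(self.channel_ids)) != d:
            raise ValidationError("channel_ids must be distinct")
        if not (len(self.gesture) == len(self.repetition) == len(self.time_s) == n):
            raise ValidationError("metadata arrays must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(f"non-finite value at row {bad[0]}, column {bad[1]}")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative sensor value at row {bad[0]}, column {bad[1]} "
                "(FSR readings are nonnegative)"
            )
        for lbl in np.unique(self.gesture.astype(str)):
            if lbl not in GESTURES:
                raise ValidationError(
                    f"unknown gesture label {lbl!r}; expected one of {GESTURES}"
                )
        if self.protocol not in ("static", "dynamic"):
            raise ValidationError(f"protocol must be static or dynamic, got {self.protocol!r}")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")
        # every repetition must contain every gesture at least once
        for rep in np.unique(self.repetition):
            present = set(self.gesture[self.repetition == rep].astype(str))
            missing = set(GESTURES) - present
            if missing:
                raise ValidationError(
                    f"repetition {rep} is missing gestures {sorted(missing)}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def repetition_ids(self) -> list[int]:
        """Sorted unique repetition ids present in the data."""
        return sorted(int(r) for r in np.unique(self.repetition))

    def select_rows(self, mask: np.ndarray) -> "FMGDataset":
        """Row-subset view (copy) keeping all channels and metadata."""
        return replace(
            self,
            values=self.values[mask],
            gesture=self.gesture[mask],
            repetition=self.repetition[mask],
            time_s=self.time_s[mask],
        )

    def restrict_channels(self, indices: Sequence[int]) -> np.ndarray:
        """Value matrix restricted to the given channel column indices."""
        idx = np.asarray(list(indices), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_channels):
            raise ValidationError(f"channel index out of range 0..{self.n_channels - 1}")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame in the canonical on-disk column order."""
        df = pd.DataFrame(
            {
                "repetition": self.repetition,
                "gesture": self.gesture.astype(str),
                "time_s": self.time_s,
            }
        )
        for j, cid in enumerate(self.channel_ids):
            df[cid] = self.values[:, j]
        return df


@dataclass(frozen=True)
class ChannelSubset:
    """An ordered set of selected channel column indices with provenance.

    ``indices`` are 0-based column positions; external reports translate
    them to ``channel_ids``.  ``rank_scores``, when present, is aligned
    with ``indices`` (the selection score that put each channel there).
    """

    indices: tuple[int, ...]
    method: str = ""
    training_reps: tuple[int, ...] = ()
    rank_scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "training_reps", tuple(int(r) for r in self.training_reps))
        if len(set(idx)) != len(idx):
            raise ValidationError("channel subset indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValidationError("channel indices are 0-based nonnegative")
        if self.rank_scores is not None:
            scores = tuple(float(s) for s in self.rank_scores)
            if len(scores) != len(idx):
                raise ValidationError("rank_scores must align with indices")
            object.__setattr__(self, "rank_scores", scores)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_set(self) -> frozenset[int]:
        return frozenset(self.indices)

    def channel_names(self, dataset: FMGDataset) -> list[str]:
        return [dataset.channel_ids[i] for i in self.indices]


def read_dataset(
    path: str | Path,
    format: str = "csv-wide",
    sample_rate_hz: float = 10.0,
    protocol: str = "static",
) -> FMGDataset:
    """Read a dataset from the canonical wide-CSV dialect.

    The header must be ``repetition,gesture,time_s,<channel_id>...``.
    Gesture labels are case-insensitive and canonicalized; validation
    errors name the offending row/column.
    """
    if format != "csv-wide":
        raise ValueError(f"unsupported format {format!r}; only 'csv-wide' is available")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns {missing} in {path}")
    channel_ids = [c for c in df.columns if c not in _META_COLUMNS]
    if not channel_ids:
        raise ValidationError(f"no channel columns found in {path}")
    values = df[channel_ids].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for cid in channel_ids:
            col = pd.to_numeric(df[cid], errors="coerce")
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise ValidationError(
                    f"non-numeric channel value at row {row}, column {cid!r}"
                )
        values = df[channel_ids].apply(pd.to_numeric).to_numpy()
    gestures = np.array([canonical_gesture(g) for g in df["gesture"]], dtype=object)
    return FMGDataset(
        values=values.astype(float),
        gesture=gestures,
        repetition=df["repetition"].to_numpy(dtype=int),
        time_s=df["time_s"].to_numpy(dtype=float),
        channel_ids=tuple(channel_ids),
        sample_rate_hz=sample_rate_hz,
        protocol=protocol,
    )


def write_dataset(dataset: FMGDataset, path: str | Path) -> None:
    """Write the canonical wide CSV: UTF-8, '.' decimal, no index column.

    ``repr``-style float formatting keeps read∘write the identity on
    canonical-dialect files.
    """
    dataset._validate()
    df = dataset.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


def split_by_repetition(dataset: FMGDataset, held_out: int) -> tuple[FMGDataset, FMGDataset]:
    """Partition rows into (train, test) with ``held_out`` as the test block.

    Used for leave-one-repetition-out cross-validation: the held-out
    protocol repetition is the test set, the remaining repetitions train.
    Rows are partitioned disjointly, exhaustively and order-preservingly.
    """
    held_out = int(held_out)
    if held_out not in dataset.repetition_ids:
        raise ValueError(
            f"repetition {held_out} not present; available: {dataset.repetition_ids}"
        )
    mask = dataset.repetition == held_out
    return dataset.select_rows(~mask), dataset.select_rows(mask)
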