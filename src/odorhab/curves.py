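"""In-memory container for continuous intensity-rating curves.

A recording session yields one intensity-vs-time trace per subject x odorant
pair: 0-100 intensity sampled at 4 Hz for 120 s (481 samples).  Curves are
held as a dense matrix (one row per curve) plus a pandas index of identifiers,
which keeps clustering and distance computations vectorised while the
long-format CSV remains the on-disk interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CurveSet"]

LONG_COLUMNS = ["subject_id", "odorant_id", "time_s", "intensity"]


@dataclass
class CurveSet:
    """A set of intensity curves on a common uniform time grid.

    Parameters
    ----------
    index : pandas.DataFrame
        One row per curve with columns ``subject_id`` and ``odorant_id``.
    values : ndarray of shape (n_curves, n_samples)
        Intensity samples, one curve per row.
    times : ndarray of shape (n_samples,)
        Shared time grid in seconds, uniform spacing.
    start_level : float
        Instructed starting intensity (level 6 of 10 on the feedback scale,
        i.e. 60 on the 0-100 recording scale).
    """

    index: pd.DataFrame
    values: np.ndarray
    times: np.ndarray
    start_level: float = 60.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_curves, n_samples) array")
        if len(self.index) != self.values.shape[0]:
            raise ValueError("index and values disagree on the number of curves")
        if self.values.shape[1] != self.times.size:
            raise ValueError("values and times disagree on the number of samples")
        dt = np.diff(self.times)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, dt[0])):
            raise ValueError("time grid must be strictly increasing and uniform")
        self.index = self.index.reset_index(drop=True)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def subjects(self) -> list:
        return list(pd.unique(self.index["subject_id"]))

    def select(self, mask: np.ndarray) -> "CurveSet":
        mask = np.asarray(mask)
        return CurveSet(
            index=self.index.loc[mask].reset_index(drop=True),
            values=self.values[mask],
            times=self.times,
            start_level=self.start_level,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to long format (subject_id, odorant_id, time_s, intensity)."""
        n, t = self.values.shape
        frame = self.index.loc[self.index.index.repeat(t), ["subject_id", "odorant_id"]]
        frame = frame.reset_index(drop=True)
        frame["time_s"] = np.tile(self.times, n)
        frame["intensity"] = self.values.ravel()
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, start_level: float = 60.0) -> "CurveSet":
        """Build a CurveSet from long-format records sharing one time grid."""
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        frame = frame.sort_values(["subject_id", "odorant_id", "time_s"], kind="stable")
        grouped = frame.groupby(["subject_id", "odorant_id"], sort=True)
        keys, rows, grids = [], [], []
        for key, grp in grouped:
            keys.append(key)
            rows.append(grp["intensity"].to_numpy(dtype=float))
            grids.append(grp["time_s"].to_numpy(dtype=float))
        lengths = {r.size for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"curves have inconsistent lengths: {sorted(lengths)}")
        times = grids[0]
        for g in grids[1:]:
            if not np.array_equal(g, times):
                raise ValueError("curves do not share a common time grid")
        index = pd.DataFrame(keys, columns=["subject_id", "odorant_id"])
        return cls(index=index, values=np.vstack(rows), times=times, start_level=start_level)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
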