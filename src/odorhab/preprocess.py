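"""Parsing, exclusion rules and intensity normalization for rating curves.

Three exclusion rules are applied before any analysis, mirroring the study
protocol:

1. subjects who did not attend all sessions (detected as subjects missing
   odorants) are dropped wholesale;
2. subjects whose ratings are chaotic -- high-frequency alternation of the
   intensity trace, nominally tracking breathing -- are dropped wholesale;
3. individual curves whose response delay exceeds 17 s (14% of the 120 s
   record) are dropped.

Retained curves are then normalized on the intensity axis by their first
sample, anchoring every curve at 1.0 before habituation begins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CurveSet, LONG_COLUMNS

__all__ = [
    "ExclusionRules",
    "ExclusionReport",
    "parse_recordings",
    "response_delay",
    "is_chaotic",
    "reversal_rate",
    "apply_exclusions",
    "normalize_intensity",
]

NOMINAL_SAMPLES = 481  # 4 Hz x 120 s + 1


class ParseError(ValueError):
    """Malformed recordings input."""


@dataclass
class ExclusionRules:
    """Thresholds of the three exclusion rules.

    delay_max_s
        Maximum admissible response delay (study value: 17 s).
    delay_deadband, delay_sustain
        A response is the first deviation from the start level larger than
        ``delay_deadband`` intensity units sustained for ``delay_sustain``
        consecutive samples; robust to one-sample jitter.
    chaos_rate_threshold
        Direction-reversal rate (reversals/s) above which a curve counts as
        chaotic.
    chaos_amplitude
        Minimum swing, intensity units, for a direction change to count as
        a reversal; suppresses reversals due to ordinary rating noise.
    chaos_smooth_s
        Moving-average window (seconds) applied before reversal counting.
    subject_chaotic_fraction
        A subject is excluded wholesale when more than this fraction of
        their curves is chaotic.
    """

    delay_max_s: float = 17.0
    delay_deadband: float = 2.0
    delay_sustain: int = 2
    chaos_rate_threshold: float = 0.5
    chaos_amplitude: float = 2.0
    chaos_smooth_s: float = 1.0
    subject_chaotic_fraction: float = 0.5


@dataclass
class ExclusionReport:
    """Bookkeeping of the exclusion stage; counts are conserved."""

    n_input_curves: int
    n_absent_excluded: int
    n_chaotic_excluded: int
    n_delay_excluded: int
    n_retained: int
    absent_subjects: list = field(default_factory=list)
    chaotic_subjects: list = field(default_factory=list)
    reasons: pd.DataFrame | None = None  # subject_id, odorant_id, reason

    def __post_init__(self) -> None:
        total = self.n_absent_excluded + self.n_chaotic_excluded + self.n_delay_excluded
        if self.n_retained != self.n_input_curves - total:
            raise ValueError("exclusion counts are not conserved")

    def to_json(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "reasons"}
        return json.dumps(payload, indent=2)


def parse_recordings(source, start_level: float = 60.0) -> CurveSet:
    """Read long-format recordings (CSV path or DataFrame) into a CurveSet.

    Validates the schema, the 0-100 intensity range, uniqueness of
    (subject, odorant, time) triples and a shared uniform time grid.
    Curves whose length differs from the nominal 481 samples raise.
    """
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(source)
    else:
        frame = source.copy()
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    intensity = pd.to_numeric(frame["intensity"], errors="coerce")
    bad = intensity.isna()
    if bad.any():
        raise ParseError(f"non-numeric intensity at row {int(np.flatnonzero(bad)[0])}")
    out_of_range = (intensity < 0) | (intensity > 100)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0])
        raise ParseError(f"intensity outside [0, 100] at row {row}")
    frame["intensity"] = intensity
    dup = frame.duplicated(subset=["subject_id", "odorant_id", "time_s"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ParseError(f"duplicated (subject, odorant, time) at row {row}")
    curves = CurveSet.from_frame(frame, start_level=start_level)
    if curves.n_samples != NOMINAL_SAMPLES:
        warnings.warn(
            f"curves have {curves.n_samples} samples, expected {NOMINAL_SAMPLES}",
            stacklevel=2,
        )
    return curves


def _delay_seconds(
    values: np.ndarray, times: np.ndarray, start_level: float, deadband: float, sustain: int
) -> np.ndarray:
    """Vectorised response delay for a curve matrix."""
    dev = np.abs(values - start_level) > deadband
    if sustain > 1:
        run = dev.copy()
        for k in range(1, sustain):
            shifted = np.zeros_like(dev)
            shifted[:, :-k] = dev[:, k:]
            run &= shifted
    else:
        run = dev
    out = np.full(values.shape[0], times[-1], dtype=float)
    any_resp = run.any(axis=1)
    first = np.argmax(run, axis=1)
    out[any_resp] = times[first[any_resp]]
    return out


def response_delay(curve, times=None, start_level: float = 60.0,
                   deadband: float = 2.0, sustain: int = 2):
    """Time (s) at which the subject first responds.

    The response is the first sample deviating from the start level by more
    than ``deadband`` intensity units for ``sustain`` consecutive samples;
    returns the final time if the curve never responds.  Accepts a single
    curve (1-D array) or a :class:`CurveSet` (returns one delay per curve).
    """
    if isinstance(curve, CurveSet):
        return _delay_seconds(curve.values, curve.times, curve.start_level, deadband, sustain)
    values = np.asarray(curve, dtype=float)[None, :]
    if times is None:
        raise ValueError("times required when passing a bare sample array")
    return float(_delay_seconds(values, np.asarray(times, float), start_level, deadband, sustain)[0])


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(values, size=window, axis=1, mode="nearest")


def reversal_rate(curve, times=None, amplitude: float = 2.0, smooth_s: float = 1.0):
    """Rate (1/s) of direction reversals exceeding an amplitude deadband.

    The curve is smoothed with a short moving average, then scanned for
    turning points: a reversal is counted each time the trace moves by at
    least ``amplitude`` intensity units in the direction opposite to the
    previous counted move (a zigzag filter).  Breathing-locked alternation
    produces rates well above 1/s; ordinary decays with rating noise stay
    near zero.
    """
    single = not isinstance(curve, CurveSet)
    if single:
        values = np.asarray(curve, dtype=float)[None, :]
        t = np.asarray(times, dtype=float)
    else:
        values, t = curve.values, curve.times
    dt = t[1] - t[0]
    window = max(int(round(smooth_s / dt)), 1)
    sm = _smooth(values, window)
    duration = t[-1] - t[0]
    rates = np.array([_count_reversals(row, amplitude) / duration for row in sm])
    return float(rates[0]) if single else rates


def _count_reversals(row: np.ndarray, amplitude: float) -> int:
    """Zigzag turning-point count: direction changes with swing >= amplitude."""
    count = 0
    direction = 0  # 0 undecided, +1 rising leg, -1 falling leg
    lo = hi = row[0]
    for x in row[1:]:
        if direction == 0:
            lo, hi = min(lo, x), max(hi, x)
            if x - lo >= amplitude:
                direction = 1
                hi = x
            elif hi - x >= amplitude:
                direction = -1
                lo = x
        elif direction == 1:
            if x > hi:
                hi = x
            elif hi - x >= amplitude:
                count += 1
                direction = -1
                lo = x
        else:
            if x < lo:
                lo = x
            elif x - lo >= amplitude:
                count += 1
                direction = 1
                hi = x
    return count


def is_chaotic(curve, times=None, rate_threshold: float = 0.5,
               amplitude: float = 2.0, smooth_s: float = 1.0):
    """True when the direction-reversal rate exceeds the threshold."""
    rates = reversal_rate(curve, times, amplitude=amplitude, smooth_s=smooth_s)
    if np.isscalar(rates) or getattr(rates, "ndim", 0) == 0:
        return bool(rates > rate_threshold)
    return rates > rate_threshold


def apply_exclusions(
    curves: CurveSet,
    rules: ExclusionRules | None = None,
    session_of: pd.Series | None = None,
) -> tuple[CurveSet, ExclusionReport]:
    """Apply the three study exclusion rules and report the bookkeeping.

    Absent subjects and chaotic subjects lose all their curves; delayed
    curves are removed individually.  Each excluded curve carries exactly
    one reason, assigned in that order of precedence.

    When ``session_of`` (odorant -> session label) is given, a subject is
    absent iff they have no curve at all for some session; this keeps the
    rule idempotent after individual delayed curves have been removed.
    Without a session map the rule falls back to flagging any subject with
    an incomplete odorant panel.
    """
    rules = rules or ExclusionRules()
    index = curves.index
    n_input = len(curves)

    if session_of is not None:
        all_sessions = set(session_of.loc[pd.unique(index["odorant_id"])])
        covered = index.assign(session=session_of.loc[index["odorant_id"]].to_numpy())
        by_subject = covered.groupby("subject_id")["session"].agg(set)
        incomplete = by_subject.apply(lambda s: s != all_sessions)
        absent_subjects = sorted(by_subject.index[incomplete])
    else:
        per_subject = index.groupby("subject_id")["odorant_id"].nunique()
        full_set = per_subject.max()
        absent_subjects = sorted(per_subject.index[per_subject < full_set])
    absent_mask = index["subject_id"].isin(absent_subjects).to_numpy()

    chaotic_flags = is_chaotic(
        curves,
        rate_threshold=rules.chaos_rate_threshold,
        amplitude=rules.chaos_amplitude,
        smooth_s=rules.chaos_smooth_s,
    )
    flag_frame = index.assign(chaotic=chaotic_flags)
    frac = flag_frame[~absent_mask].groupby("subject_id")["chaotic"].mean()
    chaotic_subjects = sorted(frac.index[frac > rules.subject_chaotic_fraction])
    chaotic_mask = index["subject_id"].isin(chaotic_subjects).to_numpy() & ~absent_mask

    delays = response_delay(
        curves, deadband=rules.delay_deadband, sustain=rules.delay_sustain
    )
    delay_mask = (delays > rules.delay_max_s) & ~absent_mask & ~chaotic_mask

    reason = np.full(n_input, "retained", dtype=object)
    reason[delay_mask] = "delayed"
    reason[chaotic_mask] = "chaotic_subject"
    reason[absent_mask] = "absent_subject"
    reasons = index.assign(reason=reason)

    keep = reason == "retained"
    report = ExclusionReport(
        n_input_curves=n_input,
        n_absent_excluded=int(absent_mask.sum()),
        n_chaotic_excluded=int(chaotic_mask.sum()),
        n_delay_excluded=int(delay_mask.sum()),
        n_retained=int(keep.sum()),
        absent_subjects=absent_subjects,
        chaotic_subjects=chaotic_subjects,
        reasons=reasons,
    )
    return curves.select(keep), report


def normalize_intensity(curves: CurveSet) -> CurveSet:
    """Divide each curve by its first sample, anchoring the onset at 1.0."""
    first = curves.values[:, 0]
    if np.any(first == 0):
        bad = int(np.flatnonzero(first == 0)[0])
        who = curves.index.iloc[bad]
        raise ValueError(
            f"degenerate curve with zero start: subject {who['subject_id']}, "
            f"odorant {who['odorant_id']}"
        )
    return CurveSet(
        index=curves.index.copy(),
        values=curves.values / first[:, None],
        times=curves.times,
        start_level=1.0,
    )
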