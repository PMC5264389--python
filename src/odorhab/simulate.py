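"""Synthetic rating cohorts with known generative truth.

The study's continuous intensity recordings were never released, so every
downstream stage is exercised on simulated cohorts whose ground truth is
known.  A subject's intensity trace for one odorant decays exponentially
from the instructed start level towards a plateau,

    I(t) = L * [p + (1 - p) * exp(-lambda(o) * t)] + noise,

where ``L`` is the start level (60 on the 0-100 scale), ``p`` the plateau
fraction, and the odorant-specific decay rate is log-linear in autoscaled
molecular descriptors: ``lambda(o) = baseline * exp(sum_j beta_j * z_j(o))``.
A larger decay rate means stronger habituation.

The generator also reproduces the study's three contamination patterns so
exclusion logic can be validated against known truth:

* *absent* subjects attend only a subset of the four sessions (their
  curves exist only for the odorants of attended sessions);
* *chaotic* subjects produce high-frequency alternating ratings on every
  trial (nominally tracking breathing rather than perception);
* *delayed* curves hold the start level for a drawn delay before the
  subject begins responding, upon which the rating jumps to the currently
  perceived intensity.

During a delay the subject is not touching the rating device, so the trace
is held exactly at the start level; rating noise begins at response onset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import CurveSet
from .datasets import NUMERIC_DESCRIPTORS, assign_sessions, load_table1, synthesize_oav

__all__ = [
    "GenerativeTruth",
    "CohortConfig",
    "CohortTruth",
    "generate_cohort",
    "default_truth",
    "default_config",
    "decay_rates",
    "clean_curve",
    "write_cohort",
]


def _autoscale_columns(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    z = table[columns].astype(float).copy()
    z = (z - z.mean()) / z.std(ddof=1)
    return z


@dataclass
class GenerativeTruth:
    """Ground-truth parameters of a synthetic cohort.

    Parameters
    ----------
    driver_coefficients : dict
        Linear effect of each named autoscaled descriptor on the log decay
        rate.  Descriptors absent from the map have zero effect.
    baseline_decay_rate : float
        Decay rate (1/s) of an odorant with average descriptors.
    plateau_fraction : float
        Fraction of the start level retained as t -> infinity, in [0, 1].
    noise_sd : float
        Rating noise standard deviation, intensity units (0-100 scale).
    rater_sd : float
        Between-subject standard deviation of the plateau shift, intensity
        units; induces the subject random effect seen by the mixed models.
    seed : int
        Seed of the single generator all cohort randomness flows through.
    """

    driver_coefficients: dict = field(
        default_factory=lambda: {"vp": 0.35, "mw": -0.25, "db_bonds": -0.2}
    )
    baseline_decay_rate: float = 0.02
    plateau_fraction: float = 0.3
    noise_sd: float = 1.5
    rater_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.rater_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.baseline_decay_rate <= 0:
            raise ValueError("baseline_decay_rate must be positive")


@dataclass
class CohortConfig:
    """Cohort layout: panel, attendance and contamination counts.

    Defaults mirror the study: 58 recruited subjects rating 32 odorants over
    4 sessions, 3 subjects missing sessions, 5 chaotic raters, and 69
    individual curves with a response delay long enough to be excluded
    (spread over about 13 subjects, 1-9 curves each).
    """

    n_subjects: int = 58
    odorants: pd.DataFrame | None = None
    n_absent_subjects: int = 3
    n_chaotic_subjects: int = 5
    n_delayed_curves: int = 69
    delay_range_s: tuple[float, float] = (18.0, 110.0)
    sampling_hz: float = 4.0
    duration_s: float = 120.0
    start_level: float = 60.0
    n_sessions: int = 4
    chaos_amplitude: float = 8.0
    chaos_hz: float = 1.0  # rating sign flips per second for chaotic raters

    def __post_init__(self) -> None:
        if self.odorants is None:
            table = load_table1()
            self.odorants = table
        if self.n_absent_subjects + self.n_chaotic_subjects > self.n_subjects:
            raise ValueError("absent + chaotic subjects exceed the cohort size")
        lo, hi = self.delay_range_s
        if not (17.0 < lo <= hi <= self.duration_s):
            raise ValueError("delay_range_s must lie within (17, duration_s]")
        n_clean = self.n_subjects - self.n_absent_subjects - self.n_chaotic_subjects
        if self.n_delayed_curves > n_clean * len(self.odorants):
            raise ValueError("more delayed curves requested than curves exist")
        if self.n_delayed_curves > 0 and n_clean == 0:
            raise ValueError("no eligible subjects left to carry delayed curves")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_hz)) + 1

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_hz


@dataclass
class CohortTruth:
    """Echo of everything the generator decided, for truth-based testing."""

    decay_rate: pd.Series
    absent_subjects: list
    chaotic_subjects: list
    delayed: pd.DataFrame  # subject_id, odorant_id, delay_s
    subject_offsets: pd.Series
    truth: GenerativeTruth

    def counts(self) -> dict:
        return {
            "n_absent_subjects": len(self.absent_subjects),
            "n_chaotic_subjects": len(self.chaotic_subjects),
            "n_delayed_curves": len(self.delayed),
        }

    def to_json(self) -> str:
        payload = {
            "decay_rate": self.decay_rate.round(10).to_dict(),
            "absent_subjects": list(self.absent_subjects),
            "chaotic_subjects": list(self.chaotic_subjects),
            "delayed": self.delayed.to_dict(orient="records"),
            "subject_offsets": self.subject_offsets.round(10).to_dict(),
            "parameters": {
                "driver_coefficients": self.truth.driver_coefficients,
                "baseline_decay_rate": self.truth.baseline_decay_rate,
                "plateau_fraction": self.truth.plateau_fraction,
                "noise_sd": self.truth.noise_sd,
                "rater_sd": self.truth.rater_sd,
                "seed": self.truth.seed,
            },
            "counts": self.counts(),
        }
        return json.dumps(payload, indent=2)


def default_truth(seed: int = 0, **overrides) -> GenerativeTruth:
    """Study-scale generative truth with vapour pressure, molecular weight
    and double bonds as the designated decay-rate drivers."""
    return GenerativeTruth(seed=seed, **overrides)


def default_config(**overrides) -> CohortConfig:
    """Default cohort mirroring the study's attendance and contamination."""
    return CohortConfig(**overrides)


def decay_rates(odorants: pd.DataFrame, truth: GenerativeTruth) -> pd.Series:
    """Per-odorant decay rate lambda(o) = baseline * exp(sum beta_j z_j)."""
    drivers = list(truth.driver_coefficients)
    unknown = [d for d in drivers if d not in odorants.columns]
    if unknown:
        raise KeyError(f"driver descriptors not in the table: {unknown}")
    if drivers:
        z = _autoscale_columns(odorants, drivers)
        log_shift = sum(truth.driver_coefficients[d] * z[d] for d in drivers)
    else:
        log_shift = pd.Series(0.0, index=odorants.index)
    rates = truth.baseline_decay_rate * np.exp(log_shift)
    rates.name = "decay_rate"
    return rates


def clean_curve(
    times: np.ndarray,
    decay_rate: float,
    plateau_fraction: float,
    start_level: float = 60.0,
    subject_offset: float = 0.0,
) -> np.ndarray:
    """Noiseless trajectory: exponential decay to a (subject-shifted) plateau.

    The subject offset ramps in with the decay so every curve still starts
    exactly at the instructed level.
    """
    ramp = 1.0 - np.exp(-decay_rate * times)
    base = start_level * (plateau_fraction + (1.0 - plateau_fraction) * np.exp(-decay_rate * times))
    return base + subject_offset * ramp


def _delay_partition(n_delayed: int, n_available: int, rng: np.random.Generator) -> list[int]:
    """Split n delayed curves over subjects, 1-9 curves each."""
    if n_delayed == 0:
        return []
    m = max(math.ceil(n_delayed / 9), round(n_delayed / 5.3), 1)
    m = min(m, n_delayed, n_available)
    if m * 9 < n_delayed:
        raise ValueError("cannot spread delayed curves at <= 9 per subject")
    base, rem = divmod(n_delayed, m)
    counts = [base + 1] * rem + [base] * (m - rem)
    rng.shuffle(counts)
    return counts


def generate_cohort(
    config: CohortConfig | None = None,
    truth: GenerativeTruth | None = None,
) -> tuple[CurveSet, pd.DataFrame, CohortTruth]:
    """Simulate one cohort of intensity recordings plus sensory ratings.

    Returns
    -------
    curves : CurveSet
        All recorded curves, including contaminated ones.
    ratings : pandas.DataFrame
        One row per attended subject x odorant pair with integer 1-9
        ratings of intensity, pleasantness, familiarity and trigeminality.
    cohort_truth : CohortTruth
        The generator's ground truth (decay rates, contamination roster).
    """
    config = config or default_config()
    truth = truth or default_truth()
    rng = np.random.default_rng(truth.seed)

    odorants = config.odorants
    if "oav" not in odorants.columns:
        odorants = odorants.copy()
        odorants["oav"] = synthesize_oav(odorants, seed=truth.seed)
    if "pres_order" not in odorants.columns:
        odorants = odorants.copy()
        odorants["pres_order"] = assign_sessions(odorants, config.n_sessions)

    odorant_ids = list(odorants.index)
    rates = decay_rates(odorants, truth)
    times = config.time_grid()
    n_samples = config.n_samples
    level = config.start_level

    width = len(str(config.n_subjects))
    subjects = [f"S{i + 1:0{width}d}" for i in range(config.n_subjects)]
    roster = rng.permutation(subjects)
    absent = sorted(roster[: config.n_absent_subjects])
    chaotic = sorted(
        roster[config.n_absent_subjects : config.n_absent_subjects + config.n_chaotic_subjects]
    )
    clean_subjects = sorted(set(subjects) - set(absent) - set(chaotic))

    offsets = pd.Series(
        rng.normal(0.0, truth.rater_sd, size=config.n_subjects), index=subjects, name="offset"
    )

    # Delayed curves live on non-chaotic, fully attending subjects.
    counts = _delay_partition(config.n_delayed_curves, len(clean_subjects), rng)
    delayed_subjects = list(rng.choice(clean_subjects, size=len(counts), replace=False))
    delayed_rows = []
    delay_lookup: dict[tuple, float] = {}
    lo, hi = config.delay_range_s
    for subj, cnt in zip(delayed_subjects, counts):
        which = rng.choice(odorant_ids, size=cnt, replace=False)
        for odo in which:
            d = float(rng.uniform(lo, hi))
            delay_lookup[(subj, odo)] = d
            delayed_rows.append({"subject_id": subj, "odorant_id": odo, "delay_s": d})
    delayed = pd.DataFrame(delayed_rows, columns=["subject_id", "odorant_id", "delay_s"])

    # Session attendance: absent subjects miss at least one session.
    session_of = odorants["pres_order"]
    sessions = sorted(session_of.unique())
    attended: dict[str, list] = {}
    for subj in subjects:
        if subj in absent:
            k = int(rng.integers(1, len(sessions)))
            attended[subj] = sorted(rng.choice(sessions, size=k, replace=False))
        else:
            attended[subj] = sessions

    index_rows, value_rows = [], []
    for subj in subjects:
        mine = [o for o in odorant_ids if session_of[o] in attended[subj]]
        b = float(offsets[subj])
        for odo in mine:
            lam = float(rates[odo])
            if subj in chaotic:
                # chaos_hz = sign flips per second; each leg survives the
                # exclusion stage's 1-s smoothing at the default 1 flip/s
                half = max(int(round(config.sampling_hz / config.chaos_hz)), 1)
                sign = np.resize(np.repeat([1.0, -1.0], half), n_samples)
                drift = clean_curve(times, 0.01, truth.plateau_fraction, level, 0.0) - level
                samples = level + drift + config.chaos_amplitude * sign
                samples = samples + rng.normal(0.0, truth.noise_sd, size=n_samples)
                samples[0] = level
            else:
                d = delay_lookup.get((subj, odo), 0.0)
                base = clean_curve(times, lam, truth.plateau_fraction, level, b)
                samples = base + rng.normal(0.0, truth.noise_sd, size=n_samples)
                samples[0] = base[0]  # instructed start, device untouched yet
                if d > 0:
                    held = times < d
                    samples[held] = level
            index_rows.append((subj, odo))
            value_rows.append(np.clip(samples, 0.0, 100.0))

    curves = CurveSet(
        index=pd.DataFrame(index_rows, columns=["subject_id", "odorant_id"]),
        values=np.vstack(value_rows),
        times=times,
        start_level=level,
    )

    ratings = _generate_ratings(curves.index, odorants, rng)

    cohort_truth = CohortTruth(
        decay_rate=rates,
        absent_subjects=absent,
        chaotic_subjects=chaotic,
        delayed=delayed,
        subject_offsets=offsets,
        truth=truth,
    )
    return curves, ratings, cohort_truth


# Latent models for the four 9-level sensory scales.  Trigeminality tracks
# intensity closely and pleasantness opposes it, reproducing the collinearity
# expected between these attributes.
_RATING_MODEL = {
    "intensity": {"vp": 0.8, "oav": 0.5},
    "pleasantness": {"vp": -0.5, "oav": -0.25, "mw": 0.3},
    "familiarity": {"conformers": 0.25},
    "trigeminality": {"vp": 0.75, "oav": 0.45, "logp": 0.25},
}


def _generate_ratings(
    pair_index: pd.DataFrame, odorants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    numeric = [c for c in [*NUMERIC_DESCRIPTORS, "oav"] if c in odorants.columns]
    z = _autoscale_columns(odorants, numeric) if numeric else pd.DataFrame(index=odorants.index)
    subjects = pd.unique(pair_index["subject_id"])
    out = pair_index[["subject_id", "odorant_id"]].copy()
    for attr, coefs in _RATING_MODEL.items():
        # only descriptors present in this panel drive the latent scale
        usable = {d: c for d, c in coefs.items() if d in z.columns}
        latent = sum(
            (c * z[d] for d, c in usable.items()),
            start=pd.Series(0.0, index=odorants.index),
        )
        subj_eff = pd.Series(rng.normal(0.0, 0.8, size=len(subjects)), index=subjects)
        raw = (
            5.0
            + 1.6 * latent.loc[out["odorant_id"]].to_numpy()
            + subj_eff.loc[out["subject_id"]].to_numpy()
            + rng.normal(0.0, 1.0, size=len(out))
        )
        out[attr] = np.clip(np.round(raw), 1, 9).astype(int)
    return out


def write_cohort(
    out_dir, curves: CurveSet, ratings: pd.DataFrame, cohort_truth: CohortTruth
) -> dict:
    """Write recordings, ratings, descriptors and the truth sidecar as text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "recordings": out / "recordings.csv",
        "ratings": out / "ratings.csv",
        "truth": out / "truth.json",
    }
    curves.write_csv(paths["recordings"])
    ratings.to_csv(paths["ratings"], index=False)
    paths["truth"].write_text(cohort_truth.to_json())
    return {k: str(v) for k, v in paths.items()}
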