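"""Packaged odorant descriptor table and helpers to complete it.

The study panel consists of 32 perfumery odorants characterised by eight
numeric molecular descriptors (accessible surface area, carbon-chain length,
logP, number of double bonds, number of conformers, molecular weight,
saturated vapour pressure, odor activity value) and two categorical ones
(olfactory family, chemical family).  The odor activity value (OAV) of the
diluted stimuli was never published, so :func:`synthesize_oav` fabricates a
plausible stand-in tied to vapour pressure; it is clearly synthetic and any
analysis using it inherits that caveat.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_table1",
    "synthesize_oav",
    "assign_sessions",
    "NUMERIC_DESCRIPTORS",
    "CATEGORICAL_DESCRIPTORS",
    "SENSORY_VARIABLES",
]

#: Numeric molecular descriptors shipped in the packaged table.
NUMERIC_DESCRIPTORS = ["asa", "c_chain", "logp", "db_bonds", "conformers", "mw", "vp"]

#: Categorical descriptors and their expected level counts on the study panel.
CATEGORICAL_DESCRIPTORS = {"cfamily": 7, "ofamily": 10, "pres_order": 4}

#: Sensory attributes rated by subjects on 9-level scales.
SENSORY_VARIABLES = ["intensity", "pleasantness", "familiarity", "trigeminality"]

_N_ODORANTS = 32

_NUMERIC_BOUNDS = {
    "asa": (0.0, 200.0),
    "c_chain": (0, 20),
    "logp": (-5.0, 10.0),
    "db_bonds": (0, 10),
    "conformers": (0, 255),
    "mw": (50.0, 500.0),
    "vp": (0.0, 10.0),
}


class FixtureIntegrityError(RuntimeError):
    """The packaged descriptor table failed a consistency check."""


def load_table1() -> pd.DataFrame:
    """Load the packaged 32-odorant descriptor table.

    Returns a DataFrame indexed by odorant abbreviation with the numeric
    descriptors, the two categorical families, CAS number and full name.
    The OAV column is *not* present (it was withheld from publication);
    use :func:`synthesize_oav` to add a synthetic stand-in.

    Raises
    ------
    FixtureIntegrityError
        If the packaged file is corrupted (wrong row count, missing or
        non-numeric fields, out-of-range values), naming the offending field.
    """
    with resources.files("odorhab.data").joinpath("table1_odorants.csv").open() as fh:
        table = pd.read_csv(fh, dtype={"cas": str})

    required = ["cas", "abbrev", "name", "ofamily", "cfamily", *NUMERIC_DESCRIPTORS]
    for col in required:
        if col not in table.columns:
            raise FixtureIntegrityError(f"descriptor fixture missing column {col!r}")
    if len(table) != _N_ODORANTS:
        raise FixtureIntegrityError(
            f"descriptor fixture has {len(table)} rows, expected {_N_ODORANTS}"
        )
    if table["abbrev"].duplicated().any():
        dup = table.loc[table["abbrev"].duplicated(), "abbrev"].iloc[0]
        raise FixtureIntegrityError(f"duplicated odorant abbreviation {dup!r}")
    for col, (lo, hi) in _NUMERIC_BOUNDS.items():
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            raise FixtureIntegrityError(f"non-numeric value in column {col!r}")
        if ((values < lo) | (values > hi)).any():
            raise FixtureIntegrityError(f"out-of-range value in column {col!r}")
    for col, n_levels in (("cfamily", 7), ("ofamily", 10)):
        found = table[col].nunique()
        if found != n_levels:
            raise FixtureIntegrityError(
                f"column {col!r} has {found} levels, expected {n_levels}"
            )
    return table.set_index("abbrev", drop=False)


def synthesize_oav(descriptors: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Generate a synthetic odor activity value for each odorant.

    The OAV is the ratio of an odorant's headspace concentration to its
    detection threshold.  The published values are confidential; this
    stand-in draws log10(OAV) as an affine function of log10(vapour
    pressure) plus lognormal scatter, reflecting that more volatile
    odorants tend to reach higher multiples of threshold.  Values are
    synthetic and reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    if "vp" in descriptors.columns:
        log_vp = np.log10(descriptors["vp"].to_numpy(dtype=float))
        log_oav = 2.0 + 0.8 * log_vp + rng.normal(0.0, 0.4, size=len(descriptors))
    else:  # panels without a volatility descriptor: pure lognormal spread
        log_oav = rng.normal(1.0, 0.8, size=len(descriptors))
    return pd.Series(10.0 ** log_oav, index=descriptors.index, name="oav")


def assign_sessions(descriptors: pd.DataFrame, n_sessions: int = 4) -> pd.Series:
    """Assign each odorant to a presentation session (categorical 1..n).

    In the study the 32 odorants were split over 4 sessions of 8, sessions
    grouping odorants of comparable intensity; the actual blocking was not
    published, so this synthetic assignment blocks odorants by their order
    in the packaged table.
    """
    block = len(descriptors) // n_sessions
    if block * n_sessions != len(descriptors):
        raise ValueError("number of odorants must be divisible by n_sessions")
    labels = np.repeat(np.arange(1, n_sessions + 1), block)
    return pd.Series([f"S{s}" for s in labels], index=descriptors.index, name="pres_order")
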