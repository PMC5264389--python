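"""Assembly and autoscaling of the PLS design matrices.

X holds 15 explanatory variables per odorant: 12 numeric (8 molecular
descriptors and the 4 sensory means) and 3 categorical (chemical family,
olfactory family, presentation session).  Each categorical is expanded to a
disjunctive (one-indicator-per-level) block whose columns are divided by the
variable's level count so that no family outweighs a single numeric column;
on the study schema this yields 12 + 7 + 10 + 4 = 33 columns.  Y holds the
three habituation-space coordinates.  Both matrices are autoscaled
(mean-centred, unit variance, n-1 denominator) before regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import NUMERIC_DESCRIPTORS, SENSORY_VARIABLES

__all__ = ["assemble_X", "assemble_Y", "autoscale", "sensory_means", "ColumnMeta"]

Y_COLUMNS = ["lowhab", "midhab", "highhab"]
CATEGORICALS = ["cfamily", "ofamily", "pres_order"]


@dataclass
class ColumnMeta:
    """Provenance of one X column."""

    source: str
    is_indicator: bool = False
    level: str | None = None
    level_rescale: float = 1.0


def sensory_means(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-odorant mean of the four 9-level sensory ratings over subjects."""
    missing = [c for c in SENSORY_VARIABLES if c not in ratings.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    return ratings.groupby("odorant_id")[SENSORY_VARIABLES].mean()


def assemble_X(
    descriptors: pd.DataFrame,
    sensory: pd.DataFrame | None = None,
    numeric_vars: list[str] | None = None,
    categorical_vars: list[str] | None = None,
) -> tuple[pd.DataFrame, list[ColumnMeta]]:
    """Build the unscaled X matrix with disjunctive categorical expansion.

    Numeric variables are copied; each categorical variable contributes one
    indicator column per observed level, divided by the level count.  The
    returned metadata records each column's source variable and rescale
    factor.

    Raises
    ------
    KeyError
        If an odorant lacks a required variable.
    """
    if numeric_vars is None:
        numeric_vars = [*NUMERIC_DESCRIPTORS, "oav"]
    if categorical_vars is None:
        categorical_vars = [c for c in CATEGORICALS if c in descriptors.columns]

    table = descriptors.copy()
    if sensory is not None:
        aligned = sensory.reindex(table.index)
        if aligned.isna().any().any():
            lost = aligned.index[aligned.isna().any(axis=1)][0]
            raise KeyError(f"odorant {lost!r} missing sensory means")
        table = table.join(aligned)
        numeric_vars = [*numeric_vars, *aligned.columns]

    blocks, meta = [], []
    for var in numeric_vars:
        if var not in table.columns:
            raise KeyError(f"variable {var!r} missing from the descriptor table")
        col = pd.to_numeric(table[var], errors="coerce")
        if col.isna().any():
            bad = col.index[col.isna()][0]
            raise KeyError(f"odorant {bad!r} has a non-numeric value for {var!r}")
        blocks.append(col.rename(var).to_frame())
        meta.append(ColumnMeta(source=var))
    for var in categorical_vars:
        if var not in table.columns:
            raise KeyError(f"variable {var!r} missing from the descriptor table")
        levels = sorted(table[var].astype(str).unique())
        n_levels = len(levels)
        onehot = pd.get_dummies(table[var].astype(str)).reindex(columns=levels)
        onehot = onehot.astype(float) / n_levels
        onehot.columns = [f"{var}:{lvl}" for lvl in levels]
        blocks.append(onehot)
        for lvl in levels:
            meta.append(
                ColumnMeta(source=var, is_indicator=True, level=lvl, level_rescale=1.0 / n_levels)
            )
    X = pd.concat(blocks, axis=1)
    return X, meta


def assemble_Y(space: pd.DataFrame, odorant_order=None) -> pd.DataFrame:
    """Align the habituation-space coordinates with the X row order.

    Larger values mean a larger distance to (lower similarity with) the
    corresponding habituation profile.
    """
    missing = [c for c in Y_COLUMNS if c not in space.columns]
    if missing:
        raise ValueError(f"habituation space missing columns: {missing}")
    Y = space[Y_COLUMNS].copy()
    if odorant_order is not None:
        if set(odorant_order) != set(Y.index):
            raise ValueError("odorant order does not match the habituation space rows")
        Y = Y.loc[list(odorant_order)]
    return Y


def autoscale(M: pd.DataFrame | np.ndarray, ddof: int = 1):
    """Mean-centre and scale each column to unit standard deviation.

    Returns (scaled, means, scales); ``scaled * scales + means`` reproduces
    the input to machine precision.  A zero-variance column is refused,
    naming the column.
    """
    frame = isinstance(M, pd.DataFrame)
    values = M.to_numpy(dtype=float) if frame else np.asarray(M, dtype=float)
    means = values.mean(axis=0)
    scales = values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        name = M.columns[zero[0]] if frame else int(zero[0])
        raise ValueError(f"zero-variance column {name!r} cannot be autoscaled")
    scaled = (values - means) / scales
    if frame:
        scaled = pd.DataFrame(scaled, index=M.index, columns=M.columns)
        means = pd.Series(means, index=M.columns)
        scales = pd.Series(scales, index=M.columns)
    return scaled, means, scales
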