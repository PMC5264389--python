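"""Odorant comparisons with subject-random-intercept linear mixed models.

For each habituation coordinate (distance to the low/mid/high centroid) the
per-curve distances are modelled as

    distance ~ odorant (fixed) + subject (random intercept) + error,

followed by an omnibus Wald F test of the odorant factor and all pairwise
odorant contrasts with Benjamini-Hochberg false-discovery-rate adjustment.
The denominator degrees of freedom are residual-based,
``n - n_odorants - n_subjects + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = ["OdorantLMM", "MixedModelReport", "fit_odorant_lmm", "pairwise_fdr"]


@dataclass
class MixedModelReport:
    """Omnibus test plus FDR-adjusted pairwise comparisons for one coordinate."""

    coordinate: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: pd.DataFrame  # odorant_i, odorant_j, estimate, se, p, p_adj
    n_significant: int
    alpha: float = 0.05


class OdorantLMM:
    """Fitted random-intercept model of one habituation coordinate.

    REML estimation is used for the variance components so the Wald F test
    is well calibrated in small samples; with the between-subject variance
    at zero the statistic coincides with the one-way fixed-effects ANOVA F.
    Maximum likelihood is available via ``reml=False``.
    """

    def __init__(self, table: pd.DataFrame, coordinate: str, reml: bool = True):
        for col in ("odorant_id", "subject_id", coordinate):
            if col not in table.columns:
                raise ValueError(f"distance table missing column {col!r}")
        self.coordinate = coordinate
        self.levels = sorted(table["odorant_id"].unique())
        if len(self.levels) < 2:
            raise ValueError("need at least two odorants to compare")
        if table["subject_id"].nunique() < 2:
            raise ValueError("need at least two subjects for a random intercept")
        self.table = table.reset_index(drop=True)
        model = MixedLM.from_formula(
            f"{coordinate} ~ C(odorant_id)", groups="subject_id", data=self.table
        )
        # the subject variance can sit on the boundary; fall back through
        # optimizers rather than fail on a singular step
        last_err: Exception | None = None
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            try:
                self.result = model.fit(reml=reml, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
        else:
            raise RuntimeError(f"mixed-model fit failed for {coordinate}") from last_err
        self.n_obs = len(self.table)
        self.n_subjects = self.table["subject_id"].nunique()

    @property
    def df_num(self) -> int:
        return len(self.levels) - 1

    @property
    def df_den(self) -> int:
        return self.n_obs - len(self.levels) - self.n_subjects + 1

    def _odorant_terms(self) -> np.ndarray:
        names = list(self.result.model.exog_names)
        return np.array([i for i, n in enumerate(names) if n.startswith("C(odorant_id)")])

    def omnibus(self) -> tuple[float, int, int, float]:
        """Wald F test of the odorant factor: (F, df_num, df_den, p)."""
        idx = self._odorant_terms()
        beta = np.asarray(self.result.fe_params)[idx]
        cov = np.asarray(self.result.cov_params())[np.ix_(idx, idx)]
        chi2 = float(beta @ np.linalg.solve(cov, beta))
        f_stat = chi2 / self.df_num
        p = float(stats.f.sf(f_stat, self.df_num, self.df_den))
        return f_stat, self.df_num, self.df_den, p

    def pairwise_contrasts(self) -> pd.DataFrame:
        """All pairwise odorant mean differences with t-based p-values."""
        names = list(self.result.model.exog_names)
        k_fe = len(names)
        rows = []
        # mean of level l = intercept + coef_l (reference level has coef 0)
        coef_index = {self.levels[0]: None}
        for lvl in self.levels[1:]:
            term = f"C(odorant_id)[T.{lvl}]"
            coef_index[lvl] = names.index(term)
        beta = np.asarray(self.result.fe_params)
        cov = np.asarray(self.result.cov_params())[:k_fe, :k_fe]
        for a, b in combinations(self.levels, 2):
            L = np.zeros(k_fe)
            if coef_index[a] is not None:
                L[coef_index[a]] = 1.0
            if coef_index[b] is not None:
                L[coef_index[b]] -= 1.0
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else 0.0
            p = float(2 * stats.t.sf(abs(t), self.df_den))
            rows.append({"odorant_i": a, "odorant_j": b, "estimate": est, "se": se, "p": p})
        return pd.DataFrame(rows)


def fit_odorant_lmm(distance_table: pd.DataFrame, coordinate: str, reml: bool = True) -> OdorantLMM:
    """Fit distance ~ odorant + (1 | subject) for one coordinate."""
    return OdorantLMM(distance_table, coordinate, reml=reml)


def pairwise_fdr(fit: OdorantLMM, alpha: float = 0.05) -> MixedModelReport:
    """All-pairs odorant contrasts, BH-adjusted, with the omnibus test."""
    f_stat, df1, df2, p_omni = fit.omnibus()
    table = fit.pairwise_contrasts()
    _, p_adj, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table = table.assign(p_adj=p_adj)
    return MixedModelReport(
        coordinate=fit.coordinate,
        f_statistic=f_stat,
        df_num=df1,
        df_den=df2,
        p_value=p_omni,
        pairwise=table,
        n_significant=int((p_adj < alpha).sum()),
        alpha=alpha,
    )
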