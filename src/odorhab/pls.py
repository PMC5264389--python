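"""Multi-response partial least squares with VIP-based variable ranking.

This is the package's core inferential machine: a from-scratch PLS2
regression in the kernel formulation (each component's predictor weight
vector is the dominant left singular vector of the deflated cross-product
matrix X'Y, which is algebraically the fixed point NIPALS iterates to), with

* leave-one-out cross-validated RMSEP per component and response, the
  autoscaling re-estimated inside every fold;
* per-component explained variance for X (loading reconstruction) and for
  each response (incremental R^2);
* variable importance in the projection (VIP), pooling the explained
  Y-variance over the responses, satisfying sum_j VIP_j^2 = p;
* an interpretation report flagging responses by |loading| and predictors
  by |loading.weight| and VIP, with directional statements that are
  invariant to component sign flips.

The component sign convention is presentational only: each component is
flipped so its largest-magnitude predictor weight is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, MultiOutputMixin, RegressorMixin

__all__ = [
    "KernelPLS",
    "InterpretationReport",
    "fit_pls",
    "loo_rmsep",
    "select_components",
    "explained_variance",
    "vip",
    "interpret",
]


class KernelPLS(MultiOutputMixin, RegressorMixin, BaseEstimator):
    """PLS2 regression via the kernel (cross-product) algorithm.

    Parameters
    ----------
    n_components : int
        Number of latent components A.
    scale : bool
        If True, autoscale X and Y (mean-centre, unit variance, n-1
        denominator) inside ``fit`` and undo the scaling in ``predict``.
        If False the inputs are only centred, the convention when the
        caller autoscales explicitly.

    Attributes
    ----------
    x_weights_ : ndarray (p, A)
        Loading weights W, unit-norm columns; interpreted like correlations
        of the predictors with each component.
    x_loadings_ : ndarray (p, A)
        X loadings P (regression of X on the scores).
    y_loadings_ : ndarray (m, A)
        Y loadings Q, orienting the responses on each component.
    x_scores_ : ndarray (n, A)
        Scores T with mutually orthogonal columns.
    x_rotations_ : ndarray (p, A)
        R = W (P'W)^-1 so that T = Xc R.
    coef_ : ndarray (p, m)
        Regression coefficients at A components, on the scaled scale.
    explained_x_variance_ : ndarray (A,)
        Percent of X variance captured per component.
    explained_y_variance_ : ndarray (A, m)
        Incremental percent of each response's variance explained.
    vip_ : ndarray (p,)
        Variable importance in the projection, pooled over responses.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        m = Y.shape[1]
        A = self.n_components
        if not 1 <= A <= min(n - 1, p):
            raise ValueError(f"n_components={A} not in [1, min(n-1, p)={min(n - 1, p)}]")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        if self.scale:
            self.x_std_ = X.std(axis=0, ddof=1)
            self.y_std_ = Y.std(axis=0, ddof=1)
            # a column constant inside this sample (e.g. a single-member
            # category level dropped by a CV fold) carries no information;
            # leave it centred-only instead of refusing the fit
            self.x_std_[self.x_std_ == 0] = 1.0
            if np.any(self.y_std_ == 0):
                raise ValueError("zero-variance response; cannot autoscale")
        else:
            self.x_std_ = np.ones(p)
            self.y_std_ = np.ones(m)
        Xc = (X - self.x_mean_) / self.x_std_
        Yc = (Y - self.y_mean_) / self.y_std_
        total_x = float((Xc**2).sum())
        if total_x == 0:
            raise ValueError("X is identically zero; nothing to decompose")

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        Q = np.zeros((m, A))
        T = np.zeros((n, A))
        Xd = Xc.copy()
        n_found = 0
        for a in range(A):
            S = Xd.T @ Yc
            if m == 1:
                s_norm = float(np.linalg.norm(S[:, 0]))
                if s_norm < 1e-14:
                    break
                w = S[:, 0] / s_norm
            else:
                U, sv, _ = np.linalg.svd(S, full_matrices=False)
                if sv[0] < 1e-14:
                    break
                w = U[:, 0]
            if w[np.argmax(np.abs(w))] < 0:  # presentational sign convention
                w = -w
            t = Xd @ w
            tt = float(t @ t)
            if tt < 1e-14:
                break
            P[:, a] = Xd.T @ t / tt
            Q[:, a] = Yc.T @ t / tt
            W[:, a] = w
            T[:, a] = t
            Xd -= np.outer(t, P[:, a])
            n_found += 1
        if n_found == 0:
            raise ValueError("no PLS component could be extracted (degenerate input)")
        self.n_components_ = n_found
        W, P, Q, T = W[:, :n_found], P[:, :n_found], Q[:, :n_found], T[:, :n_found]
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, Q, T
        self.x_rotations_ = W @ np.linalg.inv(P.T @ W)
        self.coef_ = self.x_rotations_ @ Q.T

        tt = (T**2).sum(axis=0)
        self.explained_x_variance_ = 100.0 * tt * (P**2).sum(axis=0) / total_x
        ss_y = (Yc**2).sum(axis=0)
        r2 = np.zeros((n_found, m))
        for a in range(1, n_found + 1):
            resid = Yc - T[:, :a] @ Q[:, :a].T
            r2[a - 1] = 1.0 - (resid**2).sum(axis=0) / ss_y
        self.explained_y_variance_ = 100.0 * np.diff(r2, axis=0, prepend=0.0)
        self._y_ss_components_ = tt * (Q**2).sum(axis=0)  # Y-variance per component
        self.vip_ = self._compute_vip()
        return self

    def _compute_vip(self) -> np.ndarray:
        ss = self._y_ss_components_
        total = ss.sum()
        if total <= 0:
            raise ValueError("zero explained variance; VIP undefined")
        p = self.x_weights_.shape[0]
        w2 = self.x_weights_**2  # columns already unit norm
        return np.sqrt(p * (w2 @ ss) / total)

    def coef_path(self) -> np.ndarray:
        """Coefficients (scaled space) for every truncation a = 1..A: (A, p, m)."""
        A = self.n_components_
        out = np.zeros((A, *self.coef_.shape))
        for a in range(1, A + 1):
            R_a = self.x_weights_[:, :a] @ np.linalg.inv(
                self.x_loadings_[:, :a].T @ self.x_weights_[:, :a]
            )
            out[a - 1] = R_a @ self.y_loadings_[:, :a].T
        return out

    def predict(self, X, n_components: int | None = None):
        X = np.asarray(X, dtype=float)
        if n_components is None:
            B = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValueError("n_components out of fitted range")
            B = self.coef_path()[n_components - 1]
        Yh = ((X - self.x_mean_) / self.x_std_) @ B
        return Yh * self.y_std_ + self.y_mean_

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return ((X - self.x_mean_) / self.x_std_) @ self.x_rotations_


def fit_pls(X, Y, A_max: int, scale: bool = False) -> KernelPLS:
    """Fit a PLS2 model with A_max components (X, Y typically pre-autoscaled)."""
    return KernelPLS(n_components=A_max, scale=scale).fit(X, Y)


def loo_rmsep(X, Y, A_max: int, scale: bool = True) -> pd.DataFrame:
    """Leave-one-out RMSEP for every component count and response.

    rmsep[a, r] = sqrt(mean_i (y_ir - yhat_ir^(-i, a))^2) where each
    prediction comes from a model fit without sample i; centring and
    scaling are re-estimated inside each fold, so no information leaks
    from the held-out sample.  RMSEP is reported on the original Y scale.
    """
    X = np.asarray(X, dtype=float)
    Yarr = np.asarray(Y, dtype=float)
    if Yarr.ndim == 1:
        Yarr = Yarr[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if A_max > min(n - 2, p):
        raise ValueError(f"A_max={A_max} too large for leave-one-out on n={n}, p={p}")
    m = Yarr.shape[1]
    sq_err = np.zeros((A_max, m))
    for i in range(n):
        keep = np.arange(n) != i
        model = KernelPLS(n_components=A_max, scale=scale).fit(X[keep], Yarr[keep])
        paths = model.coef_path()  # (A_fit, p, m)
        x_i = (X[i] - model.x_mean_) / model.x_std_
        for a in range(A_max):
            B = paths[min(a, model.n_components_ - 1)]
            pred = (x_i @ B) * model.y_std_ + model.y_mean_
            sq_err[a] += (Yarr[i] - pred) ** 2
    rmsep = np.sqrt(sq_err / n)
    columns = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"y{r}" for r in range(m)]
    return pd.DataFrame(rmsep, index=pd.RangeIndex(1, A_max + 1, name="n_components"),
                        columns=columns)


def select_components(rmsep: pd.DataFrame) -> tuple[dict, int]:
    """Per-response argmin of RMSEP (ties -> fewest components) and the
    global component count, the maximum over responses."""
    per_response = {col: int(rmsep[col].idxmin()) for col in rmsep.columns}
    return per_response, max(per_response.values())


def explained_variance(fit: KernelPLS) -> pd.DataFrame:
    """Percent variance explained per component: X plus each response."""
    a = fit.n_components_
    table = pd.DataFrame(
        fit.explained_y_variance_,
        index=pd.RangeIndex(1, a + 1, name="component"),
        columns=[f"y{r}" for r in range(fit.y_loadings_.shape[0])],
    )
    table.insert(0, "X", fit.explained_x_variance_)
    return table


def vip(fit: KernelPLS) -> np.ndarray:
    """Variable importance in the projection (pooled over responses)."""
    return fit.vip_


@dataclass
class InterpretationReport:
    """Thresholded reading of a PLS fit, component by component.

    ``components`` maps component number to the responses passing the
    loading threshold and the predictors passing the loading-weight
    threshold (with signed values).  ``summary`` is a Table-2-style frame:
    one row per important predictor (VIP above threshold) giving its VIP,
    the component where it contributes most, and the direction of its
    association with habituation.  Directions are phrased against the
    similarity orientation of the responses: a predictor whose weight has
    the sign *opposite* to the lowhab loading pushes odorants closer to
    the low-habituation profile, i.e. less habituation when it increases.
    """

    components: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    thresholds: tuple = (0.3, 0.2, 1.0)


def interpret(
    fit: KernelPLS,
    feature_names,
    response_names=("lowhab", "midhab", "highhab"),
    lw_threshold: float = 0.3,
    loading_threshold: float = 0.2,
    vip_threshold: float = 1.0,
    reference_response: str = "lowhab",
) -> InterpretationReport:
    """Flag influential variables and summarise directions of effect."""
    feature_names = list(feature_names)
    response_names = list(response_names)
    W, Q = fit.x_weights_, fit.y_loadings_
    A = fit.n_components_
    comps = {}
    for a in range(A):
        flagged_resp = [
            (response_names[r], float(Q[r, a]))
            for r in range(Q.shape[0])
            if abs(Q[r, a]) > loading_threshold
        ]
        flagged_pred = [
            (feature_names[j], float(W[j, a]))
            for j in range(W.shape[0])
            if abs(W[j, a]) > lw_threshold
        ]
        comps[a + 1] = {"responses": flagged_resp, "predictors": flagged_pred}

    ref = response_names.index(reference_response)
    contrib = (W**2) * fit._y_ss_components_  # (p, A) VIP contribution terms
    rows = []
    for j, name in enumerate(feature_names):
        if fit.vip_[j] <= vip_threshold:
            continue
        a_star = int(np.argmax(contrib[j]))
        sign_prod = np.sign(W[j, a_star] * Q[ref, a_star])
        direction = "decreases" if sign_prod > 0 else "increases"
        rows.append(
            {
                "variable": name,
                "vip": float(fit.vip_[j]),
                "component": a_star + 1,
                "less_habituation_when": direction,
            }
        )
    summary = pd.DataFrame(rows).sort_values("vip", ascending=False).reset_index(drop=True) \
        if rows else pd.DataFrame(columns=["variable", "vip", "component", "less_habituation_when"])
    return InterpretationReport(
        components=comps,
        summary=summary,
        thresholds=(lw_threshold, loading_threshold, vip_threshold),
    )
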