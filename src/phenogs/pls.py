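"""Univariate partial least squares by the kernel algorithm.

PLS regresses y on orthogonal latent scores T extracted to maximize
covariance with the predictors.  For a univariate response the per-component
weight reduces to the normalized cross-product w = X'y / ||X'y|| (the
dominant eigenvector of X'y y'X), and the algorithm iterates

    w = S/||S||,  t = E w (normalized),  p = E't,  q = f't,
    E <- E - t p',  f <- f - t q

on the centered, deflated matrices.  After extracting a components,

    R = W (P'W)^-1,   T = X_c R,   b = (T'T)^-1 T' y_c,   B = R b

so predictions for new data follow two algebraically identical routes,
X_new,c B and T_new b with T_new = X_new,c R.

The number of components is tuned by inner k-fold cross-validation on the
normalized root-mean-squared error, NRMSE = RMSE / sd(observed) by default
(range and mean denominators, or plain MSE, by configuration); ties resolve
to the smallest a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelPLS", "KernelPLSResults", "TuneResult", "fit_pls", "tune_components"]

_EPS = 1e-12


class KernelPLS:
    """PLS model of a univariate response on an n x p predictor matrix."""

    def __init__(self, X, y, scale: bool = False):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if np.ptp(self.y) == 0:
            raise ValueError("constant response; PLS is undefined")
        if not np.any(self.X.std(axis=0) > 0):
            raise ValueError("X has no nonconstant column")
        self.scale = scale

    def fit(self, a: int) -> "KernelPLSResults":
        """Extract up to ``a`` latent components (stops early at rank)."""
        n, p = self.X.shape
        if a < 1:
            raise ValueError("number of components must be >= 1")
        a = min(a, n - 1, p)
        x_mean = self.X.mean(axis=0)
        y_mean = self.y.mean()
        Xc = self.X - x_mean
        x_scale = np.ones(p)
        if self.scale:
            x_scale = Xc.std(axis=0, ddof=0)
            x_scale = np.where(x_scale > 0, x_scale, 1.0)
            Xc = Xc / x_scale
        yc = self.y - y_mean

        E = Xc.copy()
        f = yc.copy()
        Ws, Ts, Ps, Qs = [], [], [], []
        for _ in range(a):
            S = E.T @ f
            norm_s = np.linalg.norm(S)
            if norm_s < _EPS:  # deflated matrices numerically empty
                break
            w = S / norm_s
            t = E @ w
            norm_t = np.linalg.norm(t)
            if norm_t < _EPS:
                break
            t = t / norm_t
            pvec = E.T @ t
            qval = f @ t
            E = E - np.outer(t, pvec)
            f = f - t * qval
            Ws.append(w)
            Ts.append(t)
            Ps.append(pvec)
            Qs.append(qval)
        if not Ws:
            raise ValueError("no extractable PLS component (rank-zero predictors)")
        W = np.column_stack(Ws)
        P = np.column_stack(Ps)
        Q = np.asarray(Qs)
        R = W @ np.linalg.inv(P.T @ W)
        T = Xc @ R
        # regression of the undeflated centered y on the scores
        b = np.linalg.solve(T.T @ T, T.T @ yc)
        B = R @ b
        return KernelPLSResults(
            model=self,
            W=W, P=P, Q=Q, R=R, T=T, b=b, B=B,
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
            a=W.shape[1],
        )


@dataclass
class KernelPLSResults:
    """Fitted PLS loadings, scores and original-variable coefficients."""

    model: KernelPLS
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    T: np.ndarray
    b: np.ndarray
    B: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    a: int

    def _center(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects {self.x_mean.shape[0]}"
            )
        return (X_new - self.x_mean) / self.x_scale

    def predict(self, X_new, n_components: int | None = None) -> np.ndarray:
        """y_hat = X_new,c B + y_mean (coefficient route).

        ``n_components`` < a uses the nested sub-model (valid because the
        score columns are orthogonal, so b entries do not change).
        """
        k = self.a if n_components is None else min(n_components, self.a)
        Bk = self.R[:, :k] @ self.b[:k]
        return self._center(X_new) @ Bk + self.y_mean

    def predict_via_scores(self, X_new) -> np.ndarray:
        """y_hat = T_new b + y_mean with T_new = X_new,c R (score route)."""
        return (self._center(X_new) @ self.R) @ self.b + self.y_mean

    def predict_all_components(self, X_new) -> np.ndarray:
        """n_new x a matrix of predictions for every component count 1..a."""
        t_new = self._center(X_new) @ self.R
        return np.cumsum(t_new * self.b[None, :], axis=1) + self.y_mean

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.T @ self.b + self.y_mean

    def save(self, out_dir) -> None:
        """Serialize to a JSON (scalars/centering) + matrix-CSV bundle."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "a": self.a,
            "y_mean": self.y_mean,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "b": self.b.tolist(),
            "Q": self.Q.tolist(),
        }
        with open(out / "pls_model.json", "w") as fh:
            json.dump(meta, fh)
        for name in ("W", "P", "R", "T", "B"):
            np.savetxt(out / f"pls_{name}.csv", np.atleast_2d(getattr(self, name)), delimiter=",")

    def summary(self) -> str:
        resid = self.model.y - self.fittedvalues
        return (
            f"Kernel PLS: n={self.model.X.shape[0]}, p={self.model.X.shape[1]}, "
            f"components={self.a}\n"
            f"training RMSE: {np.sqrt(np.mean(resid**2)):.6g}\n"
            f"score norms (T'T diag): {np.round(np.diag(self.T.T @ self.T), 6)}"
        )


def fit_pls(X, y, a: int, scale: bool = False) -> KernelPLSResults:
    """Convenience wrapper for ``KernelPLS(X, y).fit(a)``."""
    return KernelPLS(X, y, scale=scale).fit(a)


@dataclass
class TuneResult:
    a_star: int
    curve: np.ndarray  # mean inner-validation metric for a = 1..a_max
    metric: str


def _fold_metric(obs, pred, metric: str) -> float:
    resid = obs - pred
    mse = float(np.mean(resid**2))
    if metric == "mse":
        return mse
    rmse = np.sqrt(mse)
    if metric == "nrmse":
        denom = float(np.std(obs, ddof=1))
    elif metric == "nrmse_range":
        denom = float(np.ptp(obs))
    elif metric == "nrmse_mean":
        denom = float(np.mean(obs))
    else:
        raise ValueError(f"unknown tuning metric {metric!r}")
    if denom == 0:
        raise ValueError("constant validation fold; NRMSE undefined")
    return rmse / denom


def tune_components(
    X,
    y,
    a_max: int,
    k_inner: int = 10,
    seed: int = 0,
    metric: str = "nrmse",
    scale: bool = False,
) -> TuneResult:
    """Choose the component count by inner k-fold cross-validation.

    For a = 1..a_max the metric is averaged over the k validation folds
    (each inner model is fitted once at a_max; nested sub-model predictions
    are exact because the scores are orthogonal).  The argmin wins, smallest
    a on ties.  Fold assignment is a uniformly random partition from
    ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    if n < k_inner:
        raise ValueError(f"n={n} observations cannot form {k_inner} folds")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % k_inner
    per_fold = np.full((k_inner, a_max), np.nan)
    for fold in range(k_inner):
        val = assignment == fold
        res = KernelPLS(X[~val], y[~val], scale=scale).fit(a_max)
        preds = res.predict_all_components(X[val])  # n_val x achieved
        for a in range(1, a_max + 1):
            col = min(a, res.a) - 1
            per_fold[fold, a - 1] = _fold_metric(y[val], preds[:, col], metric)
    curve = per_fold.mean(axis=0)
    a_star = int(np.argmin(curve)) + 1
    return TuneResult(a_star=a_star, curve=curve, metric=metric)
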