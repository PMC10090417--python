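"""Per-environment BLUEs and across-environment variance components.

Field trials follow one of two designs.  Alpha lattice:

    y_ijkl = mu + g_i + check_i + t_j + r_k(j) + b_l(jk) + e_ijkl

with fixed genotype and check effects and random trial, replicate-within-
trial and incomplete-block effects.  Augmented RCBD:

    y_ij = mu + g_i + check_i + b_j + e_ij

with a random complete-block effect.  Both are linear mixed models

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k I),  e ~ N(0, s2 I)

solved through Henderson's mixed-model equations with variance components
estimated by EM-REML (monotone in the restricted likelihood).  Genotype
BLUEs are reported as intercept + effect under a sum-to-zero constraint
over non-check genotypes.

Across environments, the per-environment BLUEs feed

    blue = mu + env (fixed) + g (random) + gxe (random) + e

whose components give the entry-mean heritability

    H2 = s2_g / (s2_g + s2_ge / n_e + s2_e / (n_e * n_r))

with n_e the mean number of environments per line and n_r the mean number
of replications.  With a single observation per line x environment cell the
gxe and residual variances are confounded (their design matrices coincide);
only their sum is then identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MixedLMM",
    "TrialBLUEModel",
    "VarianceComponentsModel",
    "VarianceComponents",
    "fit_blues",
    "estimate_variance_components",
    "heritability",
]


# --------------------------------------------------------------------------
# generic mixed linear model via Henderson's MME + EM-REML
# --------------------------------------------------------------------------


@dataclass
class MixedLMMResults:
    fixed_effects: np.ndarray
    random_effects: dict
    var_components: dict  # per random term, plus "residual"
    cinv: np.ndarray  # inverse MME coefficient matrix
    n_iter: int
    converged: bool
    loglik_path: list

    @property
    def loglik(self):
        return self.loglik_path[-1] if self.loglik_path else None


class MixedLMM:
    """y = Xb + sum_k Z_k u_k + e with i.i.d. random effects per term."""

    def __init__(self, y, X, random_terms: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.terms = {k: np.asarray(Z, dtype=float) for k, Z in random_terms.items()}
        n = self.y.shape[0]
        if self.X.shape[0] != n or any(Z.shape[0] != n for Z in self.terms.values()):
            raise ValueError("X and all Z matrices must have one row per observation")
        self.rank_x = np.linalg.matrix_rank(self.X)
        if self.rank_x < self.X.shape[1]:
            raise ValueError("fixed-effects design matrix is rank deficient (confounded factors?)")

    def fit(self, tol: float = 1e-6, max_iter: int = 500, track_loglik: bool = True) -> MixedLMMResults:
        y, X = self.y, self.X
        n, p = X.shape
        names = list(self.terms)
        Zs = [self.terms[k] for k in names]
        qs = [Z.shape[1] for Z in Zs]
        q = sum(qs)
        Zall = np.hstack(Zs) if Zs else np.zeros((n, 0))
        W = np.hstack([X, Zall])
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)

        vary = float(y.var()) or 1.0
        floor = 1e-10 * vary
        s2e = vary / 2.0
        s2 = {k: vary / (2.0 * max(len(names), 1)) for k in names}

        offsets = np.cumsum([p] + qs)
        lls: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            M = WtW.copy()
            for k, name in enumerate(names):
                sl = slice(offsets[k], offsets[k + 1])
                M[sl, sl] += np.eye(qs[k]) * (s2e / s2[name])
            cinv = np.linalg.inv(M)
            sol = cinv @ Wty
            b = sol[:p]
            new = {}
            for k, name in enumerate(names):
                sl = slice(offsets[k], offsets[k + 1])
                uk = sol[sl]
                tr = np.trace(cinv[sl, sl])
                new[name] = max((uk @ uk + s2e * tr) / qs[k], floor)
            s2e_new = max((yty - sol @ Wty) / (n - self.rank_x), floor)

            if track_loglik:
                lls.append(self._reml_loglik(M, sol, Wty, yty, s2e, s2, qs, names, n, p, q))
            delta = abs(s2e_new - s2e) / max(s2e, floor)
            for name in names:
                delta = max(delta, abs(new[name] - s2[name]) / max(s2[name], floor))
            s2e, s2 = s2e_new, new
            if delta < tol:
                converged = True
                break

        # final solve at converged variances
        M = WtW.copy()
        for k, name in enumerate(names):
            sl = slice(offsets[k], offsets[k + 1])
            M[sl, sl] += np.eye(qs[k]) * (s2e / s2[name])
        cinv = np.linalg.inv(M)
        sol = cinv @ Wty
        if track_loglik:
            lls.append(self._reml_loglik(M, sol, Wty, yty, s2e, s2, qs, names, n, p, q))
        random_effects = {
            name: sol[offsets[k] : offsets[k + 1]] for k, name in enumerate(names)
        }
        vc = dict(s2)
        vc["residual"] = s2e
        return MixedLMMResults(
            fixed_effects=sol[:p],
            random_effects=random_effects,
            var_components=vc,
            cinv=cinv,
            n_iter=it,
            converged=converged,
            loglik_path=lls,
        )

    @staticmethod
    def _reml_loglik(M, sol, Wty, yty, s2e, s2, qs, names, n, p, q) -> float:
        """Restricted log-likelihood up to a constant, via MME identities."""
        sign, logdet_m = np.linalg.slogdet(M)
        ypy = (yty - sol @ Wty) / s2e
        val = (n - p - q) * np.log(s2e) + sum(qk * np.log(s2[nm]) for qk, nm in zip(qs, names))
        return -0.5 * (val + logdet_m + ypy)


# --------------------------------------------------------------------------
# per-environment trial BLUEs
# --------------------------------------------------------------------------


def _one_hot(labels) -> tuple[np.ndarray, list]:
    labels = pd.Series(labels).astype(str)
    levels = sorted(labels.unique())
    idx = labels.map({l: i for i, l in enumerate(levels)}).to_numpy()
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), idx] = 1.0
    return Z, levels


class TrialBLUEModel:
    """Single-environment mixed model yielding genotype BLUEs.

    Built from a plot table with columns (line, is_check, yield) plus the
    design factors (trial, rep, block) for an alpha lattice or (block) for
    an augmented RCBD.
    """

    def __init__(self, plots: pd.DataFrame, design: str = "alpha_lattice"):
        if design not in ("alpha_lattice", "augmented"):
            raise ValueError(f"unknown design {design!r}")
        if plots["env"].nunique() > 1 if "env" in plots.columns else False:
            raise ValueError("one environment per TrialBLUEModel; split by env first")
        self.design = design
        self.plots = plots.reset_index(drop=True)
        y = self.plots["yield"].to_numpy(dtype=float)
        is_check = self.plots["is_check"].astype(bool).to_numpy()
        lines = self.plots["line"].astype(str)

        self.entry_levels = sorted(lines[~is_check].unique())
        self.check_levels = sorted(lines[is_check].unique())
        n = len(self.plots)
        m = len(self.entry_levels)
        if m < 2:
            raise ValueError("need at least two non-check genotypes")
        # sum-to-zero contrast over non-check genotypes: columns for first m-1,
        # last genotype coded -1 across all of them
        Xg = np.zeros((n, m - 1))
        emap = {g: i for i, g in enumerate(self.entry_levels)}
        for r, (g, chk) in enumerate(zip(lines, is_check)):
            if chk:
                continue
            i = emap[g]
            if i < m - 1:
                Xg[r, i] = 1.0
            else:
                Xg[r, :] = -1.0
        Xc = np.zeros((n, len(self.check_levels)))
        cmap = {g: i for i, g in enumerate(self.check_levels)}
        for r, (g, chk) in enumerate(zip(lines, is_check)):
            if chk:
                Xc[r, cmap[g]] = 1.0
        X = np.hstack([np.ones((n, 1)), Xg, Xc])

        random_terms = {}
        if design == "alpha_lattice":
            factors = [("trial", ["trial"]), ("rep", ["trial", "rep"]), ("block", ["trial", "rep", "block"])]
        else:
            factors = [("block", ["block"])]
        for name, cols in factors:
            key = self.plots[cols].astype(str).agg("|".join, axis=1)
            Z, levels = _one_hot(key)
            if len(levels) >= 2:  # single-level factor is confounded with mu
                random_terms[name] = Z
        self._lmm = MixedLMM(y, X, random_terms)
        self._X = X

    def fit(self, tol: float = 1e-6, max_iter: int = 500, track_loglik: bool = False) -> "TrialBLUEResults":
        res = self._lmm.fit(tol=tol, max_iter=max_iter, track_loglik=track_loglik)
        return TrialBLUEResults(self, res)


class TrialBLUEResults:
    def __init__(self, model: TrialBLUEModel, lmm_results: MixedLMMResults):
        self.model = model
        self._res = lmm_results
        self.varcomp = dict(lmm_results.var_components)
        self.loglik_path = lmm_results.loglik_path
        m = len(model.entry_levels)
        c = len(model.check_levels)
        p = 1 + (m - 1) + c
        beta = lmm_results.fixed_effects
        s2e = self.varcomp["residual"]
        cxx = lmm_results.cinv[:p, :p] * s2e
        rows = []
        for i, g in enumerate(model.entry_levels):
            contrast = np.zeros(p)
            contrast[0] = 1.0
            if i < m - 1:
                contrast[1 + i] = 1.0
            else:
                contrast[1 : m] = -1.0
            rows.append((g, False, float(contrast @ beta), float(np.sqrt(max(contrast @ cxx @ contrast, 0.0)))))
        for j, g in enumerate(model.check_levels):
            contrast = np.zeros(p)
            contrast[0] = 1.0
            contrast[m + j] = 1.0
            rows.append((g, True, float(contrast @ beta), float(np.sqrt(max(contrast @ cxx @ contrast, 0.0)))))
        self.blues = pd.DataFrame(rows, columns=["line", "is_check", "blue", "se"]).sort_values("line").reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Trial BLUE model ({self.model.design}), {len(self.model.plots)} plots, "
            f"{len(self.model.entry_levels)} entries, {len(self.model.check_levels)} checks",
            f"converged: {self._res.converged} in {self._res.n_iter} EM-REML iterations",
            "variance components:",
        ]
        for k, v in self.varcomp.items():
            lines.append(f"  {k:>10s}: {v:.6g}")
        return "\n".join(lines)


def fit_blues(plots: pd.DataFrame, design: str = "alpha_lattice", **fit_kwargs):
    """Convenience wrapper: (blues DataFrame, variance components dict)."""
    res = TrialBLUEModel(plots, design=design).fit(**fit_kwargs)
    return res.blues, res.varcomp


# --------------------------------------------------------------------------
# across-environment variance components and heritability
# --------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    var_g: float
    var_ge: float
    var_residual: float
    n_e: float
    n_r: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class VarianceComponentsModel:
    """blue = mu + env (fixed) + g (random) + gxe (random) + e.

    Built from a long table with columns (line, env, value); replicate rows
    per line x environment cell are allowed (and required to separate the
    gxe and residual variances).
    """

    def __init__(self, table: pd.DataFrame, value_col: str = "value"):
        self.table = table.reset_index(drop=True)
        self.value_col = value_col
        y = self.table[value_col].to_numpy(dtype=float)
        X, self.env_levels = _one_hot(self.table["env"])  # env one-hot doubles as intercept
        Zg, self.line_levels = _one_hot(self.table["line"])
        terms = {"g": Zg}
        self.single_env = len(self.env_levels) < 2
        if not self.single_env:
            cell = self.table["line"].astype(str) + "|" + self.table["env"].astype(str)
            Zge, self.cell_levels = _one_hot(cell)
            terms["ge"] = Zge
        self._lmm = MixedLMM(y, X, terms)

    def fit(self, tol: float = 1e-6, max_iter: int = 500, track_loglik: bool = False) -> "VarianceComponentsResults":
        res = self._lmm.fit(tol=tol, max_iter=max_iter, track_loglik=track_loglik)
        return VarianceComponentsResults(self, res)


class VarianceComponentsResults:
    def __init__(self, model: VarianceComponentsModel, lmm_results: MixedLMMResults):
        self.model = model
        self._res = lmm_results
        self.loglik_path = lmm_results.loglik_path
        vc = lmm_results.var_components
        n_e, n_r = _unbalance(model.table)
        self.components = VarianceComponents(
            var_g=vc["g"],
            var_ge=vc.get("ge", float("nan")),  # not estimable with one environment
            var_residual=vc["residual"],
            n_e=n_e,
            n_r=n_r,
        )

    @property
    def heritability(self) -> float:
        return heritability(self.components)

    def summary(self) -> str:
        c = self.components
        return (
            f"Across-environment variance components ({len(self.model.line_levels)} lines, "
            f"{len(self.model.env_levels)} environments)\n"
            f"  var_g        = {c.var_g:.6g}\n"
            f"  var_ge       = {c.var_ge:.6g}\n"
            f"  var_residual = {c.var_residual:.6g}\n"
            f"  n_e = {c.n_e:.3f}, n_r = {c.n_r:.3f}\n"
            f"  entry-mean H2 = {self.heritability:.4f}"
        )


def _unbalance(table: pd.DataFrame) -> tuple[float, float]:
    n_e = float(table.groupby("line")["env"].nunique().mean())
    n_r = float(table.groupby(["line", "env"]).size().mean())
    return n_e, n_r


def estimate_variance_components(blue_table: pd.DataFrame, value_col: str = "value", **fit_kwargs) -> VarianceComponents:
    """EM-REML variance components from a (line, env, value) table."""
    return VarianceComponentsModel(blue_table, value_col=value_col).fit(**fit_kwargs).components


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean heritability H2 = s2_g / (s2_g + s2_ge/n_e + s2_e/(n_e n_r))."""
    var_ge = 0.0 if np.isnan(vc.var_ge) else vc.var_ge
    if vc.var_g < 0 or var_ge < 0 or vc.var_residual < 0:
        raise ValueError("variance components must be non-negative")
    denom = vc.var_g + var_ge / vc.n_e + vc.var_residual / (vc.n_e * vc.n_r)
    if denom == 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return vc.var_g / denom
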