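"""Cross-validation protocols and prediction-accuracy metrics.

Two schemes evaluate multi-environment yield prediction:

* **7FCV** ("partially tested lines in tested environments"): observations
  (line x environment cells) are partitioned uniformly at random into 7
  folds; 6 folds (85.71% of the data) train, one fold (14.29%) tests, each
  fold tested once.  PLS tunes its component count by an inner 10-fold
  split of the outer-training set (inner-training 77.14% and validation
  8.57% of all data), then refits on the whole outer-training set; GBLUP
  needs no tuning.  Per-environment accuracy is the mean over folds of the
  within-fold within-environment Pearson correlation; the across-
  environment "Global" accuracy correlates per-line averages of observed
  and predicted values over whatever environments each line has.

* **LOEO** ("partially tested lines in untested environments"): each
  environment is held out once, so each environment's accuracy comes from
  its single test fold.  The Global value pools the held-out predictions
  of all environments (a per-environment average is reported alongside,
  with its standard error across environments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import PredictorBuilder, ETA_IDS
from .gblup import GblupSpec, MultiKernelGBLUP
from .markers import Kernel
from .pls import KernelPLS, tune_components

__all__ = [
    "FoldPlan",
    "CVResult",
    "PredictionDataset",
    "make_folds",
    "pearson",
    "nrmse",
    "run_7fcv",
    "run_loeo",
    "LOEO_DEFAULT_ETAS",
]

# the five predictor sets evaluated under LOEO: genomic only, spectral only
# (H / I), and the additive genomic+spectral combinations with GxE
LOEO_DEFAULT_ETAS = ("ETA1", "ETA8", "ETA9", "ETA3", "ETA6")


@dataclass
class FoldPlan:
    scheme: str  # "7FCV" or "LOEO"
    assignment: np.ndarray  # observation -> fold index (or env label for LOEO)
    seed: int | None = None

    @property
    def n_folds(self) -> int:
        return len(np.unique(self.assignment))


def make_folds(n_obs: int, k: int = 7, seed: int = 0, groups=None) -> FoldPlan:
    """Uniformly random partition into k folds of sizes floor(n/k)/ceil(n/k).

    With ``groups`` (e.g. line IDs) the partition is drawn at the group
    level so all observations of a group share a fold.
    """
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        sub = make_folds(len(uniq), k=k, seed=seed)
        lookup = dict(zip(uniq, sub.assignment))
        return FoldPlan("7FCV", np.array([lookup[g] for g in groups]), seed)
    if n_obs < k:
        raise ValueError(f"cannot split {n_obs} observations into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n_obs, dtype=int)
    assignment[rng.permutation(n_obs)] = np.arange(n_obs) % k
    return FoldPlan("7FCV", assignment, seed)


def pearson(obs, pred) -> float:
    """Sample Pearson correlation; NaN (with a warning) on degenerate input."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size < 3:
        warnings.warn("fewer than 3 pairs; correlation not reported")
        return float("nan")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        warnings.warn("constant vector; correlation undefined")
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


def nrmse(obs, pred, denominator: str = "sd") -> float:
    """RMSE normalized by a spread measure of the observed values."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if denominator == "sd":
        d = float(np.std(obs, ddof=1))
    elif denominator == "range":
        d = float(np.ptp(obs))
    elif denominator == "mean":
        d = float(np.mean(obs))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if d == 0:
        raise ValueError("constant observed values; NRMSE undefined")
    return rmse / d


@dataclass
class CVResult:
    scheme: str
    model: str
    eta_id: str
    per_env: pd.DataFrame  # columns: env, cor, se
    global_cor: float
    global_se: float
    predictions: pd.DataFrame  # line, env, fold, y_obs, y_pred
    hyperparams: list = field(default_factory=list)  # per fold (PLS)
    global_cor_averaged: float = float("nan")  # LOEO: mean of per-env correlations

    def summary(self) -> str:
        rows = [f"{self.scheme} {self.model} {self.eta_id}"]
        for _, r in self.per_env.iterrows():
            rows.append(f"  {r['env']:>10s}: cor = {r['cor']:.3f} (se {r['se']:.3f})")
        rows.append(f"  {'Global':>10s}: cor = {self.global_cor:.3f} (se {self.global_se:.3f})")
        return "\n".join(rows)


class PredictionDataset:
    """Observations (line, env, y) plus GRM and spectral features.

    Caches the :class:`~phenogs.features.PredictorBuilder` so repeated CV
    runs over different ETAs share design matrices and kernel roots.
    """

    def __init__(self, obs_table: pd.DataFrame, grm: Kernel, features: pd.DataFrame | None = None):
        required = {"line", "env", "y"}
        if not required.issubset(obs_table.columns):
            raise ValueError(f"observation table needs columns {sorted(required)}")
        self.obs_table = obs_table.reset_index(drop=True)
        self.y = self.obs_table["y"].to_numpy(dtype=float)
        self.builder = PredictorBuilder(self.obs_table, grm, features)
        self._cache: dict = {}

    @property
    def n_obs(self) -> int:
        return len(self.obs_table)

    def predictor(self, eta_id: str):
        if eta_id not in self._cache:
            self._cache[eta_id] = self.builder.build(eta_id)
        return self._cache[eta_id]


def _se_analytic(r: float, n: int) -> float:
    if not np.isfinite(r) or n <= 2:
        return float("nan")
    return float(np.sqrt(max(1.0 - r**2, 0.0) / (n - 2)))


def _fit_predict(
    dataset: PredictionDataset,
    eta_id: str,
    train: np.ndarray,
    test: np.ndarray,
    model: str,
    seed: int,
    pls_opts: dict,
    gblup_spec: GblupSpec | None,
):
    """Predictions for ``test`` rows trained on ``train`` rows only."""
    pset = dataset.predictor(eta_id)
    y = dataset.y
    if model == "pls":
        X = pset.matrix
        opts = {"a_max": 15, "k_inner": 10, "metric": "nrmse", "scale": False}
        opts.update(pls_opts)
        a_max = min(opts["a_max"], train.sum() - 1, X.shape[1])
        tune = tune_components(
            X[train], y[train], a_max=a_max, k_inner=opts["k_inner"],
            seed=seed, metric=opts["metric"], scale=opts["scale"],
        )
        res = KernelPLS(X[train], y[train], scale=opts["scale"]).fit(tune.a_star)
        return res.predict(X[test]), {"a": tune.a_star}
    if model == "gblup":
        spec = gblup_spec or GblupSpec(n_iter=3000, burn_in=1000, thin=2)
        spec = GblupSpec(
            n_iter=spec.n_iter, burn_in=spec.burn_in, thin=spec.thin,
            df0=spec.df0, r2=spec.r2, seed=seed,
        )
        mask = train.copy()
        fit = MultiKernelGBLUP(y, pset.kernels, X=pset.fixed, mask=mask).fit(spec=spec)
        return fit.yhat[test], {}
    raise ValueError(f"unknown model {model!r}")


def _per_env_from_folds(pred_df: pd.DataFrame, min_cell: int = 3) -> pd.DataFrame:
    """Mean over folds of within-fold within-environment correlations."""
    rows = []
    for env, env_df in pred_df.groupby("env", sort=True):
        cors = []
        for _, fold_df in env_df.groupby("fold"):
            if len(fold_df) < min_cell:
                continue  # skipped cell, logged by caller
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = pearson(fold_df["y_obs"], fold_df["y_pred"])
            if np.isfinite(r):
                cors.append(r)
        if cors:
            cors = np.asarray(cors)
            se = cors.std(ddof=1) / np.sqrt(len(cors)) if len(cors) > 1 else float("nan")
            rows.append((env, float(cors.mean()), float(se)))
        else:
            rows.append((env, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["env", "cor", "se"])


def _global_line_average(pred_df: pd.DataFrame) -> tuple[float, float]:
    """Correlation between per-line averages of observed and held-out
    predicted values over each line's environments."""
    per_line = pred_df.groupby("line")[["y_obs", "y_pred"]].mean()
    r = pearson(per_line["y_obs"], per_line["y_pred"])
    return r, _se_analytic(r, len(per_line))


def run_7fcv(
    dataset: PredictionDataset,
    model: str,
    eta_id: str,
    k: int = 7,
    seed: int = 0,
    fold_level: str = "obs",
    pls_opts: dict | None = None,
    gblup_spec: GblupSpec | None = None,
) -> CVResult:
    """Seven-fold cross-validation over line x environment observations."""
    if eta_id not in ETA_IDS:
        raise ValueError(f"unknown eta_id {eta_id!r}")
    # independent streams: one for the fold split, one per fold for the model
    ss = np.random.SeedSequence(seed)
    fold_seed, *model_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k + 1)]
    groups = dataset.obs_table["line"].to_numpy() if fold_level == "line" else None
    plan = make_folds(dataset.n_obs, k=k, seed=fold_seed, groups=groups)

    pred_rows = []
    hyper = []
    for fold in range(k):
        test = plan.assignment == fold
        train = ~test
        preds, hp = _fit_predict(
            dataset, eta_id, train, test, model, model_seeds[fold], pls_opts or {}, gblup_spec
        )
        hyper.append(hp)
        sub = dataset.obs_table.loc[test, ["line", "env"]].copy()
        sub["fold"] = fold
        sub["y_obs"] = dataset.y[test]
        sub["y_pred"] = preds
        pred_rows.append(sub)
    pred_df = pd.concat(pred_rows, ignore_index=True)

    per_env = _per_env_from_folds(pred_df)
    g_cor, g_se = _global_line_average(pred_df)
    return CVResult(
        scheme="7FCV", model=model, eta_id=eta_id,
        per_env=per_env, global_cor=g_cor, global_se=g_se,
        predictions=pred_df, hyperparams=hyper,
    )


def run_loeo(
    dataset: PredictionDataset,
    model: str,
    eta_id: str,
    seed: int = 0,
    pls_opts: dict | None = None,
    gblup_spec: GblupSpec | None = None,
) -> CVResult:
    """Leave-one-environment-out cross-validation."""
    if eta_id not in ETA_IDS:
        raise ValueError(f"unknown eta_id {eta_id!r}")
    envs = sorted(dataset.obs_table["env"].unique())
    if len(envs) < 2:
        raise ValueError("LOEO needs at least two environments")
    ss = np.random.SeedSequence(seed)
    model_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(envs))]

    env_col = dataset.obs_table["env"].to_numpy()
    pred_rows = []
    hyper = []
    per_env_rows = []
    for fold, env in enumerate(envs):
        test = env_col == env
        train = ~test
        # predictors without genomic relatedness cannot connect lines absent
        # from training under LOEO through the kernels, but all ETAs here
        # carry either relatedness or environment-blind spectral features, so
        # the fit is well posed as long as training data exists
        preds, hp = _fit_predict(
            dataset, eta_id, train, test, model, model_seeds[fold], pls_opts or {}, gblup_spec
        )
        hyper.append(hp)
        sub = dataset.obs_table.loc[test, ["line", "env"]].copy()
        sub["fold"] = fold
        sub["y_obs"] = dataset.y[test]
        sub["y_pred"] = preds
        pred_rows.append(sub)
        r = pearson(sub["y_obs"], sub["y_pred"])
        per_env_rows.append((env, r, _se_analytic(r, len(sub))))
    pred_df = pd.concat(pred_rows, ignore_index=True)
    per_env = pd.DataFrame(per_env_rows, columns=["env", "cor", "se"])

    pooled = pearson(pred_df["y_obs"], pred_df["y_pred"])
    env_cors = per_env["cor"].to_numpy()
    finite = env_cors[np.isfinite(env_cors)]
    averaged = float(finite.mean()) if finite.size else float("nan")
    se_env = float(finite.std(ddof=1) / np.sqrt(finite.size)) if finite.size > 1 else float("nan")
    return CVResult(
        scheme="LOEO", model=model, eta_id=eta_id,
        per_env=per_env, global_cor=pooled, global_se=se_env,
        predictions=pred_df, hyperparams=hyper,
        global_cor_averaged=averaged,
    )
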