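import numpy as np
import pandas as pd
import pytest

from phenogs.evaluation import (
    PredictionDataset,
    make_folds,
    nrmse,
    pearson,
    run_7fcv,
    run_loeo,
)
from phenogs.features import PredictorBuilder
from phenogs.gblup import GblupSpec
from phenogs.markers import Kernel
from phenogs.spectral import H_COLUMNS

FAST_GBLUP = GblupSpec(n_iter=800, burn_in=200, thin=2)


class TestFolds:
    def test_exact_sevenths(self):
        plan = make_folds(700, k=7, seed=0)
        sizes = np.bincount(plan.assignment)
        assert np.all(sizes == 100)

    def test_pigeonhole_sizes(self):
        plan = make_folds(10, k=7, seed=1)
        assert sorted(np.bincount(plan.assignment), reverse=True) == [2, 2, 2, 1, 1, 1, 1]

    def test_partition_property(self):
        plan = make_folds(53, k=7, seed=2)
        assert plan.assignment.shape == (53,)
        assert set(plan.assignment) == set(range(7))

    def test_leave_one_out_degenerate(self):
        plan = make_folds(12, k=12, seed=3)
        assert np.all(np.bincount(plan.assignment) == 1)

    def test_group_level_folding(self):
        groups = np.repeat(np.arange(20), 3)
        plan = make_folds(60, k=5, seed=4, groups=groups)
        df = pd.DataFrame({"g": groups, "f": plan.assignment})
        assert (df.groupby("g")["f"].nunique() == 1).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            make_folds(5, k=7)


class TestMetrics:
    def test_pearson_exact_cases(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)
        assert pearson(x, 2 * x) == pytest.approx(1.0)

    def test_pearson_degenerate_is_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_nrmse_hand_case(self):
        assert nrmse([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_nrmse_perfect_and_scale_invariant(self):
        obs = np.array([1.0, 3.0, 7.0])
        pred = np.array([2.0, 2.5, 6.0])
        assert nrmse(obs, obs) == 0.0
        assert nrmse(10 * obs, 10 * pred) == pytest.approx(nrmse(obs, pred))

    def test_nrmse_constant_obs_raises(self):
        with pytest.raises(ValueError):
            nrmse([1.0, 1.0], [1.0, 2.0])


def _noiseless_dataset(n_lines=40, n_envs=3, seed=0):
    """Linear, noise-free yield driven by spectral features and relatedness."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i:02d}" for i in range(n_lines)]
    obs = pd.DataFrame([(l, f"E{j}") for l in lines for j in range(n_envs)], columns=["line", "env"])
    a = rng.normal(size=(n_lines, n_lines))
    grm = Kernel(a @ a.T / n_lines, lines)
    feats = obs.copy()
    base = rng.uniform(0.2, 0.8, size=(len(obs), len(H_COLUMNS)))
    feats[H_COLUMNS] = base
    env_eff = {f"E{j}": 2.0 * j for j in range(n_envs)}
    y = base[:, :3] @ np.array([3.0, -2.0, 1.0]) + obs["env"].map(env_eff).to_numpy()
    obs["y"] = y
    return PredictionDataset(obs, grm, feats)


class TestSevenFold:
    def test_noiseless_pls_near_perfect(self):
        ds = _noiseless_dataset()
        cv = run_7fcv(ds, "pls", "ETA8", seed=0, pls_opts={"a_max": 8})
        assert (cv.per_env["cor"] > 0.99).all()
        assert cv.global_cor > 0.99

    def test_single_environment_global_collapse(self):
        ds = _noiseless_dataset(n_envs=1)
        cv = run_7fcv(ds, "pls", "ETA8", seed=0, pls_opts={"a_max": 5})
        # per-line averages coincide with the single env's observations
        pooled = pearson(cv.predictions["y_obs"], cv.predictions["y_pred"])
        assert cv.global_cor == pytest.approx(pooled, abs=1e-12)

    def test_every_observation_predicted_once(self, small_dataset):
        cv = run_7fcv(small_dataset, "pls", "ETA1", seed=2, pls_opts={"a_max": 5})
        assert len(cv.predictions) == small_dataset.n_obs
        key = cv.predictions[["line", "env"]].apply(tuple, axis=1)
        assert key.is_unique

    def test_determinism(self, small_dataset):
        a = run_7fcv(small_dataset, "pls", "ETA2", seed=7, pls_opts={"a_max": 5})
        b = run_7fcv(small_dataset, "pls", "ETA2", seed=7, pls_opts={"a_max": 5})
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.hyperparams == b.hyperparams

    def test_no_leakage_from_test_responses(self, small_dataset):
        """Perturbing the responses of one outer fold leaves that fold's
        predictions unchanged (tuning and refit see only outer-training)."""
        cv1 = run_7fcv(small_dataset, "pls", "ETA1", seed=3, pls_opts={"a_max": 4})
        fold0 = cv1.predictions[cv1.predictions["fold"] == 0]
        obs2 = small_dataset.obs_table.copy()
        # same folds arise from the same seed; perturb exactly fold 0's rows
        fold_key = set(map(tuple, fold0[["line", "env"]].to_numpy()))
        obs2["y"] = [
            y + 50.0 if (l, e) in fold_key else y
            for l, e, y in zip(obs2["line"], obs2["env"], obs2["y"])
        ]
        ds2 = PredictionDataset(obs2, _grm_of(small_dataset), _feats_of(small_dataset))
        cv2 = run_7fcv(ds2, "pls", "ETA1", seed=3, pls_opts={"a_max": 4})
        fold0b = cv2.predictions[cv2.predictions["fold"] == 0]
        m1 = fold0.set_index(["line", "env"])["y_pred"]
        m2 = fold0b.set_index(["line", "env"])["y_pred"]
        np.testing.assert_allclose(m2[m1.index], m1, atol=1e-10)

    def test_gblup_runs_and_reports(self, small_dataset):
        cv = run_7fcv(small_dataset, "gblup", "ETA8", seed=1, gblup_spec=FAST_GBLUP)
        assert set(cv.per_env.columns) == {"env", "cor", "se"}
        assert -1.0 <= cv.global_cor <= 1.0


def _grm_of(ds):
    return Kernel(ds.builder.G, ds.builder.designs.line_levels)


def _feats_of(ds):
    b = ds.builder
    means, scales = b.standardization["H"]
    f = ds.obs_table[["line", "env"]].copy()
    f[H_COLUMNS] = b.H * scales + means
    return f.drop_duplicates(subset=["line", "env"])


class TestLeaveOneEnvironmentOut:
    def test_duplicated_environment_predicts_well(self):
        """Two identical environments: spectral predictors transfer perfectly."""
        ds1 = _noiseless_dataset(n_envs=1)
        obs = ds1.obs_table
        dup = pd.concat([obs, obs.assign(env="E9")], ignore_index=True)
        feats = _feats_of(ds1)
        dup_feats = pd.concat([feats, feats.assign(env="E9")], ignore_index=True)
        ds = PredictionDataset(dup, _grm_of(ds1), dup_feats)
        cv = run_loeo(ds, "pls", "ETA8", seed=0, pls_opts={"a_max": 6})
        assert (cv.per_env["cor"] > 0.95).all()

    def test_each_environment_tested_once(self, small_dataset):
        cv = run_loeo(small_dataset, "pls", "ETA9", seed=0, pls_opts={"a_max": 4})
        tested = cv.predictions.groupby("fold")["env"].unique()
        assert sorted(e for arr in tested for e in arr) == sorted(
            small_dataset.obs_table["env"].unique()
        )
        assert len(cv.predictions) == small_dataset.n_obs

    def test_single_environment_rejected(self):
        ds = _noiseless_dataset(n_envs=1)
        with pytest.raises(ValueError, match="two environments"):
            run_loeo(ds, "pls", "ETA8")

    def test_masked_environment_responses_never_read(self, small_dataset):
        """GBLUP LOEO predictions for a held-out environment are invariant to
        the values stored in that environment's response slots."""
        cv1 = run_loeo(small_dataset, "gblup", "ETA8", seed=5, gblup_spec=FAST_GBLUP)
        env0 = sorted(small_dataset.obs_table["env"].unique())[0]
        obs2 = small_dataset.obs_table.copy()
        obs2.loc[obs2["env"] == env0, "y"] += 1000.0
        ds2 = PredictionDataset(obs2, _grm_of(small_dataset), _feats_of(small_dataset))
        cv2 = run_loeo(ds2, "gblup", "ETA8", seed=5, gblup_spec=FAST_GBLUP)
        p1 = cv1.predictions.query("env == @env0").set_index("line")["y_pred"]
        p2 = cv2.predictions.query("env == @env0").set_index("line")["y_pred"]
        np.testing.assert_allclose(p2[p1.index], p1, atol=1e-10)
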