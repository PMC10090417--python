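import numpy as np
import pandas as pd
import pytest

from oracles import blup_posterior_mean
from phenogs.gblup import GblupSpec, MultiKernelGBLUP, fit_gblup


def _kernel(n, seed=0, p=None):
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(n, p or n))
    return m @ m.T / (p or n)


class TestFit:
    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            MultiKernelGBLUP(np.ones(10), {"g": _kernel(10)})

    def test_chain_determinism(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        K = _kernel(30, seed=2)
        a = fit_gblup(y, {"g": K}, n_iter=400, burn_in=100, thin=2, seed=9)
        b = fit_gblup(y, {"g": K}, n_iter=400, burn_in=100, thin=2, seed=9)
        pd.testing.assert_frame_equal(a.chains, b.chains)
        np.testing.assert_array_equal(a.yhat, b.yhat)

    def test_stored_draw_count(self):
        rng = np.random.default_rng(2)
        fit = fit_gblup(rng.normal(size=20), {"g": _kernel(20)}, n_iter=1000, burn_in=200, thin=5)
        assert len(fit.chains) == (1000 - 200) // 5

    def test_fixed_variance_matches_closed_form_blup(self):
        """df -> infinity limit: posterior mean of u equals the closed-form
        BLUP K V^-1 (y - mu_gls) within Monte Carlo error."""
        rng = np.random.default_rng(3)
        n = 100
        K = _kernel(n, seed=4, p=80)
        y = rng.multivariate_normal(np.zeros(n), 0.6 * K + 0.4 * np.eye(n)) + 3.0
        fit = fit_gblup(
            y, {"g": K}, n_iter=20000, burn_in=2000, thin=5, seed=5,
            fix_variances={"g": 0.6, "residual": 0.4},
        )
        exact = blup_posterior_mean(y, K, 0.6, 0.4)
        assert np.max(np.abs(fit.u_means["g"] - exact)) < 0.02

    def test_zero_kernel_variance_collapses_to_env_means(self):
        rng = np.random.default_rng(6)
        n = 40
        env = np.repeat([0, 1], n // 2)
        X = np.column_stack([env == 0, env == 1]).astype(float)
        y = rng.normal(size=n) + 2.0 * env
        fit = fit_gblup(
            y, {"g": _kernel(n, seed=7)}, X=X, n_iter=3000, burn_in=500, thin=2, seed=8,
            fix_variances={"g": 0.0},
        )
        for e in (0, 1):
            assert fit.yhat[env == e].mean() == pytest.approx(y[env == e].mean(), abs=0.05)
        assert np.std(fit.yhat[env == 0]) < 0.05  # no kernel term left

    def test_heritability_recovery(self, small_dataset):
        """Posterior variance ratio near the simulated heritability."""
        # handled at full scale in the acceptance suite; here a smoke check
        pset = small_dataset.predictor("ETA1")
        fit = fit_gblup(
            small_dataset.y, pset.kernels, X=pset.fixed,
            n_iter=2000, burn_in=500, thin=2, seed=1,
        )
        vc = fit.var_components
        ratio = vc["Kg"] / (vc["Kg"] + vc["residual"])
        assert 0.1 < ratio < 0.95


class TestPrediction:
    def test_masking_contract(self):
        """Masked responses are never read: predictions are bit-identical for
        arbitrary values stored in the masked slots."""
        rng = np.random.default_rng(10)
        n = 40
        K = _kernel(n, seed=11)
        y = rng.multivariate_normal(np.zeros(n), K + 0.3 * np.eye(n))
        mask = np.ones(n, dtype=bool)
        mask[:10] = False
        y2 = y.copy()
        y2[:10] = 1e6
        kw = dict(n_iter=500, burn_in=100, thin=2, seed=12)
        p1 = fit_gblup(y, {"g": K}, mask=mask, **kw).predict_masked()
        p2 = fit_gblup(y2, {"g": K}, mask=mask, **kw).predict_masked()
        np.testing.assert_array_equal(p1, p2)

    def test_duplicate_row_prediction(self):
        """A masked row identical (in all kernels) to an observed row gets
        that row's response back on noiseless data."""
        rng = np.random.default_rng(13)
        n = 30
        K = _kernel(n, seed=14)
        K2 = np.zeros((n + 1, n + 1))
        K2[:n, :n] = K
        K2[n, :n] = K[0, :]
        K2[:n, n] = K[0, :]
        K2[n, n] = K[0, 0]
        g = rng.multivariate_normal(np.zeros(n), K)
        y = np.concatenate([g, [g[0]]])
        mask = np.ones(n + 1, dtype=bool)
        mask[n] = False
        # noiseless limit: fix the variances at the generating values so the
        # masked duplicate interpolates its twin exactly up to MC error
        fit = fit_gblup(
            y, {"g": K2}, mask=mask, n_iter=6000, burn_in=1000, thin=2, seed=15,
            fix_variances={"g": 1.0, "residual": 1e-3},
        )
        assert fit.predict_masked()[0] == pytest.approx(g[0], abs=0.05)

    def test_no_masked_rows_raises(self):
        rng = np.random.default_rng(16)
        fit = fit_gblup(rng.normal(size=15), {"g": _kernel(15)}, n_iter=300, burn_in=100, thin=2)
        with pytest.raises(ValueError, match="masked"):
            fit.predict_masked()

    def test_spectral_predictor_accuracy(self):
        """ETA8-style spectral kernel achieves clearly positive accuracy on
        strongly spectrally informed synthetic data."""
        from phenogs import SimConfig, generate_dataset, build_features, Kernel
        from phenogs.evaluation import PredictionDataset

        b = generate_dataset(SimConfig(n_lines=300, n_snps=200, spectral_signal=0.9, seed=21))
        feats = build_features(b.pixel_table, b.panel_table, b.plot_table)
        lines = sorted(set(b.plot_table["line"]))
        grm = Kernel(np.eye(len(lines)), lines)  # genomic part unused by ETA8
        obs = (
            b.plot_table.groupby(["line", "env"], as_index=False)["yield"].mean()
            .rename(columns={"yield": "y"})
        )
        ds = PredictionDataset(obs, grm, feats)
        pset = ds.predictor("ETA8")
        rng = np.random.default_rng(0)
        mask = rng.random(ds.n_obs) > 0.25
        fit = fit_gblup(ds.y, pset.kernels, X=pset.fixed, mask=mask,
                        n_iter=2000, burn_in=500, thin=2, seed=22)
        truth = np.array([b.truth["g_line"][l] for l in obs["line"]])[~mask] + np.array(
            [b.truth["ge_cells"][f"{l}|{e}"] for l, e in zip(obs["line"], obs["env"])]
        )[~mask]
        r = np.corrcoef(fit.predict_masked(), ds.y[~mask])[0, 1]
        assert r > 0.6


def test_spec_validation():
    with pytest.raises(ValueError):
        GblupSpec(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        GblupSpec(df0=0.0)
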