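import numpy as np
import pandas as pd
import pytest

from oracles import gls_fixed_effects
from phenogs.blues import (
    TrialBLUEModel,
    VarianceComponents,
    VarianceComponentsModel,
    estimate_variance_components,
    fit_blues,
    heritability,
)


def _rcbd(n_geno=12, n_block=3, block_sd=0.0, resid_sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    geno = rng.normal(scale=2.0, size=n_geno)
    block = rng.normal(scale=block_sd, size=n_block)
    rows = []
    for b in range(n_block):
        for i in range(n_geno):
            rows.append(
                ("E1", f"G{i:02d}", False, 1, 1, b + 1, 10 + geno[i] + block[b] + rng.normal(scale=resid_sd))
            )
    return pd.DataFrame(rows, columns=["env", "line", "is_check", "trial", "rep", "block", "yield"])


class TestFitBlues:
    def test_zero_block_variance_equals_raw_means(self):
        """With no block effects a balanced design's BLUEs are the genotype means."""
        df = _rcbd(block_sd=0.0, resid_sd=0.3, seed=1)
        blues, _ = fit_blues(df, design="augmented")
        raw = df.groupby("line")["yield"].mean()
        merged = blues.set_index("line")["blue"]
        np.testing.assert_allclose(merged[raw.index], raw.to_numpy(), atol=1e-6)

    def test_matches_gls_oracle_augmented(self):
        """Fixed effects from the MME equal direct-inversion GLS at the same
        variance components (tiny augmented dataset with checks)."""
        rng = np.random.default_rng(3)
        rows = []
        for b in (1, 2):
            for g, chk in [("G1", False), ("G2", False), ("G3", False), ("CHK", True)]:
                rows.append(("E1", g, chk, 1, 1, b, 10 + rng.normal()))
        df = pd.DataFrame(rows, columns=["env", "line", "is_check", "trial", "rep", "block", "yield"])
        model = TrialBLUEModel(df, design="augmented")
        res = model.fit()
        Zb = model._lmm.terms["block"]
        beta_gls = gls_fixed_effects(
            df["yield"].to_numpy(), model._X, [Zb], [res.varcomp["block"]], res.varcomp["residual"]
        )
        np.testing.assert_allclose(res._res.fixed_effects, beta_gls, atol=1e-8)

    def test_translation_invariance(self):
        df = _rcbd(block_sd=1.0, seed=2)
        b1, _ = fit_blues(df, design="augmented")
        df2 = df.assign(**{"yield": df["yield"] + 100.0})
        b2, _ = fit_blues(df2, design="augmented")
        np.testing.assert_allclose(b2["blue"] - b1["blue"], 100.0, atol=1e-6)

    def test_loglik_monotone(self):
        df = _rcbd(n_geno=30, n_block=4, block_sd=2.0, resid_sd=1.0, seed=4)
        res = TrialBLUEModel(df, design="augmented").fit(track_loglik=True)
        lls = np.array(res.loglik_path)
        assert np.all(np.diff(lls) > -1e-6)

    def test_alpha_lattice_variance_recovery(self):
        """EM-REML recovers block and residual variances on average
        (alpha lattice, 100 genotypes x 2 reps, blocks of 10)."""
        est_b, est_e = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            geno = rng.normal(scale=2.0, size=100)
            rows, beff = [], {}
            for rep in (1, 2):
                order = rng.permutation(100)
                for pos, i in enumerate(order):
                    blk = pos // 10 + 1
                    key = (rep, blk)
                    if key not in beff:
                        beff[key] = rng.normal(scale=2.0)  # block variance 4
                    rows.append(
                        ("E1", f"G{i:03d}", False, 1, rep, blk, 10 + geno[i] + beff[key] + rng.normal())
                    )
            df = pd.DataFrame(rows, columns=["env", "line", "is_check", "trial", "rep", "block", "yield"])
            _, vc = fit_blues(df, design="alpha_lattice")
            est_b.append(vc["block"])
            est_e.append(vc["residual"])
        assert np.mean(est_b) == pytest.approx(4.0, rel=0.15)
        assert np.mean(est_e) == pytest.approx(1.0, rel=0.15)


class TestVarianceComponents:
    def test_perfect_repeatability(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        df = pd.DataFrame(
            {"line": [f"L{i}" for i in range(20)] * 2, "env": ["E1"] * 20 + ["E2"] * 20,
             "value": np.concatenate([vals, vals])}
        )
        vc = estimate_variance_components(df)
        assert vc.var_ge + vc.var_residual < 1e-4 * vc.var_g

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"line": rng.choice([f"L{i}" for i in range(15)], 60),
             "env": rng.choice(["E1", "E2", "E3"], 60), "value": rng.normal(size=60)}
        )
        a = estimate_variance_components(df)
        b = estimate_variance_components(df.sample(frac=1.0, random_state=7))
        assert a.var_g == pytest.approx(b.var_g, rel=1e-6)
        assert a.var_residual == pytest.approx(b.var_residual, rel=1e-6)

    def test_recovery_simulation(self):
        """var_g=100, var_ge=25, var_res=50; mean estimates within 15% of
        truth over replicated-cell simulations."""
        acc = {"g": [], "ge": [], "e": []}
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            L, E, R = 120, 3, 2
            g = rng.normal(scale=10.0, size=L)
            ge = rng.normal(scale=5.0, size=(L, E))
            env = rng.normal(scale=6.0, size=E)
            rows = [
                (f"L{i:03d}", f"E{j}", 50 + env[j] + g[i] + ge[i, j] + rng.normal(scale=np.sqrt(50)))
                for i in range(L)
                for j in range(E)
                for _ in range(R)
            ]
            vc = estimate_variance_components(pd.DataFrame(rows, columns=["line", "env", "value"]))
            acc["g"].append(vc.var_g)
            acc["ge"].append(vc.var_ge)
            acc["e"].append(vc.var_residual)
        assert np.mean(acc["g"]) == pytest.approx(100.0, rel=0.15)
        assert np.mean(acc["ge"]) == pytest.approx(25.0, rel=0.15)
        assert np.mean(acc["e"]) == pytest.approx(50.0, rel=0.15)

    def test_single_environment_ge_not_estimable(self):
        df = pd.DataFrame(
            {"line": [f"L{i}" for i in range(10)], "env": "E1", "value": np.arange(10.0)}
        )
        vc = estimate_variance_components(df)
        assert np.isnan(vc.var_ge)


class TestHeritability:
    def test_degenerate_cases(self):
        assert heritability(VarianceComponents(2.0, 0.0, 0.0, 2.0, 1.5)) == 1.0
        assert heritability(VarianceComponents(0.0, 1.0, 1.0, 2.0, 1.5)) == 0.0

    def test_hand_arithmetic(self):
        assert heritability(VarianceComponents(1.0, 1.0, 1.0, 1.0, 1.0)) == pytest.approx(1 / 3)

    def test_monotone_in_var_g_and_replication(self):
        base = heritability(VarianceComponents(1.0, 1.0, 1.0, 2.0, 1.5))
        assert heritability(VarianceComponents(2.0, 1.0, 1.0, 2.0, 1.5)) > base
        assert heritability(VarianceComponents(1.0, 1.0, 1.0, 3.0, 1.5)) > base
        assert heritability(VarianceComponents(1.0, 1.0, 1.0, 2.0, 2.0)) > base

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 0.0, 0.0, 1.0, 1.0))


def test_summary_strings(small_bundle):
    env_df = small_bundle.plot_table[small_bundle.plot_table["env"] == "E1"]
    res = TrialBLUEModel(env_df, design="alpha_lattice").fit()
    assert "variance components" in res.summary()
    blues = res.blues.rename(columns={"blue": "value"}).assign(env="E1")
    df2 = blues.copy().assign(env="E2")
    vres = VarianceComponentsModel(pd.concat([blues, df2])).fit()
    assert "H2" in vres.summary()
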