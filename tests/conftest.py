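import warnings

import numpy as np
import pandas as pd
import pytest

from phenogs import (
    Kernel,
    PredictionDataset,
    SimConfig,
    build_features,
    compute_grm,
    filter_snps,
    fit_blues,
    generate_dataset,
    impute_markers,
)


@pytest.fixture(autouse=True)
def _quiet_degenerate_correlation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*correlation.*")
        warnings.filterwarnings("ignore", message=".*fewer than 3 pairs.*")
        yield


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete simulated trial (3 envs, 120 lines)."""
    return generate_dataset(SimConfig(n_lines=120, n_snps=300, n_envs=3, seed=42))


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    """BLUEs + GRM + spectral features assembled into a PredictionDataset."""
    b = small_bundle
    filtered, _ = filter_snps(b.markers)
    grm = compute_grm(impute_markers(filtered), center=True)
    grm = Kernel(grm.matrix / np.diag(grm.matrix).mean(), grm.ids)
    feats = build_features(b.pixel_table, b.panel_table, b.plot_table)
    rows = []
    for env, env_df in b.plot_table.groupby("env"):
        blues, _ = fit_blues(env_df, design="alpha_lattice")
        blues["env"] = env
        rows.append(blues)
    obs = pd.concat(rows, ignore_index=True).rename(columns={"blue": "y"})[["line", "env", "y"]]
    return PredictionDataset(obs, grm, feats)
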