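"""Predictor assembly: design matrices, relationship propagation, ETA sets.

Observations are line x environment cells.  From the incidence design
matrices (X_E for environments, Z_g for lines, Z_gE for cells), the genomic
relationship matrix G and the multispectral feature matrices H (11 columns)
and I (3 columns), nine named predictor sets are assembled:

    ETA1: [X_E, X_g L_g]
    ETA2: [X_E, X_g L_g, H]
    ETA3: [X_E, X_g L_g, H, X_gE L_gE]
    ETA4: [X_E, X_g L_g, H, X_gE L_gE, X_g L_g : H]
    ETA5: [X_E, X_g L_g, I]
    ETA6: [X_E, X_g L_g, I, X_gE L_gE]
    ETA7: [X_E, X_g L_g, I, X_gE L_gE, X_g L_g : I]
    ETA8: [X_E, H]
    ETA9: [X_E, I]

with L_g = G^1/2 and L_gE = K_gE^1/2 where K_gE = (Z_g G Z_g') o (X_E X_E')
(o the Hadamard product) over the observed cells.  ":" is the row-wise
Khatri-Rao product.  The same sets are mirrored as kernel lists for the
Bayesian GBLUP: K_g = Z_g G Z_g', K_gE, K_H = H~H~'/11, K_I = I~I~'/3,
K_g:H = K_g o K_H, K_g:I = K_g o K_I, with H~/I~ column-standardized, and
the environment block entering as a fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import Kernel, matrix_sqrt, psd_repair
from .spectral import H_COLUMNS, I_COLUMNS

ETA_IDS = tuple(f"ETA{k}" for k in range(1, 10))

# PLS block composition per ETA (beyond the leading X_E)
_ETA_BLOCKS = {
    "ETA1": ["XgLg"],
    "ETA2": ["XgLg", "H"],
    "ETA3": ["XgLg", "H", "XgELgE"],
    "ETA4": ["XgLg", "H", "XgELgE", "XgLg:H"],
    "ETA5": ["XgLg", "I"],
    "ETA6": ["XgLg", "I", "XgELgE"],
    "ETA7": ["XgLg", "I", "XgELgE", "XgLg:I"],
    "ETA8": ["H"],
    "ETA9": ["I"],
}

# GBLUP kernel composition per ETA (environment block always fixed)
_ETA_KERNELS = {
    "ETA1": ["Kg"],
    "ETA2": ["Kg", "KH"],
    "ETA3": ["Kg", "KH", "KgE"],
    "ETA4": ["Kg", "KH", "KgE", "KgH"],
    "ETA5": ["Kg", "KI"],
    "ETA6": ["Kg", "KI", "KgE"],
    "ETA7": ["Kg", "KI", "KgE", "KgI"],
    "ETA8": ["KH"],
    "ETA9": ["KI"],
}


@dataclass
class DesignMatrices:
    """One-hot incidence matrices over observations (each row sums to 1)."""

    X_E: np.ndarray
    Z_g: np.ndarray
    Z_gE: np.ndarray
    env_levels: list
    line_levels: list
    cell_levels: list


def build_design_matrices(obs_table: pd.DataFrame) -> DesignMatrices:
    """Incidence matrices from a (line, env) observation table.

    Column orders are deterministic (sorted levels); Z_gE has one column per
    observed line x environment cell.
    """
    lines = obs_table["line"].astype(str)
    envs = obs_table["env"].astype(str)
    env_levels = sorted(envs.unique())
    line_levels = sorted(lines.unique())
    cells = lines + "|" + envs
    cell_levels = sorted(cells.unique())

    def one_hot(series, levels):
        idx = series.map({l: i for i, l in enumerate(levels)})
        if idx.isna().any():
            raise ValueError("unresolvable IDs in observation table")
        Z = np.zeros((len(series), len(levels)))
        Z[np.arange(len(series)), idx.to_numpy()] = 1.0
        return Z

    return DesignMatrices(
        X_E=one_hot(envs, env_levels),
        Z_g=one_hot(lines, line_levels),
        Z_gE=one_hot(cells, cell_levels),
        env_levels=env_levels,
        line_levels=line_levels,
        cell_levels=cell_levels,
    )


def interaction_features(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Khatri-Rao product: per row the flattened outer product.

    Column order is (a1*b1, a1*b2, ..., a2*b1, ...); width(A)*width(B) columns.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"row-count mismatch: {A.shape[0]} vs {B.shape[0]}")
    return np.einsum("ij,ik->ijk", A, B).reshape(A.shape[0], -1)


@dataclass
class PredictorSet:
    """A named predictor set in both PLS and GBLUP form."""

    eta_id: str
    blocks: dict  # ordered name -> matrix (PLS view, X_E first)
    kernels: dict  # name -> obs x obs kernel (GBLUP view)
    fixed: np.ndarray  # environment one-hot (GBLUP fixed block)
    standardization: dict = field(default_factory=dict)  # block -> (means, scales)

    @property
    def matrix(self) -> np.ndarray:
        """Concatenated-matrix (PLS) view."""
        return np.hstack(list(self.blocks.values()))

    @property
    def width(self) -> int:
        return sum(b.shape[1] for b in self.blocks.values())

    def to_csv_dir(self, out_dir) -> None:
        """Export each block (and kernel) as a CSV for debugging."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, block in self.blocks.items():
            pd.DataFrame(block).to_csv(out / f"block_{name.replace(':', 'x')}.csv", index=False)
        for name, K in self.kernels.items():
            pd.DataFrame(K).to_csv(out / f"kernel_{name}.csv", index=False)


class PredictorBuilder:
    """Precomputes shared pieces (L_g, K_gE, standardized H/I) for all ETAs.

    Parameters
    ----------
    obs_table : DataFrame with columns (line, env), one row per observation.
    grm : Kernel over lines; must cover every line in the table.
    features : optional DataFrame with (line, env) plus the 11 H columns.
    """

    def __init__(self, obs_table: pd.DataFrame, grm: Kernel, features: pd.DataFrame | None = None):
        self.obs_table = obs_table.reset_index(drop=True)
        self.designs = build_design_matrices(self.obs_table)
        d = self.designs

        missing = [l for l in d.line_levels if l not in set(grm.ids)]
        if missing:
            raise ValueError(f"GRM does not cover lines: {missing[:5]}")
        order = [grm.ids.index(l) for l in d.line_levels]
        G = grm.matrix[np.ix_(order, order)]
        self.G = G
        self.L_g = matrix_sqrt(Kernel(G, d.line_levels)).matrix
        self.XgLg = d.Z_g @ self.L_g
        self.Kg = psd_repair(d.Z_g @ G @ d.Z_g.T)
        self.KgE = psd_repair(self.Kg * (d.X_E @ d.X_E.T))
        self._LgE = None  # lazy: only gE-based PLS ETAs need the square root

        self.H = self.I = None
        self.standardization = {}
        if features is not None:
            merged = self.obs_table.merge(features, on=["line", "env"], how="left", validate="m:1")
            if merged[H_COLUMNS].isna().any().any():
                bad = merged.loc[merged[H_COLUMNS].isna().any(axis=1), ["line", "env"]]
                raise ValueError(f"features missing for observations: {bad.head(3).to_dict('records')}")
            H_raw = merged[H_COLUMNS].to_numpy(dtype=float)
            self.H, self.standardization["H"] = _standardize(H_raw)
            self.I = self.H[:, [H_COLUMNS.index(c) for c in I_COLUMNS]]
            self.standardization["I"] = (
                self.standardization["H"][0][[H_COLUMNS.index(c) for c in I_COLUMNS]],
                self.standardization["H"][1][[H_COLUMNS.index(c) for c in I_COLUMNS]],
            )

    @property
    def LgE(self) -> np.ndarray:
        if self._LgE is None:
            if len(self.designs.cell_levels) != len(self.obs_table):
                raise ValueError(
                    "X_gE L_gE requires one observation per line x environment cell"
                )
            self._LgE = matrix_sqrt(Kernel(self.KgE)).matrix
        return self._LgE

    def build(self, eta_id: str) -> PredictorSet:
        if eta_id not in ETA_IDS:
            raise ValueError(f"unknown eta_id {eta_id!r}; expected one of {ETA_IDS}")
        needs_features = any(b in ("H", "I") or ":" in b for b in _ETA_BLOCKS[eta_id])
        if needs_features and self.H is None:
            raise ValueError(f"{eta_id} requires multispectral features; none were provided")

        blocks: dict[str, np.ndarray] = {"X_E": self.designs.X_E}
        for name in _ETA_BLOCKS[eta_id]:
            if name == "XgLg":
                blocks[name] = self.XgLg
            elif name == "H":
                blocks[name] = self.H
            elif name == "I":
                blocks[name] = self.I
            elif name == "XgELgE":
                blocks[name] = self.LgE  # Z_gE is the identity over observed cells
            elif name == "XgLg:H":
                blocks[name] = interaction_features(self.XgLg, self.H)
            elif name == "XgLg:I":
                blocks[name] = interaction_features(self.XgLg, self.I)

        kernels: dict[str, np.ndarray] = {}
        for name in _ETA_KERNELS[eta_id]:
            if name == "Kg":
                kernels[name] = self.Kg
            elif name == "KgE":
                kernels[name] = self.KgE
            elif name == "KH":
                kernels[name] = psd_repair(self.H @ self.H.T / self.H.shape[1])
            elif name == "KI":
                kernels[name] = psd_repair(self.I @ self.I.T / self.I.shape[1])
            elif name == "KgH":
                kernels[name] = psd_repair(self.Kg * (self.H @ self.H.T / self.H.shape[1]))
            elif name == "KgI":
                kernels[name] = psd_repair(self.Kg * (self.I @ self.I.T / self.I.shape[1]))

        return PredictorSet(
            eta_id=eta_id,
            blocks=blocks,
            kernels=kernels,
            fixed=self.designs.X_E,
            standardization=dict(self.standardization),
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    return (X - means) / scales, (means, scales)


def build_predictor(
    eta_id: str,
    grm: Kernel,
    obs_table: pd.DataFrame,
    features: pd.DataFrame | None = None,
) -> PredictorSet:
    """One-shot assembly of a single ETA predictor set."""
    return PredictorBuilder(obs_table, grm, features).build(eta_id)
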