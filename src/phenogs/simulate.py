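"""Seeded synthetic winter-wheat trial generator.

Emulates the structure of multi-environment breeding-program yield trials
with UAS multispectral phenotyping:

* a few hundred to ~1,400 lines genotyped at binomially drawn SNPs
  (independent loci, allele frequencies in [0.05, 0.5]) plus a configurable
  fraction of deliberately QC-failing SNPs (monomorphic, high-missing,
  high-heterozygosity);
* unbalanced line x environment incidence — each line is grown in a random
  subset of environments of size 1 + truncated-Poisson, targeting a mean of
  ~1.3-1.7 environments per line — with partial replication (a fraction of
  cells grown in two replicates);
* plot yield  y = mu + g + env + gxe + design effects + residual,  with the
  polygenic value g = M beta and every component rescaled so its realized
  plot-level variance equals its nominal value, which pins the realized
  plot-level heritability Var(g)/Var(y) at the target;
* eight multispectral bands whose plot values correlate with the total
  genetic + environmental plot value at a configurable level, emitted as
  raw-DN pixel samples plus calibration-panel DN/reflectance pairs so the
  downstream radiometric pipeline is exercised honestly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .spectral import BAND_NAMES

__all__ = ["SimConfig", "SimBundle", "generate_dataset", "realized_unbalance"]

# nominal band reflectances for a green wheat canopy
_BAND_BASE = {
    "Blue": 0.05,
    "Green": 0.09,
    "Red": 0.06,
    "RE1": 0.18,
    "RE2": 0.28,
    "B900": 0.38,
    "B975": 0.35,
    "NIR": 0.42,
}
_PANEL_REFLECTANCES = (0.02, 0.10, 0.30, 0.55, 0.85)


@dataclass
class SimConfig:
    """Conditions of a simulated multi-environment yield trial."""

    n_lines: int = 400
    n_snps: int = 1000
    n_envs: int = 4
    mean_envs_per_line: float = 1.5
    replicate_fraction: float = 0.4
    h2_target: float = 0.5
    var_g: float = 1.0
    var_env: float = 0.5
    var_ge: float = 0.2
    var_design: float = 0.06
    spectral_signal: float = 0.8
    design: str = "alpha_lattice"
    missing_marker_rate: float = 0.05
    bad_snp_fraction: float = 0.05
    n_pixels_per_plot: int = 8
    pixel_noise_sd: float = 0.05
    n_checks: int = 2
    mu: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_envs < 1:
            raise ValueError("n_envs must be >= 1")
        if not (0.0 < self.h2_target < 1.0):
            raise ValueError("h2_target must lie in (0, 1)")
        if self.mean_envs_per_line > self.n_envs:
            raise ValueError(
                f"mean_envs_per_line={self.mean_envs_per_line} exceeds n_envs={self.n_envs}"
            )
        if self.mean_envs_per_line < 1:
            raise ValueError("mean_envs_per_line must be >= 1")
        for name in ("replicate_fraction", "missing_marker_rate", "bad_snp_fraction", "spectral_signal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.design not in ("alpha_lattice", "augmented"):
            raise ValueError(f"design must be alpha_lattice or augmented, got {self.design!r}")
        if self.residual_variance() <= 0:
            raise ValueError(
                "impossible variance budget: h2_target with the configured var_env/var_ge/"
                "var_design leaves no residual variance "
                f"(needs var_g*(1-h2)/h2 = {self.var_g * (1 - self.h2_target) / self.h2_target:.3f} "
                "> var_env + var_ge + var_design)"
            )

    def residual_variance(self) -> float:
        """Residual variance implied by the heritability target.

        Plot-level h2 = var_g / (var_g + var_env + var_ge + var_design + var_e),
        solved for var_e.  Components that cannot express themselves (env and
        GxE with a single environment) drop out of the budget.
        """
        var_env = self.var_env if self.n_envs > 1 else 0.0
        var_ge = self.var_ge if self.n_envs > 1 else 0.0
        return self.var_g * (1.0 - self.h2_target) / self.h2_target - var_env - var_ge - self.var_design


@dataclass
class SimBundle:
    """A complete simulated dataset plus its generating truth."""

    markers: MarkerMatrix
    plot_table: pd.DataFrame
    pixel_table: pd.DataFrame
    panel_table: pd.DataFrame
    truth: dict
    config: SimConfig

    def to_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.markers.to_csv(out / "markers.csv")
        self.plot_table.to_csv(out / "plot_table.csv", index=False)
        self.pixel_table.to_csv(out / "pixels.csv", index=False)
        self.panel_table.to_csv(out / "panels.csv", index=False)
        truth = dict(self.truth)
        truth["config"] = asdict(self.config)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _rescale(vec: np.ndarray, target_var: float) -> np.ndarray:
    """Center-preserving rescale so the realized (ddof=0) variance of the
    centered vector equals ``target_var`` exactly; zero target zeroes it."""
    if target_var <= 0:
        return np.zeros_like(vec)
    centered = vec - vec.mean()
    sd = centered.std()
    if sd == 0:
        return np.zeros_like(vec)
    return centered * (np.sqrt(target_var) / sd)


def _residualize(vec: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the projection of ``vec`` onto the columns of ``basis``."""
    coef, *_ = np.linalg.lstsq(basis, vec, rcond=None)
    return vec - basis @ coef


def _draw_markers(cfg: SimConfig, rng: np.random.Generator):
    """Raw marker matrix with injected QC failures; returns (raw, good_mask, clean_good)."""
    n, m = cfg.n_lines, cfg.n_snps
    n_bad = int(round(cfg.bad_snp_fraction * m))
    n_good = m - n_bad
    p = rng.uniform(0.05, 0.5, size=n_good)
    # inbred lines: calls are homozygous 0/2 at the allele frequency, with a
    # small residual heterozygosity (~2% of calls)
    good = 2.0 * (rng.random((n, n_good)) < p[None, :])
    good[rng.random((n, n_good)) < 0.02] = 1.0
    clean_good = good.copy()
    # inject missingness into the clean SNPs
    if cfg.missing_marker_rate > 0:
        holes = rng.random((n, n_good)) < cfg.missing_marker_rate
        # keep at least one observed call per SNP
        for j in np.where(holes.all(axis=0))[0]:
            holes[rng.integers(n), j] = False
        good[holes] = np.nan
    bad_cols = []
    for j in range(n_bad):
        kind = j % 3
        if kind == 0:  # monomorphic
            col = np.full(n, 2.0)
        elif kind == 1:  # >50% missing
            col = 2.0 * (rng.random(n) < 0.3)
            col[rng.random(n) < 0.7] = np.nan
            if np.isfinite(col).sum() == 0:
                col[rng.integers(n)] = 2.0
        else:  # >5% heterozygous
            col = 2.0 * (rng.random(n) < 0.3)
            col[rng.random(n) < 0.25] = 1.0
        bad_cols.append(col)
    values = np.column_stack([good] + bad_cols) if n_bad else good
    order = rng.permutation(m)
    values = values[:, order]
    snp_ids = [f"S{k+1:05d}" for k in range(m)]
    line_ids = [f"L{k+1:04d}" for k in range(n)]
    good_mask = np.zeros(m, dtype=bool)
    good_mask[np.argsort(order)[:n_good]] = True
    raw = MarkerMatrix(values, line_ids, snp_ids)
    return raw, good_mask, clean_good


def _draw_incidence(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-line environment subsets: size 1 + Poisson, truncated to [1, n_envs]."""
    sizes = 1 + rng.poisson(max(cfg.mean_envs_per_line - 1.0, 0.0), size=cfg.n_lines)
    sizes = np.clip(sizes, 1, cfg.n_envs)
    return [rng.choice(cfg.n_envs, size=k, replace=False) for k in sizes]


def _layout_plots(cfg: SimConfig, env_sets, rng: np.random.Generator) -> pd.DataFrame:
    """Assign plots, replicates and design factors (trial/rep/block)."""
    rows = []
    check_idx = set(range(min(cfg.n_checks, cfg.n_lines)))
    for j in range(cfg.n_envs):
        env = f"E{j+1}"
        lines_here = [i for i, s in enumerate(env_sets) if j in s]
        if cfg.design == "alpha_lattice":
            for i in lines_here:
                n_rep = 2 if rng.random() < cfg.replicate_fraction else 1
                for r in range(1, n_rep + 1):
                    rows.append((env, i, i in check_idx, 1, r))
            env_rows = [r for r in rows if r[0] == env]
            # incomplete blocks of ~10 within (trial, rep)
            df = pd.DataFrame(env_rows, columns=["env", "line_idx", "is_check", "trial", "rep"])
            blocks = np.empty(len(df), dtype=int)
            for (_, _), idx in df.groupby(["trial", "rep"]).groups.items():
                idx = np.asarray(list(idx))
                perm = rng.permutation(len(idx))
                blocks[idx] = perm // 10 + 1
            df["block"] = blocks
            rows = [r for r in rows if r[0] != env]
            rows.extend(df[["env", "line_idx", "is_check", "trial", "rep", "block"]].itertuples(index=False, name=None))
        else:  # augmented: unreplicated entries in blocks, checks in every block
            entries = [i for i in lines_here if i not in check_idx]
            rng.shuffle(entries)
            block_size = 16
            n_blocks = max(1, int(np.ceil(len(entries) / block_size)))
            for b in range(n_blocks):
                for i in entries[b * block_size : (b + 1) * block_size]:
                    rows.append((env, i, False, 1, 1, b + 1))
                for i in sorted(check_idx & set(lines_here)) or sorted(check_idx):
                    rows.append((env, i, True, 1, 1, b + 1))
    df = pd.DataFrame(rows, columns=["env", "line_idx", "is_check", "trial", "rep", "block"])
    df.insert(0, "plot_id", [f"P{k+1:05d}" for k in range(len(df))])
    return df


def generate_dataset(config: SimConfig) -> SimBundle:
    """Generate a complete, seeded, self-consistent dataset."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    raw_markers, good_mask, clean_good = _draw_markers(cfg, rng)
    line_ids = raw_markers.line_ids

    # polygenic values from the clean SNPs, rescaled to exact var_g
    beta = rng.normal(size=clean_good.shape[1])
    centered = clean_good - clean_good.mean(axis=0, keepdims=True)
    g_line = centered @ beta
    env_sets = _draw_incidence(cfg, rng)
    plots = _layout_plots(cfg, env_sets, rng)
    n_plots = len(plots)
    li = plots["line_idx"].to_numpy()
    ej = plots["env"].str.slice(1).astype(int).to_numpy() - 1

    g_plot = _rescale(g_line[li], cfg.var_g)
    env_eff = rng.normal(size=cfg.n_envs)
    env_plot = _rescale(env_eff[ej], cfg.var_env if cfg.n_envs > 1 else 0.0)
    ge_cell = rng.normal(size=(cfg.n_lines, cfg.n_envs))
    ge_plot = _rescale(ge_cell[li, ej], cfg.var_ge if cfg.n_envs > 1 else 0.0)

    # design-factor effects (trial/rep/block within env), rescaled jointly;
    # design and residual draws are orthogonalized against the signal
    # components so the realized variance budget adds up exactly
    signal_basis = np.column_stack([np.ones(n_plots), g_plot, env_plot, ge_plot])
    d_raw = np.zeros(n_plots)
    for cols, sd in ((("env", "trial"), 0.2), (("env", "trial", "rep"), 0.2), (("env", "trial", "rep", "block"), 0.4)):
        key = plots.groupby(list(cols), sort=True).ngroup().to_numpy()
        eff = rng.normal(scale=sd, size=key.max() + 1)
        d_raw = d_raw + eff[key]
    d_plot = _rescale(_residualize(d_raw, signal_basis), cfg.var_design)

    var_e = cfg.residual_variance()
    eps = _rescale(
        _residualize(rng.normal(size=n_plots), np.column_stack([signal_basis, d_plot])), var_e
    )

    y = cfg.mu + g_plot + env_plot + ge_plot + d_plot + eps
    plots = plots.copy()
    plots["line"] = [line_ids[i] for i in li]
    plots["yield"] = y
    plot_table = plots[["plot_id", "env", "trial", "rep", "block", "line", "is_check", "yield"]]

    # --- multispectral bands -------------------------------------------------
    signal = g_plot + env_plot + ge_plot
    sd_sig = signal.std()
    z = (signal - signal.mean()) / sd_sig if sd_sig > 0 else np.zeros(n_plots)
    ss = cfg.spectral_signal
    amp = 0.15
    band_plot = {}
    for b in BAND_NAMES:
        base = _BAND_BASE[b]
        noise = rng.normal(size=n_plots)
        band_plot[b] = base * (1.0 + amp * (ss * z + np.sqrt(max(1.0 - ss**2, 0.0)) * noise))

    # true per-band affine DN map; panels invert it exactly
    slopes = {b: (1.0 / 1100.0) * (1.0 + 0.2 * rng.random()) for b in BAND_NAMES}
    intercepts = {b: rng.uniform(-0.01, 0.01) for b in BAND_NAMES}
    panel_rows = [
        {"band": b, "reflectance": r, "dn": (r - intercepts[b]) / slopes[b]}
        for b in BAND_NAMES
        for r in _PANEL_REFLECTANCES
    ]
    panel_table = pd.DataFrame(panel_rows, columns=["band", "dn", "reflectance"])

    npx = cfg.n_pixels_per_plot
    px = {"plot_id": np.repeat(plot_table["plot_id"].to_numpy(), npx)}
    for b in BAND_NAMES:
        refl = np.repeat(band_plot[b], npx)
        refl = refl + cfg.pixel_noise_sd * _BAND_BASE[b] * rng.normal(size=refl.size)
        refl = np.clip(refl, 1e-4, None)
        px[b] = (refl - intercepts[b]) / slopes[b]
    pixel_table = pd.DataFrame(px)

    var_y = y.var()
    truth = {
        "g_line": {line_ids[i]: float(v) for i, v in enumerate(_rescale_lookup(g_line, g_plot, li))},
        "env_effects": {f"E{j+1}": float(v) for j, v in enumerate(_rescale_lookup(env_eff, env_plot, ej))},
        "ge_cells": {
            f"{line_ids[i]}|E{j+1}": float(v)
            for (i, j), v in _cell_lookup(ge_cell, ge_plot, li, ej).items()
        },
        "variance_components": {
            "var_g": cfg.var_g,
            "var_env": cfg.var_env if cfg.n_envs > 1 else 0.0,
            "var_ge": cfg.var_ge if cfg.n_envs > 1 else 0.0,
            "var_design": cfg.var_design,
            "var_residual": var_e,
        },
        "realized_h2": float(g_plot.var() / var_y),
        "band_plot_values": {b: band_plot[b].tolist() for b in BAND_NAMES},
        "calibration": {"slopes": slopes, "intercepts": intercepts},
    }
    bundle = SimBundle(raw_markers, plot_table, pixel_table, panel_table, truth, cfg)
    _check_bundle(bundle)
    return bundle


def _rescale_lookup(raw_levels: np.ndarray, scaled_plot: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Recover per-level effects consistent with the rescaled plot vector."""
    out = np.zeros_like(raw_levels, dtype=float)
    for level in np.unique(idx):
        out[level] = scaled_plot[idx == level][0]
    return out


def _cell_lookup(raw_cells, scaled_plot, li, ej) -> dict:
    out = {}
    seen = set()
    for k in range(len(li)):
        key = (int(li[k]), int(ej[k]))
        if key not in seen:
            seen.add(key)
            out[key] = scaled_plot[k]
    return out


def _check_bundle(bundle: SimBundle) -> None:
    lines_in_markers = set(bundle.markers.line_ids)
    if not set(bundle.plot_table["line"]).issubset(lines_in_markers):
        raise AssertionError("plot table references lines absent from markers")
    if bundle.plot_table.groupby("line")["env"].nunique().min() < 1:
        raise AssertionError("every line must appear in at least one environment")


def realized_unbalance(bundle_or_plots) -> tuple[float, float]:
    """(n_e, n_r): mean environments per line, mean replicates per cell."""
    plots = bundle_or_plots.plot_table if isinstance(bundle_or_plots, SimBundle) else bundle_or_plots
    if len(plots) == 0:
        raise ValueError("empty plot table")
    n_e = float(plots.groupby("line")["env"].nunique().mean())
    n_r = float(plots.groupby(["line", "env"]).size().mean())
    return n_e, n_r
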