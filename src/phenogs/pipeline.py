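"""End-to-end pipeline: data -> spectra -> BLUEs -> predictors -> models -> CV.

Configuration is a YAML document holding either a ``sim:`` block (synthetic
run) or an ``inputs:`` block of file paths, plus optional per-stage blocks
(``spectral``, ``pls``, ``gblup``, ``cv``).  Every intermediate table is
persisted as CSV in the output directory together with a machine-readable
manifest of the active decisions and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .blues import TrialBLUEModel, VarianceComponentsModel, heritability
from .evaluation import LOEO_DEFAULT_ETAS, PredictionDataset, run_7fcv, run_loeo
from .gblup import GblupSpec
from .markers import MarkerMatrix, compute_grm, filter_snps, impute_markers
from .simulate import SimConfig, generate_dataset, realized_unbalance
from .spectral import build_features

log = logging.getLogger("phenogs")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    sim: dict | None = None
    inputs: dict | None = None
    spectral: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    pls: dict = field(default_factory=dict)
    gblup: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'sim' or 'inputs'")
        if self.inputs is not None:
            for key in ("plot_table", "markers", "pixels", "panels"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input file does not exist: {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # ---- stage: data ------------------------------------------------------
    stage = "data"
    try:
        if config.sim is not None:
            sim_cfg = SimConfig(**{**config.sim, "seed": config.sim.get("seed", config.seed)})
            bundle = generate_dataset(sim_cfg)
            bundle.to_dir(out / "data")
            plot_table = bundle.plot_table
            raw_markers = bundle.markers
            pixels = bundle.pixel_table
            panels = bundle.panel_table
            manifest["stages"][stage] = {"source": "simulated", "sim_seed": sim_cfg.seed}
        else:
            plot_table = pd.read_csv(config.inputs["plot_table"])
            raw_markers = MarkerMatrix.from_csv(config.inputs["markers"])
            pixels = pd.read_csv(config.inputs["pixels"])
            panels = pd.read_csv(config.inputs["panels"])
            manifest["stages"][stage] = {"source": "files", **config.inputs}
        log.info("data: %d plots, %d lines x %d SNPs", len(plot_table), raw_markers.n_lines, raw_markers.n_snps)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- stage: markers ---------------------------------------------------
    stage = "markers"
    try:
        impute_method = config.markers.get("impute", "mean")
        center = bool(config.markers.get("center_grm", False))
        filtered, flog = filter_snps(raw_markers)
        imputed = impute_markers(filtered, method=impute_method)
        grm = compute_grm(imputed, center=center)
        grm.to_csv(out / "grm.csv")
        manifest["stages"][stage] = {
            "filter_log": flog.as_dict(), "imputation": impute_method, "grm_centered": center,
        }
        log.info("markers: %d/%d SNPs kept", flog.n_kept, flog.n_input)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- stage: spectra ---------------------------------------------------
    stage = "spectra"
    try:
        mode = config.spectral.get("mode", "panel")
        canopy_mode = config.spectral.get("canopy_mode", "mean_gndvi")
        features = build_features(
            pixels, panels, plot_table, mode=mode, canopy_mode=canopy_mode,
            per_pixel_indices=bool(config.spectral.get("per_pixel_indices", False)),
        )
        features.to_csv(out / "features.csv", index=False)
        manifest["stages"][stage] = {"mode": mode, "canopy_mode": canopy_mode}
        log.info("spectra: %d line x env feature rows", len(features))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- stage: blues -----------------------------------------------------
    stage = "blues"
    try:
        design = config.sim.get("design", "alpha_lattice") if config.sim else config.cv.get("design", "alpha_lattice")
        blue_rows = []
        varcomps = {}
        for env, env_df in plot_table.groupby("env", sort=True):
            res = TrialBLUEModel(env_df, design=design).fit()
            b = res.blues.copy()
            b.insert(0, "env", env)
            blue_rows.append(b)
            varcomps[env] = res.varcomp
        blues = pd.concat(blue_rows, ignore_index=True)
        blues.to_csv(out / "blues.csv", index=False)
        vc_table = blues.rename(columns={"blue": "value"})
        vc_res = VarianceComponentsModel(vc_table).fit()
        comps = vc_res.components
        n_e, n_r = realized_unbalance(plot_table)
        varcomp_out = {
            "per_env_design": varcomps,
            "across_env": comps.as_dict(),
            "H2": heritability(comps),
            "n_e": n_e,
            "n_r": n_r,
        }
        with open(out / "varcomp.json", "w") as fh:
            json.dump(varcomp_out, fh, indent=1, default=float)
        manifest["stages"][stage] = {"design": design, "H2": heritability(comps)}
        log.info("blues: %d BLUEs, H2=%.3f", len(blues), heritability(comps))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    # ---- stage: cv --------------------------------------------------------
    stage = "cv"
    try:
        obs = blues.rename(columns={"blue": "y"})[["line", "env", "y"]]
        dataset = PredictionDataset(obs, grm, features)
        schemes = config.cv.get("schemes", ["7fcv"])
        models = config.cv.get("models", ["pls"])
        etas = config.cv.get("etas", ["ETA1", "ETA2"])
        k = int(config.cv.get("k", 7))
        gspec = GblupSpec(**config.gblup) if config.gblup else None
        result_rows = []
        pred_frames = []
        for scheme in schemes:
            for model in models:
                for eta in etas:
                    if scheme.lower() == "7fcv":
                        cv = run_7fcv(dataset, model, eta, k=k, seed=config.seed,
                                      pls_opts=config.pls, gblup_spec=gspec,
                                      fold_level=config.cv.get("fold_level", "obs"))
                    elif scheme.lower() == "loeo":
                        if eta not in config.cv.get("loeo_etas", LOEO_DEFAULT_ETAS):
                            continue
                        cv = run_loeo(dataset, model, eta, seed=config.seed,
                                      pls_opts=config.pls, gblup_spec=gspec)
                    else:
                        raise ValueError(f"unknown scheme {scheme!r}")
                    for _, r in cv.per_env.iterrows():
                        result_rows.append((cv.scheme, model, eta, r["env"], r["cor"], r["se"]))
                    result_rows.append((cv.scheme, model, eta, "Global", cv.global_cor, cv.global_se))
                    p = cv.predictions.copy()
                    p.insert(0, "eta", eta)
                    p.insert(0, "model", model)
                    p.insert(0, "scheme", cv.scheme)
                    pred_frames.append(p)
                    log.info("cv: %s %s %s Global=%.3f", cv.scheme, model, eta, cv.global_cor)
        results = pd.DataFrame(result_rows, columns=["scheme", "model", "eta", "env", "cor", "se"])
        results.to_csv(out / "results.csv", index=False)
        pd.concat(pred_frames, ignore_index=True).to_csv(out / "predictions.csv", index=False)
        manifest["stages"][stage] = {
            "schemes": schemes, "models": models, "etas": etas, "k": k,
            "fold_level": config.cv.get("fold_level", "obs"),
            "loeo_etas": list(config.cv.get("loeo_etas", LOEO_DEFAULT_ETAS)),
            "pls": {"a_max": config.pls.get("a_max", 15), "k_inner": config.pls.get("k_inner", 10),
                     "metric": config.pls.get("metric", "nrmse"), "scale": config.pls.get("scale", False)},
            "gblup": config.gblup or "defaults",
        }
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out
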