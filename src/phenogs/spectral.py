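"""Radiometric calibration and multispectral feature engineering.

The sensor records eight broad bands between 450 and 970 nm (Blue, Green,
Red, RE1, RE2, B900, B975, NIR) as raw digital numbers (DN).  Reference
panels of known reflectance give a per-band linear calibration
``SR = DN * slope + intercept``.  From calibrated plot-level reflectance we
compute the vegetation indices

    NDVI  = (R800 - R680) / (R800 + R680)      (R800 -> NIR, R680 -> Red)
    NDRE1 = (R800 - R700) / (R800 + R700)      (R700 -> RE1)
    GNDVI = (NIR - Green) / (NIR + Green)      (per pixel)
    CanopyCover = mean over pixels of GNDVI

and assemble, per line x environment observation, the 11-variable feature
vector H (8 band means + NDRE1, NDVI, CanopyCover) and its 3-index
sub-vector I (CanopyCover, NDRE1, NDVI).

Two calibration protocols are supported: ``panel`` (per-band regression on
a set of reflectance panels) and ``single2019`` (RGB/red-edge calibration
only, with NIR derived from quantum-efficiency coefficients as
``NIR = 2.921*Blue - 0.754*Red`` and normalized by 3.07 when entering the
index computations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BAND_NAMES = ["Blue", "Green", "Red", "RE1", "RE2", "B900", "B975", "NIR"]

H_COLUMNS = ["Blue", "Green", "Red", "NIR", "RE1", "RE2", "B900", "B975", "NDRE1", "NDVI", "CanopyCover"]
I_COLUMNS = ["CanopyCover", "NDRE1", "NDVI"]

# Table-of-indices wavelengths to sensor bands; configurable at call sites.
DEFAULT_WAVELENGTH_MAP = {"R800": "NIR", "R680": "Red", "R700": "RE1"}

NIR_BLUE_COEF = 2.921
NIR_RED_COEF = -0.754
NIR_NORMALIZATION = 3.07


@dataclass
class CalibrationModel:
    """Per-band linear DN -> reflectance map with its fit quality."""

    slope: float
    intercept: float
    r2: float

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")


def fit_calibration(panel_dn, panel_reflectance) -> CalibrationModel:
    """OLS regression of panel reflectance on panel digital numbers."""
    dn = np.asarray(panel_dn, dtype=float)
    sr = np.asarray(panel_reflectance, dtype=float)
    if dn.size < 2 or sr.size != dn.size:
        raise ValueError("need >=2 (DN, reflectance) panel pairs")
    if np.ptp(dn) == 0:
        raise ValueError("panel DN values are identical; calibration fit is singular")
    res = stats.linregress(dn, sr)
    r2 = float(res.rvalue**2) if np.ptp(sr) > 0 else 1.0
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept), r2=r2)


def apply_calibration(dn_values, model: CalibrationModel) -> np.ndarray:
    """``SR = DN*slope + intercept``, floored at 0."""
    dn = np.asarray(dn_values, dtype=float)
    return np.clip(dn * model.slope + model.intercept, 0.0, None)


def derive_nir_2019(blue, red, normalize: bool = False):
    """NIR from quantum-efficiency coefficients: ``2.921*Blue - 0.754*Red``.

    With ``normalize`` (the index-computation path) the result is divided by
    3.07.  Negative values are floored at 0.
    """
    nir = NIR_BLUE_COEF * np.asarray(blue, dtype=float) + NIR_RED_COEF * np.asarray(red, dtype=float)
    nir = np.clip(nir, 0.0, None)
    if normalize:
        nir = nir / NIR_NORMALIZATION
    return nir


def normalized_difference(a, b):
    """(a - b) / (a + b), with a zero denominator raising ValueError."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    if np.any(denom == 0):
        raise ValueError("undefined normalized-difference index: zero band sum")
    return (a - b) / denom


def aggregate_pixels(pixel_table: pd.DataFrame, value_cols=None) -> pd.DataFrame:
    """Per-plot arithmetic band means from a pixel table.

    ``pixel_table`` is wide format: one row per pixel with a ``plot_id``
    column and one column per band.  Returns one row per plot with band
    means and an ``n_pixels`` count.  Plots with zero pixels cannot occur by
    construction; an empty table raises.
    """
    if pixel_table.empty:
        raise ValueError("empty pixel table")
    if "plot_id" not in pixel_table.columns:
        raise ValueError("pixel table must carry a plot_id column")
    cols = value_cols or [c for c in pixel_table.columns if c != "plot_id"]
    grouped = pixel_table.groupby("plot_id", sort=True)
    means = grouped[cols].mean()
    means["n_pixels"] = grouped.size()
    return means.reset_index()


def compute_indices(
    plot_bands: pd.DataFrame,
    pixel_table: pd.DataFrame | None = None,
    wavelength_map: dict | None = None,
    canopy_mode: str = "mean_gndvi",
    canopy_threshold: float = 0.5,
    per_pixel_indices: bool = False,
) -> pd.DataFrame:
    """Spectral features per plot: 8 band means + NDVI, NDRE1, CanopyCover.

    NDVI and NDRE1 default to plot-mean reflectance (set
    ``per_pixel_indices`` to average pixel-wise indices instead).
    CanopyCover is the mean over pixels of GNDVI; ``canopy_mode='fraction'``
    instead reports the fraction of pixels whose GNDVI exceeds
    ``canopy_threshold``.  Without a pixel table, CanopyCover falls back to
    plot-mean GNDVI.
    """
    wl = dict(DEFAULT_WAVELENGTH_MAP)
    if wavelength_map:
        wl.update(wavelength_map)
    df = plot_bands.set_index("plot_id") if "plot_id" in plot_bands.columns else plot_bands.copy()
    out = df[BAND_NAMES].copy()

    if per_pixel_indices and pixel_table is not None:
        px = pixel_table
        ndvi_px = normalized_difference(px[wl["R800"]], px[wl["R680"]])
        ndre_px = normalized_difference(px[wl["R800"]], px[wl["R700"]])
        tmp = pd.DataFrame({"plot_id": px["plot_id"], "NDVI": ndvi_px, "NDRE1": ndre_px})
        agg = tmp.groupby("plot_id", sort=True).mean()
        out["NDVI"] = agg["NDVI"]
        out["NDRE1"] = agg["NDRE1"]
    else:
        out["NDVI"] = normalized_difference(df[wl["R800"]], df[wl["R680"]])
        out["NDRE1"] = normalized_difference(df[wl["R800"]], df[wl["R700"]])

    if pixel_table is not None:
        gndvi = normalized_difference(pixel_table["NIR"], pixel_table["Green"])
        tmp = pd.DataFrame({"plot_id": pixel_table["plot_id"], "GNDVI": gndvi})
        if canopy_mode == "fraction":
            cc = tmp.groupby("plot_id", sort=True)["GNDVI"].apply(
                lambda s: float((s > canopy_threshold).mean())
            )
        else:
            cc = tmp.groupby("plot_id", sort=True)["GNDVI"].mean()
        out["CanopyCover"] = cc
    else:
        out["CanopyCover"] = normalized_difference(df["NIR"], df["Green"])

    return out.reset_index()


def calibrate_pixels(
    pixel_dn: pd.DataFrame,
    panels: pd.DataFrame,
    mode: str = "panel",
) -> tuple[pd.DataFrame, dict[str, CalibrationModel]]:
    """Calibrate a raw-DN pixel table to reflectance.

    ``panels`` has columns (band, dn, reflectance).  Mode ``panel`` fits a
    per-band regression on all panels.  Mode ``single2019`` calibrates the
    Blue/Green/Red/RE1/RE2 bands from the available panel rows and derives
    NIR from Blue and Red via :func:`derive_nir_2019` (normalized for index
    computation downstream); B900/B975 are calibrated like the visible bands
    when panel rows exist for them.
    """
    models: dict[str, CalibrationModel] = {}
    out = pixel_dn.copy()
    bands_with_panels = set(panels["band"].unique())
    if mode == "single2019":
        target_bands = [b for b in BAND_NAMES if b != "NIR" and b in bands_with_panels]
    elif mode == "panel":
        target_bands = [b for b in BAND_NAMES if b in bands_with_panels]
    else:
        raise ValueError(f"unknown calibration mode {mode!r}")
    for band in target_bands:
        sub = panels[panels["band"] == band]
        models[band] = fit_calibration(sub["dn"], sub["reflectance"])
        out[band] = apply_calibration(pixel_dn[band], models[band])
    if mode == "single2019":
        out["NIR"] = derive_nir_2019(out["Blue"], out["Red"], normalize=True)
    elif "NIR" not in models:
        raise ValueError("panel mode requires NIR calibration panels")
    return out, models


def build_features(
    pixel_dn: pd.DataFrame,
    panels: pd.DataFrame,
    plot_meta: pd.DataFrame,
    mode: str = "panel",
    **index_kwargs,
) -> pd.DataFrame:
    """End-to-end spectral feature table: DN pixels -> per line x env H and I.

    ``plot_meta`` maps plot_id -> (line, env); plots of the same line and
    environment (replicates) are averaged.  Returns one row per line x env
    with the 11 H columns (I is the stated sub-vector of H).
    """
    calibrated, _ = calibrate_pixels(pixel_dn, panels, mode=mode)
    plot_bands = aggregate_pixels(calibrated, value_cols=BAND_NAMES)
    feats = compute_indices(plot_bands, pixel_table=calibrated, **index_kwargs)
    merged = feats.merge(plot_meta[["plot_id", "line", "env"]].drop_duplicates(), on="plot_id")
    per_obs = merged.groupby(["line", "env"], sort=True)[H_COLUMNS].mean().reset_index()
    return per_obs


def h_matrix(features: pd.DataFrame) -> np.ndarray:
    """The n x 11 H matrix in canonical column order."""
    return features[H_COLUMNS].to_numpy(dtype=float)


def i_matrix(features: pd.DataFrame) -> np.ndarray:
    """The n x 3 I matrix (CanopyCover, NDRE1, NDVI)."""
    return features[I_COLUMNS].to_numpy(dtype=float)
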