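"""Seeded generators for every input the analysis pipeline consumes.

Three families of synthetic data emulate the measurement types the
model was built for:

* **cellular iron maps** — micron-resolution 2D concentration grids
  with ~5 um iron-rich cell-soma hotspots on a diffuse, spatially
  correlated fiber background (stand-in for particle-beam elemental
  microscopy of SWM tissue);
* **cortical ribbon phantoms** — 2D gyrus cross-sections with banded
  iron and myelin concentrations (SWM peak 55 ug/g over cortical and
  deep-WM baselines) and an R2* map generated from the empirical linear
  contrast model;
* **surface sample tables** — per-vertex R2* values following the
  orientation GLM with known coefficients, regional iron patterns and
  noise, with a configurable orientation-variance share.

All generators are pure functions of (config, seed): identical inputs
give bit-identical outputs, and every generator returns machine-readable
ground truth alongside the data so recovery tests never compare against
hard-coded numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .fieldsim import IronConcentrationMap
from .profiles import BANDS, BoundaryPolyline
from .surface import SurfaceSampleTable

__all__ = [
    "CellularSceneConfig",
    "RibbonPhantomConfig",
    "SurfaceTableConfig",
    "gen_cellular_iron_map",
    "gen_ribbon_phantom",
    "gen_surface_table",
]


@dataclass(frozen=True)
class CellularSceneConfig:
    """Configuration of a synthetic cellular iron scene.

    Defaults mirror the reported SWM microscopy conditions: a
    200 um x 200 um field of view at 1 um resolution, ~5 um soma
    hotspots, and a soma iron-mass fraction of 0.12 of the total.
    """

    fov_um: Tuple[float, float] = (200.0, 200.0)
    pixel_size_um: float = 1.0
    section_thickness_um: float = 10.0
    soma_density_per_um2: float = 0.002
    soma_radius_um: float = 2.5
    background_mean: float = 33.0          # ug/g wtw, diffuse fiber iron
    background_rel_sd: float = 0.3
    correlation_length_um: float = 5.0
    target_soma_fraction: Optional[float] = 0.12
    soma_peak_concentration: float = 120.0  # used when no target fraction
    seed: int = 0


@dataclass(frozen=True)
class RibbonPhantomConfig:
    """Configuration of a 2D cortical-ribbon phantom.

    Band iron concentrations default to the reported values:
    upper cortex 15.6, middle cortex 29.2, SWM 55, DWM 33 ug/g wtw.
    The R2* map is the linear contrast model
    ``r_fe * iron + r_m * myelin + offset`` plus Gaussian noise.
    """

    shape: Tuple[int, int] = (160, 200)     # rows x cols
    boundary_row: int = 70
    cortical_thickness_px: int = 60
    iron_bands: Tuple[float, ...] = (15.6, 29.2, 38.0, 55.0, 44.0, 33.0)
    myelin_bands: Tuple[float, ...] = (0.10, 0.15, 0.20, 0.35, 0.40, 0.45)
    iron_relaxivity: float = 0.35           # s^-1 per ug/g wtw
    myelin_coefficient: float = 47.0        # s^-1 per volume fraction
    offset: float = 13.7                    # s^-1
    noise_sd: float = 3.0                   # s^-1, per-pixel R2* noise
    n_boundary_points: int = 20
    seed: int = 0


@dataclass(frozen=True)
class SurfaceTableConfig:
    """Configuration of a synthetic per-vertex SWM sample table.

    theta follows the normals of a sphere-like surface (sin-weighted).
    The orientation-variance share defaults to 0.08, with the remaining
    variance split between regional iron contrast and vertex noise.
    """

    n_vertices: int = 10_000
    beta0: float = 20.0
    beta1: float = 3.0
    beta2: float = -1.0
    orientation_share: Optional[float] = 0.08
    n_regions: int = 6
    region_variance_fraction: float = 0.7   # of the non-orientation variance
    noise_sd: float = 1.0                   # used when no share target
    region_sd: float = 1.5                  # used when no share target
    seed: int = 0


# boundaries of the six phantom depth bands, in the profile depth
# coordinate (-1 pial ... 0 GM-WM boundary ... +1 deep WM)
_RIBBON_BAND_EDGES = (-0.75, -0.35, 0.0, 0.20, 0.50)


def gen_cellular_iron_map(
    config: CellularSceneConfig = CellularSceneConfig(),
) -> Tuple[IronConcentrationMap, dict]:
    """Synthetic cellular iron map plus ground truth.

    The diffuse background is smoothed Gaussian noise with the
    configured correlation length; somata are Gaussian hotspots placed
    without overlap.  When ``target_soma_fraction`` is set, soma
    amplitudes are scaled analytically so that the iron mass inside the
    soma mask is exactly that fraction of the total.

    Returns ``(map, truth)`` where truth has ``soma_mask``,
    ``soma_fraction``, ``centers`` and ``amplitude``.
    """
    rng = np.random.default_rng(config.seed)
    nx = int(round(config.fov_um[0] / config.pixel_size_um))
    ny = int(round(config.fov_um[1] / config.pixel_size_um))

    sigma_px = config.correlation_length_um / config.pixel_size_um
    background = gaussian_filter(rng.standard_normal((nx, ny)), sigma_px)
    sd = background.std()
    if sd > 0:
        background = background / sd * (config.background_rel_sd * config.background_mean)
    background = np.clip(background + config.background_mean, 0.0, None)

    n_somata = int(round(config.soma_density_per_um2 * config.fov_um[0] * config.fov_um[1]))
    r_px = config.soma_radius_um / config.pixel_size_um
    min_sep = 2.0 * r_px
    centers_arr = np.empty((0, 2))
    max_tries = 50 * max(n_somata, 1)
    tries = 0
    while len(centers_arr) < n_somata and tries < max_tries:
        tries += 1
        c = rng.uniform([r_px, r_px], [nx - r_px, ny - r_px])
        if (
            len(centers_arr) == 0
            or np.min(np.hypot(*(centers_arr - c).T)) >= min_sep
        ):
            centers_arr = np.vstack([centers_arr, c])
    centers = [tuple(c) for c in centers_arr]
    if len(centers) < n_somata:
        raise ValueError(
            f"infeasible soma density: placed {len(centers)} of {n_somata} "
            "non-overlapping somata"
        )

    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    unit = np.zeros((nx, ny))
    mask = np.zeros((nx, ny), dtype=bool)
    sigma_soma = r_px / 2.0  # ~95% of the soma profile within the radius
    for cx, cy in centers:
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        unit += np.exp(-r2 / (2.0 * sigma_soma**2))
        mask |= r2 <= r_px**2

    if n_somata == 0:
        values = background
        amplitude = 0.0
    elif config.target_soma_fraction is not None:
        f = config.target_soma_fraction
        total_bg = background.sum()
        bg_in = background[mask].sum()
        unit_in = unit[mask].sum()
        amplitude = (f * total_bg - bg_in) / ((1.0 - f) * unit_in)
        if amplitude <= 0:
            raise ValueError(
                "target soma fraction is below the background's own share "
                "inside the soma mask; increase the target or lower density"
            )
        values = background + amplitude * unit
    else:
        amplitude = config.soma_peak_concentration - config.background_mean
        values = background + amplitude * unit

    iron = IronConcentrationMap(
        values, (config.pixel_size_um,) * 2, config.section_thickness_um
    )
    realized = float(values[mask].sum() / values.sum()) if mask.any() else 0.0
    truth = {
        "soma_mask": mask,
        "soma_fraction": realized,
        "centers": np.asarray(centers),
        "amplitude": float(amplitude),
    }
    return iron, truth


def _band_lookup(depth: np.ndarray, band_values: Tuple[float, ...]) -> np.ndarray:
    """Piecewise-constant depth profile over the six phantom bands."""
    idx = np.searchsorted(np.asarray(_RIBBON_BAND_EDGES), depth, side="left")
    return np.asarray(band_values, dtype=float)[idx]


def gen_ribbon_phantom(
    config: RibbonPhantomConfig = RibbonPhantomConfig(),
) -> dict:
    """Cortical ribbon phantom: iron, myelin and R2* maps plus boundary.

    The GM-WM boundary is a horizontal line; depth bands are
    piecewise-constant so band averages recover the configured
    concentrations exactly.  The noiseless R2* map is exactly the linear
    combination of the iron and myelin maps with the configured
    coefficients.

    Returns a dict with ``iron``, ``myelin``, ``r2s``, ``r2s_noiseless``
    maps, a ``boundary`` polyline, ``cortical_depth`` (px) and
    ``truth`` (coefficients, band values, noise SD).
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.shape
    rows = np.arange(n_rows, dtype=float)
    depth = (rows - config.boundary_row) / config.cortical_thickness_px

    iron_profile = _band_lookup(depth, config.iron_bands)
    myelin_profile = _band_lookup(depth, config.myelin_bands)
    iron = np.repeat(iron_profile[:, None], n_cols, axis=1)
    myelin = np.repeat(myelin_profile[:, None], n_cols, axis=1)
    r2s_clean = (
        config.iron_relaxivity * iron
        + config.myelin_coefficient * myelin
        + config.offset
    )
    r2s = r2s_clean + config.noise_sd * rng.standard_normal(r2s_clean.shape)

    # ordered so that the +90deg normal convention of extract_profiles
    # points toward increasing rows, i.e. into the phantom's white matter
    cols = np.linspace(n_cols - 3.0, 2.0, config.n_boundary_points)
    boundary = BoundaryPolyline(
        np.column_stack([np.full_like(cols, float(config.boundary_row)), cols])
    )
    truth = {
        "coefficients": (
            config.iron_relaxivity,
            config.myelin_coefficient,
            config.offset,
        ),
        "iron_bands": dict(zip(
            ("cortex-upper", "cortex-middle", "cortex-deep", "swm", "transition", "dwm"),
            config.iron_bands,
        )),
        "noise_sd": config.noise_sd,
    }
    return {
        "iron": iron,
        "myelin": myelin,
        "r2s": r2s,
        "r2s_noiseless": r2s_clean,
        "boundary": boundary,
        "cortical_depth": float(config.cortical_thickness_px),
        "truth": truth,
    }


def gen_surface_table(
    config: SurfaceTableConfig = SurfaceTableConfig(),
) -> Tuple[SurfaceSampleTable, dict]:
    """Synthetic per-vertex table following the orientation GLM.

    ``r2s = beta0 + beta1 sin^2 theta + beta2 sin^4 theta +
    eps(region) + noise``, with theta drawn as the polar angle of
    uniformly distributed sphere normals.  When ``orientation_share`` is
    set, the regional and noise variances are scaled so the orientation
    term carries exactly that share of the total variance in
    expectation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_vertices
    u = rng.uniform(-1.0, 1.0, size=n)
    theta = np.arccos(u)
    s2 = np.sin(theta) ** 2
    orient = config.beta1 * s2 + config.beta2 * s2**2
    var_orient = float(np.var(orient))

    region_labels = rng.integers(0, config.n_regions, size=n)
    region_effects_raw = rng.standard_normal(config.n_regions)
    region_effects_raw -= region_effects_raw.mean()
    region_raw = region_effects_raw[region_labels]
    noise_raw = rng.standard_normal(n)

    if config.orientation_share is not None:
        share = config.orientation_share
        if not 0 < share < 1:
            raise ValueError("orientation_share must be in (0, 1)")
        var_rest = var_orient * (1.0 - share) / share
        var_region = config.region_variance_fraction * var_rest
        var_noise = (1.0 - config.region_variance_fraction) * var_rest
        region = region_raw / region_raw.std() * np.sqrt(var_region)
        noise = noise_raw * np.sqrt(var_noise)
    else:
        region = region_raw * config.region_sd
        noise = noise_raw * config.noise_sd

    r2s = config.beta0 + orient + region + noise
    data = pd.DataFrame({
        "vertex": np.arange(n),
        "r2s": r2s,
        "theta": theta,
        "region": region_labels,
    })
    table = SurfaceSampleTable(
        data, metadata={"b0_direction": [0.0, 0.0, 1.0], "synthetic": True}
    )
    total_var = float(np.var(r2s))
    truth = {
        "betas": (config.beta0, config.beta1, config.beta2),
        "orientation_share": var_orient / total_var if total_var else 0.0,
        "region_effect": region,
        "noise_sd": float(noise.std()),
    }
    return table, truth
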