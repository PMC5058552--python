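"""Seeded synthetic treeline landscapes with known ground truth.

A scene emulates the ingredients of a shrub-encroachment study at the alpine
timberline: spatially autocorrelated covariate fields, a six-class vegetation
mosaic (pasture, three heathland types, green alder, conifer forest) sampled
from a multinomial logit with known coefficients, class-dependent spectral
bands with noise, auxiliary terrain/climate/infrastructure layers, vegetation
training plots inside homogeneous patches, and breeding presences drawn from
a known suitability law with unimodal responses to the 100 m vegetation-cover
proportions (optima between 10% and 50%).  Optionally, dense shrub discs are
"planted" into the truth map so that downstream patch-prioritization can be
scored against exact cell sets.

Everything is a deterministic function of the scene seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import (
    RasterGrid,
    RasterStack,
    WindowSpec,
    focal_proportion,
    ndvi,
    simpson_diversity,
    terrain_derivatives,
)

__all__ = [
    "VEG_CLASSES",
    "HEATHLAND_CLASSES",
    "SDM_VEG_LAYERS",
    "PlantedPatch",
    "SceneConfig",
    "LandscapeScene",
    "gaussian_field",
    "build_scene",
    "sample_training_plots",
    "sample_presences",
]

#: Fixed six-type vegetation vocabulary (integer codes = list position).
VEG_CLASSES = ("PASTURE", "RHODO", "JUNI", "MIXED", "ALNUS", "FOREST")
#: The three heathland types, grouped for patch detection.
HEATHLAND_CLASSES = ("RHODO", "JUNI", "MIXED")
#: Habitat-model layer names for the five non-forest vegetation proportions.
#: The pasture class surfaces as "MEADOW" in the habitat-model layer set.
SDM_VEG_LAYERS = ("MEADOW", "RHODO", "JUNI", "MIXED", "ALNUS")

_CLASS_INDEX = {c: i for i, c in enumerate(VEG_CLASSES)}


def class_code(name: str) -> int:
    return _CLASS_INDEX[name]


def gaussian_field(
    shape: tuple[int, int], range_m: float, cell_size: float = 25.0, rng=None
) -> np.ndarray:
    """Stationary, ~N(0,1) random field with Gaussian autocorrelation.

    White noise is filtered in the frequency domain with a Gaussian kernel of
    standard deviation ``range_m`` (metres), then standardized to zero mean
    and unit variance.  The field is periodic (wrap-around), which is
    irrelevant at the scales used here.
    """
    if not range_m > 0:
        raise ValueError("range_m must be positive")
    rng = np.random.default_rng(rng)
    sigma = range_m / cell_size
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    filt = np.exp(-0.5 * (2 * np.pi * sigma) ** 2 * (fx**2 + fy**2))
    f = np.real(np.fft.ifft2(np.fft.fft2(white) * filt))
    f -= f.mean()
    sd = f.std()
    if sd > 0:
        f /= sd
    return f


@dataclass
class PlantedPatch:
    """A dense shrub disc stamped into the truth map (encroachment stand-in)."""

    veg_class: str
    center_xy: tuple[float, float]
    radius_m: float

    def __post_init__(self):
        if self.veg_class not in VEG_CLASSES:
            raise ValueError(f"unknown class {self.veg_class!r}")


def _default_coefficients() -> np.ndarray:
    # rows: classes in VEG_CLASSES order; cols: PCA04, PCA05, PCA08, ELEVZ
    return np.array(
        [
            [1.6, 0.0, -0.8, 0.3],   # PASTURE
            [0.0, 1.5, 0.6, 0.4],    # RHODO
            [-1.4, 0.8, 0.0, 0.2],   # JUNI
            [0.0, 1.1, -1.1, 0.3],   # MIXED
            [0.0, 0.0, 0.0, 0.0],    # ALNUS (reference)
            [0.5, -0.5, 0.5, -2.2],  # FOREST (recedes above the treeline)
        ]
    )


def _default_band_means() -> np.ndarray:
    # Synthetic reflectance archetypes (RED, BLUE, GREEN, NIR) per class;
    # loosely ordered from bright grassy to dark conifer canopy.
    return np.array(
        [
            [0.16, 0.10, 0.22, 0.62],  # PASTURE: bright, very high NIR
            [0.08, 0.06, 0.13, 0.42],  # RHODO: dark evergreen shrub
            [0.11, 0.08, 0.15, 0.34],  # JUNI
            [0.09, 0.07, 0.17, 0.38],  # MIXED
            [0.07, 0.05, 0.18, 0.55],  # ALNUS: lush deciduous shrub
            [0.05, 0.04, 0.09, 0.28],  # FOREST: dark conifer
        ]
    )


@dataclass
class SceneConfig:
    """Study conditions for one synthetic scene.

    Defaults mirror the study setup where one is stated (25 m cells, 100 m
    window, 67 presences with <=100 m precision, 600 training plots, 625 m2
    minimum homogeneous-patch size) and otherwise hold one fixed, realistic
    choice (documented in the methods note).
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 25.0
    seed: int = 0

    # spatial autocorrelation ranges (metres)
    covariate_range_m: float = 200.0
    dem_range_m: float = 600.0
    dem_base: float = 2050.0
    dem_amplitude: float = 250.0

    # vegetation generative model: softmax over utility_scale * (B @ g + a)
    utility_scale: float = 2.0
    veg_coefficients: np.ndarray = field(default_factory=_default_coefficients)
    veg_intercepts: np.ndarray = field(
        default_factory=lambda: np.array([0.3, -0.1, -0.1, -0.3, 0.9, 0.4])
    )

    # spectral bands
    band_means: np.ndarray = field(default_factory=_default_band_means)
    band_noise_sd: float = 0.035
    band_elev_trend: float = 4e-5  # per metre, mild brightness drift

    # true suitability: product of unimodal kernels on 100 m vegetation cover
    response_optima: dict = field(
        default_factory=lambda: {
            "MEADOW": 0.25,
            "RHODO": 0.30,
            "JUNI": 0.10,
            "MIXED": 0.50,
            "ALNUS": 0.27,
        }
    )
    response_widths: dict = field(
        default_factory=lambda: {
            "MEADOW": 0.20,
            "RHODO": 0.20,
            "JUNI": 0.15,
            "MIXED": 0.25,
            "ALNUS": 0.18,
        }
    )
    sidi_gain: float = 1.5
    tave_optimum: float = 10.5
    tave_width: float = 1.3
    dforest_optimum: float = 0.20
    dforest_width: float = 0.30

    # sampling
    n_plots: int = 600
    min_patch_area_m2: float = 625.0
    n_presences: int = 67
    presence_jitter_m: float = 100.0

    # auxiliary layers
    rock_threshold: float = 1.9
    tree_rate: float = 0.03
    n_roads: int = 8

    window_radius_m: float = 100.0
    planted_patches: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["veg_coefficients"] = np.asarray(self.veg_coefficients).tolist()
        d["veg_intercepts"] = np.asarray(self.veg_intercepts).tolist()
        d["band_means"] = np.asarray(self.band_means).tolist()
        d["shape"] = list(self.shape)
        d["planted_patches"] = [
            {"veg_class": p.veg_class, "center_xy": list(p.center_xy), "radius_m": p.radius_m}
            for p in self.planted_patches
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        for key in ("veg_coefficients", "veg_intercepts", "band_means"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        d["planted_patches"] = [
            PlantedPatch(p["veg_class"], tuple(p["center_xy"]), p["radius_m"])
            for p in d.get("planted_patches", [])
        ]
        return cls(**d)


@dataclass
class LandscapeScene:
    """A fully built scene: covariate stack plus every ground truth."""

    config: SceneConfig
    stack: RasterStack
    class_map: RasterGrid  # integer codes into VEG_CLASSES
    suitability: RasterGrid  # true relative suitability in [0, 1]
    irrelevant_mask: np.ndarray  # rock/scree/glacier cells excluded from modelling
    plots: pd.DataFrame  # x, y, veg_class
    presences: pd.DataFrame  # x, y, precision_m
    planted: list  # dicts with veg_class, center, radius and exact cell index sets
    truth: dict  # generative coefficients (reference-class form), optima, etc.

    @property
    def class_names(self) -> tuple[str, ...]:
        return VEG_CLASSES


#: Predictor layers the vegetation classifier sees by default.
VEG_PREDICTORS_DEFAULT = (
    "BAND1",
    "BAND2",
    "BAND3",
    "BAND4",
    "NDVI8",
    "PCA04",
    "PCA05",
    "PCA08",
    "SLOPE",
    "NORTH",
    "EAST",
)


def build_scene(config: SceneConfig | None = None) -> LandscapeScene:
    """Deterministically build the full synthetic scene from its config."""
    cfg = config or SceneConfig()
    ny, nx = cfg.shape
    cs = cfg.cell_size
    seeds = np.random.SeedSequence(cfg.seed).spawn(12)
    rngs = [np.random.default_rng(s) for s in seeds]
    (
        rng_dem,
        rng_cov,
        rng_class,
        rng_band,
        rng_clim,
        rng_rock,
        rng_tree,
        rng_road,
        rng_oforest,
        rng_settle,
        rng_plots,
        rng_pres,
    ) = rngs

    def grid(values, mask=None):
        return RasterGrid(values, mask=mask, cell_size=cs, origin=(0.0, 0.0))

    # -- terrain ----------------------------------------------------------
    dem_vals = np.clip(
        cfg.dem_base + cfg.dem_amplitude * gaussian_field(cfg.shape, cfg.dem_range_m, cs, rng_dem),
        1600.0,
        2500.0,
    )
    dem = grid(dem_vals)
    terrain = terrain_derivatives(dem, WindowSpec(cfg.window_radius_m))
    elevz = (dem_vals - cfg.dem_base) / cfg.dem_amplitude

    # -- generative covariates -------------------------------------------
    cov = {
        name: gaussian_field(cfg.shape, cfg.covariate_range_m, cs, rng_cov)
        for name in ("PCA04", "PCA05", "PCA08")
    }
    G = np.stack([cov["PCA04"], cov["PCA05"], cov["PCA08"], elevz])  # (4, ny, nx)

    # -- vegetation truth map --------------------------------------------
    B = np.asarray(cfg.veg_coefficients, dtype=float)
    a = np.asarray(cfg.veg_intercepts, dtype=float)
    util = cfg.utility_scale * (np.tensordot(B, G, axes=(1, 0)) + a[:, None, None])
    # Gumbel-argmax == one draw from softmax(util) per cell
    gumbel = -np.log(-np.log(rng_class.uniform(size=util.shape)))
    classes = np.argmax(util + gumbel, axis=0)

    planted_records = []
    X, Y = grid(classes).cell_centers()
    for p in cfg.planted_patches:
        inside = (X - p.center_xy[0]) ** 2 + (Y - p.center_xy[1]) ** 2 <= p.radius_m**2
        classes = np.where(inside, class_code(p.veg_class), classes)
        planted_records.append(
            {
                "veg_class": p.veg_class,
                "center_xy": tuple(p.center_xy),
                "radius_m": p.radius_m,
                "cells": np.argwhere(inside),
            }
        )
    class_map = grid(classes.astype(float))

    # -- spectral bands (from the final truth map) ------------------------
    means = np.asarray(cfg.band_means, dtype=float)
    bands = {}
    for b in range(4):
        vals = (
            means[classes, b]
            + cfg.band_elev_trend * (dem_vals - 2000.0)
            + cfg.band_noise_sd * rng_band.standard_normal(cfg.shape)
        )
        bands[f"BAND{b + 1}"] = grid(np.clip(vals, 0.01, None))
    ndvi8 = ndvi(bands["BAND4"], bands["BAND1"])

    # -- climate and auxiliary layers ------------------------------------
    tave6 = grid(
        14.0 - 0.0055 * (dem_vals - 1600.0) + 0.3 * gaussian_field(cfg.shape, 800.0, cs, rng_clim)
    )
    prec6 = grid(110.0 + 25.0 * gaussian_field(cfg.shape, 900.0, cs, rng_clim))
    sold6 = grid(
        220.0 + 20.0 * gaussian_field(cfg.shape, 700.0, cs, rng_clim) + 8.0 * terrain["EAST"].values
    )
    solr6 = grid(
        180.0
        + 15.0 * gaussian_field(cfg.shape, 700.0, cs, rng_clim)
        + 25.0 * terrain["NORTH"].values * -1.0
    )

    rock = gaussian_field(cfg.shape, 300.0, cs, rng_rock) > cfg.rock_threshold
    glacier = dem_vals > 2480.0
    irrelevant = rock | glacier
    # never blank out a planted patch: the recovery experiments need them modelled
    for rec in planted_records:
        irrelevant[rec["cells"][:, 0], rec["cells"][:, 1]] = False

    oforest = (gaussian_field(cfg.shape, 400.0, cs, rng_oforest) > 0.8) & (dem_vals < 2300.0)
    settle = (gaussian_field(cfg.shape, 250.0, cs, rng_settle) > 2.4) & (dem_vals < 1900.0)
    trees = rng_tree.poisson(cfg.tree_rate, size=cfg.shape).astype(float)

    roads = np.zeros(cfg.shape)
    for _ in range(cfg.n_roads):
        if rng_road.uniform() < 0.5:
            i = rng_road.integers(0, ny)
            roads[i, :] += cs  # metres of road per crossed cell
        else:
            j = rng_road.integers(0, nx)
            roads[:, j] += cs

    # -- true suitability -------------------------------------------------
    window = WindowSpec(cfg.window_radius_m)
    props = {}
    for layer, cls in zip(SDM_VEG_LAYERS, ("PASTURE", "RHODO", "JUNI", "MIXED", "ALNUS")):
        props[layer] = focal_proportion(class_map, [class_code(cls)], window)
    dforest = focal_proportion(class_map, [class_code("FOREST")], window)
    sidi = simpson_diversity([props[n] for n in SDM_VEG_LAYERS])

    def kernel(values, opt, width):
        return np.exp(-0.5 * ((values - opt) / width) ** 2)

    suit = kernel(tave6.values, cfg.tave_optimum, cfg.tave_width)
    for layer in SDM_VEG_LAYERS:
        suit = suit * kernel(
            props[layer].values, cfg.response_optima[layer], cfg.response_widths[layer]
        )
    suit = suit * kernel(dforest.values, cfg.dforest_optimum, cfg.dforest_width)
    suit = suit * np.exp(cfg.sidi_gain * sidi.values)
    suit = np.where(irrelevant, 0.0, suit)
    m = suit.max()
    if m > 0:
        suit = suit / m
    suitability = grid(suit, mask=irrelevant.copy())

    # -- assemble stack ---------------------------------------------------
    stack = RasterStack()
    stack.add("DEM", dem)
    for name in ("SLOPE", "NORTH", "EAST"):
        stack.add(name, terrain[name])
    stack.add("ELEVZ", grid(elevz))
    for name, vals in cov.items():
        stack.add(name, grid(vals))
    for name, g in bands.items():
        stack.add(name, g)
    stack.add("NDVI8", ndvi8)
    stack.add("TAVE6", tave6)
    stack.add("PREC6", prec6)
    stack.add("SOLD6", sold6)
    stack.add("SOLR6", solr6)
    stack.add("ROCK", grid(rock.astype(float)))
    stack.add("SETTLE", grid(settle.astype(float)))
    stack.add("OFOREST", grid(oforest.astype(float)))
    stack.add("TREE", grid(trees))
    stack.add("ROAD", grid(roads))

    # reference-class (ALNUS) generative coefficients, on utility scale
    ref = class_code("ALNUS")
    coef_ref = cfg.utility_scale * (B - B[ref])
    icpt_ref = cfg.utility_scale * (a - a[ref])

    scene = LandscapeScene(
        config=cfg,
        stack=stack,
        class_map=class_map,
        suitability=suitability,
        irrelevant_mask=irrelevant,
        plots=pd.DataFrame(),
        presences=pd.DataFrame(),
        planted=planted_records,
        truth={
            "generative_predictors": ["PCA04", "PCA05", "PCA08", "ELEVZ"],
            "reference_class": "ALNUS",
            "coefficients": coef_ref,
            "intercepts": icpt_ref,
            "response_optima": dict(cfg.response_optima),
        },
    )
    scene.plots = sample_training_plots(
        scene, cfg.n_plots, min_patch_area_m2=cfg.min_patch_area_m2, rng=rng_plots
    )
    scene.presences = sample_presences(
        scene, cfg.n_presences, jitter_max_m=cfg.presence_jitter_m, rng=rng_pres
    )
    return scene


def sample_training_plots(
    scene: LandscapeScene,
    n_plots: int,
    min_patch_area_m2: float = 625.0,
    rng=None,
) -> pd.DataFrame:
    """Vegetation training plots inside homogeneous patches of the truth map.

    Eligible cells belong to an 8-connected single-class component whose area
    meets ``min_patch_area_m2`` and are outside the irrelevant mask.  At most
    one plot per 25x25 m cell (the central-subcell field rule collapses to
    one record per cell on this grid); labels equal the truth map.
    """
    rng = np.random.default_rng(rng)
    classes = scene.class_map.values.astype(int)
    cell_area = scene.class_map.cell_size**2
    min_cells = max(1, int(np.ceil(min_patch_area_m2 / cell_area)))
    eligible = np.zeros(classes.shape, dtype=bool)
    structure = np.ones((3, 3), dtype=int)
    for code in range(len(VEG_CLASSES)):
        lab, n = ndimage.label(classes == code, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        big = sizes >= min_cells
        big[0] = False
        eligible |= big[lab]
    eligible &= ~scene.irrelevant_mask
    idx = np.argwhere(eligible)
    if len(idx) < n_plots:
        warnings.warn(
            f"only {len(idx)} eligible homogeneous cells; returning fewer than {n_plots} plots"
        )
    take = rng.choice(len(idx), size=min(n_plots, len(idx)), replace=False)
    ii, jj = idx[take, 0], idx[take, 1]
    cs = scene.class_map.cell_size
    x0, y0 = scene.class_map.origin
    return pd.DataFrame(
        {
            "x": x0 + (jj + 0.5) * cs,
            "y": y0 + (ii + 0.5) * cs,
            "veg_class": [VEG_CLASSES[c] for c in classes[ii, jj]],
        }
    )


def sample_presences(
    scene: LandscapeScene,
    n: int = 67,
    jitter_max_m: float = 100.0,
    rng=None,
) -> pd.DataFrame:
    """Breeding presences by rejection sampling on the true suitability.

    Cell locations are accepted with probability proportional to the true
    suitability, then jittered by a uniform distance in [0, jitter_max_m] in
    a uniform direction; the jitter magnitude is recorded as the location's
    precision (all records therefore pass a 100 m precision filter under the
    default).

    Randomness is consumed in fixed-size chunks so that scenes differing
    only locally (e.g. planted patches) share the rest of their proposal
    stream — common random numbers across scenario comparisons.
    """
    rng = np.random.default_rng(rng)
    suit = scene.suitability.values
    smax = suit.max()
    if smax <= 0:
        raise ValueError("all-zero suitability; cannot sample presences")
    ny, nx = suit.shape
    cs = scene.suitability.cell_size
    x0, y0 = scene.suitability.origin
    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    got = 0
    chunk = 256
    while got < n:
        ii = rng.integers(0, ny, size=chunk)
        jj = rng.integers(0, nx, size=chunk)
        keep = rng.uniform(size=chunk) < suit[ii, jj] / smax
        k = min(keep.sum(), n - got)
        rows[got : got + k] = ii[keep][:k]
        cols[got : got + k] = jj[keep][:k]
        got += k
    x = x0 + (cols + 0.5) * cs
    y = y0 + (rows + 0.5) * cs
    r = rng.uniform(0.0, jitter_max_m, size=n)
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    xj = np.clip(x + r * np.cos(theta), x0 + 1e-6, x0 + nx * cs - 1e-6)
    yj = np.clip(y + r * np.sin(theta), y0 + 1e-6, y0 + ny * cs - 1e-6)
    return pd.DataFrame({"x": xj, "y": yj, "precision_m": r})
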