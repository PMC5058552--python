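"""Restoration planning: counterfactual habitat, shrub patches, priorities.

The management product of the pipeline.  Breeding-habitat suitability is
re-predicted after setting the manageable ground/shrub vegetation layers
(five cover proportions plus their Simpson diversity) to their means at the
presence locations — the "if optimally vegetated" counterfactual.  Cells
whose 100 m neighbourhood is dominated (> 50%) by one shrub group (heathland
= the three dwarf-shrub types grouped, or green alder) are aggregated into
connected homogeneous patches; patches intersected with the potential
(counterfactual) habitat map are the priority areas for intervention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .maxent import MaxentSDM, predict_suitability
from .raster import RasterGrid, RasterStack, WindowSpec, focal_proportion

__all__ = [
    "COUNTERFACTUAL_LAYERS",
    "PatchSet",
    "PriorityReport",
    "counterfactual_stack",
    "potential_habitat",
    "detect_homogeneous_patches",
    "patch_stats",
    "priority_areas",
]

#: Manageable layers replaced by presence means in the counterfactual map.
COUNTERFACTUAL_LAYERS = ("MEADOW", "RHODO", "JUNI", "MIXED", "ALNUS", "SIDI")


def counterfactual_stack(
    sdm_stack: RasterStack,
    presences: pd.DataFrame,
    veg_variables=COUNTERFACTUAL_LAYERS,
) -> tuple[RasterStack, dict[str, float]]:
    """Replace each vegetation layer by its constant presence-location mean.

    All other layers are untouched.  Presences falling on masked cells are
    skipped with a warning.  Returns the new stack and the means used.
    """
    xs = presences["x"].to_numpy(dtype=float)
    ys = presences["y"].to_numpy(dtype=float)
    out = sdm_stack.copy()
    means: dict[str, float] = {}
    for name in veg_variables:
        layer = sdm_stack[name]
        vals = layer.sample(xs, ys)
        bad = np.isnan(vals)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} presence(s) on masked cells skipped for {name}")
        if np.all(bad):
            raise ValueError(f"no presence resolvable in layer {name!r}")
        mu = float(np.nanmean(vals))
        means[name] = mu
        out[name] = layer.like(np.full(layer.shape, mu), mask=layer.mask.copy())
    return out, means


def potential_habitat(
    model: MaxentSDM, cf_stack: RasterStack, threshold: float
) -> RasterGrid:
    """Binary potential-habitat map: counterfactual suitability >= threshold."""
    return predict_suitability(model, cf_stack, threshold=threshold).binary


@dataclass
class PatchSet:
    """Labelled homogeneous shrub patches of one vegetation group."""

    group: str
    labels: RasterGrid  # 0 = no patch, 1..n = patch id
    table: pd.DataFrame  # patch_id, n_cells, area_ha, size_class
    frac: float
    window_radius_m: float

    @property
    def n_patches(self) -> int:
        return len(self.table)

    @property
    def total_area_ha(self) -> float:
        return float(self.table["area_ha"].sum()) if len(self.table) else 0.0


def detect_homogeneous_patches(
    veg_class_map: RasterGrid,
    group_codes,
    group_name: str = "",
    window: WindowSpec = WindowSpec(100.0),
    frac: float = 0.5,
    connectivity: int = 8,
) -> PatchSet:
    """Connected components of cells whose window cover of the group > frac.

    The inequality is strict ("more than 50%"); components use 8-neighbour
    connectivity by default.  Patch areas are cell counts times cell area;
    size classes split at the 1 ha boundary.  An empty selection yields an
    empty PatchSet, not an error.
    """
    present = [
        c for c in group_codes if np.any(veg_class_map.values[veg_class_map.valid] == c)
    ]
    if present:
        prop = focal_proportion(veg_class_map, present, window)
        selected = (prop.values > frac) & prop.valid
    else:  # the group does not occur on the map: empty patch set
        selected = np.zeros(veg_class_map.shape, dtype=bool)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(selected, structure=structure)
    cell_area = veg_class_map.cell_area_ha
    if n:
        counts = np.bincount(labels.ravel())[1:]
        areas = counts * cell_area
        table = pd.DataFrame(
            {
                "patch_id": np.arange(1, n + 1),
                "n_cells": counts,
                "area_ha": areas,
                "size_class": np.where(areas < 1.0, "<1ha", ">=1ha"),
            }
        )
    else:
        table = pd.DataFrame(columns=["patch_id", "n_cells", "area_ha", "size_class"])
    return PatchSet(
        group=group_name,
        labels=veg_class_map.like(labels.astype(float), mask=veg_class_map.mask.copy()),
        table=table,
        frac=frac,
        window_radius_m=window.radius_m,
    )


def patch_stats(patch_set: PatchSet) -> dict:
    """Patch-size summary: share below 1 ha, median and IQR above it.

    Quantiles use linear interpolation (numpy default).  An empty patch set
    returns NaN statistics with ``defined = False``.
    """
    areas = patch_set.table["area_ha"].to_numpy(dtype=float)
    if len(areas) == 0:
        return {
            "n_total": 0,
            "fraction_below_1ha": float("nan"),
            "median_area_ge_1ha": float("nan"),
            "iqr_area_ge_1ha": (float("nan"), float("nan")),
            "defined": False,
        }
    big = areas[areas >= 1.0]
    out = {
        "n_total": int(len(areas)),
        "fraction_below_1ha": float((areas < 1.0).mean()),
        "defined": True,
    }
    if len(big):
        out["median_area_ge_1ha"] = float(np.median(big))
        out["iqr_area_ge_1ha"] = (
            float(np.percentile(big, 25)),
            float(np.percentile(big, 75)),
        )
    else:
        out["median_area_ge_1ha"] = float("nan")
        out["iqr_area_ge_1ha"] = (float("nan"), float("nan"))
    return out


@dataclass
class PriorityReport:
    """Area accounting of the restoration analysis.

    Percentages are reported against two denominators: the full grid
    ("total") and the modelled (unmasked) study area ("valid").
    """

    cell_area_ha: float
    study_area_ha_total: float
    study_area_ha_valid: float
    current_ha: float
    potential_ha: float
    groups: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def pct(x, denom):
            return 100.0 * x / denom if denom > 0 else float("nan")

        d = {
            "study_area_ha_total": self.study_area_ha_total,
            "study_area_ha_valid": self.study_area_ha_valid,
            "current_habitat": {
                "ha": self.current_ha,
                "pct_of_valid": pct(self.current_ha, self.study_area_ha_valid),
                "pct_of_total": pct(self.current_ha, self.study_area_ha_total),
            },
            "potential_habitat": {
                "ha": self.potential_ha,
                "pct_of_valid": pct(self.potential_ha, self.study_area_ha_valid),
                "pct_of_total": pct(self.potential_ha, self.study_area_ha_total),
            },
            "groups": {},
        }
        for g, v in self.groups.items():
            d["groups"][g] = {
                "patch_ha": v["patch_ha"],
                "patch_pct_of_valid": pct(v["patch_ha"], self.study_area_ha_valid),
                "priority_ha": v["priority_ha"],
                "priority_pct_of_potential": pct(v["priority_ha"], self.potential_ha),
                "fraction_of_patch_area_in_potential": (
                    v["priority_ha"] / v["patch_ha"] if v["patch_ha"] > 0 else 0.0
                ),
                "stats": v["stats"],
            }
        return d

    def to_markdown(self) -> str:
        d = self.to_dict()
        lines = [
            "| quantity | ha | % of study area |",
            "|---|---|---|",
            (
                f"| current breeding habitat | {d['current_habitat']['ha']:.1f} | "
                f"{d['current_habitat']['pct_of_valid']:.1f} |"
            ),
            (
                f"| potential breeding habitat | {d['potential_habitat']['ha']:.1f} | "
                f"{d['potential_habitat']['pct_of_valid']:.1f} |"
            ),
        ]
        for g, v in d["groups"].items():
            lines.append(
                f"| {g} homogeneous patches | {v['patch_ha']:.1f} | {v['patch_pct_of_valid']:.1f} |"
            )
            lines.append(
                f"| {g} priority area | {v['priority_ha']:.1f} | "
                f"{100 * v['fraction_of_patch_area_in_potential']:.1f}% of its patch area |"
            )
        return "\n".join(lines)


def priority_areas(
    patch_sets: dict[str, PatchSet],
    potential: RasterGrid,
    current: RasterGrid,
) -> tuple[RasterGrid, dict[str, RasterGrid], PriorityReport]:
    """Intersect homogeneous shrub patches with potential habitat.

    Returns a combined priority grid (0 none, then 1, 2, ... per group in
    input order), per-group priority grids, and the area report.  Priority
    area per group is by construction <= its patch area and <= the potential
    habitat area.
    """
    if not potential.same_geometry(current):
        raise ValueError("potential and current grids must share geometry")
    pot = (potential.values > 0) & potential.valid
    cur = (current.values > 0) & current.valid
    cell_area = potential.cell_area_ha
    ny, nx = potential.shape
    combined = np.zeros((ny, nx))
    per_group: dict[str, RasterGrid] = {}
    report = PriorityReport(
        cell_area_ha=cell_area,
        study_area_ha_total=ny * nx * cell_area,
        study_area_ha_valid=float(potential.valid.sum()) * cell_area,
        current_ha=float(cur.sum()) * cell_area,
        potential_ha=float(pot.sum()) * cell_area,
    )
    for gi, (name, ps) in enumerate(patch_sets.items(), start=1):
        if not ps.labels.same_geometry(potential):
            raise ValueError(f"patch set {name!r} geometry mismatch")
        in_patch = ps.labels.values > 0
        prio = in_patch & pot
        combined[prio] = gi
        per_group[name] = potential.like(prio.astype(float), mask=potential.mask.copy())
        report.groups[name] = {
            "patch_ha": float(in_patch.sum()) * cell_area,
            "priority_ha": float(prio.sum()) * cell_area,
            "stats": patch_stats(ps),
        }
    grid = potential.like(combined, mask=potential.mask.copy())
    return grid, per_group, report
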