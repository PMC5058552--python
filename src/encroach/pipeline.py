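"""End-to-end orchestration: simulate -> vegetation model -> habitat model
-> restoration priorities, with every intermediate artifact written to disk
and a consolidated report.

A run is a pure function of its configuration (which embeds every seed):
re-running with the same config produces byte-identical report JSON.  Stages
write their outputs under ``<outdir>/<stage>/`` and drop a ``.done`` marker;
with ``resume=True`` completed stages are reloaded instead of recomputed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import maxent, restore, synth, vegclass
from .raster import RasterGrid, WindowSpec, read_raster, read_stack, write_raster, write_stack

__all__ = ["PipelineConfig", "run_all", "report", "PipelineError", "DataError", "NumericalError"]

log = logging.getLogger("encroach")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


class DataError(PipelineError):
    pass


class NumericalError(PipelineError):
    pass


@dataclass
class PipelineConfig:
    """All tunables of the framework, with the study defaults baked in.

    Window radius 100 m, 10,000 background points, at most 500 fitting
    iterations with a 1e-5 convergence threshold, Spearman screening at
    |rs| > 0.7, 3-fold vegetation CV, 5-fold habitat CV, strict >50% patch
    rule, and a 0.005 threshold search grid.
    """

    scene: synth.SceneConfig = field(default_factory=synth.SceneConfig)
    seed: int = 0
    veg_predictors: tuple = synth.VEG_PREDICTORS_DEFAULT
    rs_threshold: float = 0.7
    ridge: float = 1e-6
    k_veg: int = 3
    grid_step: float = 0.005
    sdm_variables: tuple = maxent.SDM_LAYER_CODES
    background_n: int = 10000
    k_sdm: int = 5
    max_iter: int = 500
    tol: float = 1e-5
    beta_multiplier: float = 1.0
    n_hinge_knots: int = 10
    jackknife: bool = True
    window_radius_m: float = 100.0
    patch_frac: float = 0.5
    raster_fmt: str = "%.8g"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["scene"] = self.scene.to_dict()
        d["veg_predictors"] = list(self.veg_predictors)
        d["sdm_variables"] = list(self.sdm_variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            d["scene"] = synth.SceneConfig.from_dict(d["scene"])
        if "veg_predictors" in d:
            d["veg_predictors"] = tuple(d["veg_predictors"])
        if "sdm_variables" in d:
            d["sdm_variables"] = tuple(d["sdm_variables"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def _stage_dir(outdir: Path, name: str, resume: bool) -> tuple[Path, bool]:
    d = outdir / name
    done = (d / ".done").exists()
    if done and not resume:
        done = False
    d.mkdir(parents=True, exist_ok=True)
    return d, done


def _mark_done(d: Path) -> None:
    (d / ".done").write_text("ok\n")


def run_all(config: PipelineConfig, outdir, resume: bool = False) -> Path:
    """Execute the whole framework and return the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_bg, seed_cv_veg, seed_cv_sdm, seed_perm = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    manifest = {
        "seed": config.seed,
        "stage_seeds": {
            "background": seed_bg,
            "veg_cv": seed_cv_veg,
            "sdm_cv": seed_cv_sdm,
            "permutation": seed_perm,
        },
    }
    _dump_json(manifest, outdir / "manifest.json")
    t0 = time.time()

    # -- stage 1: scene ---------------------------------------------------
    d_scene, done = _stage_dir(outdir, "scene", resume)
    if not done:
        log.info("stage scene: building synthetic landscape")
        scene = synth.build_scene(config.scene)
        write_stack(scene.stack, d_scene / "stack", fmt=config.raster_fmt)
        write_raster(scene.class_map, d_scene / "class_map.asc", fmt="%d")
        write_raster(scene.suitability, d_scene / "true_suitability.asc", fmt=config.raster_fmt)
        write_raster(
            scene.class_map.like(scene.irrelevant_mask.astype(float)),
            d_scene / "irrelevant_mask.asc",
            fmt="%d",
        )
        scene.plots.to_csv(d_scene / "plots.csv", index=False)
        scene.presences.to_csv(d_scene / "presences.csv", index=False)
        _dump_json(
            {
                "classes": list(synth.VEG_CLASSES),
                "response_optima": scene.truth["response_optima"],
                "planted": [
                    {
                        "veg_class": r["veg_class"],
                        "center_xy": list(r["center_xy"]),
                        "radius_m": r["radius_m"],
                        "n_cells": int(len(r["cells"])),
                    }
                    for r in scene.planted
                ],
            },
            d_scene / "truth.json",
        )
        _mark_done(d_scene)
    else:
        log.info("stage scene: reusing existing artifacts")
        scene = synth.build_scene(config.scene)  # cheap; guarantees in-memory truth

    # -- stage 2: vegetation model ---------------------------------------
    d_veg, done = _stage_dir(outdir, "veg", resume)
    if not done:
        log.info("stage veg: fitting multinomial vegetation model")
        plots = scene.plots
        X = vegclass.extract_predictors(
            scene.stack, plots["x"].to_numpy(), plots["y"].to_numpy(), list(config.veg_predictors)
        )
        y = plots["veg_class"].to_numpy()
        retained = vegclass.screen_collinear(X, y, rs_threshold=config.rs_threshold)
        try:
            full = vegclass.MultinomialVegetationClassifier(
                predictors=retained,
                ridge=config.ridge,
                required_classes=synth.VEG_CLASSES,
            ).fit(X, y)
        except ValueError as e:
            raise DataError(f"veg: {e}") from e
        model = vegclass.stepwise_backward_aic(full, X, y)
        ev = vegclass.evaluate_vegclass(
            model, X, y, k=config.k_veg, grid_step=config.grid_step, random_state=seed_cv_veg
        )
        probs, hard = vegclass.predict_vegetation(model, scene.stack, scene.irrelevant_mask)
        write_raster(hard, d_veg / "veg_hard_map.asc", fmt="%d")
        write_stack(probs, d_veg / "probabilities", fmt=config.raster_fmt)
        _dump_json(
            {
                "predictors_screened": retained,
                "predictors_final": model.predictors_,
                "reference_class": model.reference_class_,
                "classes": [str(c) for c in model.classes_],
                "coefficients": model.coef_frame().round(10).to_dict(),
                "aic_full": full.aic_,
                "aic_final": model.aic_,
                "log_likelihood": model.log_likelihood_,
            },
            d_veg / "model.json",
        )
        _dump_json(
            {
                "fit": ev["fit"].round(10).to_dict(),
                "cv_mean": ev["cv_mean"].round(10).to_dict(),
                "cv_sd": ev["cv_sd"].round(10).to_dict(),
                "k": ev["k"],
            },
            d_veg / "evaluation.json",
        )
        _mark_done(d_veg)
    hard = read_raster(d_veg / "veg_hard_map.asc")
    veg_model_info = json.loads((d_veg / "model.json").read_text())
    veg_classes = veg_model_info["classes"]

    # -- stage 3: habitat model ------------------------------------------
    d_sdm, done = _stage_dir(outdir, "sdm", resume)
    window = WindowSpec(config.window_radius_m)
    if not done:
        log.info("stage sdm: assembling predictors and fitting maxent model")
        pred_stack = maxent.assemble_sdm_predictors(scene.stack, hard, veg_classes, window)
        write_stack(pred_stack, d_sdm / "predictors", fmt=config.raster_fmt)
        bg, _ = maxent.background_table(
            pred_stack,
            n=config.background_n,
            random_state=seed_bg,
            variables=list(config.sdm_variables),
        )
        pres = maxent.presence_table(pred_stack, scene.presences, list(config.sdm_variables))
        if len(pres) < 5:
            raise DataError("sdm: fewer than 5 usable presences")
        params = {
            "max_iter": config.max_iter,
            "tol": config.tol,
            "beta_multiplier": config.beta_multiplier,
            "n_hinge_knots": config.n_hinge_knots,
        }
        variables = list(config.sdm_variables)
        if config.jackknife:
            variables, history = maxent.jackknife_select(
                pres,
                bg,
                variables,
                k=config.k_sdm,
                random_state=seed_cv_sdm,
                stationarity_tol=1e-6,
                **params,
            )
            history.to_csv(d_sdm / "jackknife.csv", index=False)
        cv = maxent.cv_auc(
            pres[variables], bg[variables], k=config.k_sdm, random_state=seed_cv_sdm, **params
        )
        model = maxent.fit_maxent(pres[variables], bg[variables], **params)
        if not model.converged_:
            log.warning("sdm: solver hit the iteration cap before stationarity")
        threshold = cv["threshold"]
        model.to_json(d_sdm / "model.json")
        curves_dir = d_sdm / "curves"
        curves_dir.mkdir(exist_ok=True)
        optima = {}
        for var in [v for v in restore.COUNTERFACTUAL_LAYERS if v in variables]:
            # point curve from the full-data model; band from the CV replicates
            curve = maxent.response_curve([model], var, pres[variables])
            band = maxent.response_curve(cv["fold_models"], var, pres[variables])
            curve["lo"], curve["hi"] = band["lo"], band["hi"]
            curve.to_csv(curves_dir / f"{var}.csv", index=False)
            optima[var] = maxent.curve_optimum(curve)
        importance = maxent.permutation_importance(
            model, pres[variables], bg[variables], random_state=seed_perm
        )
        _dump_json(
            {
                "variables": variables,
                "cv_auc_mean": cv["mean"],
                "cv_auc_sd": cv["sd"],
                "fold_aucs": cv["fold_aucs"],
                "threshold": threshold,
                "fold_thresholds": cv["fold_thresholds"],
                "fit_auc": model.score(
                    pd.concat([pres[variables], bg[variables]], ignore_index=True),
                    np.concatenate([np.ones(len(pres), int), np.zeros(len(bg), int)]),
                ),
                "response_optima": optima,
                "permutation_importance_pct": importance.round(10).to_dict(),
                "converged": model.converged_,
                "n_iter": model.n_iter_,
                "stationarity_gap_max": float(np.max(model.stationarity_gap_)),
            },
            d_sdm / "evaluation.json",
        )
        _mark_done(d_sdm)
    sdm_model = maxent.MaxentSDM.from_json(d_sdm / "model.json")
    sdm_eval = json.loads((d_sdm / "evaluation.json").read_text())
    pred_stack = read_stack(d_sdm / "predictors")
    threshold = sdm_eval["threshold"]

    # -- stage 4: restoration priorities ---------------------------------
    d_res, done = _stage_dir(outdir, "restore", resume)
    if not done:
        log.info("stage restore: counterfactual habitat and priority areas")
        current = maxent.predict_suitability(sdm_model, pred_stack, threshold=threshold)
        write_raster(current.suitability, d_res / "current_suitability.asc", fmt=config.raster_fmt)
        write_raster(current.binary, d_res / "current_binary.asc", fmt="%d")
        cf_stack, cf_means = restore.counterfactual_stack(pred_stack, scene.presences)
        potential = restore.potential_habitat(sdm_model, cf_stack, threshold)
        write_raster(potential, d_res / "potential_binary.asc", fmt="%d")
        code_of = {c: i for i, c in enumerate(veg_classes)}
        patch_sets = {
            "HEATHLAND": restore.detect_homogeneous_patches(
                hard,
                [code_of[c] for c in synth.HEATHLAND_CLASSES],
                "HEATHLAND",
                window,
                frac=config.patch_frac,
            ),
            "ALNUS": restore.detect_homogeneous_patches(
                hard, [code_of["ALNUS"]], "ALNUS", window, frac=config.patch_frac
            ),
        }
        prio, per_group, prio_report = restore.priority_areas(
            patch_sets, potential, current.binary
        )
        write_raster(prio, d_res / "priority.asc", fmt="%d")
        for name, ps in patch_sets.items():
            write_raster(ps.labels, d_res / f"patches_{name}.asc", fmt="%d")
            ps.table.to_csv(d_res / f"patches_{name}.csv", index=False)
        _dump_json(
            {"report": prio_report.to_dict(), "counterfactual_means": cf_means},
            d_res / "priority_report.json",
        )
        (d_res / "priority_report.md").write_text(prio_report.to_markdown() + "\n")
        _mark_done(d_res)

    report(outdir)
    log.info("run complete in %.1f s", time.time() - t0)
    return outdir


def report(run_dir) -> dict:
    """Consolidate stage artifacts into report.json / report.md.

    A pure function of the artifacts: regenerating the report from a
    completed run reproduces it exactly.
    """
    run_dir = Path(run_dir)
    for stage in ("veg", "sdm", "restore"):
        if not (run_dir / stage / ".done").exists():
            raise PipelineError(f"report: stage {stage!r} incomplete")
    veg_eval = json.loads((run_dir / "veg" / "evaluation.json").read_text())
    veg_model = json.loads((run_dir / "veg" / "model.json").read_text())
    sdm_eval = json.loads((run_dir / "sdm" / "evaluation.json").read_text())
    prio = json.loads((run_dir / "restore" / "priority_report.json").read_text())
    rep = {
        "vegetation": {
            "classes": veg_model["classes"],
            "predictors": veg_model["predictors_final"],
            "evaluation": veg_eval,
        },
        "habitat_model": sdm_eval,
        "priority": prio,
    }
    _dump_json(rep, run_dir / "report.json")

    lines = ["# Run report", "", "## Vegetation model (per class)", ""]
    fit = pd.DataFrame(veg_eval["fit"])
    cvm = pd.DataFrame(veg_eval["cv_mean"])
    cvs = pd.DataFrame(veg_eval["cv_sd"])
    lines.append("| class | Kappa max | threshold | AUC | sensitivity | CV AUC |")
    lines.append("|---|---|---|---|---|---|")
    for cls in fit.index:
        cv_txt = (
            f"{cvm.loc[cls, 'auc']:.3f} ± {cvs.loc[cls, 'auc']:.3f}"
            if cls in cvm.index
            else "—"
        )
        lines.append(
            f"| {cls} | {fit.loc[cls, 'kappa_max']:.3f} | {fit.loc[cls, 'threshold']:.3f} "
            f"| {fit.loc[cls, 'auc']:.3f} | {fit.loc[cls, 'sensitivity']:.3f} | {cv_txt} |"
        )
    lines += [
        "",
        "## Breeding habitat model",
        "",
        f"- fit AUC: {sdm_eval['fit_auc']:.3f}",
        f"- CV AUC: {sdm_eval['cv_auc_mean']:.3f} ± {sdm_eval['cv_auc_sd']:.3f}",
        f"- binary threshold (mean max sens+spec): {sdm_eval['threshold']:.3f}",
        "- response-curve optima: "
        + ", ".join(f"{k} {v:.2f}" for k, v in sorted(sdm_eval["response_optima"].items())),
        "",
        "## Priority areas",
        "",
    ]
    pr = restore.PriorityReport(
        cell_area_ha=0.0,
        study_area_ha_total=prio["report"]["study_area_ha_total"],
        study_area_ha_valid=prio["report"]["study_area_ha_valid"],
        current_ha=prio["report"]["current_habitat"]["ha"],
        potential_ha=prio["report"]["potential_habitat"]["ha"],
    )
    lines.append("| quantity | value |")
    lines.append("|---|---|")
    r = prio["report"]
    lines.append(
        f"| current habitat | {r['current_habitat']['ha']:.0f} ha "
        f"({r['current_habitat']['pct_of_valid']:.1f}%) |"
    )
    lines.append(
        f"| potential habitat | {r['potential_habitat']['ha']:.0f} ha "
        f"({r['potential_habitat']['pct_of_valid']:.1f}%) |"
    )
    for g, v in r["groups"].items():
        lines.append(
            f"| {g}: patch / priority | {v['patch_ha']:.0f} ha / {v['priority_ha']:.0f} ha "
            f"({100 * v['fraction_of_patch_area_in_potential']:.0f}% of patches in context) |"
        )
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")
    return rep
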