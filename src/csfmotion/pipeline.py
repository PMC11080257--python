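"""End-to-end orchestration: generate -> fit -> quantify -> report.

``run_pipeline`` executes the full analysis on a seeded synthetic cohort (or
on user-supplied volumes for the single-subject stages), writes every
artifact under the output directory, and returns a manifest with per-stage
checksums so a rerun with the same config and seed can be verified
bit-for-bit on its deterministic outputs.
"""
from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .asl import quantify_perfusion_map, roi_perfusion, surround_subtract
from .config import RunConfig, validate_config
from .dwi import (ablation_fit, estimate_noise_sigma, fit_decay_map, roi_summary,
                  trace_signal, trace_signal_arithmetic)
from .errors import CSFMotionError
from .io import (load_asl, load_dwi, load_masks, read_cohort_table, save_asl,
                 save_dwi, save_masks, save_volume, write_cohort_table)
from .masks import CHOROID_PLEXUS, SUPRASELLAR_CSF, TISSUE_CLASSES
from .stats import cohort_report, covariate_regression, voxelwise_group_map
from .synth import (CohortConfig, iter_cohort_subjects, make_phantom_masks,
                    simulate_cohort_table)


class StageError(CSFMotionError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    error: dict | None = None

    def to_dict(self) -> dict:
        return {"version": self.version, "config_hash": self.config_hash,
                "seed": self.seed, "stages": self.stages,
                "checksums": self.checksums, "warnings": self.warnings,
                "error": self.error}

    def save(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return path


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | RunConfig | None, out_dir: str) -> RunManifest:
    """Run every stage and write artifacts plus ``manifest.json`` to out_dir."""
    cfg = validate_config(config)
    os.makedirs(out_dir, exist_ok=True)
    cfg_yaml = cfg.to_yaml()
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        fh.write(cfg_yaml)
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        seed=cfg.seed,
    )
    state: dict = {}
    stages = [
        ("ingest_or_generate", _stage_generate),
        ("trace", _stage_trace),
        ("noise_sigma", _stage_noise),
        ("decay_fits", _stage_decay),
        ("ablation", _stage_ablation),
    ]
    if cfg.raw["asl"]["enabled"]:
        stages.append(("asl_quantification", _stage_asl))
    stages += [
        ("cohort_measurements", _stage_cohort),
        ("group_statistics", _stage_stats),
        ("voxelwise_map", _stage_voxelwise),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs = fn(cfg, state, out_dir) or {}
        except Exception as exc:
            manifest.error = {"stage": name, "type": type(exc).__name__,
                              "message": str(exc)}
            manifest.save(os.path.join(out_dir, "manifest.json"))
            raise StageError(name, exc) from exc
        elapsed = time.perf_counter() - t0
        for label, path in outputs.items():
            manifest.checksums[f"{name}/{label}"] = _sha256(path)
        manifest.stages.append({"stage": name, "seconds": round(elapsed, 3),
                                "outputs": sorted(outputs)})
        manifest.warnings.extend(state.pop("warnings", []))
    manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest


# ---------------------------------------------------------------------------
# stages (each returns {artifact_label: file_path})

def _stage_generate(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    """Representative-subject volumes: synthetic by default, files when given."""
    geom = cfg.geometry()
    inputs = cfg.raw["inputs"]
    cohort_cfg = cfg.cohort_config()
    state["cohort_cfg"] = cohort_cfg
    if inputs["masks"]:
        state["masks"] = load_masks(inputs["masks"])
    else:
        state["masks"] = make_phantom_masks(geom, seed=cfg.seed)
    if inputs["dwi"]:
        state["dwi"] = load_dwi(inputs["dwi"], inputs["bvals"], None)
        state["external_subject"] = True
    else:
        from .synth import default_tissue_params, simulate_dwi
        params = default_tissue_params(noise_sigma=cohort_cfg.noise_sigma,
                                       d_sd_voxel=cohort_cfg.d_sd_voxel)
        state["dwi"] = simulate_dwi(state["masks"], params,
                                    bvalues=cohort_cfg.bvalues,
                                    n_directions=cohort_cfg.n_directions,
                                    seed=cfg.seed)
    out = {"masks": save_masks(state["masks"], os.path.join(out_dir, "masks.nii"))}
    out.update({f"dwi_{k}": v for k, v in
                save_dwi(state["dwi"], out_dir, stem="subject_dwi").items()
                if k != "order_flag"})
    if cfg.raw["asl"]["enabled"]:
        if inputs["asl"]:
            state["asl"] = load_asl(inputs["asl"], inputs["m0"])
        else:
            from .synth import simulate_asl
            rep_f = cohort_cfg.perfusion_mean_sd["control"][0]
            f_map = np.where(state["masks"].region(CHOROID_PLEXUS), rep_f, 0.0)
            state["asl"] = simulate_asl(state["masks"], f_map, cfg.asl_params(),
                                        m0_blood=cohort_cfg.m0_blood,
                                        n_pairs=cohort_cfg.n_asl_pairs,
                                        noise_sigma=cohort_cfg.asl_noise_sigma,
                                        seed=cfg.seed + 1)
        saved = save_asl(state["asl"], out_dir, stem="subject_asl")
        out["asl_nii"] = saved["nii"]
        out["asl_m0"] = saved["m0"]
    return out


def _stage_trace(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    tracer = (trace_signal if cfg.raw["dwi"]["trace"] == "geometric"
              else trace_signal_arithmetic)
    state["trace"] = tracer(state["dwi"])
    return {f"trace_{k}": v for k, v in
            save_dwi(state["trace"], out_dir, stem="subject_trace").items()}


def _stage_noise(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    # estimate on a raw (not direction-averaged) highest-b magnitude image,
    # where cistern fluid signal is fully suppressed
    dwi = state["dwi"]
    b = dwi.bvalues
    highb = dwi.volumes[..., int(np.argmax(b))]
    est = estimate_noise_sigma(highb, state["masks"].region(SUPRASELLAR_CSF))
    state["noise"] = est
    path = os.path.join(out_dir, "noise_estimate.json")
    with open(path, "w") as fh:
        json.dump({"sigma": est.sigma, "floor": est.floor,
                   "n_voxels": est.n_voxels,
                   "highest_bvalue": float(b.max())}, fh, indent=2)
    return {"noise_estimate": path}


def _stage_decay(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    trace = state["trace"]
    mask = state["masks"].labels > 0
    out = {}
    state["decay_maps"] = {}
    for kind in ("noise_modeled", "standard"):
        dmap = fit_decay_map(trace, mask, model_kind=kind)
        state["decay_maps"][kind] = dmap
        geom = trace.geometry
        for arr, label in ((dmap.D, "D"), (dmap.S0, "S0"),
                           (dmap.Nfloor, "Nfloor"), (dmap.r2, "r2")):
            p = os.path.join(out_dir, f"map_{label}_{kind}.nii")
            save_volume(arr, geom, p)
            out[f"map_{label}_{kind}"] = p
        summ = roi_summary(dmap, state["masks"])
        p = os.path.join(out_dir, f"roi_summary_{kind}.csv")
        summ.to_csv(p, index=False)
        out[f"roi_summary_{kind}"] = p
        if dmap.n_skipped:
            state.setdefault("warnings", []).append(
                f"decay_fits[{kind}]: skipped {dmap.n_skipped} degenerate voxels")
    return out


def _stage_ablation(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    """Ablation table on the mean suprasellar trace curve."""
    trace = state["trace"]
    roi = state["masks"].region(SUPRASELLAR_CSF)
    curve = trace.volumes[roi].mean(axis=0)
    tab = ablation_fit(curve, trace.bvalues,
                       model_kinds=cfg.raw["dwi"]["model"])
    path = os.path.join(out_dir, "ablation.csv")
    tab.to_csv(path, index=False)
    return {"ablation": path}


def _stage_asl(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    res = surround_subtract(state["asl"])
    geom = state["asl"].geometry
    out = {"delta_m": save_volume(res.delta_m, geom,
                                  os.path.join(out_dir, "delta_m.nii"))}
    roi = state["masks"].region(CHOROID_PLEXUS)
    pmap = quantify_perfusion_map(res.delta_m, state["asl"].m0, cfg.asl_params(),
                                  brain_mask=roi,
                                  threshold=float(cfg.raw["asl"]["threshold"]),
                                  blood_water_factor=float(cfg.raw["asl"]["blood_water_factor"]))
    state["perfusion_map"] = pmap
    out["perfusion"] = save_volume(np.nan_to_num(pmap.f, nan=-1.0), geom,
                                   os.path.join(out_dir, "perfusion.nii"))
    mean, sd, n = roi_perfusion(pmap, roi)
    path = os.path.join(out_dir, "perfusion_roi.json")
    with open(path, "w") as fh:
        json.dump({"roi": CHOROID_PLEXUS, "mean": mean, "sd": sd, "n_voxels": n,
                   "n_clamped_negative": pmap.n_clamped_negative,
                   "n_out_of_range": pmap.n_out_of_range}, fh, indent=2)
    if pmap.n_clamped_negative:
        state.setdefault("warnings", []).append(
            f"asl: clamped {pmap.n_clamped_negative} negative delta-M voxels to f=0")
    return out


def _stage_cohort(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    """Per-subject measurements over the simulated cohort."""
    inputs = cfg.raw["inputs"]
    cohort_cfg: CohortConfig = state["cohort_cfg"]
    geom = cfg.geometry()
    asl_on = bool(cfg.raw["asl"]["enabled"])
    tracer = (trace_signal if cfg.raw["dwi"]["trace"] == "geometric"
              else trace_signal_arithmetic)
    if inputs["cohort"]:
        table = read_cohort_table(inputs["cohort"])
        state["cohort_table"] = table
        state["d_stack"] = None
        return {"cohort_table": write_cohort_table(
            table, os.path.join(out_dir, "cohort_table.csv"))}
    table = simulate_cohort_table(cohort_cfg)
    model = cfg.raw["dwi"]["model"]
    d_cols = {cls: [] for cls in TISSUE_CLASSES}
    perf_col = []
    d_stack = np.full((len(table),) + tuple(geom.shape), np.nan, dtype=np.float32)
    params = cfg.asl_params()
    for k, subj in enumerate(iter_cohort_subjects(cohort_cfg, geom, table=table)):
        trace = tracer(subj.dwi)
        mask = subj.masks.labels > 0
        dmap = fit_decay_map(trace, mask, model_kind=model)
        summ = roi_summary(dmap, subj.masks).set_index("roi")
        for cls in TISSUE_CLASSES:
            d_cols[cls].append(float(summ.loc[cls, "mean_D"]))
        d_stack[k][subj.masks.region(SUPRASELLAR_CSF)] = \
            dmap.D[subj.masks.region(SUPRASELLAR_CSF)]
        if asl_on:
            res = surround_subtract(subj.asl)
            roi = subj.masks.region(CHOROID_PLEXUS)
            pmap = quantify_perfusion_map(res.delta_m, subj.asl.m0, params,
                                          brain_mask=roi,
                                          threshold=float(cfg.raw["asl"]["threshold"]),
                                          blood_water_factor=float(cfg.raw["asl"]["blood_water_factor"]))
            mean, _, _ = roi_perfusion(pmap, roi)
            perf_col.append(mean)
    for cls in TISSUE_CLASSES:
        table[f"D_{cls}"] = d_cols[cls]
    if asl_on:
        table["perfusion"] = perf_col
    state["cohort_table"] = table
    state["d_stack"] = d_stack
    return {"cohort_table": write_cohort_table(
        table, os.path.join(out_dir, "cohort_table.csv"))}


def _stage_stats(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    table = state["cohort_table"]
    report, text = cohort_report(
        table, stratified_correlation=bool(cfg.raw["stats"]["stratified_correlation"]))
    out = {}
    p = os.path.join(out_dir, "cohort_report.csv")
    report.to_csv(p, index=False)
    out["cohort_report"] = p
    p = os.path.join(out_dir, "cohort_report.txt")
    with open(p, "w") as fh:
        fh.write(text + "\n")
    out["cohort_report_text"] = p
    d_col = f"D_{SUPRASELLAR_CSF}"
    if d_col in table:
        sub = table.dropna(subset=[d_col])
        reg = covariate_regression(sub[d_col], sub[["group", "age", "sex"]],
                                   combined=bool(cfg.raw["stats"]["combined_regression"]))
        p = os.path.join(out_dir, "regressions.csv")
        reg.to_csv(p, index=False)
        out["regressions"] = p
    return out


def _stage_voxelwise(cfg: RunConfig, state: dict, out_dir: str) -> dict:
    if state.get("d_stack") is None:
        return {}
    table = state["cohort_table"]
    template_roi = state["masks"].region(SUPRASELLAR_CSF)
    cmap = voxelwise_group_map(state["d_stack"], table["group"].to_numpy(),
                               template_roi,
                               alpha_fdr=float(cfg.raw["stats"]["alpha_fdr"]),
                               min_extent=int(cfg.raw["stats"]["min_extent"]))
    out = {"cluster_labels": save_volume(cmap.label_volume, cfg.geometry(),
                                         os.path.join(out_dir, "cluster_labels.nii"))}
    p = os.path.join(out_dir, "clusters.csv")
    pd.DataFrame(cmap.clusters).to_csv(p, index=False)
    out["clusters"] = p
    p = os.path.join(out_dir, "cluster_method.json")
    with open(p, "w") as fh:
        json.dump({"method": cmap.method, "alpha_fdr": cmap.alpha_fdr,
                   "min_extent": cmap.min_extent,
                   "n_clusters": cmap.n_clusters}, fh, indent=2)
    out["cluster_method"] = p
    return out
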