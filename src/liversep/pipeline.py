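"""Stage orchestration: simulate -> fit -> qsm -> learn-r -> separate -> stats.

Each stage reads its upstream artifacts from the output directory, writes
its products plus a JSON manifest (inputs, outputs, parameters, seed,
package version) and is skipped on rerun when its manifest and outputs
already exist, unless forced.
"""

from __future__ import annotations

import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__, decay, io, qsm, separation, signal_fitting, stats
from .config import PipelineConfig
from .phantom import CohortSpec, MaskSet, MetricCohort, make_cohort

STAGES = ("simulate", "fit", "qsm", "learn-r", "separate", "stats")


class MissingUpstreamError(RuntimeError):
    pass


def _manifest_path(cfg: PipelineConfig, stage: str) -> Path:
    return cfg.out_dir / "manifests" / f"{stage}.json"


def _write_manifest(cfg, stage, inputs, outputs, params):
    mp = _manifest_path(cfg, stage)
    mp.parent.mkdir(parents=True, exist_ok=True)
    doc = {"stage": stage, "inputs": sorted(map(str, inputs)),
           "outputs": sorted(map(str, outputs)), "parameters": params,
           "seed": cfg.seed, "version": __version__,
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    with open(mp, "w") as fh:
        json.dump(doc, fh, indent=2)
    return doc


def _done(cfg, stage) -> bool:
    mp = _manifest_path(cfg, stage)
    if not mp.exists():
        return False
    with open(mp) as fh:
        doc = json.load(fh)
    return all(Path(o).exists() for o in doc.get("outputs", []))


def _require(path, stage, needed_by):
    if not Path(path).exists():
        raise MissingUpstreamError(
            f"stage {needed_by!r} needs {path} (run {stage!r} first)")
    return Path(path)


def _cohort_table(cfg) -> pd.DataFrame:
    path = _require(cfg.out_dir / "cohort" / "cohort.csv", "simulate", "fit")
    return pd.read_csv(path)


def run_stage(stage: str, cfg: PipelineConfig, force: bool = False) -> dict:
    """Execute one pipeline stage; returns its manifest (or the cached one)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if not force and _done(cfg, stage):
        with open(_manifest_path(cfg, stage)) as fh:
            return json.load(fh)
    fn = {"simulate": _stage_simulate, "fit": _stage_fit, "qsm": _stage_qsm,
          "learn-r": _stage_learn_r, "separate": _stage_separate,
          "stats": _stage_stats}[stage]
    return fn(cfg)


def run_all(cfg: PipelineConfig, force: bool = False) -> list[dict]:
    return [run_stage(s, cfg, force=force) for s in STAGES]


def _stage_simulate(cfg):
    out = cfg.out_dir / "cohort"
    spec = replace(cfg.cohort, seed=cfg.seed)
    table = make_cohort(spec, cfg.acq, out, grid_shape=cfg.grid_shape)
    outputs = [out / "cohort.csv"] + list(table["path"])
    return _write_manifest(cfg, "simulate", [], outputs,
                           {"grid_shape": list(cfg.grid_shape),
                            "counts": list(spec.counts)})


def _sample_dir(cfg, sid) -> Path:
    d = cfg.out_dir / "samples" / sid
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stage_fit(cfg):
    table = _cohort_table(cfg)
    inputs, outputs = [cfg.out_dir / "cohort" / "cohort.csv"], []
    for _, row in table.iterrows():
        series = io.read_echo_series(_require(row["path"], "simulate", "fit"))
        inputs.append(row["path"])
        d = _sample_dir(cfg, row["sample_id"])
        r2s = signal_fitting.arlo_r2star(series)
        f0 = signal_fitting.initial_field(series)
        # PDFF path co-estimates decay inside the fit: the fixed ARLO
        # R2* carries fat-beating bias that skews W/F allocation
        fw = signal_fitting.ideal_fit(series, f0, r2s, co_estimate_r2s=True)
        mask = signal_fitting.liver_mask(r2s, threshold=cfg.mask_threshold,
                                         erosion_radius=cfg.erosion_radius)
        mag0 = series.magnitude[..., 0]
        signal = mag0 > 0.2 * np.median(mag0[mag0 > 0.05 * mag0.max()])
        balloon = _balloon_mask(signal, r2s, mask, cfg.balloon_r2s_max)
        vs = cfg.acq.voxel_size
        for name, vol in [("r2s", r2s), ("field", fw.field),
                          ("water", fw.water), ("fat", fw.fat),
                          ("pdff", fw.pdff), ("mask", mask.astype(np.uint8)),
                          ("balloon", balloon.astype(np.uint8)),
                          ("signal", signal.astype(np.uint8)),
                          ("magnitude", mag0)]:
            outputs.append(io.write_volume(vol, d / f"{name}.nii.gz", vs))
    return _write_manifest(cfg, "fit", inputs, outputs,
                           {"mask_threshold": cfg.mask_threshold,
                            "erosion_radius": cfg.erosion_radius})


def _balloon_mask(signal, r2s, liver, r2s_max):
    """Programmatic stand-in for manual balloon delineation: the largest
    low-R2* high-signal component outside the specimen."""
    cand = signal & (r2s < r2s_max) & ~liver
    cand = ndimage.binary_erosion(cand)
    labels, nlab = ndimage.label(cand)
    if nlab == 0:
        raise RuntimeError("no water-balloon candidate region found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _load_sample(cfg, sid, names):
    d = cfg.out_dir / "samples" / sid
    return [io.read_volume(_require(d / f"{n}.nii.gz", "fit", "qsm"))
            for n in names]


def _stage_qsm(cfg):
    table = _cohort_table(cfg)
    inputs, outputs = [], []
    kernel = None
    for sid in table["sample_id"]:
        field, mag, signal, balloon = _load_sample(
            cfg, sid, ["field", "magnitude", "signal", "balloon"])
        signal = signal.astype(bool)
        if kernel is None or kernel.grid_shape != field.shape:
            kernel = qsm.dipole_kernel(field.shape, cfg.acq.voxel_size,
                                       cfg.acq.b0_direction)
        local = qsm.pdf_background_removal(field, signal, kernel, weight=mag)
        chi, diag = qsm.medi_inversion(local, mag, signal, kernel,
                                       cfg.acq.larmor_hz,
                                       lambda_tv=cfg.medi_lambda)
        chi = qsm.reference_to_balloon(chi, balloon.astype(bool))
        d = cfg.out_dir / "samples" / sid
        outputs.append(io.write_volume(local, d / "local_field.nii.gz",
                                       cfg.acq.voxel_size))
        outputs.append(io.write_volume(chi, d / "qsm.nii.gz", cfg.acq.voxel_size))
        with open(d / "qsm_diagnostics.json", "w") as fh:
            json.dump(diag, fh)
        inputs.append(d / "field.nii.gz")
    return _write_manifest(cfg, "qsm", inputs, outputs,
                           {"medi_lambda": cfg.medi_lambda})


def _metric_cohort_from_outputs(cfg, table) -> MetricCohort:
    voxels, rows = {}, []
    for _, row in table.iterrows():
        sid = row["sample_id"]
        d = cfg.out_dir / "samples" / sid
        r2s = io.read_volume(_require(d / "r2s.nii.gz", "fit", "learn-r"))
        chi = io.read_volume(_require(d / "qsm.nii.gz", "qsm", "learn-r"))
        pdff = io.read_volume(d / "pdff.nii.gz")
        mask = io.read_volume(d / "mask.nii.gz").astype(bool)
        voxels[sid] = (r2s[mask], chi[mask])
        rows.append({"sample_id": sid,
                     "fibrosis_stage": int(row["fibrosis_stage"]),
                     "iron_grade": str(row["iron_grade"]),
                     "steatosis_grade": str(row["steatosis_grade"]),
                     "mean_chi": float(chi[mask].mean()),
                     "mean_r2s": float(r2s[mask].mean()),
                     "mean_pdff": float(pdff[mask].mean())})
    return MetricCohort(table=pd.DataFrame(rows), voxels=voxels)


def _stage_learn_r(cfg):
    table = _cohort_table(cfg)
    cohort = _metric_cohort_from_outputs(cfg, table)
    res = decay.loocv_r(cohort, cfg.grid_lo, cfg.grid_hi, cfg.grid_step)
    d = cfg.out_dir / "decay"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"r": res.grid, "loss": res.loss_curve}).to_csv(
        d / "loss_curve.csv", index=False)
    res.fold_r.rename("r_fold").rename_axis("sample_id").to_csv(d / "folds.csv")
    with open(d / "summary.json", "w") as fh:
        json.dump({"r_opt_full": res.r_opt, **res.summary, "tie": res.tie}, fh,
                  indent=2)
    outputs = [d / "loss_curve.csv", d / "folds.csv", d / "summary.json"]
    return _write_manifest(cfg, "learn-r", [cfg.out_dir / "cohort" / "cohort.csv"],
                           outputs, {"grid": [cfg.grid_lo, cfg.grid_hi,
                                              cfg.grid_step]})


def _stage_separate(cfg):
    table = _cohort_table(cfg)
    folds = pd.read_csv(_require(cfg.out_dir / "decay" / "folds.csv",
                                 "learn-r", "separate"), index_col=0)["r_fold"]
    kernel = None
    rows, outputs = [], []
    for _, row in table.iterrows():
        sid = row["sample_id"]
        d = cfg.out_dir / "samples" / sid
        local = io.read_volume(_require(d / "local_field.nii.gz", "qsm",
                                        "separate"))
        r2s, mag, pdff = _load_sample(cfg, sid, ["r2s", "magnitude", "pdff"])
        mask = io.read_volume(d / "mask.nii.gz").astype(bool)
        balloon = io.read_volume(d / "balloon.nii.gz").astype(bool)
        chi = io.read_volume(d / "qsm.nii.gz")
        masks = MaskSet(liver_mask=mask, balloon_mask=balloon)
        if kernel is None or kernel.grid_shape != local.shape:
            kernel = qsm.dipole_kernel(local.shape, cfg.acq.voxel_size,
                                       cfg.acq.b0_direction)
        r_fold = float(folds.loc[sid])
        res_opt = decay.final_maps(local, r2s, mag, masks, kernel,
                                   cfg.acq.larmor_hz, r_fold,
                                   cfg=cfg.separation, pdff=pdff)
        res_def = decay.final_maps(local, r2s, mag, masks, kernel,
                                   cfg.acq.larmor_hz, decay.DEFAULT_R_BRAIN,
                                   cfg=cfg.separation, pdff=pdff)
        vs = cfg.acq.voxel_size
        outputs.append(io.write_volume(res_opt.chi_plus, d / "chi_pos.nii.gz", vs))
        outputs.append(io.write_volume(res_opt.chi_minus, d / "chi_neg.nii.gz", vs))
        rows.append({"sample_id": sid,
                     "fibrosis_stage": int(row["fibrosis_stage"]),
                     "iron_grade": str(row["iron_grade"]),
                     "steatosis_grade": str(row["steatosis_grade"]),
                     "r_applied": r_fold,
                     "chi_neg_abs_opt": res_opt.mean_chi_neg_abs,
                     "chi_pos_opt": res_opt.mean_chi_pos,
                     "chi_neg_abs_def": res_def.mean_chi_neg_abs,
                     "chi_pos_def": res_def.mean_chi_pos,
                     "chi": float(chi[mask].mean()),
                     "r2s": float(r2s[mask].mean()),
                     "pdff": 100.0 * float(pdff[mask].mean())})
    metrics = pd.DataFrame(rows)
    mpath = cfg.out_dir / "metrics.csv"
    metrics.to_csv(mpath, index=False)
    outputs.append(mpath)
    return _write_manifest(cfg, "separate", [cfg.out_dir / "decay" / "folds.csv"],
                           outputs, {"lambda1": cfg.separation.lambda1,
                                     "lambda2": cfg.separation.lambda2})


def _stage_stats(cfg):
    mpath = _require(cfg.out_dir / "metrics.csv", "separate", "stats")
    metrics = pd.read_csv(mpath)
    report = stats.staging_report(metrics, method=cfg.stats_method)
    outputs = []
    for name, frame in report.items():
        path = cfg.out_dir / ("report.csv" if name == "roc"
                              else f"{name}.csv")
        frame.to_csv(path, index=False)
        outputs.append(path)
    return _write_manifest(cfg, "stats", [mpath], outputs,
                           {"method": cfg.stats_method})
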