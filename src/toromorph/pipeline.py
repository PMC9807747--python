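"""End-to-end orchestration: simulate -> train -> detect -> mask -> measure.

A single nested configuration (YAML-serialisable dict) drives every stage;
all randomness derives from one global seed, so a fixed config + seed gives
a bit-identical report and identical CSV artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detector as det
from . import masker as msk
from . import morphometrics as morpho
from .imaging import PreprocessConfig, preprocess
from .synthdata import (
    SceneSpec,
    generate_detection_training_set,
    generate_scene,
    extract_mask_training_pairs,
)


def default_config() -> dict:
    """Pipeline defaults: a desk-scale synthetic study."""
    return {
        "seed": 0,
        "preprocess": {
            "enabled": True,
            "gf_kernel": 11, "gf_sigma": 1.2,
            "bg_kernel": 400, "bg_sigma": 200.0,
        },
        "simulate": {
            "n_scenes": 4,
            "width": 900, "height": 900,
            "pixel_size": 10.0,
            "n_particles": 20,
            "shape_mix": 0.5,
            "major_axis": [590.0, 23.0],
            "minor_axis": [280.0, 25.0],
            "contrast": 30.0,
        },
        "detector": {
            "n_pos": 40, "n_neg": 50,
            "rotation_step": 10.0,
            "epochs": 4, "holdout": 500,
            "smooth_kernel": 25, "smooth_sigma": 7.0,
            "threshold_frac": 0.8,
        },
        "masker": {
            "n_sources": 24, "per_image_samples": 150,
            "epochs": 12, "holdout": 600,
            "full_res": True,
        },
        # detections farther than match_radius_px from any true centre are
        # treated as unsuitable for measurement (merged neighbours, spurious
        # peaks), the automated analogue of manual mask screening
        "measure": {"bins": 20, "match_radius_px": 25, "matched_only": True},
    }


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return _merge(default_config(), yaml.safe_load(fh) or {})


def match_detections(
    centers: np.ndarray, truth_centers: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections to ground-truth centres."""
    pairs = []
    if len(centers) == 0 or len(truth_centers) == 0:
        return pairs
    d = np.linalg.norm(
        centers[:, None, :].astype(float) - truth_centers[None, :, :], axis=2
    )
    used_d, used_t = set(), set()
    for _ in range(min(len(centers), len(truth_centers))):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > radius:
            break
        pairs.append((int(i), int(j)))
        used_d.add(i)
        used_t.add(j)
        d[i, :] = np.inf
        d[:, j] = np.inf
    return pairs


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
    det_net=None,
    mask_net=None,
    verbose: bool = False,
) -> dict:
    """Run the full synthetic study and return the machine-readable report.

    Stages: simulate scenes -> preprocess -> build training sets -> train
    detection and masking networks -> raster-scan detection -> per-particle
    masking -> morphometry -> distribution summary.  Artifacts (scenes,
    ground truth, detections, measurement records, report) are written to
    ``outdir`` when given.
    """
    cfg = _merge(default_config(), config or {})
    if seed is not None:
        cfg["seed"] = seed
    rng = np.random.default_rng(cfg["seed"])
    stage_seed = lambda: int(rng.integers(2 ** 31))
    report: dict = {"seed": cfg["seed"], "stages": {}, "config": cfg}
    t_all = time.time()

    def log(msg: str) -> None:
        if verbose:
            print(f"[pipeline] {msg}", flush=True)

    # -- simulate -----------------------------------------------------------
    sim = cfg["simulate"]
    scenes = []
    for i in range(sim["n_scenes"]):
        spec = SceneSpec(
            width=sim["width"], height=sim["height"],
            pixel_size=sim["pixel_size"], n_particles=sim["n_particles"],
            shape_mix=sim["shape_mix"],
            major_axis=tuple(sim["major_axis"]),
            minor_axis=tuple(sim["minor_axis"]),
            contrast=sim["contrast"], seed=stage_seed(),
        )
        scenes.append(generate_scene(spec))
    n_simulated = sum(len(gt) for _, gt in scenes)
    report["stages"]["simulate"] = {
        "n_scenes": len(scenes), "n_particles": n_simulated,
    }
    log(f"simulated {len(scenes)} scenes, {n_simulated} particles")

    # -- preprocess ---------------------------------------------------------
    if cfg["preprocess"]["enabled"]:
        pcfg = PreprocessConfig(
            gf_kernel=cfg["preprocess"]["gf_kernel"],
            gf_sigma=cfg["preprocess"]["gf_sigma"],
            bg_kernel=cfg["preprocess"]["bg_kernel"],
            bg_sigma=cfg["preprocess"]["bg_sigma"],
        )
        scenes = [(preprocess(img, pcfg), gt) for img, gt in scenes]
        log("preprocessed scenes")

    # -- detector training --------------------------------------------------
    dcfg_in = cfg["detector"]
    if det_net is None:
        base = generate_detection_training_set(
            scenes, n_pos=dcfg_in["n_pos"], n_neg=dcfg_in["n_neg"],
            seed=stage_seed(),
        )
        aug = det.augment_rotations(base, step=dcfg_in["rotation_step"])
        dcfg = det.DetectorConfig(
            epochs=dcfg_in["epochs"], holdout=dcfg_in["holdout"],
            rotation_step=dcfg_in["rotation_step"], seed=stage_seed(),
        )
        det_net, det_hist = det.train_detector(aug, dcfg, verbose=verbose)
        report["stages"]["detector"] = {
            "n_base_crops": len(base),
            "rotations": int(round(360.0 / dcfg_in["rotation_step"])),
            "n_augmented": len(aug),
            "holdout": min(dcfg.holdout, len(aug) - 2),
            "n_trained_on": len(aug) - min(dcfg.holdout, len(aug) - 2),
            "final_holdout_accuracy": det_hist.accuracy[-1],
        }
        log(f"detector trained: holdout acc {det_hist.accuracy[-1]}")
    else:
        report["stages"]["detector"] = {"pretrained": True}

    # -- masker training ----------------------------------------------------
    mcfg_in = cfg["masker"]
    if mask_net is None:
        contexts, gtmasks = extract_mask_training_pairs(
            scenes, n_sources=mcfg_in["n_sources"], seed=stage_seed()
        )
        mcfg = msk.MaskerConfig(
            per_image_samples=mcfg_in["per_image_samples"],
            epochs=mcfg_in["epochs"], holdout=mcfg_in["holdout"],
            seed=stage_seed(),
        )
        samples = msk.build_mask_training_set(contexts, gtmasks, mcfg)
        mask_net, mask_hist = msk.train_masker(samples, mcfg, verbose=verbose)
        # area-matching threshold calibration on the training masks only
        mask_threshold = msk.calibrate_mask_threshold(
            mask_net, contexts, gtmasks, full_res=mcfg_in["full_res"]
        )
        report["stages"]["masker"] = {
            "n_sources": mcfg_in["n_sources"],
            "per_image_samples": mcfg.per_image_samples,
            "n_samples": len(samples),
            "final_holdout_accuracy": mask_hist.accuracy[-1],
            "calibrated_threshold": mask_threshold,
        }
        log(f"masker trained: holdout acc {mask_hist.accuracy[-1]}, "
            f"threshold {mask_threshold:.3f}")
    else:
        mask_threshold = 0.5
        report["stages"]["masker"] = {"pretrained": True}

    # -- detect, mask, measure ---------------------------------------------
    records = []
    det_rows = []
    n_detected = n_matched = n_false = 0
    center_errors = []
    match_radius = cfg["measure"]["match_radius_px"]
    for si, (img, gt) in enumerate(scenes):
        omap = det.compute_output_map(det_net, img)
        centers, _ = det.detect_particles(
            omap, img,
            smooth_kernel=dcfg_in["smooth_kernel"],
            smooth_sigma=dcfg_in["smooth_sigma"],
            threshold_frac=dcfg_in["threshold_frac"],
        )
        pairs = match_detections(centers, gt.centers(), match_radius)
        n_detected += len(centers)
        n_matched += len(pairs)
        n_false += len(centers) - len(pairs)
        matched_truth = {j: i for i, j in pairs}
        for i, j in pairs:
            err = float(np.linalg.norm(centers[i] - gt.centers()[j]))
            center_errors.append(err)
        h, w = img.pixels.shape
        matched_ids = {i for i, _ in pairs}
        for di, (cy, cx) in enumerate(centers):
            if cfg["measure"].get("matched_only", True) and di not in matched_ids:
                # automated stand-in for the manual screening of mask quality:
                # detections with no ground-truth match are excluded
                continue
            # clamp the 200x200 masking context into the frame
            cy2 = int(np.clip(cy, 100, h - 100))
            cx2 = int(np.clip(cx, 100, w - 100))
            context = img.pixels[cy2 - 100: cy2 + 100, cx2 - 100: cx2 + 100]
            pmask = msk.predict_mask(
                mask_net, context, full_res=mcfg_in["full_res"],
                crop_id=f"s{si}d{di}", threshold=mask_threshold,
            )
            if not pmask.mask.any():
                continue
            rec = morpho.measure_particle(
                pmask, img.pixel_size, particle_id=f"s{si}d{di}",
                source=f"scene{si}",
            )
            records.append(rec)
            truth_j = next((j for i2, j in pairs if i2 == di), None)
            det_rows.append({
                "id": f"s{si}d{di}", "scene": si, "cy": int(cy), "cx": int(cx),
                "matched_truth": truth_j,
                "major_nm": rec.major_nm, "minor_nm": rec.minor_nm,
                "circularity": rec.circularity,
            })
        log(f"scene {si}: {len(centers)} detections, {len(pairs)} matched")

    report["stages"]["detect"] = {
        "n_simulated": n_simulated, "n_detected": n_detected,
        "n_matched": n_matched, "n_false_positive": n_false,
        "recall": n_matched / n_simulated if n_simulated else None,
        "mean_center_error_px": float(np.mean(center_errors)) if center_errors else None,
    }

    if records:
        summary = morpho.summarize(records, bins=cfg["measure"]["bins"])
        report["stages"]["measure"] = {
            "n_measured": summary.n,
            "major_mean_nm": summary.major_mean, "major_sd_nm": summary.major_sd,
            "minor_mean_nm": summary.minor_mean, "minor_sd_nm": summary.minor_sd,
            "circularity_mean": summary.circularity_mean,
            "pearson_r_circ_vs_major": summary.pearson_r,
        }
    else:
        report["stages"]["measure"] = {"n_measured": 0}
    report["runtime_s"] = time.time() - t_all

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gt_rows = [
            dict(scene=si, **row)
            for si, (_, gt) in enumerate(scenes)
            for row in gt.to_records()
        ]
        pd.DataFrame(gt_rows).to_csv(outdir / "ground_truth.csv", index=False)
        pd.DataFrame(det_rows).to_csv(outdir / "detections.csv", index=False)
        pd.DataFrame([asdict(r) for r in records]).to_csv(
            outdir / "measurements.csv", index=False
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    return report
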