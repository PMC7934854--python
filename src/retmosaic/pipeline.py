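"""Seeded end-to-end pipeline driver.

``run_pipeline`` executes the full contralateral-eye analysis: simulate (or
load) paired treated/control flat mounts, count cones in each, quantify
craters and the central-third ratio, and run the paired statistics across
eye pairs.  Every output file is written under the output directory and
hashed into a manifest, so a run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import copy
import datetime
import json
from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np

from . import io as rio
from .detection import DetectionParams, count_cones
from .errors import ValidationError
from .mosaic import central_ratio, detect_craters
from .stats import paired_t
from .synthetic import FlatMountSpec, generate_flatmount, sample_craters

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_pairs": 6,
    "flatmount": {
        # shared geometry of every simulated eye; see FlatMountSpec for units
        "image_height_px": 512,
        "image_width_px": 512,
        "retina_radius_px": 240.0,
        "n_cones": 700,
    },
    "control_craters": {"n": 2, "area_fraction": 0.10},
    "treated_craters": {"n": 1, "area_fraction": 0.01},
    "detection": {},
    "crater": {"coverage_radius_px": None, "min_crater_area_px": None},
    "central_definition": "area_third",
    "eyes": None,  # optional: list of {"treated": {...}, "control": {...}} file refs
}

_FM_FIELDS = {f.name for f in dc_fields(FlatMountSpec)}
_DET_FIELDS = {f.name for f in dc_fields(DetectionParams)}


def load_config(path) -> dict:
    cfg = json.loads(Path(path).read_text())
    return merge_config(cfg)


def merge_config(cfg: dict) -> dict:
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def validate_config(cfg: dict) -> None:
    """Fail fast, before any compute, on malformed configs."""
    unknown = set(cfg.get("flatmount", {})) - _FM_FIELDS
    if unknown:
        raise ValidationError(f"unknown flatmount parameters: {sorted(unknown)}")
    unknown = set(cfg.get("detection", {})) - _DET_FIELDS
    if unknown:
        raise ValidationError(f"unknown detection parameters: {sorted(unknown)}")
    if cfg.get("eyes"):
        for pair in cfg["eyes"]:
            for side in ("treated", "control"):
                ref = pair.get(side, {})
                for key in ("image", "mask"):
                    p = ref.get(key)
                    if p is not None and not Path(p).exists():
                        raise ValidationError(f"missing {side} {key} file: {p}")
    elif int(cfg.get("n_pairs", 0)) < 2:
        raise ValidationError("need n_pairs >= 2 for paired statistics")
    if cfg.get("central_definition") not in ("area_third", "radius_third"):
        raise ValidationError("central_definition must be 'area_third' or 'radius_third'")


def _simulate_eye(cfg: dict, crater_cfg: dict, seed: int) -> "FlatMountSpec":
    base = {k: v for k, v in cfg["flatmount"].items() if k in _FM_FIELDS}
    spec = FlatMountSpec(**base, seed=seed)
    if crater_cfg and crater_cfg.get("n", 0) > 0:
        craters = sample_craters(
            spec,
            n_craters=int(crater_cfg["n"]),
            area_fraction=float(crater_cfg["area_fraction"]),
            seed=seed,
        )
        spec = FlatMountSpec(**base, craters=craters, seed=seed)
    return spec


def _analyse_eye(image, retina_mask, onh, cfg: dict, out: Path, tag: str, outputs: dict) -> dict:
    det = DetectionParams(**{k: v for k, v in cfg["detection"].items() if k in _DET_FIELDS})
    cone_set = count_cones(image, retina_mask, det)
    report = detect_craters(
        cone_set,
        retina_mask,
        coverage_radius_px=cfg["crater"].get("coverage_radius_px"),
        min_crater_area_px=cfg["crater"].get("min_crater_area_px"),
        cone_area_px=cone_set.cone_area_estimate_px,
    )
    ratio = central_ratio(cone_set, onh, retina_mask, cfg["central_definition"])

    calls_path = out / f"{tag}_cone_calls.csv"
    rio.write_cone_calls(calls_path, cone_set)
    summary_path = out / f"{tag}_summary.json"
    rio.write_json(
        summary_path,
        {
            "cones": cone_set.summary(),
            "craters": report.to_dict(),
            "central_ratio": ratio.to_dict(),
        },
    )
    crater_png = out / f"{tag}_crater_labels.png"
    rio.write_mask(crater_png, report.labels > 0)
    for p in (calls_path, summary_path, crater_png):
        outputs[p.name] = rio.sha256_file(p)
    return {
        "tag": tag,
        "n_cones": cone_set.n_cones,
        "n_craters": report.n_craters,
        "crater_percent": report.percent_of_retina,
        "central_ratio": ratio.ratio,
    }


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the paired-eye pipeline and return (and write) the manifest."""
    cfg = merge_config(config)
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    per_eye: list[dict] = []

    ss = np.random.SeedSequence(int(cfg["seed"]))
    if cfg.get("eyes"):
        pairs = []
        for i, pair in enumerate(cfg["eyes"]):
            loaded = {}
            for side in ("treated", "control"):
                ref = pair[side]
                image = rio.read_image(ref["image"])
                mask = (
                    rio.read_mask(ref["mask"])
                    if ref.get("mask")
                    else np.ones(image.shape, dtype=bool)
                )
                onh = tuple(ref.get("onh", ((image.shape[0] - 1) / 2, (image.shape[1] - 1) / 2)))
                loaded[side] = (image, mask, onh)
            pairs.append((i, loaded))
    else:
        pairs = []
        for i, child in enumerate(ss.spawn(int(cfg["n_pairs"]))):
            eye_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)]
            loaded = {}
            for side, seed in zip(("treated", "control"), eye_seeds):
                crater_cfg = cfg[f"{side}_craters"]
                spec = _simulate_eye(cfg, crater_cfg, seed)
                truth = generate_flatmount(spec)
                img_path = out / f"pair{i:02d}_{side}.tif"
                rio.write_image_u16(img_path, truth.image)
                mask_path = out / f"pair{i:02d}_{side}_retina.png"
                rio.write_mask(mask_path, truth.retina_mask)
                truth_path = out / f"pair{i:02d}_{side}_truth.csv"
                truth.truth_dataframe().to_csv(truth_path, index=False)
                for p in (img_path, mask_path, truth_path):
                    outputs[p.name] = rio.sha256_file(p)
                loaded[side] = (truth.image, truth.retina_mask, truth.onh_center)
            pairs.append((i, loaded))

    for i, loaded in pairs:
        for side in ("treated", "control"):
            image, mask, onh = loaded[side]
            per_eye.append(_analyse_eye(image, mask, onh, cfg, out, f"pair{i:02d}_{side}", outputs))

    def paired(metric: str):
        tr = [e[metric] for e in per_eye if e["tag"].endswith("treated")]
        co = [e[metric] for e in per_eye if e["tag"].endswith("control")]
        res = paired_t(np.asarray(tr, dtype=float), np.asarray(co, dtype=float))
        return {
            "t": res.t,
            "df": res.df,
            "p_two_tailed": res.p,
            "n_pairs": res.n,
            "mean_difference_treated_minus_control": res.mean_diff,
        }

    stats = {
        "crater_percent": paired("crater_percent"),
        "n_craters": paired("n_craters"),
        "central_ratio": paired("central_ratio"),
    }

    manifest = {
        "config": cfg,
        "seed": int(cfg["seed"]),
        "per_eye": per_eye,
        "stats": stats,
        "outputs": outputs,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    rio.write_json(out / "manifest.json", manifest)
    return manifest
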