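"""Stage implementations behind the ``snap`` command-line interface.

Stages run in dependency order (simulate -> select / anchors ->
train-detector / train-segmenter -> detect / segment -> quantify ->
evaluate); each writes its artifact plus a JSON run-manifest recording
inputs, the effective configuration hash, the stage seed and library
versions.  Re-running a stage with the same configuration and seed
reproduces counts and selections exactly; model training is reproducible
up to floating-point reduction order, which the manifest declares.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io_formats, metrics, selection, spatial, synthetic
from . import anchors as anchors_mod
from . import detector as det_mod
from . import segmenter as seg_mod
from .config import PipelineConfig
from .types import AnnotatedImage, BoundingBox, Detection

log = logging.getLogger(__name__)

STAGES = ["simulate", "select", "anchors", "train-detector", "train-segmenter",
          "detect", "segment", "quantify", "evaluate"]


def _write_manifest(cfg: PipelineConfig, stage: str, inputs: list[str],
                    outputs: list[str]) -> None:
    mdir = cfg.out_dir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    doc = {
        "stage": stage,
        "inputs": inputs,
        "outputs": outputs,
        "config_hash": cfg.config_hash(),
        "seed": cfg.stage_seed(stage),
        "versions": {
            "snap": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "training_bitwise_reproducible": stage not in ("train-detector",
                                                       "train-segmenter"),
    }
    (mdir / f"{stage.replace('-', '_')}.json").write_text(json.dumps(doc, indent=1))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first")
    return path


def _load_dataset(cfg: PipelineConfig, with_masks: bool = True) -> list[AnnotatedImage]:
    data = cfg.out_dir / "data"
    ann = io_formats.read_vgg_annotations(_require(data / "annotations.json", "simulate"))
    images = []
    for img_path in sorted((data / "images").glob("*.png")):
        image_id = img_path.stem
        mask_path = data / "masks" / f"{image_id}.png"
        images.append(AnnotatedImage(
            image_id=image_id,
            pixels=io_formats.load_image(img_path),
            boxes=ann.get(image_id, []),
            taproot_mask=io_formats.read_mask(mask_path)
            if with_masks and mask_path.exists() else None,
        ))
    return images


def _scene_params(cfg: PipelineConfig) -> synthetic.SceneParams:
    s = cfg["synthetic"]
    return synthetic.SceneParams.for_canvas(
        s["height"], s["width"],
        nodule_count_mean=s["nodule_count_mean"],
        nodule_count_dispersion=s["nodule_count_dispersion"],
        taproot_zone_fraction=s["taproot_zone_fraction"],
        n_laterals=s["n_laterals"],
        n_distractors=s["n_distractors"],
        noise_sd=s["noise_sd"],
        seed=cfg.stage_seed("simulate"),
    )


def stage_simulate(cfg: PipelineConfig, overwrite: bool = True) -> None:
    out = cfg.out_dir / "data"
    synthetic.generate_dataset(cfg["synthetic"]["n_scenes"], _scene_params(cfg),
                               out, overwrite=overwrite)
    _write_manifest(cfg, "simulate", [], [str(out)])


def stage_select(cfg: PipelineConfig) -> None:
    images = _load_dataset(cfg, with_masks=False)
    s = cfg["selection"]
    fc = selection.FeatureConfig(
        downsample_size=(s["downsample_height"], s["downsample_width"]),
        latent_channels=s["latent_channels"],
        pca_components=s["pca_components"],
        variance_target=s["variance_target"],
        train_epochs=s["train_epochs"],
        seed=cfg.stage_seed("select"),
    )
    feats = selection.extract_features(images, fc)
    k = s["k"] or max(1, int(round(0.2 * len(images))))
    sel = selection.greedy_select(feats, k)
    out = cfg.out_dir / "selection.csv"
    pd.DataFrame({
        "rank": np.arange(1, len(sel.indices) + 1),
        "image_id": sel.ids,
        "marginal_gain": sel.gains,
    }).to_csv(out, index=False)
    _write_manifest(cfg, "select", [str(cfg.out_dir / "data")], [str(out)])


def stage_anchors(cfg: PipelineConfig) -> None:
    a = cfg["anchors"]
    bases, strides = tuple(a["base_sizes"]), tuple(a["strides"])
    if a["method"] == "default":
        config = anchors_mod.default_anchors(bases, strides)
    else:
        ann = io_formats.read_vgg_annotations(
            _require(cfg.out_dir / "data" / "annotations.json", "simulate"))
        boxes = [b for bs in ann.values() for b in bs]
        if a["method"] == "percentile":
            config = anchors_mod.percentile_anchors(
                boxes, a["n_scales"], a["n_ratios"], bases, strides)
        elif a["method"] == "de":
            config = anchors_mod.optimize_anchors_de(
                boxes, a["n_scales"], a["n_ratios"], seed=cfg.stage_seed("anchors"),
                generations=a["de_generations"], population=a["de_population"],
                base_sizes=bases, strides=strides)
        else:
            raise ValueError(f"unknown anchor method {a['method']!r}")
    out = cfg.out_dir / "anchors.yaml"
    config.to_yaml(out)
    _write_manifest(cfg, "anchors", [], [str(out)])


def stage_train_detector(cfg: PipelineConfig) -> None:
    images = _load_dataset(cfg, with_masks=False)
    d = cfg["detector"]
    anchor_cfg = anchors_mod.AnchorConfig.from_yaml(
        _require(cfg.out_dir / "anchors.yaml", "anchors"))
    tcfg = det_mod.DetectorTrainConfig(
        anchor_config=anchor_cfg,
        iterations=d["iterations"], batch_size=d["batch_size"],
        learning_rate=d["learning_rate"], input_scale=d["input_scale"],
        seed=cfg.stage_seed("train-detector"),
    )
    model, info = det_mod.train_detector(images, tcfg, arch=d["arch"])
    out = cfg.out_dir / "detector.npz"
    det_mod.save_detector(model, out)
    (cfg.out_dir / "detector_train.json").write_text(json.dumps(info, indent=1))
    _write_manifest(cfg, "train-detector", [str(cfg.out_dir / "anchors.yaml")],
                    [str(out)])


def stage_train_segmenter(cfg: PipelineConfig) -> None:
    images = _load_dataset(cfg, with_masks=True)
    s = cfg["segmenter"]
    tcfg = seg_mod.SegmenterTrainConfig(
        iterations=s["iterations"], batch_size=s["batch_size"],
        learning_rate=s["learning_rate"], threshold=s["threshold"],
        seed=cfg.stage_seed("train-segmenter"),
    )
    model, info = seg_mod.train_segmenter(
        images, tcfg, arch=seg_mod.SegmenterArch(base_width=s["base_width"]))
    out = cfg.out_dir / "segmenter.npz"
    seg_mod.save_segmenter(model, out)
    (cfg.out_dir / "segmenter_train.json").write_text(json.dumps(info, indent=1))
    _write_manifest(cfg, "train-segmenter", [str(cfg.out_dir / "data")], [str(out)])


def stage_detect(cfg: PipelineConfig, images_dir: Path | None = None) -> None:
    model = det_mod.load_detector(_require(cfg.out_dir / "detector.npz",
                                           "train-detector"))
    d = cfg["detector"]
    images_dir = images_dir or cfg.out_dir / "data" / "images"
    rows = []
    for img_path in sorted(Path(images_dir).glob("*.png")):
        dets = det_mod.detect_nodules(model, io_formats.load_image(img_path),
                                      score_threshold=d["score_threshold"],
                                      nms_iou=d["nms_iou"])
        for det in dets:
            rows.append({"image_id": img_path.stem, **dict(zip(
                ("x_min", "y_min", "x_max", "y_max"), det.box.as_tuple())),
                "score": det.score})
    out = cfg.out_dir / "detections.csv"
    pd.DataFrame(rows, columns=["image_id", "x_min", "y_min", "x_max", "y_max",
                                "score"]).to_csv(out, index=False)
    _write_manifest(cfg, "detect", [str(images_dir)], [str(out)])


def stage_segment(cfg: PipelineConfig, images_dir: Path | None = None) -> None:
    model = seg_mod.load_segmenter(_require(cfg.out_dir / "segmenter.npz",
                                            "train-segmenter"))
    images_dir = images_dir or cfg.out_dir / "data" / "images"
    out = cfg.out_dir / "pred_masks"
    out.mkdir(parents=True, exist_ok=True)
    for img_path in sorted(Path(images_dir).glob("*.png")):
        mask = seg_mod.segment_taproot(model, io_formats.load_image(img_path),
                                       threshold=cfg["segmenter"]["threshold"])
        io_formats.write_mask(mask, out / img_path.name)
    _write_manifest(cfg, "segment", [str(images_dir)], [str(out)])


def read_detections_csv(path: Path) -> dict[str, list[Detection]]:
    df = pd.read_csv(path)
    out: dict[str, list[Detection]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image_id"]), []).append(Detection(
            BoundingBox(row["x_min"], row["y_min"], row["x_max"], row["y_max"]),
            float(row["score"])))
    return out


def stage_quantify(cfg: PipelineConfig) -> None:
    dets = read_detections_csv(_require(cfg.out_dir / "detections.csv", "detect"))
    p = cfg["postprocess"]
    mask_dir = (cfg.out_dir / "pred_masks" if p["masks"] == "predicted"
                else cfg.out_dir / "data" / "masks")
    qcfg = spatial.QuantifyConfig(r_dilate=p["r_dilate"],
                                  scale_with_width=p["scale_with_width"])
    reports = []
    image_ids = sorted(pth.stem for pth in
                       (cfg.out_dir / "data" / "images").glob("*.png"))
    for image_id in image_ids:
        mask_path = mask_dir / f"{image_id}.png"
        mask = io_formats.read_mask(mask_path) if mask_path.exists() else None
        if mask is not None and mask.sum() == 0:
            mask = None
        reports.append(spatial.quantify(dets.get(image_id, []), mask,
                                        qcfg, image_id=image_id))
    out = cfg.out_dir / "report.csv"
    io_formats.write_report(reports, out)
    _write_manifest(cfg, "quantify", [str(cfg.out_dir / "detections.csv"),
                                      str(mask_dir)], [str(out)])


def stage_evaluate(cfg: PipelineConfig) -> None:
    dets = read_detections_csv(_require(cfg.out_dir / "detections.csv", "detect"))
    truth = io_formats.read_vgg_annotations(
        _require(cfg.out_dir / "data" / "annotations.json", "simulate"))
    iou = cfg["evaluation"]["iou_threshold"]
    rows = []
    pooled_preds, pooled_truths = [], []
    offset = 0.0
    for image_id in sorted(truth):
        preds = dets.get(image_id, [])
        m = metrics.match_detections(preds, truth[image_id], iou)
        curve = (metrics.average_precision(preds, truth[image_id], iou)
                 if truth[image_id] else None)
        rows.append({
            "image_id": image_id, "tp": m.tp, "fp": m.fp, "fn": m.fn,
            "sensitivity": metrics.sensitivity(m),
            "precision": metrics.precision(m),
            "ap": curve.ap if curve else np.nan,
        })
        # pooled AP needs globally comparable boxes: shift each image into
        # its own horizontal band so cross-image IoU is zero
        for d in preds:
            b = d.box
            pooled_preds.append(Detection(BoundingBox(
                b.x_min + offset, b.y_min, b.x_max + offset, b.y_max), d.score))
        for t in truth[image_id]:
            pooled_truths.append(BoundingBox(
                t.x_min + offset, t.y_min, t.x_max + offset, t.y_max))
        offset += 1e6
    pooled = metrics.match_detections(pooled_preds, pooled_truths, iou)
    pooled_curve = metrics.average_precision(pooled_preds, pooled_truths, iou)
    rows.append({
        "image_id": "__pooled__", "tp": pooled.tp, "fp": pooled.fp, "fn": pooled.fn,
        "sensitivity": metrics.sensitivity(pooled),
        "precision": metrics.precision(pooled),
        "ap": pooled_curve.ap,
    })
    out = cfg.out_dir / "metrics.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    _write_manifest(cfg, "evaluate", [str(cfg.out_dir / "detections.csv")], [str(out)])


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "select": stage_select,
    "anchors": stage_anchors,
    "train-detector": stage_train_detector,
    "train-segmenter": stage_train_segmenter,
    "detect": stage_detect,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "evaluate": stage_evaluate,
}


def run_pipeline(config_path: str | Path, stages: list[str] | None = None) -> None:
    cfg = PipelineConfig.from_yaml(config_path)
    logging.basicConfig(level=getattr(logging, cfg.values["log_level"], logging.INFO))
    todo = stages or STAGES
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:  # dependency order
        if stage in todo:
            log.info("=== stage %s ===", stage)
            _STAGE_FUNCS[stage](cfg)
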