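"""End-to-end pipeline: synthesis, training, prediction, watershed, fusion,
morphometry and evaluation, with per-stage manifests.

Stage order: ``synth -> train-unet -> train-detector -> predict ->
watershed -> fuse -> ellipse -> eval``.  The division of labour mirrors the
method: the U-Net segments nuclei per pixel, the FPN detector finds whole
cells with coarse masks, marker-controlled watershed carves the detector's
cell foreground into per-cell cytoplasm using nucleus markers, and the
fusion stage reconciles the candidate labelings (probability averaging for
nuclei, instance voting for cytoplasm).

Every stage writes a ``manifest.json`` with its configuration, the run seed
and content hashes of its inputs, so any stage can be re-run and checked
for drift.  All stages are deterministic under the run seed.

The default configuration is the package's small-scale synthetic benchmark:
40 training / 10 test images of 64 x 64 pixels with one or two cells each, a
depth-2 / 8-channel U-Net, and a 2-level FPN detector — sized so the whole
pipeline runs in minutes on one CPU.  The published full-scale
hyperparameters remain the defaults of the individual config classes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

import yaml

from . import unet as unet_mod
from .augment import AugmentConfig, augment_pair
from .detect import (Detector, DetectorConfig, detect_instances,
                     detection_probmap, train_detector)
from .ellipse import fit_ellipse, descriptor_table
from .fusion import FusionConfig, fuse_probmaps, resolve_overlaps, vote_instances
from .imgio import HEImage, InstanceLabelMap, load_image, load_labelmap, save_labelmap
from .metrics import EvalReport, full_report
from .synthgen import SynthConfig, generate_dataset, write_dataset
from .unet import LossConfig, TrainConfig, UNet, UNetConfig, predict_probmap
from .watershed import WatershedConfig, extract_contours, threshold_probmap, watershed_cytoplasm
from .imgio import export_contours

logger = logging.getLogger(__name__)

STAGES = ("synth", "train-unet", "train-detector", "predict", "watershed",
          "fuse", "ellipse", "eval")


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=lambda: SynthConfig(
        image_height=64, image_width=64, n_cells_range=(1, 2),
        nucleus_semiaxis_range=(5.0, 9.0), cyto_scale_range=(1.8, 2.4),
        max_overlap_fraction=0.2, noise_sd=0.02))
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(crop_size=(64, 64)))
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(
        depth=2, base_channels=8, n_classes=2, dropout_p=0.1))
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=0.3, epochs=100, batch_size=8, l2_lambda=1e-4, max_steps=300))
    detector: DetectorConfig = field(default_factory=lambda: DetectorConfig(
        fpn_levels=2, anchor_scales=((24.0,), (40.0,)),
        neg_iou_thresh=0.4, score_thresh=0.7, nms_iou=0.2))
    watershed: WatershedConfig = field(default_factory=WatershedConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    n_train: int = 40
    n_test: int = 10
    augment_per_image: int = 0
    detector_steps: int = 800
    detector_lr: float = 0.05
    seed: int = 0
    out_dir: str = "runs/default"

    def replace_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        cfg.seed = seed
        cfg.synth = dataclasses.replace(cfg.synth, seed=seed)
        cfg.train = dataclasses.replace(cfg.train, seed=seed)
        return cfg

    # -- (de)serialisation ------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(getattr(obj, k)) for k in obj.__dataclass_fields__}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        Path(path).write_text(yaml.safe_dump(enc(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def tup(x):
            return tuple(tup(v) for v in x) if isinstance(x, list) else x
        kwargs: dict = {}
        sub = {"synth": SynthConfig, "augment": AugmentConfig, "unet": UNetConfig,
               "loss": LossConfig, "train": TrainConfig, "detector": DetectorConfig,
               "watershed": WatershedConfig, "fusion": FusionConfig}
        for key, val in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**{k: tup(v) for k, v in (val or {}).items()})
            else:
                kwargs[key] = tup(val)
        return cls(**kwargs)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _write_manifest(stage_dir: Path, config: PipelineConfig, stage: str,
                    inputs: list[Path], outputs: list[str]) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, tuple):
            return list(obj)
        return obj
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config": enc(config),
        "input_hashes": {str(p): _hash_file(p) for p in inputs if p.exists()},
        "outputs": outputs,
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_split(out: Path, split: str) -> list[tuple[HEImage, InstanceLabelMap, InstanceLabelMap]]:
    d = out / "synth" / split
    manifest = json.loads((d / "manifest.json").read_text())
    triplets = []
    for rec in manifest["images"]:
        triplets.append((
            load_image(d / rec["image"]),
            load_labelmap(d / rec["nucleus_labels"]),
            load_labelmap(d / rec["cyto_labels"]),
        ))
    return triplets


def nucleus_instances(probs: np.ndarray, threshold: float = 0.5) -> InstanceLabelMap:
    """Nucleus instances from a probability map: threshold the nucleus class
    and label 4-connected components."""
    fg = threshold_probmap(probs, 1, threshold)
    return InstanceLabelMap(measure.label(fg, connectivity=1).astype(np.int64))


def nucleus_markers(probs: np.ndarray, threshold: float = 0.5) -> InstanceLabelMap:
    """Nucleus instance markers from a probability map: threshold, label
    4-connected components, erode each by one pixel (fall back to the
    un-eroded component when erosion empties it)."""
    fg = threshold_probmap(probs, 1, threshold)
    lab = measure.label(fg, connectivity=1)
    out = np.zeros_like(lab)
    for i in range(1, lab.max() + 1):
        m = lab == i
        er = ndimage.binary_erosion(m)
        out[er if er.any() else m] = i
    return InstanceLabelMap(out.astype(np.int64))


def hard_probs(labels: InstanceLabelMap) -> np.ndarray:
    """Convert an instance labeling to a 2-class hard probability map."""
    fg = (labels.labels > 0).astype(np.float64)
    return np.stack([1.0 - fg, fg], axis=-1)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing upstream artifact {path}; "
            "run the earlier stages first")
    return path


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order; returns a dict of in-memory
    artifacts (always including ``report`` after the eval stage)."""
    stages = list(STAGES) if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage '{s}'; valid: {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    if "synth" in stages:
        logger.info("synth: generating %d train / %d test images",
                    config.n_train, config.n_test)
        train_cfg = dataclasses.replace(config.synth, seed=config.seed)
        test_cfg = dataclasses.replace(config.synth, seed=config.seed + 10_000)
        train_pairs = generate_dataset(train_cfg, config.n_train)
        test_pairs = generate_dataset(test_cfg, config.n_test)
        write_dataset(train_pairs, out / "synth" / "train", train_cfg)
        write_dataset(test_pairs, out / "synth" / "test", test_cfg)
        _write_manifest(out / "synth", config, "synth", [],
                        ["train/manifest.json", "test/manifest.json"])

    if "train-unet" in stages:
        d = out / "unet"
        d.mkdir(exist_ok=True)
        _require(out / "synth" / "train" / "manifest.json", "train-unet")
        triplets = _load_split(out, "train")
        dataset = [(im.pixels, nuc.labels) for im, nuc, _cyt in triplets]
        if config.augment_per_image > 0:
            rng = np.random.default_rng(config.seed + 1)
            extra = []
            for im, lab in dataset:
                for _ in range(config.augment_per_image):
                    extra.append(augment_pair(im, lab, config.augment, rng))
            dataset += extra
        model = UNet(config.unet, seed=config.seed)
        history = unet_mod.train(model, dataset, config.train, config.loss)
        model.save(d / "checkpoint.npz")
        with open(d / "loss_history.csv", "w") as fh:
            fh.write("epoch,loss\n")
            fh.writelines(f"{i},{v}\n" for i, v in enumerate(history))
        _write_manifest(d, config, "train-unet",
                        [out / "synth" / "train" / "manifest.json"],
                        ["checkpoint.npz", "loss_history.csv"])
        artifacts["unet"] = model

    if "train-detector" in stages:
        d = out / "detector"
        d.mkdir(exist_ok=True)
        _require(out / "synth" / "train" / "manifest.json", "train-detector")
        triplets = _load_split(out, "train")
        ds = []
        for im, _nuc, cyt in triplets:
            boxes, masks = [], []
            for iid in cyt.ids():
                m = cyt.mask(int(iid))
                rr, cc = np.nonzero(m)
                boxes.append([rr.min(), cc.min(), rr.max() + 1, cc.max() + 1])
                masks.append(m)
            ds.append((im.pixels, np.asarray(boxes, dtype=np.float64), masks))
        model = Detector(config.detector, seed=config.seed)
        history = train_detector(model, ds, steps=config.detector_steps,
                                 learning_rate=config.detector_lr, seed=config.seed)
        model.save(d / "checkpoint.npz")
        with open(d / "loss_history.csv", "w") as fh:
            fh.write("step,loss\n")
            fh.writelines(f"{i},{v}\n" for i, v in enumerate(history))
        _write_manifest(d, config, "train-detector",
                        [out / "synth" / "train" / "manifest.json"],
                        ["checkpoint.npz", "loss_history.csv"])
        artifacts["detector"] = model

    if "predict" in stages:
        d = out / "predict"
        d.mkdir(exist_ok=True)
        _require(out / "unet" / "checkpoint.npz", "predict")
        _require(out / "detector" / "checkpoint.npz", "predict")
        unet = artifacts.get("unet") or UNet(config.unet, seed=config.seed)
        unet.load(out / "unet" / "checkpoint.npz")
        det = artifacts.get("detector") or Detector(config.detector, seed=config.seed)
        det.load(out / "detector" / "checkpoint.npz")
        triplets = _load_split(out, "test")
        det_records = []
        for i, (im, _nuc, _cyt) in enumerate(triplets):
            probs = predict_probmap(unet, im)
            dets = detect_instances(det, im)
            np.savez(d / f"image_{i:04d}.npz",
                     unet_probs=probs,
                     det_probs=detection_probmap(dets, im.shape),
                     det_boxes=np.array([dd.box for dd in dets]).reshape(-1, 4),
                     det_scores=np.array([dd.score for dd in dets]),
                     det_masks=np.array([dd.mask for dd in dets], dtype=bool).reshape(
                         (-1,) + im.shape))
            det_records.append({"image": i, "n_detections": len(dets)})
        (d / "detections.json").write_text(json.dumps(det_records, indent=1))
        _write_manifest(d, config, "predict",
                        [out / "unet" / "checkpoint.npz", out / "detector" / "checkpoint.npz"],
                        [f"image_{i:04d}.npz" for i in range(len(triplets))])

    if "watershed" in stages:
        d = out / "watershed"
        d.mkdir(exist_ok=True)
        _require(out / "predict" / "manifest.json", "watershed")
        n = len(list((out / "predict").glob("image_*.npz")))
        for i in range(n):
            z = np.load(out / "predict" / f"image_{i:04d}.npz")
            markers = nucleus_markers(z["unet_probs"], config.watershed.prob_threshold)
            fg = threshold_probmap(z["det_probs"], 1, config.watershed.prob_threshold)
            fg |= markers.labels > 0  # nuclei always belong to their cell
            labels = watershed_cytoplasm(fg, markers, config.watershed.min_region_pixels)
            save_labelmap(labels, d / f"cyto_{i:04d}.png")
            export_contours(extract_contours(labels), d / f"contours_{i:04d}.txt")
        _write_manifest(d, config, "watershed", [out / "predict" / "manifest.json"],
                        [f"cyto_{i:04d}.png" for i in range(n)])

    if "fuse" in stages:
        d = out / "fuse"
        d.mkdir(exist_ok=True)
        _require(out / "watershed" / "manifest.json", "fuse")
        n = len(list((out / "predict").glob("image_*.npz")))
        report_recs = []
        for i in range(n):
            z = np.load(out / "predict" / f"image_{i:04d}.npz")
            ws = load_labelmap(out / "watershed" / f"cyto_{i:04d}.png")
            # pixel-level nucleus fusion: U-Net probabilities + hard
            # probabilities of the extracted nucleus instances
            instances = nucleus_instances(z["unet_probs"], config.watershed.prob_threshold)
            w = config.fusion.source_weights or (1.0, 1.0)
            fused_nuc = fuse_probmaps([z["unet_probs"], hard_probs(instances)], list(w)[:2])
            np.savez(d / f"fused_nuc_{i:04d}.npz", probs=fused_nuc)
            nuc_labels = InstanceLabelMap(
                measure.label(fused_nuc[:, :, 1] >= 0.5, connectivity=1).astype(np.int64))
            save_labelmap(nuc_labels, d / f"nuclei_{i:04d}.png")
            # instance-level cytoplasm fusion: watershed labeling vs detector
            # instances, then overlap resolution
            det_masks = z["det_masks"]
            det_scores = z["det_scores"]
            det_label_arr = np.zeros(ws.shape, dtype=np.int64)
            cands = []
            for k in range(det_masks.shape[0]):
                det_label_arr[det_masks[k] & (det_label_arr == 0)] = k + 1
                cands.append((k + 1, det_masks[k], float(det_scores[k])))
            det_labels = InstanceLabelMap(det_label_arr)
            consensus = vote_instances([ws, det_labels], config.fusion)
            final = resolve_overlaps(
                [(int(j), consensus.mask(int(j)), 1.0) for j in consensus.ids()]
                or [(1, np.zeros(ws.shape, bool), 0.0)])
            if final.shape != ws.shape:
                final = InstanceLabelMap(np.zeros(ws.shape, dtype=np.int64))
            save_labelmap(final, d / f"cyto_{i:04d}.png")
            report_recs.append({"image": i, "n_consensus": int(len(consensus.ids()))})
        (d / "fusion_report.json").write_text(json.dumps(report_recs, indent=1))
        _write_manifest(d, config, "fuse", [out / "watershed" / "manifest.json"],
                        [f"nuclei_{i:04d}.png" for i in range(n)])

    if "ellipse" in stages:
        d = out / "ellipse"
        d.mkdir(exist_ok=True)
        _require(out / "fuse" / "manifest.json", "ellipse")
        n = len(list((out / "fuse").glob("nuclei_*.png")))
        rows = []
        for i in range(n):
            for kind in ("nuclei", "cyto"):
                lab = load_labelmap(out / "fuse" / f"{kind}_{i:04d}.png")
                fits = {}
                for iid in lab.ids():
                    try:
                        fits[int(iid)] = fit_ellipse(lab.mask(int(iid)))
                    except ValueError:
                        continue
                for rec in descriptor_table(fits):
                    rows.append({"image": i, "kind": kind, **rec})
        with open(d / "morphology.csv", "w") as fh:
            cols = ["image", "kind", "instance", "xc", "yc", "a", "b", "theta",
                    "aspect_ratio", "area"]
            fh.write(",".join(cols) + "\n")
            for r in rows:
                fh.write(",".join(str(r[c]) for c in cols) + "\n")
        _write_manifest(d, config, "ellipse", [out / "fuse" / "manifest.json"],
                        ["morphology.csv"])
        artifacts["morphology"] = rows

    if "eval" in stages:
        d = out / "eval"
        d.mkdir(exist_ok=True)
        _require(out / "fuse" / "manifest.json", "eval")
        triplets = _load_split(out, "test")
        nuc_reports, cyto_reports = [], []
        for i, (_im, nuc_gt, cyt_gt) in enumerate(triplets):
            nuc_pred = load_labelmap(out / "fuse" / f"nuclei_{i:04d}.png")
            cyt_pred = load_labelmap(out / "fuse" / f"cyto_{i:04d}.png")
            nuc_reports.append(full_report(nuc_pred, nuc_gt, config.fusion.match_iou))
            cyto_reports.append(full_report(cyt_pred, cyt_gt, config.fusion.match_iou))
        report = _mean_report(nuc_reports, config.fusion.match_iou)
        cyto_report = _mean_report(cyto_reports, config.fusion.match_iou)
        report.to_csv(d / "nucleus_report.csv")
        cyto_report.to_csv(d / "cytoplasm_report.csv")
        (d / "report.txt").write_text(
            "NUCLEUS\n" + report.pretty() + "\n\nCYTOPLASM\n" + cyto_report.pretty() + "\n")
        _write_manifest(d, config, "eval", [out / "fuse" / "manifest.json"],
                        ["nucleus_report.csv", "cytoplasm_report.csv"])
        artifacts["report"] = report
        artifacts["cyto_report"] = cyto_report

    return artifacts


def _mean_report(reports: list[EvalReport], match_iou: float) -> EvalReport:
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    fn = sum(r.fn for r in reports)
    precision = tp / (tp + fp) if tp + fp else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(
        object_precision=precision, object_recall=recall, object_f1=f1,
        pixel_dice=float(np.mean([r.pixel_dice for r in reports])),
        pixel_jaccard=float(np.mean([r.pixel_jaccard for r in reports])),
        pixel_accuracy=float(np.mean([r.pixel_accuracy for r in reports])),
        tp=tp, fp=fp, fn=fn, match_iou=match_iou,
    )
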