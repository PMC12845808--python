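"""Minimal single-class dense detector for CPU-scale experiments.

A deliberately small detector whose only architectural degree of freedom
is the stem: either a baseline single stride-2 convolution consuming one
image, or the dual-stream fusion stem consuming both the facility-applied
input image and the facility-applied background-suppressed image.  The
shared body is a short stack of stride-2 convolutions; because the dual
stem downsamples to 1/4 resolution before the body starts, the body runs
at half the baseline's spatial resolution, and the baseline appends one
extra downsampling block so both variants predict on the same final grid.

The head predicts, per grid cell, an objectness logit and four box
parameters (sigmoid-squashed center offsets within the cell and box sides
as a fraction of ``4 * grid_stride``).  Training uses binary cross-entropy
on objectness plus an L1 box loss on positive cells; everything is seeded
and deterministic.

This is the harness that lets the preprocessing pipeline be ranked
end-to-end (train on a "seen" synthetic pen, evaluate on an "unseen" one)
without any external dataset or GPU.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import nn
from .bsi_stem import BSIConfig, BSIStem
from .detmetrics import Detection, EvalReport, evaluate, iou
from .facility_masking import (
    build_background_model,
    facility_mask_from_depth,
    fuse_inputs,
)
from .scene_synth import SceneConfig, generate_dataset, read_yolo_labels
from .complexity import ConvLayerSpec

__all__ = [
    "ToyDetectorConfig",
    "ToyDetector",
    "VARIANTS",
    "variant_config",
    "decode_and_nms",
    "train",
    "evaluate_on_dataset",
    "run_experiment",
    "detector_conv_layers",
    "load_dataset",
]


@dataclass
class ToyDetectorConfig:
    stem: str = "baseline"  # "baseline" | "bsi"
    bsi: BSIConfig = field(default_factory=lambda: BSIConfig(channels=4))
    body_channels: tuple[int, ...] = (16, 32)
    grid_stride: int = 16
    conf_threshold: float = 0.30
    nms_iou: float = 0.45
    epochs: int = 90
    batch_size: int = 8
    lr: float = 4e-3
    seed: int = 0
    # preprocessing pipeline flags
    use_big: bool = False
    use_fig: bool = False
    input_mode: str = "suppressed"

    def validate(self) -> None:
        if self.stem not in ("baseline", "bsi"):
            raise ValueError("stem must be 'baseline' or 'bsi'")
        expected_stride = 4 * 2 ** len(self.body_channels)
        if self.grid_stride != expected_stride:
            raise ValueError(
                f"grid_stride {self.grid_stride} inconsistent with stem+body stride "
                f"{expected_stride}"
            )
        for thr in (self.conf_threshold, self.nms_iou):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must be in (0, 1)")


# variant -> pipeline/stem flags; "big_fig" is the full proposed pipeline
VARIANTS: dict[str, dict] = {
    "baseline": {"stem": "baseline", "use_big": False, "use_fig": False},
    "big": {"stem": "bsi", "use_big": True, "use_fig": False},
    "big_fig": {"stem": "bsi", "use_big": True, "use_fig": True},
    "big_fig_addition": {"stem": "bsi", "use_big": True, "use_fig": True,
                         "fusion": "addition"},
    "big_fig_concat2d": {"stem": "bsi", "use_big": True, "use_fig": True,
                         "fusion": "concat2d"},
    "difference": {"stem": "bsi", "use_big": True, "use_fig": True,
                   "input_mode": "difference"},
}


def variant_config(name: str, seed: int = 0, **overrides) -> ToyDetectorConfig:
    """Build a ToyDetectorConfig for a named pipeline variant."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choices: {sorted(VARIANTS)}")
    spec = dict(VARIANTS[name])
    fusion = spec.pop("fusion", "3dconv")
    cfg = ToyDetectorConfig(seed=seed, **spec, **overrides)
    cfg.bsi = replace(cfg.bsi, fusion=fusion, seed=seed)
    cfg.validate()
    return cfg


class ToyDetector:
    """Dense single-scale detector with an interchangeable stem."""

    def __init__(self, cfg: ToyDetectorConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed, 0xDE])
        C = cfg.bsi.channels
        self.stem: BSIStem | nn.Conv2d
        if cfg.stem == "bsi":
            self.stem = BSIStem(replace(cfg.bsi, seed=cfg.seed))
        else:
            self.stem = nn.Conv2d(3, C, 3, stride=2, padding=1, rng=rng)
        self.body: list[nn.Conv2d] = []
        prev = C
        for ch in cfg.body_channels:
            self.body.append(nn.Conv2d(prev, ch, 3, stride=2, padding=1, rng=rng))
            prev = ch
        self.extra: nn.Conv2d | None = None
        if cfg.stem == "baseline":
            # equalizing block: the baseline body runs at 2x resolution, so one
            # extra stride-2 block brings it to the same final grid
            self.extra = nn.Conv2d(prev, prev, 3, stride=2, padding=1, rng=rng)
        self.head_obj = nn.Conv2d(prev, 1, 1, stride=1, padding=0, rng=rng)
        self.head_box = nn.Conv2d(prev, 4, 1, stride=1, padding=0, rng=rng)

    def params(self) -> list[nn.Tensor]:
        params: list[nn.Tensor] = []
        params += self.stem.params()
        for blk in self.body:
            params += blk.params()
        if self.extra is not None:
            params += self.extra.params()
        params += self.head_obj.params() + self.head_box.params()
        return params

    def forward(self, views: np.ndarray | tuple[np.ndarray, np.ndarray]):
        """Run the detector; returns (objectness logits, box logits) tensors.

        ``views`` is a single (B, 3, H, W) float batch for the baseline
        stem, or an (input_view, suppressed_view) pair for the dual stem.
        """
        if self.cfg.stem == "bsi":
            x_in, x_sup = views
            feat = self.stem.forward(x_in, x_sup).silu()
        else:
            x = views if isinstance(views, nn.Tensor) else nn.Tensor(views)
            if x.data.shape[2] % self.cfg.grid_stride or x.data.shape[3] % self.cfg.grid_stride:
                raise ValueError("input dims must be divisible by grid_stride")
            feat = self.stem(x).silu()
        for blk in self.body:
            feat = blk(feat).silu()
        if self.extra is not None:
            feat = self.extra(feat).silu()
        return self.head_obj(feat), self.head_box(feat)

    __call__ = forward

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(_config_to_dict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ToyDetector":
        data = np.load(path)
        cfg = _config_from_dict(json.loads(bytes(data["config_json"]).decode()))
        model = cls(cfg)
        for i, p in enumerate(model.params()):
            p.data = data[f"p{i}"].astype(np.float32)
        return model


def _config_to_dict(cfg: ToyDetectorConfig) -> dict:
    d = {k: getattr(cfg, k) for k in (
        "stem", "body_channels", "grid_stride", "conf_threshold", "nms_iou",
        "epochs", "batch_size", "lr", "seed", "use_big", "use_fig", "input_mode")}
    d["body_channels"] = list(cfg.body_channels)
    d["bsi"] = {
        "channels": cfg.bsi.channels, "lambda_mult": cfg.bsi.lambda_mult,
        "activation": cfg.bsi.activation, "softmax_axis": cfg.bsi.softmax_axis,
        "fusion": cfg.bsi.fusion, "kernel_3d": list(cfg.bsi.kernel_3d),
        "seed": cfg.bsi.seed,
    }
    return d


def _config_from_dict(d: dict) -> ToyDetectorConfig:
    b = d.pop("bsi")
    bsi = BSIConfig(
        channels=b["channels"], lambda_mult=b["lambda_mult"], activation=b["activation"],
        softmax_axis=b["softmax_axis"], fusion=b["fusion"],
        kernel_3d=tuple(b["kernel_3d"]), seed=b["seed"],
    )
    d["body_channels"] = tuple(d["body_channels"])
    return ToyDetectorConfig(bsi=bsi, **d)


# ---------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_and_nms(
    obj_logits: np.ndarray, box_logits: np.ndarray, cfg: ToyDetectorConfig,
    image_hw: tuple[int, int],
) -> list[Detection]:
    """Decode one image's prediction grid and apply greedy NMS.

    Cells whose objectness clears ``conf_threshold`` become boxes; a box is
    suppressed when its IoU with an already-kept higher-confidence box
    exceeds ``nms_iou``.
    """
    stride = cfg.grid_stride
    max_size = 4.0 * stride
    obj = _sigmoid(obj_logits.reshape(obj_logits.shape[-2:]))
    box = _sigmoid(box_logits.reshape((4,) + box_logits.shape[-2:]))
    H, W = image_hw
    cand: list[Detection] = []
    ii, jj = np.nonzero(obj > cfg.conf_threshold)
    for i, j in zip(ii, jj):
        cx = (j + 2.0 * box[0, i, j] - 0.5) * stride
        cy = (i + 2.0 * box[1, i, j] - 0.5) * stride
        bw = box[2, i, j] * max_size
        bh = box[3, i, j] * max_size
        x1, y1 = max(0.0, cx - bw / 2), max(0.0, cy - bh / 2)
        x2, y2 = min(float(W), cx + bw / 2), min(float(H), cy + bh / 2)
        if x2 > x1 and y2 > y1:
            cand.append(Detection(box=(x1, y1, x2, y2), confidence=float(obj[i, j])))
    cand.sort(key=lambda d: -d.confidence)
    kept: list[Detection] = []
    for d in cand:
        if all(iou(d.box, k.box) <= cfg.nms_iou for k in kept):
            kept.append(d)
    return kept


# ---------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------


def load_dataset(data_dir: str | Path) -> dict:
    """Read a synthetic dataset directory back into arrays and boxes."""
    data_dir = Path(data_dir)
    manifest = yaml.safe_load((data_dir / "manifest.yaml").read_text())
    h, w = manifest["height"], manifest["width"]
    frames, boxes, names = [], [], []
    for img_path in sorted((data_dir / "images").glob("*.png")):
        frames.append(np.asarray(Image.open(img_path)))
        label = data_dir / "labels" / (img_path.stem + ".txt")
        boxes.append(read_yolo_labels(label, w, h) if label.exists() else [])
        names.append(img_path.stem)
    if not frames:
        raise ValueError(f"empty dataset in {data_dir}")
    return {
        "frames": frames,
        "boxes": boxes,
        "names": names,
        "background": np.asarray(Image.open(data_dir / "background.png")),
        "depth": np.asarray(Image.open(data_dir / "depth.png")),
        "manifest": manifest,
    }


def _to_chw(img: np.ndarray) -> np.ndarray:
    return (img.astype(np.float32) / 255.0).transpose(2, 0, 1)


def prepare_views(dataset: dict, cfg: ToyDetectorConfig) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply the variant's preprocessing to every frame.

    Returns (primary_batch, suppressed_batch-or-None), each (N, 3, H, W)
    float32 in [0, 1].
    """
    model = build_background_model(dataset["background"], dataset["depth"],
                                   env_id=dataset["manifest"]["env_id"])
    primary, suppressed = [], []
    for frame in dataset["frames"]:
        if cfg.stem == "bsi" or cfg.use_big:
            pair = fuse_inputs(frame, model, use_fig=cfg.use_fig, input_mode=cfg.input_mode)
            primary.append(_to_chw(pair.input_view))
            suppressed.append(_to_chw(pair.suppressed_view))
        elif cfg.use_fig:
            pair = fuse_inputs(frame, model, use_fig=True, input_mode="suppressed")
            primary.append(_to_chw(pair.input_view))
        else:
            primary.append(_to_chw(frame))
    prim = np.stack(primary)
    if cfg.stem == "bsi":
        return prim, np.stack(suppressed)
    if cfg.use_big:
        # single-input ablation consuming the suppressed image itself
        return np.stack(suppressed), None
    return prim, None


def _cell_facility_fraction(facility_mask: np.ndarray, stride: int) -> np.ndarray:
    h, w = facility_mask.shape
    return (facility_mask > 0).reshape(h // stride, stride, w // stride, stride).mean(axis=(1, 3))


def _build_targets(
    boxes: list, grid_hw: tuple[int, int], stride: int,
    facility_frac: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell objectness and box targets for one image.

    An animal is assigned to the grid cell inside its box that is least
    covered by facility structures (ties broken toward the box center).
    A box-center cell hidden behind a feeder or pipe carries no observable
    evidence in the facility-equalized views, so anchoring the positive
    cell on visible territory keeps the supervision consistent.
    """
    gh, gw = grid_hw
    max_size = 4.0 * stride
    obj = np.zeros((1, gh, gw), dtype=np.float32)
    box_t = np.zeros((4, gh, gw), dtype=np.float32)
    for x1, y1, x2, y2 in boxes:
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        jc, ic = cx / stride, cy / stride
        i_lo = max(0, int(y1 // stride))
        i_hi = min(gh - 1, int((y2 - 1e-6) // stride))
        j_lo = max(0, int(x1 // stride))
        j_hi = min(gw - 1, int((x2 - 1e-6) // stride))
        if i_hi < i_lo or j_hi < j_lo:
            continue
        best: tuple[float, float, int, int] | None = None
        for i in range(i_lo, i_hi + 1):
            for j in range(j_lo, j_hi + 1):
                occ = float(facility_frac[i, j]) if facility_frac is not None else 0.0
                dist = (i + 0.5 - ic) ** 2 + (j + 0.5 - jc) ** 2
                key = (occ, dist, i, j)
                if best is None or key < best:
                    best = key
        _, _, i, j = best
        obj[0, i, j] = 1.0
        # offsets decode as 2*sigmoid - 0.5 cells, so centers up to half a
        # cell outside the assigned cell stay representable
        box_t[0, i, j] = np.clip((cx / stride - j + 0.5) / 2.0, 1e-4, 1 - 1e-4)
        box_t[1, i, j] = np.clip((cy / stride - i + 0.5) / 2.0, 1e-4, 1 - 1e-4)
        box_t[2, i, j] = np.clip((x2 - x1) / max_size, 1e-4, 1 - 1e-4)
        box_t[3, i, j] = np.clip((y2 - y1) / max_size, 1e-4, 1 - 1e-4)
    return obj, box_t


def _batch_loss(model: ToyDetector, views, obj_t, box_t, pos_mask) -> nn.Tensor:
    obj_logits, box_logits = model.forward(views)
    weights = np.where(pos_mask > 0, 8.0, 1.0)
    loss = nn.bce_with_logits(obj_logits, obj_t, weights)
    n_pos = float(pos_mask.sum())
    if n_pos > 0:
        mask4 = np.repeat(pos_mask, 4, axis=1)
        diff = (box_logits.sigmoid() - nn.Tensor(box_t)) * nn.Tensor(mask4)
        loss = loss + diff.abs().sum() * (5.0 / (4.0 * n_pos))
    return loss


def train(data_dir: str | Path, cfg: ToyDetectorConfig,
          checkpoint: str | Path | None = None) -> tuple[ToyDetector, list[float]]:
    """Train a detector on a synthetic dataset directory.

    Returns the trained model and the per-epoch mean loss log.  Fully
    deterministic for a fixed (dataset, config) pair.
    """
    cfg.validate()
    dataset = load_dataset(data_dir)
    prim, sup = prepare_views(dataset, cfg)
    n = prim.shape[0]
    H, W = prim.shape[2], prim.shape[3]
    gh, gw = H // cfg.grid_stride, W // cfg.grid_stride
    facility = facility_mask_from_depth(dataset["depth"])
    fac_frac = _cell_facility_fraction(facility, cfg.grid_stride)
    targets = [
        _build_targets(b, (gh, gw), cfg.grid_stride, fac_frac) for b in dataset["boxes"]
    ]
    obj_all = np.stack([t[0] for t in targets])
    box_all = np.stack([t[1] for t in targets])
    model = ToyDetector(cfg)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    rng = np.random.default_rng([cfg.seed, 0x7A])
    log: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pb, sb = prim[idx].copy(), (sup[idx].copy() if sup is not None else None)
            ob, bb = obj_all[idx].copy(), box_all[idx].copy()
            # seeded flip augmentation: a static camera sees one facility
            # layout, so flips are what keeps the detector from memorizing
            # absolute structure positions
            for k in range(len(idx)):
                if rng.random() < 0.5:
                    pb[k] = pb[k, :, :, ::-1]
                    if sb is not None:
                        sb[k] = sb[k, :, :, ::-1]
                    ob[k] = ob[k, :, :, ::-1]
                    bb[k] = bb[k, :, :, ::-1]
                    bb[k, 0] = np.where(ob[k, 0] > 0, 1.0 - bb[k, 0], bb[k, 0])
                if rng.random() < 0.5:
                    pb[k] = pb[k, :, ::-1, :]
                    if sb is not None:
                        sb[k] = sb[k, :, ::-1, :]
                    ob[k] = ob[k, :, ::-1, :]
                    bb[k] = bb[k, :, ::-1, :]
                    bb[k, 1] = np.where(ob[k, 0] > 0, 1.0 - bb[k, 1], bb[k, 1])
            views = (
                (nn.Tensor(pb), nn.Tensor(sb)) if cfg.stem == "bsi" else nn.Tensor(pb)
            )
            loss = _batch_loss(model, views, ob, bb, ob)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    if checkpoint is not None:
        model.save(checkpoint)
    return model, log


def predict(model: ToyDetector, dataset: dict) -> dict[str, list[Detection]]:
    """Detections for every image of a dataset, keyed by image stem."""
    cfg = model.cfg
    prim, sup = prepare_views(dataset, cfg)
    out: dict[str, list[Detection]] = {}
    H, W = prim.shape[2], prim.shape[3]
    for i, name in enumerate(dataset["names"]):
        views = (
            (nn.Tensor(prim[i : i + 1]), nn.Tensor(sup[i : i + 1]))
            if cfg.stem == "bsi"
            else nn.Tensor(prim[i : i + 1])
        )
        obj_logits, box_logits = model.forward(views)
        out[name] = decode_and_nms(obj_logits.data, box_logits.data, cfg, (H, W))
    return out


def evaluate_on_dataset(model: ToyDetector, data_dir: str | Path) -> EvalReport:
    dataset = load_dataset(data_dir)
    dets = predict(model, dataset)
    gts = {name: [tuple(b) for b in boxes] for name, boxes in zip(dataset["names"], dataset["boxes"])}
    return evaluate(dets, gts)


# ---------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------


def run_experiment(
    seen_cfg: SceneConfig,
    unseen_cfg: SceneConfig,
    variants: list[str],
    seeds: list[int],
    work_dir: str | Path,
    n_train: int = 24,
    n_eval: int = 12,
    detector_overrides: dict | None = None,
    results_path: str | Path | None = None,
) -> list[dict]:
    """Train each pipeline variant on the seen environment, test on both.

    One row per (variant, seed) with seen/unseen AP50 and F1.  Optionally
    writes the table as CSV plus a YAML copy next to it.
    """
    work_dir = Path(work_dir)
    rows: list[dict] = []
    for seed in seeds:
        train_dir = work_dir / f"seed{seed}" / "train_seen"
        seen_eval_dir = work_dir / f"seed{seed}" / "eval_seen"
        unseen_eval_dir = work_dir / f"seed{seed}" / "eval_unseen"
        generate_dataset(seen_cfg, n_train, train_dir, seed=seed * 1000 + 1)
        generate_dataset(seen_cfg, n_eval, seen_eval_dir, seed=seed * 1000 + 2)
        generate_dataset(unseen_cfg, n_eval, unseen_eval_dir, seed=seed * 1000 + 3)
        for name in variants:
            cfg = variant_config(name, seed=seed, **(detector_overrides or {}))
            model, log = train(train_dir, cfg)
            seen_rep = evaluate_on_dataset(model, seen_eval_dir)
            unseen_rep = evaluate_on_dataset(model, unseen_eval_dir)
            rows.append({
                "variant": name,
                "seed": seed,
                "final_loss": round(log[-1], 4),
                "ap50_seen": round(seen_rep.ap50, 4),
                "f1_seen": round(seen_rep.f1, 4),
                "ap50_unseen": round(unseen_rep.ap50, 4),
                "f1_unseen": round(unseen_rep.f1, 4),
            })
    if results_path is not None:
        results_path = Path(results_path)
        results_path.parent.mkdir(parents=True, exist_ok=True)
        with open(results_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
        results_path.with_suffix(".yaml").write_text(yaml.safe_dump(rows))
    return rows


# ---------------------------------------------------------------------
# FLOPs enumeration of the two variants
# ---------------------------------------------------------------------


def detector_conv_layers(cfg: ToyDetectorConfig, image_hw: tuple[int, int]) -> list[ConvLayerSpec]:
    """Enumerate every conv layer of a variant with its output size."""
    cfg.validate()
    H, W = image_hw
    C = cfg.bsi.channels
    layers: list[ConvLayerSpec] = []
    if cfg.stem == "bsi":
        layers += [
            ConvLayerSpec("conv2d", 3, C, (3, 3), (H // 2, W // 2), name="stem_input"),
            ConvLayerSpec("conv2d", 3, C, (3, 3), (H // 2, W // 2), name="stem_suppressed"),
        ]
        if cfg.bsi.fusion == "3dconv":
            layers.append(
                ConvLayerSpec("conv3d", C, C, tuple(cfg.bsi.kernel_3d),
                              (2, H // 4, W // 4), name="stem_fuse3d")
            )
        elif cfg.bsi.fusion == "concat2d":
            layers.append(
                ConvLayerSpec("conv2d", 2 * C, C, (3, 3), (H // 4, W // 4), name="stem_fuse2d")
            )
        h, w = H // 4, W // 4
    else:
        layers.append(ConvLayerSpec("conv2d", 3, C, (3, 3), (H // 2, W // 2), name="stem"))
        h, w = H // 2, W // 2
    prev = C
    for k, ch in enumerate(cfg.body_channels):
        h, w = h // 2, w // 2
        layers.append(ConvLayerSpec("conv2d", prev, ch, (3, 3), (h, w), name=f"body{k}"))
        prev = ch
    if cfg.stem == "baseline":
        h, w = h // 2, w // 2
        layers.append(ConvLayerSpec("conv2d", prev, prev, (3, 3), (h, w), name="extra_down"))
    layers.append(ConvLayerSpec("conv2d", prev, 1, (1, 1), (h, w), name="head_obj"))
    layers.append(ConvLayerSpec("conv2d", prev, 4, (1, 1), (h, w), name="head_box"))
    return layers
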