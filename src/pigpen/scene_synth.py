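"""Seeded synthetic pen scenes for a static camera.

Emulates the geometry of a fixed-camera pig pen: a static background with
low-frequency texture, bright facility structures (feeders, pipes) closer
to the camera that occlude the animals, and several elliptical animal blobs
with speckled texture.  Each scene ships with the two per-environment
plates the preprocessing phase needs — a clean background plate and an
8-bit depth plate (higher = closer) — plus visibility-filtered ground
truth: an animal is labeled only when more than 20% of its pixels remain
visible under the facility structures (strictly greater; boxes at exactly
0.2 are dropped).

Determinism contract: ``(config, seed)`` fully determines every emitted
byte.  The background plate depends only on the config (its ``seed`` field
selects the plate texture), so frames generated with different per-call
seeds share one plate, as a static camera requires.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "FacilityBar",
    "SceneConfig",
    "GroundTruthBox",
    "SynthScene",
    "generate_scene",
    "visible_fraction",
    "generate_dataset",
    "seen_config",
    "unseen_config",
    "write_yolo_labels",
    "read_yolo_labels",
]


@dataclass(frozen=True)
class FacilityBar:
    """Axis-aligned facility rectangle in pixel coordinates (half-open)."""

    x1: int
    y1: int
    x2: int
    y2: int
    brightness: int = 230


@dataclass
class SceneConfig:
    """Parameters of one synthetic pen environment.

    ``animal_axis_range`` gives the (min, max) ellipse semi-axes in pixels,
    ``animal_intensity`` the (mean, std) of the blob's 8-bit gray level,
    ``background_texture`` the Gaussian smoothing scale (px) plus base RGB
    of the floor, and ``facility_depth_value``/``background_depth_value``
    the two 8-bit depth levels of the plate (facility must be closer, i.e.
    higher).
    """

    height: int = 160
    width: int = 160
    n_animals: int = 4
    animal_axis_range: tuple[int, int] = (10, 20)
    animal_intensity: tuple[float, float] = (185.0, 18.0)
    background_texture: tuple[float, tuple[int, int, int]] = (8.0, (92, 72, 58))
    facility_layout: tuple[FacilityBar, ...] = (
        FacilityBar(8, 8, 52, 48, brightness=235),    # feeder block
        FacilityBar(0, 56, 160, 70, brightness=238),  # horizontal pipe
        FacilityBar(100, 0, 114, 160, brightness=222),  # vertical pipe
    )
    facility_depth_value: int = 220
    background_depth_value: int = 40
    noise_std: float = 2.0
    env_id: str = "seen"
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.height % 4 or self.width % 4:
            raise ValueError("height and width must be divisible by 4")
        if not self.facility_depth_value > self.background_depth_value:
            raise ValueError("facility must be closer (higher depth value) than background")
        lo, hi = self.animal_axis_range
        if not 0 < lo <= hi:
            raise ValueError("animal_axis_range must satisfy 0 < min <= max")
        if 2 * hi >= min(self.height, self.width):
            raise ValueError("animal larger than image")
        for v in (self.facility_depth_value, self.background_depth_value):
            if not 0 <= v <= 255:
                raise ValueError("depth values must be 8-bit")
        for bar in self.facility_layout:
            if not 0 <= bar.brightness <= 255:
                raise ValueError("facility brightness must be 8-bit")


@dataclass(frozen=True)
class GroundTruthBox:
    """Half-open pixel box (origin top-left) with the animal's visible fraction."""

    x1: float
    y1: float
    x2: float
    y2: float
    visible_fraction: float = 1.0


@dataclass
class SynthScene:
    frame: np.ndarray
    background_plate: np.ndarray
    depth_plate: np.ndarray
    gt_boxes: list[GroundTruthBox]


def visible_fraction(animal_pixels: np.ndarray, facility_mask: np.ndarray) -> float:
    """Share of an animal's pixels not covered by facility structures.

    Both arguments are binary masks of the same shape (nonzero = set).
    """
    animal = np.asarray(animal_pixels) > 0
    facility = np.asarray(facility_mask) > 0
    if animal.shape != facility.shape:
        raise ValueError("masks must share shape")
    total = int(animal.sum())
    if total == 0:
        raise ValueError("visible_fraction: empty animal mask")
    visible = int((animal & ~facility).sum())
    return visible / total


def _facility_raster(config: SceneConfig) -> np.ndarray:
    mask = np.zeros((config.height, config.width), dtype=bool)
    for bar in config.facility_layout:
        x1 = max(0, bar.x1)
        y1 = max(0, bar.y1)
        x2 = min(config.width, bar.x2)
        y2 = min(config.height, bar.y2)
        if x2 > x1 and y2 > y1:
            mask[y1:y2, x1:x2] = True
    return mask


def _make_plates(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Background plate, depth plate and facility raster from the config seed."""
    rng = np.random.default_rng([config.seed, 0xB6])
    h, w = config.height, config.width
    sigma, base_rgb = config.background_texture
    tex = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=sigma)
    std = tex.std()
    if std > 1e-9:
        tex *= 14.0 / std
    plate = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        fine = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(sigma / 4, 1.0))
        fstd = fine.std()
        if fstd > 1e-9:
            fine *= 4.0 / fstd
        plate[:, :, c] = base_rgb[c] + tex + fine
    facility = _facility_raster(config)
    for bar in config.facility_layout:
        x1, y1 = max(0, bar.x1), max(0, bar.y1)
        x2, y2 = min(w, bar.x2), min(h, bar.y2)
        if x2 > x1 and y2 > y1:
            plate[y1:y2, x1:x2, :] = bar.brightness
    if config.noise_std > 0:
        plate += rng.normal(0.0, config.noise_std, plate.shape)
    plate = np.clip(np.rint(plate), 0, 255).astype(np.uint8)

    depth = np.full((h, w), config.background_depth_value, dtype=np.float64)
    depth[facility] = config.facility_depth_value
    if config.noise_std > 0:
        # bounded so the two depth levels can never swap order
        gap = (config.facility_depth_value - config.background_depth_value) / 2 - 1
        noise = np.clip(rng.normal(0.0, config.noise_std, depth.shape), -gap, gap)
        depth += noise
    depth = np.clip(np.rint(depth), 0, 255).astype(np.uint8)
    return plate, depth, facility


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_scene(config: SceneConfig, seed: int) -> SynthScene:
    """Render one frame plus its environment plates and ground truth.

    The plate depends only on ``config``; ``seed`` drives animal placement
    and texture, so successive frames of one environment share their plates.
    """
    config.validate()
    plate, depth, facility = _make_plates(config)
    h, w = config.height, config.width
    frame = plate.copy()
    rng = np.random.default_rng([seed, 0xA9])
    boxes: list[GroundTruthBox] = []
    lo, hi = config.animal_axis_range
    mean_i, std_i = config.animal_intensity
    centers: list[tuple[float, float]] = []
    for _ in range(config.n_animals):
        # rejection-sample a center keeping blobs mostly apart (deterministic)
        for _attempt in range(40):
            cy = rng.uniform(hi, h - hi)
            cx = rng.uniform(hi, w - hi)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (1.4 * hi) ** 2 for py, px in centers):
                break
        centers.append((cy, cx))
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi) * rng.uniform(0.55, 0.8)
        theta = rng.uniform(0.0, np.pi)
        body = _ellipse_mask(h, w, cy, cx, a, b, theta)
        if not body.any():
            continue
        # speckled body texture with a slight pinkish tint
        speckle = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=1.2)
        sstd = speckle.std()
        if sstd > 1e-9:
            speckle *= std_i / sstd
        gray = np.clip(mean_i + speckle, 0, 255)
        paint = body & ~facility  # facilities occlude animals
        for c, tint in enumerate((8.0, -2.0, -8.0)):
            channel = frame[:, :, c].astype(np.float64)
            channel[paint] = np.clip(gray[paint] + tint, 0, 255)
            frame[:, :, c] = np.rint(channel).astype(np.uint8)
        vis = visible_fraction(body, facility)
        if vis > 0.2:
            ys, xs = np.nonzero(body)
            boxes.append(
                GroundTruthBox(
                    x1=float(xs.min()),
                    y1=float(ys.min()),
                    x2=float(xs.max() + 1),
                    y2=float(ys.max() + 1),
                    visible_fraction=vis,
                )
            )
    return SynthScene(frame=frame, background_plate=plate, depth_plate=depth, gt_boxes=boxes)


def seen_config(**overrides) -> SceneConfig:
    """The default training environment."""
    return replace(SceneConfig(), **overrides)


def unseen_config(**overrides) -> SceneConfig:
    """A deployment environment: new floor color/texture and facility layout."""
    base = SceneConfig(
        background_texture=(5.0, (152, 148, 132)),
        facility_layout=(
            FacilityBar(112, 100, 156, 144, brightness=240),  # feeder block
            FacilityBar(0, 20, 160, 32, brightness=230),      # horizontal pipe
            FacilityBar(28, 0, 42, 160, brightness=215),      # vertical pipe
        ),
        env_id="unseen",
        seed=1,
    )
    return replace(base, **overrides)


def write_yolo_labels(path: str | Path, boxes: list[GroundTruthBox], width: int, height: int) -> None:
    """Write normalized `0 cx cy w h` label lines, 6-decimal fixed point."""
    lines = []
    for b in boxes:
        cx = (b.x1 + b.x2) / 2 / width
        cy = (b.y1 + b.y2) / 2 / height
        bw = (b.x2 - b.x1) / width
        bh = (b.y2 - b.y1) / height
        lines.append(f"0 {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path: str | Path, width: int, height: int) -> list[tuple[float, float, float, float]]:
    """Read YOLO label lines back into pixel (x1, y1, x2, y2) boxes."""
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        _, cx, cy, bw, bh = (float(p) for p in parts[:5])
        boxes.append(
            (
                (cx - bw / 2) * width,
                (cy - bh / 2) * height,
                (cx + bw / 2) * width,
                (cy + bh / 2) * height,
            )
        )
    return boxes


def generate_dataset(
    config: SceneConfig, n_images: int, out_dir: str | Path, seed: int
) -> dict:
    """Write a full synthetic dataset directory and return its manifest.

    Layout: ``images/frame_XXXX.png``, ``labels/frame_XXXX.txt``,
    ``background.png``, ``depth.png``, ``manifest.yaml``.  Per-image seeds
    are derived deterministically from the master seed.
    """
    config.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    state = np.random.SeedSequence([seed, config.seed]).generate_state(n_images)
    total_boxes = 0
    first_scene = None
    for i in range(n_images):
        scene = generate_scene(config, int(state[i] % (2**31)))
        if first_scene is None:
            first_scene = scene
        stem = f"frame_{i:04d}"
        Image.fromarray(scene.frame).save(out_dir / "images" / f"{stem}.png")
        write_yolo_labels(
            out_dir / "labels" / f"{stem}.txt", scene.gt_boxes, config.width, config.height
        )
        total_boxes += len(scene.gt_boxes)
    assert first_scene is not None
    Image.fromarray(first_scene.background_plate).save(out_dir / "background.png")
    Image.fromarray(first_scene.depth_plate).save(out_dir / "depth.png")
    manifest = {
        "env_id": config.env_id,
        "seed": seed,
        "n_images": n_images,
        "height": config.height,
        "width": config.width,
        "total_boxes": total_boxes,
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return manifest
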