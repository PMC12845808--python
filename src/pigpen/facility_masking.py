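"""Depth-based facility masking and the image fuser.

Pen infrastructure (feeders, pipes, rails) sits closer to the camera than
the floor, so on an 8-bit depth map with the "higher = closer" convention
the facility separates cleanly from the background by Otsu thresholding.
The facility mask is computed once per static environment, stored in a
:class:`BackgroundModel`, and applied to every frame: facility pixels are
painted white (255 on all channels) in *both* network inputs so that
heterogeneous facility textures are equalized across environments.

The fuser produces the detector's two co-registered views: the
facility-applied input image and the facility-applied background-suppressed
image (or, for ablation, the raw difference image).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .background_suppression import big_generate, difference_image, otsu_threshold

__all__ = [
    "BackgroundModel",
    "FusedPair",
    "facility_mask_from_depth",
    "apply_facility_mask",
    "build_background_model",
    "estimate_background",
    "fuse_inputs",
]


def facility_mask_from_depth(depth: np.ndarray) -> np.ndarray:
    """Binary facility mask from an 8-bit depth image (higher = closer).

    Otsu's threshold splits the depth histogram; pixels strictly above the
    threshold (closer to the camera) are binarized to 255 and kept, the rest
    set to 0.  A uniform depth image yields an empty mask — first-class
    support for pens with no occluding facility.  Intended to run once per
    static environment.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("facility_mask_from_depth: empty depth image")
    t = otsu_threshold(depth)
    binarized = np.where(depth > t, 255, 0).astype(np.uint8)
    # pass the binarized map through its own >128 gate (a no-op on {0,255})
    return np.where(binarized > 128, 255, 0).astype(np.uint8)


def apply_facility_mask(frame: np.ndarray, facility: np.ndarray) -> np.ndarray:
    """Paint facility pixels white, leaving the rest of the frame unchanged.

    Pixels where ``facility >= 128`` become 255 on every channel.
    """
    frame = np.asarray(frame)
    facility = np.asarray(facility)
    if facility.shape != frame.shape[:2]:
        raise ValueError(
            f"facility mask shape {facility.shape} incompatible with frame {frame.shape}"
        )
    hit = facility >= 128
    if frame.ndim == 3:
        hit = hit[:, :, None]
    return np.where(hit, 255, frame).astype(np.uint8)


@dataclass
class BackgroundModel:
    """Per-environment bundle built once in the static-camera preprocessing phase.

    Attributes
    ----------
    background : ndarray
        uint8 RGB background plate (scene without animals).
    depth : ndarray
        uint8 depth map of the plate, higher values closer to the camera.
    facility_mask : ndarray
        uint8 {0, 255} mask of occluding infrastructure.
    env_id : str
        Environment label.
    """

    background: np.ndarray
    depth: np.ndarray
    facility_mask: np.ndarray
    env_id: str = "default"

    def __post_init__(self) -> None:
        hw = self.background.shape[:2]
        if self.depth.shape != hw or self.facility_mask.shape != hw:
            raise ValueError("BackgroundModel components must share height/width")
        vals = np.unique(self.facility_mask)
        if not np.isin(vals, (0, 255)).all():
            raise ValueError("facility_mask must only contain {0, 255}")

    def save(self, model_dir: str | Path) -> Path:
        """Persist as a directory {background.png, depth.png, facility_mask.png, meta.yaml}."""
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        Image.fromarray(self.background).save(model_dir / "background.png")
        Image.fromarray(self.depth).save(model_dir / "depth.png")
        Image.fromarray(self.facility_mask).save(model_dir / "facility_mask.png")
        (model_dir / "meta.yaml").write_text(yaml.safe_dump({"env_id": self.env_id}))
        return model_dir

    @classmethod
    def load(cls, model_dir: str | Path) -> "BackgroundModel":
        model_dir = Path(model_dir)
        meta = yaml.safe_load((model_dir / "meta.yaml").read_text())
        return cls(
            background=np.asarray(Image.open(model_dir / "background.png")),
            depth=np.asarray(Image.open(model_dir / "depth.png")),
            facility_mask=np.asarray(Image.open(model_dir / "facility_mask.png")),
            env_id=meta["env_id"],
        )


@dataclass
class FusedPair:
    """The two co-registered detector inputs produced by the fuser."""

    input_view: np.ndarray
    suppressed_view: np.ndarray

    def __post_init__(self) -> None:
        if self.input_view.shape != self.suppressed_view.shape:
            raise ValueError("FusedPair views must share shape")


def build_background_model(
    background: np.ndarray,
    depth: np.ndarray,
    env_id: str = "default",
    facility_mask: np.ndarray | None = None,
) -> BackgroundModel:
    """Build the per-environment model, deriving the facility mask from depth.

    Pass an explicit ``facility_mask`` (e.g. all zeros) to override the
    depth-derived mask for environments known to have no occluding facility.
    """
    if depth.shape != background.shape[:2]:
        raise ValueError("background and depth must share height/width")
    if facility_mask is None:
        facility_mask = facility_mask_from_depth(depth)
    return BackgroundModel(background, depth, facility_mask, env_id)


def estimate_background(frames: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Temporal-median background plate estimate from a stack of frames.

    Fallback for environments where no clean plate is available: with enough
    frames, each pixel shows background more often than any animal, so the
    per-pixel median recovers the plate.
    """
    stack = np.stack([np.asarray(f) for f in frames], axis=0)
    if stack.shape[0] < 3:
        raise ValueError("estimate_background needs at least 3 frames")
    return np.median(stack, axis=0).astype(np.uint8)


def fuse_inputs(
    frame: np.ndarray,
    model: BackgroundModel,
    use_fig: bool = True,
    input_mode: str = "suppressed",
) -> FusedPair:
    """Produce the dual detector input for one frame.

    Parameters
    ----------
    frame : ndarray
        uint8 RGB frame from the static camera.
    model : BackgroundModel
        The environment's preprocessing bundle.
    use_fig : bool
        Apply the facility mask (white-out) to both views.  With ``False``
        the input view is the unmodified frame (facility-masking ablation).
    input_mode : {"suppressed", "difference"}
        Second view: the background-suppressed image, or the raw absolute
        difference image replicated to three channels (ablation).
    """
    if frame.shape[:2] != model.background.shape[:2]:
        raise ValueError("frame does not match model shape")
    if input_mode == "suppressed":
        second = big_generate(frame, model.background)
    elif input_mode == "difference":
        diff = difference_image(frame, model.background)
        second = np.repeat(diff[:, :, None], 3, axis=2)
    else:
        raise ValueError(f"unknown input_mode {input_mode!r}")
    if use_fig:
        input_view = apply_facility_mask(frame, model.facility_mask)
        second = apply_facility_mask(second, model.facility_mask)
    else:
        input_view = frame.copy()
    return FusedPair(input_view=input_view, suppressed_view=second)
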