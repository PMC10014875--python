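"""Video reading/writing, arena cropping, and model-input preprocessing.

Frames live in memory as ``(N, H, W, 3)`` uint8 RGB arrays wrapped in a
:class:`FrameStack`. On disk, videos are plain uncompressed AVI
containers (see :mod:`explore.avi`). Before classification every frame is
cropped to the arena region and rescaled to 150 x 150 pixels with values
in [0, 1] — the fixed input contract of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import avi
from .errors import BoundsError, ConsistencyError
from .roi import RegionOfInterest

#: Side length of the (square) network input.
MODEL_INPUT_SIZE = 150


@dataclass
class FrameStack:
    """An in-memory video: ordered frames at a fixed rate."""

    frames: np.ndarray  # (N, H, W, 3) uint8
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[3] != 3:
            raise ConsistencyError("frames must have shape (N, H, W, 3)")
        if self.fps <= 0:
            raise ConsistencyError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps


def write_frames(path, stack: FrameStack) -> None:
    avi.write_avi(path, stack.frames, stack.fps)


def read_frames(path, arena: RegionOfInterest | None = None) -> FrameStack:
    """Read a video file, optionally cropping every frame to ``arena``."""
    frames, fps = avi.read_avi(path)
    if arena is not None:
        if not arena.within(frames.shape[2], frames.shape[1]):
            raise BoundsError(
                f"arena {arena} outside {frames.shape[2]}x{frames.shape[1]} frame"
            )
        rows, cols = arena.slice()
        frames = frames[:, rows, cols]
    return FrameStack(frames=frames, fps=fps, source_id=Path(path).stem)


def _to_rgb(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.repeat(frame[:, :, None], 3, axis=2)
    return frame


def crop_resize(frame: np.ndarray, arena: RegionOfInterest) -> np.ndarray:
    """Crop ``frame`` to ``arena`` and rescale to the network input.

    Returns a float32 array of shape ``(150, 150, 3)`` with values in
    [0, 1]. The aspect ratio is *not* preserved: whatever the arena
    shape, the output is square. Bilinear interpolation.
    """
    frame = _to_rgb(frame)
    h, w = frame.shape[:2]
    if not arena.within(w, h):
        raise BoundsError(f"arena {arena} outside {w}x{h} frame")
    rows, cols = arena.slice()
    crop = frame[rows, cols]
    img = Image.fromarray(np.ascontiguousarray(crop.astype(np.uint8)))
    img = img.resize((MODEL_INPUT_SIZE, MODEL_INPUT_SIZE), Image.BILINEAR)
    return np.asarray(img, dtype=np.float32) / 255.0


def preprocess_stack(stack: FrameStack, arena: RegionOfInterest | None = None) -> np.ndarray:
    """Crop+resize every frame; returns uint8 (N, 150, 150, 3).

    Kept as uint8 so a full experiment fits in memory; the classifier
    rescales to [0, 1] per batch (batch-wise memory contract).
    """
    if arena is None:
        arena = RegionOfInterest(0, 0, stack.width, stack.height)
    out = np.empty((len(stack), MODEL_INPUT_SIZE, MODEL_INPUT_SIZE, 3), dtype=np.uint8)
    rows, cols = arena.slice()
    if not arena.within(stack.width, stack.height):
        raise BoundsError(f"arena {arena} outside video frame")
    for i in range(len(stack)):
        img = Image.fromarray(np.ascontiguousarray(stack.frames[i, rows, cols]))
        out[i] = np.asarray(img.resize((MODEL_INPUT_SIZE, MODEL_INPUT_SIZE), Image.BILINEAR))
    return out


@dataclass
class RenderStyle:
    """Colours and geometry for prediction-video overlays."""

    class_colours: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    border_px: int = 2
    corner_box: RegionOfInterest | None = None  # drawn for behaviour classes

    def colour_for(self, class_index: int) -> tuple[int, int, int]:
        palette = [
            (255, 0, 0), (0, 160, 255), (0, 200, 0),
            (255, 200, 0), (200, 0, 255), (0, 255, 200),
        ]
        return self.class_colours.get(
            class_index, palette[(class_index - 1) % len(palette)]
        )


def _draw_border(frame: np.ndarray, roi: RegionOfInterest,
                 colour: tuple[int, int, int], border_px: int) -> None:
    c = np.asarray(colour, dtype=np.uint8)
    b = border_px
    frame[roi.y0 : roi.y0 + b, roi.x0 : roi.x1] = c
    frame[max(roi.y1 - b, roi.y0) : roi.y1, roi.x0 : roi.x1] = c
    frame[roi.y0 : roi.y1, roi.x0 : roi.x0 + b] = c
    frame[roi.y0 : roi.y1, max(roi.x1 - b, roi.x0) : roi.x1] = c


def render_prediction_video(
    stack: FrameStack,
    hard_classes: np.ndarray,
    object_rois: dict[int, RegionOfInterest],
    behaviour_classes: set[int] | None = None,
    style: RenderStyle | None = None,
    out_path=None,
) -> FrameStack:
    """Overlay class-coloured boxes on frames predicted as exploration.

    ``object_rois`` maps class index -> the ROI whose border is drawn
    when that class is predicted. Classes in ``behaviour_classes`` draw
    the style's corner box instead. Background frames are untouched.
    """
    hard_classes = np.asarray(hard_classes)
    if len(hard_classes) != len(stack):
        raise ConsistencyError(
            f"track length {len(hard_classes)} != frame count {len(stack)}"
        )
    style = style or RenderStyle()
    behaviour_classes = behaviour_classes or set()
    out = stack.frames.copy()
    for i, cls in enumerate(hard_classes):
        cls = int(cls)
        if cls == 0:
            continue
        colour = style.colour_for(cls)
        if cls in behaviour_classes:
            box = style.corner_box or RegionOfInterest(
                0, 0, min(20, stack.width), min(20, stack.height)
            )
            _draw_border(out[i], box, colour, style.border_px)
        elif cls in object_rois:
            _draw_border(out[i], object_rois[cls], colour, style.border_px)
    rendered = FrameStack(out, stack.fps, stack.source_id + "_prediction")
    if out_path is not None:
        write_frames(out_path, rendered)
    return rendered
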