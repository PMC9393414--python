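"""Frame ingestion and bedding-ROI rectification.

Sleep video is sampled at a low, fixed rate (default 2 frames/s).  The bed
area is isolated with a four-point perspective ("trapezoidal") correction so
that motion outside the bedding — a parent leaning over the cot, a door
opening — never enters the movement signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import ProjectiveTransform, warp

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for color -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


class VideoInputError(ValueError):
    """Unreadable, empty or inconsistently shaped frame source."""


class GeometryError(ValueError):
    """Degenerate or out-of-bounds ROI quadrilateral."""


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image to an 8-bit luminance raster.

    Color input is reduced with BT.601 weights (0.299 R + 0.587 G + 0.114 B)
    and rounded to the nearest integer; grayscale input passes through.
    """
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim == 3 and image.shape[2] in (3, 4):
        gray = image[..., :3].astype(float) @ _LUMA
        return np.rint(np.clip(gray, 0, 255)).astype(np.uint8)
    raise VideoInputError(f"unsupported image shape {image.shape}")


@dataclass
class FrameSequence:
    """Ordered, uniformly sampled grayscale frames.

    ``frames`` is a (n, height, width) uint8 array; ``sample_interval`` is
    the spacing between consecutive frames in seconds (0.5 s at 2 fps).
    """

    frames: np.ndarray
    sample_interval: float = 0.5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise VideoInputError(
                f"frames must be a (n, h, w) array, got ndim={self.frames.ndim}"
            )
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise VideoInputError("luminance values must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)
        if self.sample_interval <= 0:
            raise VideoInputError("sample_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class RoiQuad:
    """Four-corner bedding region in source-frame pixel coordinates.

    Corners are ordered top-left, top-right, bottom-right, bottom-left and
    must form a strictly convex quadrilateral.  ``out_width``/``out_height``
    give the rectified raster size; when omitted they default to the
    quadrilateral's bounding-box size.
    """

    corners: np.ndarray
    out_width: int | None = None
    out_height: int | None = None

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise GeometryError("corners must be four (x, y) points")
        if not self._is_convex():
            raise GeometryError("corners must form a convex, positive-area quadrilateral")
        if self.out_width is None:
            self.out_width = int(np.ceil(self.corners[:, 0].max() - self.corners[:, 0].min())) + 1
        if self.out_height is None:
            self.out_height = int(np.ceil(self.corners[:, 1].max() - self.corners[:, 1].min())) + 1
        if self.out_width < 2 or self.out_height < 2:
            raise GeometryError("rectified size must be at least 2x2")

    def _is_convex(self) -> bool:
        pts = self.corners
        cross = np.empty(4)
        for i in range(4):
            u = pts[(i + 1) % 4] - pts[i]
            v = pts[(i + 2) % 4] - pts[(i + 1) % 4]
            cross[i] = u[0] * v[1] - u[1] * v[0]
        return bool(np.all(cross > 0) or np.all(cross < 0))


def load_frames(source: str | Path, sample_interval: float = 0.5) -> FrameSequence:
    """Load a video file or a directory of image frames.

    A directory is read in lexicographic filename order.  All frames are
    converted to 8-bit grayscale and must share identical dimensions.
    """
    source = Path(source)
    if not source.exists():
        raise VideoInputError(f"source does not exist: {source}")

    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if len(paths) < 2:
            raise VideoInputError(f"need at least 2 frames, found {len(paths)} in {source}")
        raw = [iio.imread(p) for p in paths]
    else:
        try:
            raw = list(iio.imiter(source))
        except Exception as exc:  # decoder errors vary by backend
            raise VideoInputError(f"cannot decode {source}: {exc}") from exc
        if len(raw) < 2:
            raise VideoInputError(f"need at least 2 decodable frames in {source}")

    gray = [to_grayscale(frame) for frame in raw]
    shapes = {g.shape for g in gray}
    if len(shapes) != 1:
        raise VideoInputError(f"frames have inconsistent dimensions: {sorted(shapes)}")

    seq = FrameSequence(np.stack(gray), sample_interval=sample_interval)
    logger.info(
        "loaded %d frames of %dx%d at %.3g s/frame from %s",
        len(seq), seq.width, seq.height, sample_interval, source,
    )
    return seq


def _roi_transform(roi: RoiQuad) -> ProjectiveTransform:
    """Projective map from rectified-output coordinates to source coordinates."""
    w, h = roi.out_width, roi.out_height
    dst_rect = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], dtype=float)
    tform = ProjectiveTransform.from_estimate(dst_rect, roi.corners)
    if not tform:
        raise GeometryError("could not estimate perspective transform (degenerate quad)")
    return tform


def correct_perspective(frame: np.ndarray, roi: RoiQuad) -> np.ndarray:
    """Rectify the ROI quadrilateral of one frame to a rectangle.

    The unique homography sending ``roi.corners`` to the corners of an
    ``out_width`` x ``out_height`` rectangle is applied with bilinear
    interpolation.  Everything outside the quadrilateral is discarded.  For
    an axis-aligned rectangular quad rendered at native size this reduces to
    an exact crop.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise VideoInputError("frame must be a 2-D luminance raster")
    h_src, w_src = frame.shape
    x, y = roi.corners[:, 0], roi.corners[:, 1]
    if x.min() < 0 or y.min() < 0 or x.max() > w_src - 1 or y.max() > h_src - 1:
        raise GeometryError("ROI corners fall outside the frame bounds")

    tform = _roi_transform(roi)
    out = warp(
        frame.astype(float),
        inverse_map=tform,
        output_shape=(roi.out_height, roi.out_width),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    return np.rint(out).astype(np.uint8)


def rectify_sequence(seq: FrameSequence, roi: RoiQuad) -> FrameSequence:
    """Apply :func:`correct_perspective` to every frame of a sequence."""
    rectified = np.stack([correct_perspective(f, roi) for f in seq.frames])
    logger.info(
        "rectified %d frames to %dx%d ROI", len(seq), roi.out_width, roi.out_height
    )
    return FrameSequence(rectified, sample_interval=seq.sample_interval)
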