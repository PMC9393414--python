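"""Body-movement extraction by dual-lag frame differencing.

Two movement signals are computed every frame: a *fast* signal from the
difference with the previous frame (0.5 s apart at 2 fps), which captures
quick movements, and a *slow* signal from the difference with the frame six
steps back (3.0 s apart), which captures slow drifts such as posture shifts.
Each signal is the count of pixels whose absolute luminance change exceeds a
binarization threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .video import FrameSequence, VideoInputError

logger = logging.getLogger(__name__)

#: Default binarization threshold on the 0-255 luminance scale.
DEFAULT_THRESHOLD = 30

#: Default lags in frames at 2 fps: 1 frame = 0.5 s, 6 frames = 3.0 s.
FAST_LAG_SECONDS = 0.5
SLOW_LAG_SECONDS = 3.0


@dataclass
class MovementSeries:
    """Per-sample fast/slow movement pixel counts for one recording.

    ``fast`` and ``slow`` are aligned 1:1 with the video frames (one sample
    per 0.5 s).  ``roi_area`` is the pixel count of the rectified ROI, the
    upper bound of any movement count.
    """

    fast: np.ndarray
    slow: np.ndarray
    sample_interval: float = 0.5
    roi_area: int = 0

    def __post_init__(self) -> None:
        self.fast = np.asarray(self.fast, dtype=np.int64)
        self.slow = np.asarray(self.slow, dtype=np.int64)
        if self.fast.shape != self.slow.shape or self.fast.ndim != 1:
            raise ValueError("fast and slow must be 1-D arrays of equal length")
        if self.roi_area <= 0:
            self.roi_area = int(max(self.fast.max(initial=0), self.slow.max(initial=0), 1))
        if (self.fast < 0).any() or (self.slow < 0).any():
            raise ValueError("movement counts must be non-negative")
        if self.fast.max(initial=0) > self.roi_area or self.slow.max(initial=0) > self.roi_area:
            raise ValueError("movement counts cannot exceed roi_area")

    def __len__(self) -> int:
        return self.fast.shape[0]

    @property
    def combined(self) -> np.ndarray:
        """Per-sample fast + slow sum, the quantity most features use."""
        return self.fast + self.slow


def movement_amount(frame_a: np.ndarray, frame_b: np.ndarray, threshold: int = DEFAULT_THRESHOLD) -> int:
    """Count pixels whose absolute luminance difference exceeds ``threshold``.

    The absolute difference image is binarized (strictly greater than the
    threshold -> white) and the white pixels are counted as the amount of
    body movement.
    """
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise VideoInputError(
            f"frame dimensions differ: {frame_a.shape} vs {frame_b.shape}"
        )
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    diff = np.abs(frame_a.astype(np.int16) - frame_b.astype(np.int16))
    return int(np.count_nonzero(diff > threshold))


def _lag_in_frames(lag_seconds: float, sample_interval: float) -> int:
    frames = lag_seconds / sample_interval
    rounded = int(round(frames))
    if abs(frames - rounded) > 1e-9:
        warnings.warn(
            f"lag of {lag_seconds} s is not an integral number of frames at "
            f"{sample_interval} s/frame; rounding {frames:.3f} -> {rounded}",
            stacklevel=3,
        )
    return max(rounded, 1)


def extract_movement_series(
    seq: FrameSequence,
    threshold: int = DEFAULT_THRESHOLD,
    fast_lag: int | None = None,
    slow_lag: int | None = None,
) -> MovementSeries:
    """Compute the fast/slow movement series of a rectified frame sequence.

    ``fast_lag``/``slow_lag`` are in frames; when omitted they are derived
    from the sequence's sample interval so the temporal lags stay at 0.5 s
    and 3.0 s.  Samples whose lagged frame precedes the recording are
    defined as 0, keeping the series aligned 1:1 with the frames.
    """
    if fast_lag is None:
        fast_lag = _lag_in_frames(FAST_LAG_SECONDS, seq.sample_interval)
    if slow_lag is None:
        slow_lag = _lag_in_frames(SLOW_LAG_SECONDS, seq.sample_interval)
    if len(seq) < slow_lag + 1:
        raise VideoInputError(
            f"need at least {slow_lag + 1} frames for a {slow_lag}-frame lag, got {len(seq)}"
        )

    frames = seq.frames.astype(np.int16)
    n = len(seq)
    fast = np.zeros(n, dtype=np.int64)
    slow = np.zeros(n, dtype=np.int64)
    for lag, out in ((fast_lag, fast), (slow_lag, slow)):
        diff = np.abs(frames[lag:] - frames[:-lag])
        out[lag:] = np.count_nonzero(diff > threshold, axis=(1, 2))

    roi_area = seq.height * seq.width
    logger.info(
        "extracted movement from %d frames (threshold=%d, lags=%d/%d, roi_area=%d)",
        n, threshold, fast_lag, slow_lag, roi_area,
    )
    return MovementSeries(fast, slow, sample_interval=seq.sample_interval, roi_area=roi_area)


def write_movement_csv(series: MovementSeries, path: str | Path) -> None:
    """Write a movement series to CSV (the video->feature interchange file).

    Columns: ``sample_index`` (1-based), ``t_seconds``, ``fast``, ``slow``.
    The ROI area rides along in a ``# roi_area=`` comment line.
    """
    path = Path(path)
    idx = np.arange(1, len(series) + 1)
    df = pd.DataFrame(
        {
            "sample_index": idx,
            "t_seconds": (idx - 1) * series.sample_interval,
            "fast": series.fast,
            "slow": series.slow,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# roi_area={series.roi_area}\n")
        fh.write(f"# sample_interval={series.sample_interval}\n")
        df.to_csv(fh, index=False)


def read_movement_csv(path: str | Path) -> MovementSeries:
    """Read a movement series written by :func:`write_movement_csv`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    df = pd.read_csv(path, comment="#")
    required = {"sample_index", "fast", "slow"}
    if not required.issubset(df.columns):
        raise ValueError(f"movement CSV must have columns {sorted(required)}")
    interval = meta.get("sample_interval")
    if interval is None:
        t = df["t_seconds"].to_numpy()
        interval = float(t[1] - t[0]) if len(t) > 1 else 0.5
    return MovementSeries(
        df["fast"].to_numpy(),
        df["slow"].to_numpy(),
        sample_interval=interval,
        roi_area=int(meta.get("roi_area", 0)),
    )
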