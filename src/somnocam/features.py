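"""Per-epoch feature computation and per-recording standardization.

Six parameters summarize the dual-lag movement series once per 30 s scoring
epoch (60 samples at 2 fps), mirroring the cadence of clinical sleep
scoring:

* ``sum_mean_30`` — mean combined movement over the epoch's 60 samples
  (magnitude of short-term movement; separates Wake).
* ``prop_mean_300`` — log10 of the mean fast*slow product over a 300 s
  forward window, clamped to 0 below 1 (movement frequency over 5 min;
  separates REM from Light).
* ``sum_mean_300`` — mean combined movement over the 300 s window
  (long-term magnitude; separates sustained Wake from Deep).
* ``non_bm`` — a running stillness counter, reset whenever combined
  movement exceeds a threshold ``k``, sampled at the epoch's last frame
  (duration of the stationary state; separates Deep).
* ``epoch`` — the 1-based epoch number (elapsed time; Deep dominates early
  night, REM late night).
* ``variance_30`` — population variance of combined movement within the
  epoch (short-term movement frequency; separates Deep from REM).

Because body size and sleep duration vary enormously between children, all
six parameters are standardized to zero mean and unit variance *within each
recording* before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .movement import MovementSeries

#: Samples per 30 s scoring epoch at 2 fps.
EPOCH_SAMPLES = 60
#: Samples in the long (300 s) feature window.
LONG_WINDOW = 600

RAW_COLUMNS = [
    "sum_mean_30",
    "prop_mean_300",
    "sum_mean_300",
    "non_bm",
    "epoch",
    "variance_30",
]
Z_COLUMNS = [c + "_z" for c in RAW_COLUMNS]


class EpochRangeError(ValueError):
    """Epoch start index outside the series or not on the 30 s grid."""


def default_k(roi_area: int) -> int:
    """Stillness threshold tied to ROI size: 0.1% of the ROI pixel count."""
    return int(np.ceil(0.001 * roi_area))


def _check_start(series: MovementSeries, n: int) -> int:
    """Validate a 1-based epoch start sample and return its 0-based index."""
    if n < 1 or (n - 1) % EPOCH_SAMPLES != 0:
        raise EpochRangeError(f"epoch start must be 1, 61, 121, ...; got {n}")
    if n > len(series):
        raise EpochRangeError(f"epoch start {n} beyond series end ({len(series)} samples)")
    return n - 1


def sum_mean_30(series: MovementSeries, n: int) -> float:
    """Mean combined (fast + slow) movement over the 30 s epoch starting at ``n``."""
    i = _check_start(series, n)
    window = series.combined[i : i + EPOCH_SAMPLES]
    return float(window.sum() / len(window))


def prop_mean_300(series: MovementSeries, n: int) -> float:
    """log10 of the mean fast*slow product over 300 s, clamped to 0 below 1.

    The window looks forward from the epoch start and is truncated at the
    end of the recording (the mean then uses the actual sample count).
    """
    i = _check_start(series, n)
    fast = series.fast[i : i + LONG_WINDOW].astype(float)
    slow = series.slow[i : i + LONG_WINDOW].astype(float)
    m = float((fast * slow).sum() / len(fast))
    return float(np.log10(m)) if m > 1.0 else 0.0


def sum_mean_300(series: MovementSeries, n: int) -> float:
    """Mean combined movement over the 300 s forward window starting at ``n``."""
    i = _check_start(series, n)
    window = series.combined[i : i + LONG_WINDOW]
    return float(window.sum() / len(window))


def non_bm_series(series: MovementSeries, k: int) -> np.ndarray:
    """Running stillness counter over the whole series.

    The counter resets to 0 at any sample whose combined movement exceeds
    ``k`` and increments otherwise; the per-epoch feature is the counter at
    the epoch's final sample.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    still = series.combined <= k
    counters = np.zeros(len(series), dtype=np.int64)
    run = 0
    for i, s in enumerate(still):
        run = run + 1 if s else 0
        counters[i] = run
    return counters


def epoch_number(n: int) -> int:
    """1-based epoch number of the epoch starting at sample ``n``."""
    if n < 1 or (n - 1) % EPOCH_SAMPLES != 0:
        raise EpochRangeError(f"epoch start must be 1, 61, 121, ...; got {n}")
    return (n + EPOCH_SAMPLES - 1) // EPOCH_SAMPLES


def variance_30(series: MovementSeries, n: int, printed_formula: bool = False) -> float:
    """Dispersion of combined movement within the 30 s epoch starting at ``n``.

    By default this is the population variance (mean of squares minus
    squared mean) of the 60 combined samples.  ``printed_formula=True``
    instead evaluates the un-normalized sum-of-squares-minus-squared-mean
    variant, kept for comparison only (see the methods note).
    """
    i = _check_start(series, n)
    window = series.combined[i : i + EPOCH_SAMPLES].astype(float)
    mean = window.mean()
    if printed_formula:
        return float((window**2).sum() - mean**2)
    return float((window**2).mean() - mean**2)


@dataclass
class FeatureMatrix:
    """Per-epoch raw (and optionally standardized) parameters of one recording."""

    data: pd.DataFrame
    recording_id: str = ""

    def __len__(self) -> int:
        return len(self.data)

    @property
    def standardized(self) -> np.ndarray:
        """(n_epochs, 6) array of standardized features, classifier input."""
        missing = [c for c in Z_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"standardized columns missing: {missing}; call standardize() first")
        return self.data[Z_COLUMNS].to_numpy(dtype=float)


def compute_features(
    series: MovementSeries,
    k: int | None = None,
    recording_id: str = "",
    printed_variance: bool = False,
) -> FeatureMatrix:
    """Compute the six raw parameters for every complete 30 s epoch.

    ``k`` defaults to 0.1% of the ROI area.  A trailing partial epoch
    (fewer than 60 samples) is dropped.
    """
    if len(series) < EPOCH_SAMPLES:
        raise ValueError(f"need at least {EPOCH_SAMPLES} samples, got {len(series)}")
    if k is None:
        k = default_k(series.roi_area)

    n_epochs = len(series) // EPOCH_SAMPLES
    counters = non_bm_series(series, k)
    rows = []
    for r in range(n_epochs):
        n = 1 + EPOCH_SAMPLES * r
        rows.append(
            {
                "epoch_index": r + 1,
                "sum_mean_30": sum_mean_30(series, n),
                "prop_mean_300": prop_mean_300(series, n),
                "sum_mean_300": sum_mean_300(series, n),
                "non_bm": int(counters[n + EPOCH_SAMPLES - 2]),
                "epoch": epoch_number(n),
                "variance_30": variance_30(series, n, printed_formula=printed_variance),
            }
        )
    return FeatureMatrix(pd.DataFrame(rows), recording_id=recording_id)


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize each raw column to zero mean and unit variance.

    Scaling is per recording (population standard deviation); a constant
    column maps to all zeros.  Returns a new matrix with ``*_z`` columns
    added.
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 epochs")
    data = matrix.data.copy()
    for col in RAW_COLUMNS:
        values = data[col].to_numpy(dtype=float)
        std = values.std()  # population (ddof=0)
        if std == 0.0:
            data[col + "_z"] = 0.0
        else:
            data[col + "_z"] = (values - values.mean()) / std
    return FeatureMatrix(data, recording_id=matrix.recording_id)


def write_feature_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.insert(0, "recording_id", matrix.recording_id)
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    recording_id = str(df["recording_id"].iloc[0]) if "recording_id" in df.columns else ""
    return FeatureMatrix(df.drop(columns=["recording_id"], errors="ignore"), recording_id=recording_id)
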