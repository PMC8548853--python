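"""Robust preprocessing of raw squiggles into fixed-length network inputs.

A classifiable window is produced in three deterministic steps:

1. trim: skip the adapter-dominated prefix (1500 samples for training
   corpora, 1000 at inference — the adapter plus pore noise occupy roughly
   the first 1000-1500 samples at 4 kHz) and keep the next 3000 samples,
   about 300 nucleotides of sequence;
2. outlier repair: samples whose modified z-score
   0.6745*|x - median| / MAD exceeds 3.5 (Iglewicz-Hoaglin rule) are
   replaced by the mean of the nearest non-outlier neighbor on each side;
3. MAD normalization: subtract the median and divide by the MAD, both
   recomputed on the repaired window, yielding median 0 / MAD 1.

Because the normalization is invariant to affine rescaling, it does not
matter whether the input is in DAC counts or picoamperes; by default the
calibrated pA trace is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from nanosieve.errors import DegenerateSignalError, NanosieveError, ValidationError
from nanosieve.signal_io import Squiggle

logger = logging.getLogger(__name__)

#: training-time adapter skip (overestimate of adapter length, in samples)
DEFAULT_SKIP_TRAIN = 1500
#: inference-time adapter skip (closer estimate, for earlier decisions)
DEFAULT_SKIP_INFER = 1000
#: window length consumed by the classifier (~300 nt at ~10 samples/base)
DEFAULT_WINDOW = 3000
#: modified z-score threshold above which a sample is treated as an outlier
DEFAULT_MAD_THRESHOLD = 3.5

_MODIFIED_Z_CONSTANT = 0.6745


class ReadTooShortError(NanosieveError):
    """Read shorter than skip + window; excluded from the batch, not fatal."""


@dataclass
class NormalizationStats:
    """Median/MAD used for normalization and the number of repaired samples."""

    median: float
    mad: float
    n_outliers_replaced: int


@dataclass
class NormalizedWindow:
    """A fixed-length, median-0 / MAD-1 signal window ready for the network."""

    values: np.ndarray
    read_id: str
    stats: NormalizationStats

    def __len__(self) -> int:
        return int(self.values.size)


def _median_mad(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, mad


def trim_window(signal: np.ndarray, skip: int = DEFAULT_SKIP_TRAIN,
                length: int = DEFAULT_WINDOW) -> np.ndarray:
    """Return samples [skip, skip+length) of the signal.

    Raises :class:`ReadTooShortError` when the read cannot supply the full
    window — callers exclude such reads rather than aborting the batch.
    """
    if skip < 0 or length < 1:
        raise ValidationError(f"skip must be >= 0 and length >= 1, got {skip}, {length}")
    signal = np.asarray(signal)
    if signal.size < skip + length:
        raise ReadTooShortError(
            f"read has {signal.size} samples, needs {skip + length}")
    return signal[skip:skip + length]


def modified_zscores(window: np.ndarray) -> np.ndarray:
    """Iglewicz-Hoaglin modified z-scores, 0.6745*(x - median)/MAD."""
    window = np.asarray(window, dtype=np.float64)
    med, mad = _median_mad(window)
    if mad == 0:
        raise DegenerateSignalError("window MAD is zero; modified z undefined")
    return _MODIFIED_Z_CONSTANT * (window - med) / mad


def replace_outliers(window: np.ndarray,
                     threshold: float = DEFAULT_MAD_THRESHOLD
                     ) -> tuple[np.ndarray, int]:
    """Replace extreme samples by the average of their closest inliers.

    A sample is extreme when |modified z| > threshold.  Each flagged sample
    is replaced by the mean of the nearest non-outlier neighbor on each
    side (a single neighbor at the window edges); runs of consecutive
    outliers all resolve to the same bracketing inliers.  Returns the
    repaired copy and the number of replacements.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.size < 3:
        raise ValidationError(f"window must have >= 3 samples, got {window.size}")
    z = modified_zscores(window)
    mask = np.abs(z) > threshold
    n_out = int(mask.sum())
    if n_out == 0:
        return window.copy(), 0

    repaired = window.copy()
    inlier_idx = np.flatnonzero(~mask)
    # nearest inlier strictly to the left / right of each position
    out_idx = np.flatnonzero(mask)
    left_pos = np.searchsorted(inlier_idx, out_idx) - 1
    right_pos = left_pos + 1
    for j, left, right in zip(out_idx, left_pos, right_pos):
        neighbors = []
        if left >= 0:
            neighbors.append(window[inlier_idx[left]])
        if right < inlier_idx.size:
            neighbors.append(window[inlier_idx[right]])
        repaired[j] = float(np.mean(neighbors))
    return repaired, n_out


def mad_normalize(window: np.ndarray, read_id: str = "",
                  n_outliers_replaced: int = 0) -> NormalizedWindow:
    """Z-scored-MAD normalization: (x - median) / MAD on the given window."""
    window = np.asarray(window, dtype=np.float64)
    med, mad = _median_mad(window)
    if mad == 0:
        raise DegenerateSignalError("window MAD is zero; cannot normalize")
    values = (window - med) / mad
    return NormalizedWindow(
        values=values,
        read_id=read_id,
        stats=NormalizationStats(median=med, mad=mad,
                                 n_outliers_replaced=n_outliers_replaced),
    )


def preprocess_read(squiggle: Squiggle, skip: int = DEFAULT_SKIP_TRAIN,
                    length: int = DEFAULT_WINDOW,
                    threshold: float = DEFAULT_MAD_THRESHOLD,
                    use_pA: bool = True) -> NormalizedWindow:
    """Trim, repair outliers, and normalize one read.

    Raises :class:`ReadTooShortError` for reads that cannot fill the
    window (callers exclude them) and :class:`DegenerateSignalError` for
    constant signal.  Deterministic: the same read always yields the same
    window.
    """
    signal = squiggle.to_pA() if use_pA else np.asarray(squiggle.raw, dtype=np.float64)
    trimmed = trim_window(signal, skip=skip, length=length)
    repaired, n_out = replace_outliers(trimmed, threshold=threshold)
    return mad_normalize(repaired, read_id=squiggle.read_id,
                         n_outliers_replaced=n_out)


def preprocess_batch(squiggles, skip: int = DEFAULT_SKIP_TRAIN,
                     length: int = DEFAULT_WINDOW,
                     threshold: float = DEFAULT_MAD_THRESHOLD,
                     use_pA: bool = True
                     ) -> tuple[list[NormalizedWindow], list[tuple[str, str]]]:
    """Preprocess many reads; returns (windows, exclusions as (id, reason))."""
    windows: list[NormalizedWindow] = []
    excluded: list[tuple[str, str]] = []
    for sq in squiggles:
        try:
            windows.append(preprocess_read(sq, skip=skip, length=length,
                                           threshold=threshold, use_pA=use_pA))
        except (ReadTooShortError, DegenerateSignalError) as exc:
            logger.warning("excluding read %s: %s", sq.read_id, exc)
            excluded.append((sq.read_id, str(exc)))
    return windows, excluded
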