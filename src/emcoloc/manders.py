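"""Pixel-overlap Manders coefficients M1/M2 for registered channel pairs.

The fluorescence-microscopy counterpart of the point-pattern coefficients:
M1 is the fraction of channel-A signal residing in pixels where channel B is
above its threshold, M2 the symmetric quantity for channel B,

    M1 = sum(A over pixels with B > t_B) / sum(A over pixels with A > t_A).

Above-threshold is strict (> t), so t = 0 is exact for binary masks, where
both coefficients reduce to overlap-pixel count ratios.  Thresholds are
user-supplied; automatic threshold selection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .errors import FormatError, UndefinedCoefficientError

__all__ = ["ChannelPair", "manders_overlap", "load_channel", "MandersOverlap"]


@dataclass
class ChannelPair:
    """Two equally shaped non-negative 2-D intensity arrays (or 0/1 masks)."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    threshold_a: float = 0.0
    threshold_b: float = 0.0

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError(
                f"channel shapes differ: {self.channel_a.shape} vs "
                f"{self.channel_b.shape}"
            )
        if self.channel_a.ndim != 2:
            raise ValueError("channels must be 2-D single-channel arrays")
        if self.threshold_a < 0 or self.threshold_b < 0:
            raise ValueError("thresholds must be non-negative")


def manders_overlap(pair: ChannelPair) -> tuple[float, float]:
    """(M1, M2) for one channel pair; each lies in [0, 1].

    Raises :class:`UndefinedCoefficientError` when a denominator channel has
    no above-threshold pixel.
    """
    above_a = pair.channel_a > pair.threshold_a
    above_b = pair.channel_b > pair.threshold_b
    denom_a = pair.channel_a[above_a].sum()
    denom_b = pair.channel_b[above_b].sum()
    if denom_a <= 0:
        raise UndefinedCoefficientError(
            "M1 undefined: channel A has no pixel above its threshold"
        )
    if denom_b <= 0:
        raise UndefinedCoefficientError(
            "M2 undefined: channel B has no pixel above its threshold"
        )
    m1 = pair.channel_a[above_b].sum() / denom_a
    m2 = pair.channel_b[above_a].sum() / denom_b
    return float(m1), float(m2)


def load_channel(path) -> np.ndarray:
    """Read a single-channel image (TIFF, PGM, PNG, ...) as a float array.

    0/255 binary masks are accepted as-is (any positive value is "on" at the
    default zero threshold).
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}"
        )
    return arr.astype(float)


class MandersOverlap(BaseEstimator):
    """Estimator wrapper around :func:`manders_overlap`.

    ``fit(X)`` accepts a :class:`ChannelPair` or an ``(A, B)`` array pair and
    exposes ``m1_`` and ``m2_``.
    """

    def __init__(self, threshold_a: float = 0.0, threshold_b: float = 0.0):
        self.threshold_a = threshold_a
        self.threshold_b = threshold_b

    def fit(self, X, y=None) -> "MandersOverlap":
        if isinstance(X, ChannelPair):
            pair = ChannelPair(
                X.channel_a, X.channel_b, self.threshold_a, self.threshold_b
            )
        else:
            a, b = X
            pair = ChannelPair(a, b, self.threshold_a, self.threshold_b)
        self.m1_, self.m2_ = manders_overlap(pair)
        return self
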