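"""Windowed forward-lag cross-correlation summary features.

Every ordered pair of behavior channels (i, j) — including i = j — is
summarized by the mean and the standard deviation, across overlapping
windows, of the maximal Pearson correlation over forward lags of the second
channel.  Forward-only lag makes the pair ordered: (i, j) captures channel i
leading channel j.  With C channels the feature vector has length
M = 2 * C**2 (C = 56 gives M = 6272).

Per window [s, s + W) and lag l in {0..max_lag}, the correlation is the
Pearson coefficient of the truncated overlapping segments a[s : s+W-l] and
b[s+l : s+W], each segment re-centered and re-scaled (no zero padding).
Zero-variance segments yield correlation 0 for that lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .behavior_series import BehaviorMatrix

__all__ = [
    "DEFAULT_TW_GRID",
    "WindowConfig",
    "CoordinationFeatureVector",
    "window_starts",
    "windowed_max_xcorr",
    "extract_features",
    "feature_names",
]

#: Candidate window lengths (seconds) searched by the classifier's inner CV.
DEFAULT_TW_GRID = (1.0, 2.0, 4.0, 6.0)

MIN_WINDOW_FRAMES = 4


def default_max_lag(window_frames: int) -> int:
    """Default lag bound: half a window, capped so segments keep >= 3 frames."""
    return min(window_frames // 2, window_frames - 3)


@dataclass(frozen=True)
class WindowConfig:
    """Windowing parameters for cross-correlation feature extraction.

    ``window_seconds`` is converted to frames by nearest-integer rounding;
    the step is half a window (floor), i.e. 50% overlap.  ``max_lag_frames``
    defaults to half a window.
    """

    window_seconds: float
    frame_rate: float
    max_lag_frames: int | None = None

    def __post_init__(self) -> None:
        wf = int(np.rint(self.window_seconds * self.frame_rate))
        if wf < MIN_WINDOW_FRAMES:
            raise ValueError(
                f"window of {self.window_seconds} s at {self.frame_rate} fps "
                f"spans {wf} frames; need >= {MIN_WINDOW_FRAMES}"
            )
        if self.max_lag_frames is None:
            object.__setattr__(self, "max_lag_frames", default_max_lag(wf))
        if not 0 <= self.max_lag_frames <= wf - 3:
            raise ValueError(
                f"max_lag_frames must be in [0, {wf - 3}], got {self.max_lag_frames}"
            )

    @property
    def window_frames(self) -> int:
        return int(np.rint(self.window_seconds * self.frame_rate))

    @property
    def step_frames(self) -> int:
        return self.window_frames // 2


@dataclass(frozen=True)
class CoordinationFeatureVector:
    """Flat feature vector with per-feature names and its window config.

    Names follow ``mu(chA->chB)`` / ``sigma(chA->chB)``: all mu features in
    (i, j) row-major channel order, then all sigma features.
    """

    values: np.ndarray
    names: tuple[str, ...]
    config: WindowConfig = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))
        if vals.ndim != 1 or vals.shape[0] != len(self.names):
            raise ValueError("values and names must have equal length")

    def __len__(self) -> int:
        return self.values.shape[0]


def window_starts(n_frames: int, cfg: WindowConfig) -> np.ndarray:
    """Start indices of the 50%-overlapping windows covering ``n_frames``.

    Trailing frames that do not fill a whole window are discarded.
    """
    wf, step = cfg.window_frames, cfg.step_frames
    if n_frames < wf:
        raise ValueError(
            f"series too short: {n_frames} frames < window of {wf} frames"
        )
    return np.arange(0, n_frames - wf + 1, step)


def _lagged_corr_stack(windows: np.ndarray, max_lag: int) -> np.ndarray:
    """Max-over-lag Pearson correlation for every window and channel pair.

    ``windows`` has shape (n_windows, C, W).  Returns (n_windows, C, C)
    where entry [w, i, j] is the max over lags l of the correlation of
    channel i's segment [0 : W-l] with channel j's segment [l : W].
    """
    n_w, n_ch, wf = windows.shape
    best = np.full((n_w, n_ch, n_ch), -np.inf)
    for lag in range(max_lag + 1):
        n = wf - lag
        lead = windows[:, :, : wf - lag]
        lagged = windows[:, :, lag:]
        lz = _zscore(lead)
        gz = _zscore(lagged)
        corr = lz @ gz.transpose(0, 2, 1) / n
        np.maximum(best, corr, out=best)
    return np.clip(best, -1.0, 1.0)


def _zscore(seg: np.ndarray) -> np.ndarray:
    """Population z-score along the last axis; zero-variance rows become 0."""
    mean = seg.mean(axis=-1, keepdims=True)
    std = seg.std(axis=-1, keepdims=True)
    safe = np.where(std > 0.0, std, 1.0)
    z = (seg - mean) / safe
    return np.where(std > 0.0, z, 0.0)


def windowed_max_xcorr(
    a: np.ndarray, b: np.ndarray, cfg: WindowConfig
) -> np.ndarray:
    """Per-window maximal forward-lag correlation for one ordered pair.

    Channel ``a`` leads; ``b`` is shifted forward by each candidate lag.
    Returns one maximum (signed, not absolute) per window.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D series")
    pair = np.vstack([a, b])
    maxima = _pairwise_window_maxima(pair, cfg)
    return maxima[:, 0, 1]


def _pairwise_window_maxima(Y: np.ndarray, cfg: WindowConfig) -> np.ndarray:
    starts = window_starts(Y.shape[1], cfg)
    views = sliding_window_view(Y, cfg.window_frames, axis=1)  # (C, T-W+1, W)
    windows = views[:, starts, :].transpose(1, 0, 2).astype(float)
    return _lagged_corr_stack(windows, cfg.max_lag_frames)


def extract_features(Y: BehaviorMatrix, cfg: WindowConfig) -> CoordinationFeatureVector:
    """Coordination feature vector of a behavior matrix.

    For every ordered channel pair (i, j), mu = mean and sigma = population
    standard deviation of the per-window maxima.  Output length is
    ``2 * C**2``; ordering is all mu features (row-major in (i, j)) followed
    by all sigma features.
    """
    maxima = _pairwise_window_maxima(Y.values, cfg)  # (n_windows, C, C)
    mu = maxima.mean(axis=0)
    sigma = maxima.std(axis=0)  # ddof 0: a single window gives sigma = 0
    values = np.concatenate([mu.ravel(), sigma.ravel()])
    return CoordinationFeatureVector(values, feature_names(Y.channel_descriptors), cfg)


def feature_names(channels: tuple[str, ...] | list[str]) -> tuple[str, ...]:
    """Deterministic feature-name order matching :func:`extract_features`."""
    pairs = [f"({a}->{b})" for a in channels for b in channels]
    return tuple([f"mu{p}" for p in pairs] + [f"sigma{p}" for p in pairs])
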