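"""Activation maps and automated region-of-interest extraction.

The active cortical territory is located from the stimulus data itself: a
per-pixel activation map (mean fractional HbT over the stimulus window
minus the baseline-window mean) is thresholded at the spatial
mean + 1.5 × SD of the map, and the largest 8-connected component is kept,
yielding the area of cortex with the largest haemodynamic response. The
ROI-mean time series is the unweighted pixel average. User-drawn masks
(e.g. an arterial region) bypass the automatic rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import HaemSeries

__all__ = ["ActivationMap", "RoiMask", "activation_map", "auto_roi", "extract_timeseries"]


@dataclass
class ActivationMap:
    """Per-pixel stimulus-vs-baseline fractional HbT change."""

    values: np.ndarray
    stim_window: tuple[float, float]
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation map must be finite")


@dataclass
class RoiMask:
    """Binary pixel mask with its provenance (auto rule or user supplied)."""

    mask: np.ndarray
    k_sd: float | None = 1.5
    provenance: str = "auto"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def activation_map(
    h: HaemSeries,
    stim_window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> ActivationMap:
    """Mean fractional HbT over the stimulus window minus the baseline mean."""
    if h.hbt.ndim < 2:
        raise ValueError("activation_map needs a pixel-level series")
    frac = h.to_fractional()
    stim_idx = frac.window_index(stim_window)
    base_idx = frac.window_index(baseline_window)
    if not stim_idx.any() or not base_idx.any():
        raise ValueError("stimulus or baseline window contains no frames")
    if (stim_idx & base_idx).any():
        raise ValueError("stimulus and baseline windows overlap")
    values = frac.hbt[stim_idx].mean(axis=0) - frac.hbt[base_idx].mean(axis=0)
    return ActivationMap(values=values, stim_window=stim_window, baseline_window=baseline_window)


def auto_roi(amap: ActivationMap, k_sd: float = 1.5) -> RoiMask:
    """Threshold the map at spatial mean + k·SD; keep the largest 8-connected blob.

    The SD is the spatial standard deviation of the map's own pixel
    values, which makes the rule invariant to rescaling the map by any
    positive constant.
    """
    v = amap.values
    sd = v.std()
    if sd == 0:
        raise ValueError("activation map is constant (spatial SD = 0); no pixel exceeds the threshold")
    mask = v > v.mean() + k_sd * sd
    if not mask.any():
        raise ValueError(
            f"no pixel exceeds mean + {k_sd:g} x SD; lower k_sd or inspect the data"
        )
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    return RoiMask(mask=labels == largest, k_sd=k_sd, provenance="auto")


def extract_timeseries(h: HaemSeries, roi: RoiMask) -> HaemSeries:
    """Unweighted mean over ROI pixels per time point, per component."""
    return h.roi_mean(roi.mask)
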