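"""Core data containers shared across the pipeline.

All time series are stored time-major. Spatial dimensions are free: a
pixel-level series has shape ``(T, H, W)``, an ROI-level series ``(T,)``.
Haemoglobin series exist in two modes:

``absolute``
    Concentration *changes* from baseline, in µM. In this mode
    ``hbt == hbo + hbr`` holds exactly (conservation of total haemoglobin).
``fractional``
    Each component divided by its own baseline concentration, so the
    baseline level is 1.0. This is the form in which results are reported
    (a stimulus that raises blood volume by 5% gives a fractional HbT
    peak of 1.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BaselineState",
    "ReflectanceStack",
    "AttenuationSeries",
    "HaemSeries",
]


@dataclass(frozen=True)
class BaselineState:
    """Assumed resting state of the tissue.

    Parameters
    ----------
    c_hbt0 : float
        Baseline total haemoglobin concentration in µM. Default 100 µM.
    s0 : float
        Baseline oxygen saturation (fraction in (0, 1)). Default 0.70.
    """

    c_hbt0: float = 100.0
    s0: float = 0.70

    def __post_init__(self) -> None:
        if not self.c_hbt0 > 0:
            raise ValueError(f"c_hbt0 must be positive, got {self.c_hbt0}")
        if not 0.0 < self.s0 < 1.0:
            raise ValueError(f"s0 must lie in (0, 1), got {self.s0}")

    @property
    def c_hbo0(self) -> float:
        """Baseline oxyhaemoglobin concentration (µM)."""
        return self.s0 * self.c_hbt0

    @property
    def c_hbr0(self) -> float:
        """Baseline deoxyhaemoglobin concentration (µM)."""
        return (1.0 - self.s0) * self.c_hbt0


def _window_index(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError(f"window end must exceed start, got ({t0}, {t1})")
    return (times >= t0) & (times < t1)


@dataclass
class ReflectanceStack:
    """Multi-wavelength cortical reflectance movie.

    ``frames`` has shape ``(T, H, W, n_wavelengths)``; intensities are in
    arbitrary camera units and must be strictly positive wherever used.
    ``frame_rate`` is the rate at which complete wavelength sets are
    acquired (Hz). ``pixel_pitch_um`` is the physical size of one pixel.
    """

    frames: np.ndarray
    wavelengths_nm: np.ndarray
    frame_rate: float
    pixel_pitch_um: float = 75.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be (T, H, W, wavelength), got shape {self.frames.shape}"
            )
        if self.frames.shape[-1] != self.wavelengths_nm.size:
            raise ValueError(
                f"last frame axis ({self.frames.shape[-1]}) must match the "
                f"number of wavelengths ({self.wavelengths_nm.size})"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def window_index(self, window: tuple[float, float]) -> np.ndarray:
        return _window_index(self.times, window)


@dataclass
class AttenuationSeries:
    """Change in optical density (natural log) relative to a baseline window.

    ``values`` has shape ``(T, *spatial, n_wavelengths)``.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    frame_rate: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation values must be finite everywhere")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.frame_rate


@dataclass
class HaemSeries:
    """HbT / HbO / HbR time series, absolute (ΔµM) or fractional.

    ``hbt``, ``hbo``, ``hbr`` share a ``(T, *spatial)`` shape. ``meta``
    carries provenance such as PLSA iteration counts.
    """

    hbt: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    frame_rate: float
    mode: str = "fractional"
    baseline: BaselineState = field(default_factory=BaselineState)
    pixel_pitch_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbt = np.asarray(self.hbt, dtype=float)
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if not (self.hbt.shape == self.hbo.shape == self.hbr.shape):
            raise ValueError("hbt, hbo and hbr must share one shape")
        if self.mode not in ("absolute", "fractional"):
            raise ValueError(f"mode must be 'absolute' or 'fractional', got {self.mode!r}")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")

    # -- axes ---------------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.hbt.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.hbt.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def window_index(self, window: tuple[float, float]) -> np.ndarray:
        return _window_index(self.times, window)

    # -- mode conversion ----------------------------------------------------

    def to_fractional(self) -> "HaemSeries":
        if self.mode == "fractional":
            return self
        b = self.baseline
        return HaemSeries(
            hbt=(b.c_hbt0 + self.hbt) / b.c_hbt0,
            hbo=(b.c_hbo0 + self.hbo) / b.c_hbo0,
            hbr=(b.c_hbr0 + self.hbr) / b.c_hbr0,
            frame_rate=self.frame_rate,
            mode="fractional",
            baseline=b,
            pixel_pitch_um=self.pixel_pitch_um,
            meta=dict(self.meta),
        )

    def to_absolute(self) -> "HaemSeries":
        if self.mode == "absolute":
            return self
        b = self.baseline
        return HaemSeries(
            hbt=self.hbt * b.c_hbt0 - b.c_hbt0,
            hbo=self.hbo * b.c_hbo0 - b.c_hbo0,
            hbr=self.hbr * b.c_hbr0 - b.c_hbr0,
            frame_rate=self.frame_rate,
            mode="absolute",
            baseline=b,
            pixel_pitch_um=self.pixel_pitch_um,
            meta=dict(self.meta),
        )

    def saturation(self) -> np.ndarray:
        """Instantaneous oxygen saturation HbO/(HbO+HbR) per sample."""
        a = self.to_absolute()
        b = self.baseline
        hbt = b.c_hbt0 + a.hbt
        hbo = b.c_hbo0 + a.hbo
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(hbt > 0, hbo / hbt, b.s0)
        return s

    def roi_mean(self, mask: np.ndarray | None = None) -> "HaemSeries":
        """Collapse spatial axes to an unweighted mean, optionally over a mask."""
        if self.hbt.ndim == 1:
            return self
        if mask is None:
            axes = tuple(range(1, self.hbt.ndim))
            sel = lambda a: a.mean(axis=axes)  # noqa: E731
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.spatial_shape:
                raise ValueError(
                    f"mask shape {mask.shape} does not match spatial shape {self.spatial_shape}"
                )
            if not mask.any():
                raise ValueError("mask is empty")
            sel = lambda a: a[:, mask].mean(axis=1)  # noqa: E731
        return HaemSeries(
            hbt=sel(self.hbt),
            hbo=sel(self.hbo),
            hbr=sel(self.hbr),
            frame_rate=self.frame_rate,
            mode=self.mode,
            baseline=self.baseline,
            pixel_pitch_um=self.pixel_pitch_um,
            meta=dict(self.meta),
        )
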