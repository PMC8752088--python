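"""Synthetic forward models with known ground truth.

Every downstream stage of the pipeline (spectral inversion, ROI
extraction, evoked and spreading-depression metrics, multi-unit activity,
coupling regression) is validated against data produced here: a
haemodynamic field with a configurable evoked kernel or a radially
propagating spreading-depression wave, rendered into multi-wavelength
reflectance through the same modified Beer-Lambert physics the inversion
assumes (plus multiplicative shot-like noise), and a multichannel
extracellular voltage generator with Poisson spiking whose event times are
returned alongside the traces.

All generators are pure functions of (configuration, seed): identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BaselineState, HaemSeries, ReflectanceStack
from .mua import ElectrodeRecording
from .spectra import INSTRUMENT_WAVELENGTHS_NM, SpectraTables

__all__ = [
    "SimConfig",
    "EvokedKernelParams",
    "CSDParams",
    "NeuralSimParams",
    "disc_mask",
    "evoked_kernel",
    "simulate_evoked_field",
    "simulate_csd_field",
    "render_reflectance",
    "simulate_electrode",
]


@dataclass(frozen=True)
class SimConfig:
    """Imaging-side simulation configuration.

    Defaults emulate the study conditions: 64x64 pixel field of view,
    4-wavelength illumination cycled at 5 Hz, 1% multiplicative
    reflectance noise.
    """

    grid: tuple[int, int] = (64, 64)
    pixel_pitch_um: float = 75.0
    frame_rate: float = 5.0
    duration: float = 60.0
    wavelengths_nm: tuple = INSTRUMENT_WAVELENGTHS_NM
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 1 or self.pixel_pitch_um <= 0 or self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("grid, pixel_pitch_um, frame_rate and duration must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(int(round(self.duration * self.frame_rate))) / self.frame_rate


@dataclass(frozen=True)
class EvokedKernelParams:
    """Shape of the stimulus-evoked haemodynamic response.

    HbT rises along a gamma-variate to ``1 + peak_fraction`` at
    ``onset_delay + time_to_peak`` after stimulus onset, holds a plateau
    for long stimuli, then decays with a post-stimulus undershoot.
    Deoxyhaemoglobin washes out (falls) in proportion
    ``hbr_washout_ratio`` to the HbT rise; in ``triphasic`` mode an early
    positive HbR bump of ``triphasic_bump_fraction`` (of the HbR baseline)
    precedes the washout, the waveform shape reported in the comorbid
    model.
    """

    onset_delay: float = 0.2
    time_to_peak: float = 3.0
    peak_fraction: float = 0.05
    undershoot_fraction: float = 0.01
    stimulus_duration: float = 2.0
    hbr_mode: str = "biphasic"
    triphasic_bump_fraction: float = 0.0
    hbr_washout_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be positive")
        if self.hbr_mode not in ("biphasic", "triphasic"):
            raise ValueError(f"hbr_mode must be 'biphasic' or 'triphasic', got {self.hbr_mode!r}")
        if self.hbr_mode == "triphasic" and not self.triphasic_bump_fraction > 0:
            raise ValueError("triphasic mode requires triphasic_bump_fraction > 0")


@dataclass(frozen=True)
class CSDParams:
    """Spreading-depression wave: dip -> rebound -> prolonged undershoot.

    ``dip_fraction``, ``rebound_fraction`` and ``undershoot_fraction`` are
    fractional HbT levels (1.0 = baseline); the wave reaches a pixel at
    distance d from ``origin`` after d/speed. The undershoot decays back
    toward baseline with time constant ``undershoot_decay_tau``.
    ``hbo_share`` is dΔ[HbO]/dΔ[HbT]; values slightly above 1 make the
    tissue desaturate during the constriction (HbR rises as HbT falls),
    the hypoxic signature of the wave.
    """

    origin: tuple[int, int] = (32, 32)
    speed_mm_per_min: float = 3.0
    dip_fraction: float = 0.70
    rebound_fraction: float = 1.15
    undershoot_fraction: float = 0.90
    undershoot_decay_tau: float = 400.0
    hbo_share: float = 1.05
    t_dip: float = 15.0
    dip_width: float = 8.0
    t_rebound: float = 45.0
    rebound_width: float = 15.0
    t_undershoot: float = 80.0

    def __post_init__(self) -> None:
        if not self.speed_mm_per_min > 0:
            raise ValueError("speed must be positive")
        if not self.dip_fraction < 1.0:
            raise ValueError("dip_fraction must be below 1.0 (a constriction)")


@dataclass(frozen=True)
class NeuralSimParams:
    """Multichannel extracellular recording generator settings.

    Defaults emulate a 16-channel laminar probe at 100 µm spacing sampled
    at 25 kHz, with ~10 background multi-unit events/s/channel doubling
    during whisker stimulation. The default spike amplitude (60 noise-SDs)
    deliberately places the mean + 1.5 SD crossing counter in its
    spike-dominated operating regime: the baseline SD of the filtered
    trace is then inflated by the spikes themselves, pushing the threshold
    several noise-SDs up, where the Gaussian level-crossing (Rice) rate is
    negligible next to the event rate. Small ratios instead probe the
    noise-dominated false-positive regime.
    """

    n_channels: int = 16
    channel_spacing_um: float = 100.0
    sampling_rate: float = 25000.0
    baseline_rate: float = 10.0
    evoked_gain: float = 2.0
    spike_amplitude_sd_ratio: float = 60.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        if self.evoked_gain < 0:
            raise ValueError("evoked_gain must be non-negative")


def disc_mask(grid: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Binary disc in pixel coordinates (row, col)."""
    rr, cc = np.ogrid[: grid[0], : grid[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# evoked field
# ---------------------------------------------------------------------------

_GAMMA_SHAPE = 3.0  # rise-phase gamma-variate shape


def _raw_kernel(fine: np.ndarray, p: EvokedKernelParams) -> np.ndarray:
    """Unnormalised smooth response kernel on a fine uniform grid.

    A gamma-variate impulse response convolved with the stimulus boxcar
    (so long stimuli plateau), minus a delayed, wider gamma-variate
    undershoot lobe. Everything is C1-smooth, which keeps peak-time
    estimation on noisy traces well behaved.
    """
    tp = p.time_to_peak
    dt = fine[1] - fine[0]
    x = fine / tp
    g = (x**_GAMMA_SHAPE) * np.exp(_GAMMA_SHAPE * (1.0 - x))
    n_box = max(int(round(p.stimulus_duration / dt)), 1)
    resp = np.convolve(g, np.ones(n_box) / n_box)[: fine.size]
    resp /= resp.max()
    # undershoot depth relative to the peak; a null response has no undershoot
    u = p.undershoot_fraction / p.peak_fraction if p.peak_fraction > 0 else 0.0
    xu = fine / (3.0 * tp)
    g_u = (xu**2) * np.exp(2.0 * (1.0 - xu))
    return resp - u * g_u


def evoked_kernel(t: np.ndarray, p: EvokedKernelParams) -> np.ndarray:
    """Normalised evoked kernel: maximum exactly 1 at t = onset_delay + time_to_peak.

    The raw curve is evaluated on a fine internal grid, its maximum
    located, and — for stimuli no longer than the rise time — the time
    axis is rescaled so that the peak lands exactly on ``time_to_peak``
    with unit height; the requested times are then read off by
    interpolation. Long stimuli keep their natural time base (the
    response ramps to a sustained plateau and peaks near stimulus end),
    normalised to unit height.
    """
    t = np.asarray(t, dtype=float)
    tp = p.time_to_peak
    plateau = max(0.0, p.stimulus_duration - tp)
    span = 3.0 * tp + 2.0 * p.stimulus_duration + 90.0
    fine = np.linspace(0.0, span, 8192)
    raw = _raw_kernel(fine, p)
    i_max = int(np.argmax(raw))
    t_max, v_max = fine[i_max], raw[i_max]
    scale = t_max / tp if (t_max > 0 and plateau == 0.0) else 1.0
    shifted = (t - p.onset_delay) * scale
    out = np.interp(shifted, fine, raw, left=0.0, right=0.0) / v_max
    return out


def _bump_kernel(t: np.ndarray, p: EvokedKernelParams) -> np.ndarray:
    """Early positive HbR deflection for triphasic mode (peak 1).

    Centred early in the HbT rise and lasting one to two seconds at the
    default kinetics, so the initial HbR rise clearly precedes the
    washout minimum.
    """
    t0 = p.onset_delay
    tc = 0.4 * p.time_to_peak
    w = 0.35 * p.time_to_peak
    out = np.exp(-(((t - t0 - tc) / w) ** 2))
    out[t < t0] = 0.0
    return out


def simulate_evoked_field(
    cfg: SimConfig,
    kernel: EvokedKernelParams,
    active_region: np.ndarray,
    stimulus_onsets,
    baseline: BaselineState | None = None,
    onset_scales=None,
) -> HaemSeries:
    """Ground-truth pixel-level haemodynamic field for a stimulation run.

    Returns an absolute-mode (ΔµM) :class:`HaemSeries`; inside
    ``active_region`` HbT follows the evoked kernel scaled to
    ``peak_fraction``, outside it stays at baseline. ``onset_scales``
    optionally multiplies the response amplitude per trial (shared
    trial-to-trial drive for coupling simulations). Conservation
    Δ[HbT] = Δ[HbO] + Δ[HbR] holds by construction.
    """
    baseline = baseline or BaselineState()
    active_region = np.asarray(active_region, dtype=bool)
    if active_region.shape != cfg.grid:
        raise ValueError(f"active_region shape {active_region.shape} != grid {cfg.grid}")
    onsets = np.sort(np.asarray(stimulus_onsets, dtype=float))
    if onset_scales is None:
        onset_scales = np.ones(onsets.size)
    onset_scales = np.asarray(onset_scales, dtype=float)
    if onset_scales.size != onsets.size:
        raise ValueError("onset_scales must have one entry per stimulus onset")
    if onsets.size >= 2:
        gaps = np.diff(onsets)
        if np.any(gaps < kernel.stimulus_duration):
            raise ValueError("overlapping stimulus windows: onsets closer than stimulus_duration")
    t = cfg.times
    k = np.zeros_like(t)
    for onset, sc in zip(onsets, onset_scales):
        k += sc * evoked_kernel(t - onset, kernel)

    dhbt_t = baseline.c_hbt0 * kernel.peak_fraction * k  # µM, (T,)
    dhbr_t = -kernel.hbr_washout_ratio * dhbt_t
    if kernel.hbr_mode == "triphasic":
        bump = np.zeros_like(t)
        for onset, sc in zip(onsets, onset_scales):
            bump += sc * _bump_kernel(t - onset, kernel)
        dhbr_t = dhbr_t + kernel.triphasic_bump_fraction * baseline.c_hbr0 * bump
    dhbo_t = dhbt_t - dhbr_t

    shape = (t.size,) + cfg.grid
    region = active_region[np.newaxis, :, :]
    hbt = np.where(region, dhbt_t[:, None, None], 0.0).reshape(shape)
    hbo = np.where(region, dhbo_t[:, None, None], 0.0).reshape(shape)
    hbr = np.where(region, dhbr_t[:, None, None], 0.0).reshape(shape)
    return HaemSeries(
        hbt=hbt,
        hbo=hbo,
        hbr=hbr,
        frame_rate=cfg.frame_rate,
        mode="absolute",
        baseline=baseline,
        pixel_pitch_um=cfg.pixel_pitch_um,
        meta={"truth": "evoked", "onsets": onsets.tolist()},
    )


# ---------------------------------------------------------------------------
# spreading-depression field
# ---------------------------------------------------------------------------

def csd_profile(t_local: np.ndarray, csd: CSDParams) -> np.ndarray:
    """Fractional HbT deviation profile at wavefront-local time (0 = arrival).

    Continuous at arrival: the small Gaussian-tail offset at t = 0 is
    subtracted with a fast-decaying correction so the profile starts at
    exactly zero deviation.
    """
    t = np.asarray(t_local, dtype=float)

    def raw(tt):
        dip = -(1.0 - csd.dip_fraction) * np.exp(-(((tt - csd.t_dip) / csd.dip_width) ** 2))
        reb = (csd.rebound_fraction - 1.0) * np.exp(-(((tt - csd.t_rebound) / csd.rebound_width) ** 2))
        gate = 0.5 * (1.0 + np.tanh((tt - csd.t_undershoot) / 20.0))
        decay = np.exp(-np.maximum(tt - csd.t_undershoot, 0.0) / csd.undershoot_decay_tau)
        under = -(1.0 - csd.undershoot_fraction) * gate * decay
        return dip + reb + under

    dev = raw(t) - raw(np.zeros(())) * np.exp(-np.maximum(t, 0.0) / 5.0)
    return np.where(t >= 0.0, dev, 0.0)


def simulate_csd_field(
    cfg: SimConfig,
    csd: CSDParams,
    t_insert: float = 0.0,
    baseline: BaselineState | None = None,
) -> HaemSeries:
    """Radially propagating spreading-depression haemodynamic field.

    Each pixel at distance d (mm) from the origin runs the
    dip-rebound-undershoot profile delayed by d/speed after the electrode
    insertion time. Returns an absolute-mode pixel-level series.
    """
    baseline = baseline or BaselineState()
    if not (0 <= csd.origin[0] < cfg.grid[0] and 0 <= csd.origin[1] < cfg.grid[1]):
        raise ValueError(f"origin {csd.origin} outside grid {cfg.grid}")
    rr, cc = np.ogrid[: cfg.grid[0], : cfg.grid[1]]
    dist_mm = (
        np.sqrt((rr - csd.origin[0]) ** 2 + (cc - csd.origin[1]) ** 2)
        * cfg.pixel_pitch_um
        / 1000.0
    )
    delay_s = dist_mm / (csd.speed_mm_per_min / 60.0)
    t = cfg.times
    t_local = t[:, None, None] - t_insert - delay_s[None, :, :]
    dev = csd_profile(t_local, csd)

    dhbt = baseline.c_hbt0 * dev
    dhbo = csd.hbo_share * dhbt
    dhbr = dhbt - dhbo
    return HaemSeries(
        hbt=dhbt,
        hbo=dhbo,
        hbr=dhbr,
        frame_rate=cfg.frame_rate,
        mode="absolute",
        baseline=baseline,
        pixel_pitch_um=cfg.pixel_pitch_um,
        meta={"truth": "csd", "t_insert": float(t_insert), "delay_s": delay_s},
    )


# ---------------------------------------------------------------------------
# reflectance renderer
# ---------------------------------------------------------------------------

def render_reflectance(
    truth: HaemSeries,
    spectra: SpectraTables,
    baseline: BaselineState | None = None,
    cfg: SimConfig | None = None,
    i0: float = 1.0,
    saturation_mode: str = "dynamic",
) -> ReflectanceStack:
    """Forward-model a ground-truth field into a noisy reflectance stack.

    ``I(λ,t,px) = I0 · exp(−L(λ,S)·[ε_HbO·Δc_HbO + ε_HbR·Δc_HbR]) · (1+n)``
    with n ~ N(0, noise_sigma) multiplicative noise drawn from the seeded
    generator. ``saturation_mode='dynamic'`` evaluates the pathlength at
    the instantaneous ground-truth saturation; ``'baseline'`` freezes it at
    S0 (a linearised forward model).
    """
    if truth.mode != "absolute":
        raise ValueError("render_reflectance requires an absolute-mode (ΔµM) truth series")
    baseline = baseline or truth.baseline
    cfg = cfg or SimConfig(grid=truth.spatial_shape, frame_rate=truth.frame_rate)
    if saturation_mode == "dynamic":
        S = truth.saturation()
    elif saturation_mode == "baseline":
        S = np.full(truth.hbt.shape, baseline.s0)
    else:
        raise ValueError("saturation_mode must be 'dynamic' or 'baseline'")
    Lmat = spectra.pathlength(S)  # (..., n_wavelengths)
    dA = Lmat * (
        spectra.eps_hbo * truth.hbo[..., None] * 1e-6
        + spectra.eps_hbr * truth.hbr[..., None] * 1e-6
    )
    frames = i0 * np.exp(-dA)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        frames = frames * (1.0 + rng.normal(0.0, cfg.noise_sigma, frames.shape))
    return ReflectanceStack(
        frames=frames,
        wavelengths_nm=spectra.wavelengths_nm,
        frame_rate=truth.frame_rate,
        pixel_pitch_um=truth.pixel_pitch_um or cfg.pixel_pitch_um,
        meta={"noise_sigma": cfg.noise_sigma, "seed": cfg.seed, "log_base": "natural"},
    )


# ---------------------------------------------------------------------------
# electrophysiology generator
# ---------------------------------------------------------------------------

_SPIKE_DUR_S = 1.2e-3  # stereotyped biphasic spike duration
_SPIKE_BANDWIDTH_HZ = 2.5e3


def _spike_waveform(sampling_rate: float) -> np.ndarray:
    """Stereotyped biphasic extracellular spike, peak amplitude 1."""
    n = max(int(round(_SPIKE_DUR_S * sampling_rate)), 4)
    t = np.arange(n) / sampling_rate
    w = np.sin(2.0 * np.pi * t / _SPIKE_DUR_S) * np.exp(-3.0 * t / _SPIKE_DUR_S)
    return w / np.max(np.abs(w))


def simulate_electrode(
    duration: float,
    p: NeuralSimParams,
    stimulus_onsets,
    stimulus_duration: float,
    seed: int = 0,
    window_gains=None,
) -> tuple[ElectrodeRecording, list[np.ndarray]]:
    """Multichannel voltage traces with Poisson spiking and known event times.

    Background is white Gaussian noise per channel; event times follow an
    inhomogeneous Poisson process at ``baseline_rate``, multiplied by
    ``evoked_gain`` inside stimulus windows; each event adds the
    stereotyped biphasic waveform scaled to
    ``spike_amplitude_sd_ratio × noise SD``. ``window_gains`` optionally
    scales the evoked rate per stimulus window (shared trial-to-trial
    drive for coupling simulations). Returns the recording and the
    ground-truth event times per channel.
    """
    if p.sampling_rate < 2.0 * _SPIKE_BANDWIDTH_HZ:
        raise ValueError(
            f"sampling_rate {p.sampling_rate:g} Hz is below twice the spike "
            f"bandwidth ({_SPIKE_BANDWIDTH_HZ:g} Hz)"
        )
    onsets = np.sort(np.asarray(stimulus_onsets, dtype=float))
    if window_gains is None:
        window_gains = np.ones(onsets.size)
    window_gains = np.asarray(window_gains, dtype=float)
    if window_gains.size != onsets.size:
        raise ValueError("window_gains must have one entry per stimulus onset")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * p.sampling_rate))
    waveform = _spike_waveform(p.sampling_rate) * p.spike_amplitude_sd_ratio * p.noise_sd
    peak_gain = float(window_gains.max()) if window_gains.size else 0.0
    rate_max = p.baseline_rate * max(p.evoked_gain * peak_gain, 1.0)

    def local_rate(times: np.ndarray) -> np.ndarray:
        rate = np.full(times.shape, p.baseline_rate)
        for onset, g in zip(onsets, window_gains):
            hit = (times >= onset) & (times < onset + stimulus_duration)
            rate[hit] = p.baseline_rate * p.evoked_gain * g
        return rate

    traces = rng.normal(0.0, p.noise_sd, (p.n_channels, n_samples))
    event_times: list[np.ndarray] = []
    for ch in range(p.n_channels):
        # thinning of a homogeneous process at rate_max
        n_cand = rng.poisson(rate_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        keep = rng.uniform(0.0, rate_max, n_cand) < local_rate(cand)
        times = cand[keep]
        event_times.append(times)
        idx = np.round(times * p.sampling_rate).astype(int)
        for i in idx:
            j = min(i + waveform.size, n_samples)
            traces[ch, i:j] += waveform[: j - i]
    rec = ElectrodeRecording(
        traces=traces,
        sampling_rate=p.sampling_rate,
        channel_spacing_um=p.channel_spacing_um,
    )
    return rec, event_times
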