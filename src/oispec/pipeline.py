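"""Config-driven orchestration of the full analysis.

A single YAML (or dict) configuration describes either a synthetic
session (evoked stimulation or an electrode-insertion spreading
depression, plus the electrophysiology generator) or paths to recorded
inputs, together with every analysis parameter. ``run_pipeline`` executes
the stages in dependency order — spectral conversion, ROI extraction,
evoked metrics or CSD quantification, MUA binning, coupling regression —
writes tables and series under the output directory, and returns a
summary dict that is also written as ``summary.json`` stamped with the
config hash. A rerun with the same config and seed is bit-identical for
simulated inputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as oio
from .containers import BaselineState
from .coupling import build_pairs, fit_line
from .csd import detect_csd, wavefront_speed
from .evoked import TrialSet, classify_hbr, summarise_evoked, trial_average
from .mua import CORTICAL_CHANNELS, HEATMAP_CHANNELS, bin_threshold, depth_select, highpass
from .roi import RoiMask, activation_map, auto_roi, extract_timeseries
from .simulate import (
    CSDParams,
    EvokedKernelParams,
    NeuralSimParams,
    SimConfig,
    disc_mask,
    render_reflectance,
    simulate_csd_field,
    simulate_electrode,
)
from .spectra import compute_attenuation, default_spectra, load_pathlength_tsv, plsa_refine, unmix
from .simulate import simulate_evoked_field

__all__ = ["load_config", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger("oispec.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "mode": "evoked",  # evoked | csd
    "simulate": {
        "grid": [64, 64],
        "pixel_pitch_um": 75.0,
        "frame_rate": 5.0,
        "duration": None,  # derived from trials when absent
        "noise_sigma": 0.01,
        "trial_gain_sd": 0.2,
        "active_center": [32, 32],
        "active_radius": 10.0,
        "kernel": {},  # EvokedKernelParams overrides
        "csd": {},  # CSDParams overrides
        "neural": {},  # NeuralSimParams overrides
    },
    "inputs": {"stack": None, "ephys": None},
    "baseline": {"c_hbt0": 100.0, "s0": 0.70},
    "spectra": {"wavelengths_nm": [494.0, 560.0, 575.0, 595.0], "pathlength_tsv": None},
    "windows": {"baseline": [0.0, 4.0]},
    "trials": {"n_trials": 30, "stim_duration": 2.0, "first_onset": 10.0, "period": 25.0,
               "pre_window": 4.0, "post_window": 20.0},
    "unmix": {"method": "plsa", "tol": 1e-4, "max_iter": 20},
    "roi": {"k_sd": 1.5, "mask_png": None},
    "mua": {"hp_cutoff": 500.0, "bin_width": 0.1, "threshold_k": 1.5,
            "baseline_window": [0.0, 8.0]},
    # insertion after a 30 s pre-insertion baseline, as in an acute session
    "csd_analysis": {"t_insert": 30.0, "dip_threshold": 0.05, "late_window": [625.0, 1250.0]},
    "plots": False,
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return validate_config(user)


def validate_config(user: dict) -> dict:
    """Merge with defaults and fail fast on inconsistent settings."""
    cfg = _deep_update(DEFAULT_CONFIG, user)
    if cfg["mode"] not in ("evoked", "csd"):
        raise ValueError(f"mode must be 'evoked' or 'csd', got {cfg['mode']!r}")
    if cfg["inputs"]["stack"] is None and cfg["simulate"] is None:
        raise ValueError("config needs either inputs.stack or a simulate block")
    if not cfg["spectra"].get("wavelengths_nm"):
        raise ValueError("spectra.wavelengths_nm must be set")
    b = cfg["baseline"]
    BaselineState(b["c_hbt0"], b["s0"])  # raises on bad values
    t = cfg["trials"]
    if cfg["mode"] == "evoked" and t["n_trials"] < 1:
        raise ValueError("trials.n_trials must be >= 1")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _trial_onsets(cfg: dict) -> np.ndarray:
    t = cfg["trials"]
    return t["first_onset"] + t["period"] * np.arange(t["n_trials"])


def _simulate_stack(cfg: dict):
    s = cfg["simulate"]
    b = cfg["baseline"]
    baseline = BaselineState(b["c_hbt0"], b["s0"])
    trials = cfg["trials"]
    if cfg["mode"] == "evoked":
        onsets = _trial_onsets(cfg)
        duration = s["duration"] or float(onsets[-1] + trials["period"])
        kernel = EvokedKernelParams(
            stimulus_duration=trials["stim_duration"], **s["kernel"]
        )
    else:
        ca = cfg["csd_analysis"]
        duration = s["duration"] or float(ca["t_insert"] + ca["late_window"][1] + 50.0)
        kernel = None
    sim = SimConfig(
        grid=tuple(s["grid"]),
        pixel_pitch_um=s["pixel_pitch_um"],
        frame_rate=s["frame_rate"],
        duration=duration,
        wavelengths_nm=tuple(cfg["spectra"]["wavelengths_nm"]),
        noise_sigma=s["noise_sigma"],
        seed=int(cfg["seed"]),
    )
    spectra = _spectra(cfg)
    scales = None
    if cfg["mode"] == "evoked":
        # one shared per-trial drive scales both the haemodynamic response
        # and (via window_gains) the evoked neural rate
        gain_sd = float(s.get("trial_gain_sd") or 0.0)
        onsets = _trial_onsets(cfg)
        if gain_sd > 0:
            rng = np.random.default_rng(int(cfg["seed"]) + 2)
            scales = np.clip(rng.normal(1.0, gain_sd, onsets.size), 0.1, None)
        region = disc_mask(sim.grid, tuple(s["active_center"]), s["active_radius"])
        truth = simulate_evoked_field(sim, kernel, region, onsets, baseline, onset_scales=scales)
    else:
        csd = CSDParams(**({"origin": tuple(s["active_center"])} | s["csd"]))
        truth = simulate_csd_field(sim, csd, cfg["csd_analysis"]["t_insert"], baseline)
        region = None
    stack = render_reflectance(truth, spectra, baseline, sim)
    return stack, truth, region, sim, scales


def _spectra(cfg: dict):
    spc = cfg["spectra"]
    if spc.get("pathlength_tsv"):
        return load_pathlength_tsv(spc["pathlength_tsv"]).subset(spc["wavelengths_nm"])
    return default_spectra(tuple(spc["wavelengths_nm"]), c_ref_uM=cfg["baseline"]["c_hbt0"])


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute all stages for the given validated config; return the summary."""
    cfg = validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"config_hash": chash, "mode": cfg["mode"], "seed": cfg["seed"]}
    try:
        log.info("config hash %s; full config: %s", chash, json.dumps(cfg, sort_keys=True, default=str))
        baseline = BaselineState(cfg["baseline"]["c_hbt0"], cfg["baseline"]["s0"])
        spectra = _spectra(cfg)

        # --- stage: acquire -------------------------------------------------
        if cfg["inputs"]["stack"]:
            p = str(cfg["inputs"]["stack"])
            stack = oio.read_stack_tiff(p) if p.endswith((".tif", ".tiff")) else oio.read_stack_h5(p)
            truth = region = trial_scales = None
        else:
            stack, truth, region, _sim, trial_scales = _simulate_stack(cfg)
        log.info("stage acquire: %d frames, %d wavelengths", stack.n_frames, stack.wavelengths_nm.size)

        # --- stage: spectral conversion ------------------------------------
        atten = compute_attenuation(stack, tuple(cfg["windows"]["baseline"]))
        u = cfg["unmix"]
        if u["method"] == "plsa":
            haem = plsa_refine(atten, spectra, baseline, tol=u["tol"], max_iter=u["max_iter"],
                               pixel_pitch_um=stack.pixel_pitch_um)
        else:
            haem = unmix(atten, spectra, baseline, pixel_pitch_um=stack.pixel_pitch_um)
        summary["unmix"] = dict(haem.meta)
        log.info("stage unmix: %s", haem.meta)

        trials = cfg["trials"]
        onsets = _trial_onsets(cfg)
        if cfg["mode"] == "evoked":
            # --- stage: ROI --------------------------------------------------
            stim_win = (float(onsets[0]), float(onsets[0] + trials["stim_duration"] + 3.0))
            amap = activation_map(haem, stim_win, tuple(cfg["windows"]["baseline"]))
            if cfg["roi"].get("mask_png"):
                roi = RoiMask(oio.read_mask_png(cfg["roi"]["mask_png"]), k_sd=None, provenance="user")
            else:
                roi = auto_roi(amap, k_sd=cfg["roi"]["k_sd"])
            roi_series = extract_timeseries(haem, roi)
            oio.write_roi_csv(out / "roi_series.csv", roi_series)
            oio.write_haem_h5(out / "haem_roi.h5", roi_series)
            summary["roi"] = {"n_pixels": roi.n_pixels, "provenance": roi.provenance}
            if truth is not None and region is not None:
                inter = np.logical_and(roi.mask, region).sum()
                union = np.logical_or(roi.mask, region).sum()
                summary["roi"]["jaccard_vs_truth"] = float(inter / union)
            log.info("stage roi: %s", summary["roi"])

            # --- stage: evoked metrics --------------------------------------
            tset = TrialSet(
                onsets=tuple(onsets),
                stim_duration=trials["stim_duration"],
                pre_window=trials["pre_window"],
                post_window=trials["post_window"],
            )
            trace = trial_average(roi_series, tset)
            summary["evoked"] = {}
            for comp, signed in (("hbt", False), ("hbo", False), ("hbr", True)):
                es = summarise_evoked(trace.times, getattr(trace, comp), tset.stim_duration, signed=signed)
                summary["evoked"][comp] = {
                    "peak": es.peak, "time_to_peak": es.time_to_peak,
                    "rise_time": es.rise_time, "auc": es.auc,
                }
            summary["evoked"]["hbr_class"] = classify_hbr(trace.times, trace.hbr)
            log.info("stage evoked: %s", summary["evoked"])
        else:
            # --- stage: CSD --------------------------------------------------
            # ROI: disc around the insertion site, so propagation delay does
            # not smear the dip below the late undershoot
            sblk = cfg["simulate"]
            center = tuple((cfg["csd_analysis"].get("origin") or sblk["active_center"]))
            roi_series = haem.roi_mean(disc_mask(haem.spatial_shape, center, sblk["active_radius"]))
            oio.write_roi_csv(out / "roi_series.csv", roi_series)
            ca = cfg["csd_analysis"]
            event = detect_csd(roi_series, t_insert=ca["t_insert"],
                               dip_threshold=ca["dip_threshold"],
                               late_window=tuple(ca["late_window"]))
            if event is None:
                summary["csd"] = None
            else:
                origin = ca.get("origin") or cfg["simulate"]["active_center"]
                event = wavefront_speed(haem, event, origin=tuple(origin))
                summary["csd"] = {
                    "t_onset": event.t_onset,
                    "dip_value": event.dip_value,
                    "rebound_value": event.rebound_value,
                    "undershoot_mean": event.undershoot_mean,
                    "recovery_time": event.recovery_time,
                    "speed_mm_per_min": event.speed_mm_per_min,
                    "speed_r2": event.speed_r2,
                    "speed_flag": event.speed_flag,
                    "truncated": event.truncated,
                }
            log.info("stage csd: %s", summary["csd"])

        # --- stage: MUA ------------------------------------------------------
        if cfg["inputs"]["ephys"]:
            rec = oio.read_ephys_h5(cfg["inputs"]["ephys"])
        elif cfg["mode"] == "evoked":
            p = NeuralSimParams(**cfg["simulate"]["neural"])
            rec, _truth_events = simulate_electrode(
                duration=float(onsets[-1] + trials["period"]),
                p=p,
                stimulus_onsets=onsets,
                stimulus_duration=trials["stim_duration"],
                seed=int(cfg["seed"]) + 1,
                window_gains=trial_scales,
            )
        else:
            rec = None
        if rec is not None:
            m = cfg["mua"]
            filt = highpass(rec, cutoff=m["hp_cutoff"])
            mua = bin_threshold(filt, tuple(m["baseline_window"]),
                                bin_width=m["bin_width"], k=m["threshold_k"])
            cortical = depth_select(mua, CORTICAL_CHANNELS) if mua.n_channels >= 12 else mua
            oio.write_mua_csv(out / "mua.csv", cortical)
            heat = depth_select(mua, HEATMAP_CHANNELS) if mua.n_channels >= 9 else cortical
            np.savetxt(out / "mua_heatmap.csv", heat.fractional, delimiter=",")
            summary["mua"] = {
                "n_channels": cortical.n_channels,
                "mean_baseline_count": float(cortical.counts.mean(axis=1).mean()),
            }
            log.info("stage mua: %s", summary["mua"])

            # --- stage: coupling --------------------------------------------
            if cfg["mode"] == "evoked":
                tset = TrialSet(onsets=tuple(onsets), stim_duration=trials["stim_duration"],
                                pre_window=trials["pre_window"], post_window=trials["post_window"])
                table = build_pairs(cortical, roi_series, tset)
                table.to_csv(out / "coupling_table.csv", index=False)
                fit = fit_line(table)
                summary["coupling"] = {
                    "slope": fit.slope, "intercept": fit.intercept,
                    "r_squared": fit.r_squared, "n_trials": fit.n,
                }
                log.info("stage coupling: %s", summary["coupling"])

        if cfg.get("plots"):
            _write_plots(out, cfg, locals())
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_plots(out: Path, cfg: dict, ns: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roi_series = ns.get("roi_series")
    if roi_series is not None:
        frac = roi_series.to_fractional()
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.plot(frac.times, frac.hbt, label="HbT", color="tab:green")
        ax.plot(frac.times, frac.hbo, label="HbO", color="tab:red")
        ax.plot(frac.times, frac.hbr, label="HbR", color="tab:blue")
        ax.axhline(1.0, color="k", lw=0.5)
        ax.set(xlabel="time (s)", ylabel="fractional change", title="ROI haemodynamics")
        ax.legend()
        fig.savefig(out / "roi_series.png", dpi=120)
        plt.close(fig)
    amap = ns.get("amap")
    if amap is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(amap.values, cmap="inferno")
        fig.colorbar(im, ax=ax, label="fractional HbT change")
        ax.set_title("activation map")
        fig.savefig(out / "activation_map.png", dpi=120)
        plt.close(fig)
    mua = ns.get("cortical")
    if mua is not None:
        fig, ax = plt.subplots(figsize=(8, 3))
        im = ax.imshow(mua.fractional, aspect="auto", cmap="viridis",
                       extent=[mua.bin_starts[0], mua.bin_starts[-1], mua.n_channels, 0])
        fig.colorbar(im, ax=ax, label="fractional MUA")
        ax.set(xlabel="time (s)", ylabel="channel", title="MUA depth profile")
        fig.savefig(out / "mua_heatmap.png", dpi=120)
        plt.close(fig)
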