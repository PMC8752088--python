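"""Trial-wise neurovascular-coupling regression.

Neurovascular coupling is assessed on trial-by-trial data: for every
stimulation trial the peak fractional multi-unit activity within the
stimulus window is paired with the peak fractional HbT within the
stimulus-plus-post window, and an ordinary least-squares line
``HbT_peak = slope · MUA_peak + intercept`` is fitted with its R²
(squared Pearson correlation). Reduced HbT per unit of evoked MUA is the
signature of coupling breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import HaemSeries
from .evoked import TrialSet
from .mua import MUASeries

__all__ = ["CouplingFit", "build_pairs", "fit_line"]


@dataclass(frozen=True)
class CouplingFit:
    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float
    n: int

    def ci95_slope(self) -> tuple[float, float]:
        """95% confidence interval of the slope (t distribution, n-2 dof)."""
        tcrit = stats.t.ppf(0.975, self.n - 2)
        return (self.slope - tcrit * self.stderr_slope, self.slope + tcrit * self.stderr_slope)


def build_pairs(
    mua: MUASeries,
    haem: HaemSeries,
    trials: TrialSet,
    condition: str = "",
    post_window: float | None = None,
) -> pd.DataFrame:
    """One row per trial: peak fractional MUA vs peak fractional HbT.

    The MUA peak is taken over the stimulus window [onset, onset + stim]
    on the channel-pooled fractional series; the HbT peak over
    [onset, onset + stim + post]. Both modalities must share the trial
    structure (the same onsets on a common clock).
    """
    frac_h = haem.to_fractional()
    if frac_h.hbt.ndim != 1:
        raise ValueError("build_pairs expects an ROI-level haemodynamic series")
    post = trials.post_window if post_window is None else post_window
    pooled = mua.pooled_fractional()
    bin_t = mua.bin_starts
    t_h = frac_h.times
    max_t_mua = bin_t[-1] + mua.bin_width
    rows = []
    for i, onset in enumerate(trials.onsets):
        m_idx = (bin_t + mua.bin_width > onset) & (bin_t < onset + trials.stim_duration)
        h_idx = (t_h >= onset) & (t_h < onset + trials.stim_duration + post)
        if not m_idx.any() or onset + trials.stim_duration > max_t_mua:
            raise ValueError(f"trial {i} (onset {onset:g} s) outside the MUA recording")
        if not h_idx.any():
            raise ValueError(f"trial {i} (onset {onset:g} s) outside the imaging recording")
        rows.append(
            {
                "trial_id": i,
                "stim_duration": trials.stim_duration,
                "condition": condition,
                "peak_mua_fractional": float(pooled[m_idx].max()),
                "peak_hbt_fractional": float(frac_h.hbt[h_idx].max()),
            }
        )
    return pd.DataFrame(rows)


def fit_line(table: pd.DataFrame) -> CouplingFit:
    """OLS of peak HbT on peak MUA across trials, with R²."""
    if len(table) < 3:
        raise ValueError(f"need at least 3 trials to fit, got {len(table)}")
    x = table["peak_mua_fractional"].to_numpy(dtype=float)
    y = table["peak_hbt_fractional"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("coupling table contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in MUA peaks; cannot fit a line")
    fit = stats.linregress(x, y)
    return CouplingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        stderr_slope=float(fit.stderr),
        n=len(table),
    )
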