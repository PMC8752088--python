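# Methods

This note records the models implemented by `oispec`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical choices that affect results.

## Spectral model

Attenuation is natural-log optical density relative to a baseline
window, `ΔA = −ln(I / I₀)`. The baseline reference `I₀` is the
**geometric** mean of the baseline frames (an average in OD domain):
for multiplicative noise `I·(1+n)` an arithmetic-mean reference leaves a
Jensen bias `E[−ln(1+n)] = σ²/2` in every sample (≈5×10⁻⁵ OD at the 1%
default noise), which is negligible for peak metrics but visible in
long-window means such as the 625–1250 s undershoot average. The
geometric mean cancels it to O(σ⁴). `baseline_mean="arithmetic"`
restores the plain intensity average.

The inversion solves, per pixel and frame,

    ΔA(λ) = L(λ, S) [ ε_HbO(λ) Δc_HbO + ε_HbR(λ) Δc_HbR ]

by ordinary least squares over the ≥2 wavelengths. No non-negativity
constraint is applied: the stimulus-evoked washout makes Δ[HbR] negative
by design. A design matrix with condition number above 10⁸ (wavelengths
that cannot separate the chromophores) is rejected with the condition
number reported. Fractional outputs divide each component by its own
baseline concentration, `c_HbO⁰ = S⁰·c_HbT⁰` and
`c_HbR⁰ = (1−S⁰)·c_HbT⁰`; fractional results are therefore invariant to
rescaling the assumed baseline concentration, which is why the assumed
100 µM matters little for the reported percentage changes.

### Optical constants

- **Extinction** (`data/extinction_synthetic.tsv`): a *synthetic*
  Gaussian-band parameterisation of the visible oxy/deoxy haemoglobin
  spectra (alpha/beta bands at 542/577 nm on a broad pedestal, a single
  broad deoxy band at 556 nm, Soret-edge tails), sampled every 1 nm over
  450–650 nm, in Napierian units. Measured in-vitro tables are not
  redistributed with the package; the synthetic table preserves the
  qualitative oxy/deoxy contrast the four-wavelength inversion relies on
  (HbR > HbO at 560 nm, HbO > HbR at 575 nm; design condition number ≈6)
  and is used self-consistently by both the forward renderer and the
  inversion. Users with calibrated tables load them via
  `load_extinction_tsv`.
- **Pathlength**: a two-parameter diffusion closure,
  `L(λ,S) = 1/√(3 μa (μa + μs'))` with
  `μa = c_ref (S ε_HbO + (1−S) ε_HbR)` at `c_ref = 100 µM` and
  `μs' = a (λ/560)⁻ᵇ`, defaults a = 20 cm⁻¹, b = 1.3. This yields a few
  hundred µm of effective path in the green and longer paths in the red,
  and shrinks as the tissue desaturates. Default tables evaluate the
  closure analytically — a gridded TSV would re-enter through
  interpolation error and break the exact forward→inverse identity — but
  `(λ, S)` grids can be exported (`write_pathlength_tsv`) and
  user-supplied grids are interpolated linearly in S
  (`load_pathlength_tsv`).

### Path-length scaling algorithm

`plsa_refine` iterates {invert with L(λ, S_est); update per-sample
S = c_HbO/c_HbT from the estimates; re-evaluate L} until the largest
fractional-HbT change between iterates falls below `tol = 1e-4`
(`max_iter = 20`). Saturation estimates are clamped to [0.05, 0.99] and
clamped samples are reported (`meta["clamped_fraction"]`), as is
non-convergence. The update is per pixel *and* per frame; whether the
original formulation updates per pixel or globally is not documented in
the sources that cite it, and the per-sample form is the more general
fixed point. On self-consistent data the iteration converges to the
generating concentrations at machine precision in ~5–15 iterations; with
a saturation-independent pathlength table it reproduces the single-pass
inversion exactly.

## Synthetic data

The generators are pure functions of (configuration, seed) —
bit-identical on reruns — and exist to give every analysis stage a known
ground truth.

- **Evoked kernel**: HbT follows a gamma-variate impulse (shape 3)
  convolved with the stimulus boxcar, normalised so the maximum is
  exactly `peak_fraction` at `onset_delay + time_to_peak` for short
  stimuli (long stimuli keep their natural ramp-and-plateau time base),
  minus a delayed, wider gamma undershoot lobe of depth
  `undershoot_fraction`. The kernel is C¹-smooth; an earlier piecewise
  construction had a kink at the peak that biased noisy peak-time
  estimates. Δ[HbR] = −`hbr_washout_ratio`·Δ[HbT] (default 0.3), so
  Δ[HbO] = 1.3·Δ[HbT] and conservation holds identically. Triphasic mode
  adds an early positive HbR bump (Gaussian centred at 0.4·time-to-peak,
  width 0.35·time-to-peak, amplitude `triphasic_bump_fraction` of the
  HbR baseline) preceding the washout. Defaults (5% HbT peak, 3 s to
  peak, 1% undershoot) are typical whisker-response magnitudes.
- **Spreading depression**: each pixel at distance d from the origin
  runs a dip (Gaussian, centre 15 s, width 8 s, floor `dip_fraction`),
  rebound (centre 45 s, width 15 s, ceiling `rebound_fraction`), and a
  tanh-gated undershoot to `undershoot_fraction` decaying back to 1 with
  `undershoot_decay_tau`, all delayed by d/speed. The profile is made
  exactly zero at arrival (a fast-decaying correction removes the
  Gaussian tails' offset). Δ[HbO] = `hbo_share`·Δ[HbT] with
  `hbo_share = 1.05`, so the constriction desaturates the tissue
  (S ≈ 0.55 at a 30% dip) — the regime in which PLSA visibly beats the
  single-pass inversion. The wave is radially symmetric; real waves are
  vessel-structured, but symmetry is irrelevant to the dip/rebound/
  undershoot/speed metrics under test.
- **Reflectance renderer**:
  `I = I₀ exp(−L(λ,S)[εΔc]) (1 + n)`, n ~ N(0, σ) multiplicative
  (shot-like), σ = 1% by default; `saturation_mode` selects whether L
  follows the instantaneous true saturation (default) or stays at S⁰.
- **Electrode**: per channel, white Gaussian background plus an
  inhomogeneous Poisson stream of stereotyped biphasic spikes
  (1.2 ms, damped sine), rate `baseline_rate` (10 s⁻¹) times
  `evoked_gain` (2.0) inside stimulus windows; ground-truth event times
  are returned. The default spike amplitude is **60 noise-SD**,
  deliberately large: a mean + 1.5 SD threshold on kHz-bandwidth
  Gaussian noise crosses at the Rice rate ν₀·exp(−u²/2σ²) (thousands per
  second), so with small spikes the counter measures noise, not rate.
  At amplitude 60 the spikes inflate the baseline SD enough to push the
  threshold ≈5 noise-SD up, where noise crossings are negligible and
  counts track the event rate. Small amplitudes reproduce the
  noise-dominated false-positive regime, which is tested against a
  brute-force oracle. Residual biases of the counter (filter ringing
  contributes a constant factor of crossings per spike; episode overlap
  loses ~1–2% at doubled rates) leave the recovered gain within ~3% of
  truth. An optional per-trial gain (`window_gains`), shared with the
  haemodynamic generator's `onset_scales`, provides the common drive
  that produces trial-by-trial neurovascular scatter for the coupling
  fit; the pipeline draws it as N(1, 0.2) per trial by default.

What the synthetic data do **not** emulate: vascular anatomy and
pial-vessel weighting of the signal, heart-beat and breathing artefacts,
slow drifts, photobleaching, correlated camera noise, stimulus artefacts
in the electrophysiology, and real extracellular noise statistics
(which are spike-hash dominated rather than Gaussian). Passing recovery
tests therefore demonstrates correctness of the computations under the
stated noise model, not robustness to every artefact of real recordings.

## Analysis choices

- **ROI rule**: the SD in "mean + 1.5×SD" is the *spatial* SD of the
  activation map's own pixels (configurable), making the rule invariant
  to positive rescaling; the largest 8-connected component is kept so a
  session yields one region. No pre-smoothing is applied.
- **Evoked summaries**: rise time is 10%→90% of the peak deviation on
  the rising limb (fractions configurable); the HbR "peak" is the signed
  extremum of largest magnitude; AUC integrates onset → stimulus end +
  10 s by the trapezoid rule. Peak time is refined by the vertex of a
  parabola through the extremum and its neighbours, removing frame-grid
  quantisation. The waveform classifier requires deflections to hold the
  2×pre-onset-SD floor for 3 consecutive samples; isolated supra-floor
  noise samples occur by chance and would otherwise dominate the labels.
- **CSD**: onset requires fractional HbT below 1 − 0.05 sustained ≥2 s;
  the dip is searched before the late window (the undershoot may be the
  global minimum otherwise); recovery means |HbT−1| ≤ 0.02 sustained
  60 s; pixel arrival for the speed fit is the first *sustained* (2 s)
  crossing below half the dip amplitude — single noisy frames otherwise
  fake early arrivals and wreck the regression; a slope below 1 s/mm is
  reported as non-propagating rather than as an implausibly high speed.
  The 625–1250 s reporting window is a fixed convention, configurable.
  Analyses near the insertion site should use a compact ROI: averaging
  the whole field smears the travelling dip below the undershoot level.
- **MUA**: 4th-order zero-phase Butterworth high-pass (the cutoff, 500
  Hz, is standard; the family/order is this package's choice); *upward
  threshold crossings* are counted, not supra-threshold samples, so one
  spike cannot count many samples; thresholds are per channel; an option
  mirrors the threshold for negative-going spikes.
- **Coupling**: y-on-x OLS (not orthogonal regression), matching how
  such trial-scatter line equations are conventionally reported; R² is
  the squared Pearson correlation; 2 s and 16 s stimulus clusters pool
  into one fit by default with per-cluster fits available.

## Validation benchmarks and problem sizes

`oispec.validation` holds the seeded recovery studies used by both the
acceptance tests and `scripts/acceptance.py`. Sizes are desk-scale by
design: 64×64 px for the spectral round trip and ROI studies (20 seeds),
32×32 px × 30 trials × 5 seeds for evoked recovery, 24–32 px grids at
1 Hz for the 1330 s spreading-depression runs, 50 independent 10 s
trials for the MUA gain, 200 simulations for coupling CI coverage. The
standard error quoted for late-window means is computed across ROI
pixels: each pixel's baseline anchor (I₀ estimated from finitely many
baseline frames) is an independent per-run offset and dominates the
uncertainty of long time averages.

## Known limitations

- Two chromophores only; no cytochrome or scattering-change terms.
- The synthetic extinction and pathlength tables are self-consistent but
  not calibrated; absolute µM outputs on real data require measured
  instrument tables.
- The PLSA reading (iterate-until-stable, per-sample saturation) is one
  faithful interpretation of a procedure whose original form is
  documented only in secondary sources.
- The MUA counter's absolute counts depend on filter ringing and noise
  bandwidth; only fractional changes are comparable across settings.
- No artefact rejection (movement, heartbeat, stimulation transients).
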