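# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `phytoswitch`, module by module.

## Photokinetic model (`phytoswitch.photokinetics`)

The protein is modelled as a two-state system: fluorescent Pr and dark Pfr.
Under piecewise-constant illumination the populations obey

    d[Pr]/dt = −Φ_off R_Pr + Φ_on R_Pfr + Σ_i k_i [Pfr]_i

with per-species volumetric absorption rates

    R_X = I₀ (ε_X[X]/S)(1 − 10^−A) · 1000/l,   S = ε_Pr[Pr] + ε_Pfr[Pfr],  A = l·S.

**Units.** Concentrations in M, extinction in M⁻¹cm⁻¹, optical path in cm,
photon flux density in einstein cm⁻² s⁻¹. The absorbed *areal* flux
(einstein cm⁻² s⁻¹) is divided by the path length and scaled by 1000 cm³/L
to become a volumetric rate in einstein L⁻¹ s⁻¹ = M s⁻¹ — the standard
photochemical convention for a well-stirred cuvette. In the optically thin
limit the off-rate reduces to the per-molecule form Φ_off·σ·F with
σ = ln10·ε·1000/N_A cm² (≈ 3.3×10⁻¹⁶ cm² for ε = 86,100), which the test
suite checks against the integrator to 1%.

**Thermal recovery** is modelled as parallel first-order Pfr→Pr channels
with amplitude fractions summing to 1. The ODE state carries one sub-pool
per channel: Pfr created photochemically is distributed over the pools by
their fractions, each pool relaxes with its own rate, and on-switching light
drains each pool in proportion to its occupancy. In the dark this reproduces
the closed form Σ aᵢ(1 − e^(−kᵢt)) exactly. Two empirically distinct rate
sets coexist for these proteins — a slow set calibrated from bulk absorption
recovery (minutes–hours) and a fast set calibrated from in-cell fluorescence
recovery (milliseconds). The package treats them as alternative
configurations of the same `k_thermal` field rather than attempting a
mechanistic unification; the imaging simulator defaults to the fast set.

**Solver.** Each protocol segment is integrated with LSODA
(adaptive, stiffness-switching) at rtol 10⁻¹⁰ / atol 10⁻¹⁵ M, restarting
with state hand-off at segment boundaries. Total concentration is conserved
to better than 10⁻⁸ relative over multi-segment protocols. Extinction
spectra are linearly interpolated on their stored wavelength grid; a query
outside the grid under non-zero flux is an error, never an extrapolation.

**Photostationary state.** With no thermal recovery the residual Pr fraction
has the closed form 1/C with contrast C = 1 + ε_PrΦ_off/(ε_PfrΦ_on) — the
shared photokinetic factor cancels, so the relation holds at any optical
density. With thermal channels the stationary pool balance is solved by
bisection on [Pr] with a fixed-point inner loop for the pools; the
integrator cross-checks this to 10⁻⁵ relative in the tests.

**Plateau scaling.** Dark thermal recovery of these proteins consistently
plateaus a little below the light-driven recovery level (≈80–85% vs. 90–95%
of equilibrium). A two-state model cannot produce two different plateaus, so
the synthetic recovery generator exposes a `plateau` parameter that scales
the recovery endpoint without asserting a mechanism.

## Quantum-yield estimation (`phytoswitch.qy`)

The differential (t = 0) quantum yield is

    Φ_d = −(dA_probe/dt)|₀ · l_irr / (ε_Pr,probe l_probe · 1000 · I₀ (1 − 10^(−l_irr ε_Pr,irr [Pr]₀))),

valid while [Pfr] ≈ 0 and assuming a Pr-specific probe wavelength
(ε_Pfr,probe = 0 unless supplied).

**Initial-slope estimation.** A straight-line fit over a finite window
returns the window-average slope of a curved decay, biased low by
≈(1 − e^−x)/x for fractional conversion x — already 2.5% at 5% conversion,
which would dominate the error budget. The estimator instead fits a local
single-exponential A_∞ + (A₀ − A_∞)e^(−kt) over the initial window and
differentiates it at t = 0. The window default is the first 50% of the total
absorbance excursion (minimum 5 points): long enough to constrain the
curvature under realistic absorbance noise, short enough that the Pr-specific
probe assumption stays serviceable. Ordinary least squares remains as the
fallback when the exponential fit fails to converge.

**Actinometry.** Photon flux is calibrated by inverting the same relation
for I₀ on a reference photoreaction of known quantum yield (default 0.015,
the diarylethene value at 638 nm). The actinometer's extinction coefficients
are required inputs — no default is assumed.

**Pooling.** Replicate estimates at different flux levels are combined by
inverse-variance weighting, with per-experiment variances propagated from
the slope fit. The slope of estimate-vs-flux is reported with a 95% CI as a
linearity diagnostic; a genuine quantum yield is flux-independent, so the CI
should contain zero.

## Trace analysis (`phytoswitch.traces`)

**Off-switching.** Two decay models are fitted — exponential-plus-plateau
and gamma-survival-plus-plateau, S(t) = plateau + amp·Q(k, t/θ) with Q the
regularized upper incomplete gamma (reducing to the exponential at k = 1) —
and the winner chosen by AICc. The half-time is reported *model-free* as the
time where the fitted curve crosses midway between its initial value and
plateau, so the number is comparable across model families; the residual
fraction is plateau/initial. Both are invariant under affine rescaling of
the signal axis.

**Fatigue.** Per-cycle maxima are fitted as a geometric decay m_n = m₀qⁿ by
log-linear least squares; cycles-to-half is the interpolated ln(0.5)/ln(q).
Non-decaying maxima yield an infinite sentinel with a warning rather than an
error. Cycle boundaries come from protocol markup; there is no peak-detection
guessing.

**Thermal recovery.** Candidates are saturating multi-exponentials with 1–3
non-negative components and a logarithmic growth curve a + b·log₁₀(t)
(clipped to physical bounds), selected by AICc. Because noiseless data would
drive the residual sum of squares to machine precision and reward spurious
components, the AICc computation floors the RSS at (10⁻¹⁰ × signal scale)²
per point — the model-complexity penalty then decides, and the smallest
adequate model wins. The half-recovery time is solved analytically
(logarithmic model) or by bracketing (exponential models) at 50% of the
equilibrium reference, which the caller can supply for normalized traces.

**Photobleaching** is a mono-exponential fit over frame index with
interpolated frames-to-half. **pH titration** is a Henderson–Hasselbalch
sigmoid base + span/(1 + 10^(n(pKa − pH))) with standard errors from the
covariance. **Molecular brightness** is EC·QY/1000 with a
3-significant-figure presentation helper. **Line profiles** are fitted with
baseline + Lorentzian (FWHM = 2γ) after averaging 3 adjacent parallel
profiles when a 2-D patch is supplied; a profile without a single dominant
half-height peak raises unless a window is given. Fitting a Lorentzian to a
Gaussian peak biases the FWHM by an amount that depends on the fitted range
(≈0% at ±2 FWHM, −15% at ±5 FWHM) — a documented model-mismatch effect.

## Spectral analysis (`phytoswitch.spectra`)

Extinction spectra are anchored at the biliverdin Soret band by defining
ε(391 nm) = 39,900 M⁻¹cm⁻¹ per bound chromophore, making all derived values
per-holo-protein. The ensemble off-state is a photostationary Pr/Pfr mixture
whose residual Pr fraction is 1/contrast; the pure Pfr spectrum follows by
linear unmixing, with negative results clipped to zero and flagged. Binary
operations resample to the coarser grid (linear interpolation) rather than
inventing resolution. Baseline correction subtracts a flat offset estimated
from a configurable silent window (default 800–850 nm); aromatic-content
ε280 prediction from sequence is out of scope — ε280 is a direct input.

## RESOLFT simulation (`phytoswitch.resolft`)

**Optics are scalar and 2-D.** The readout beam is an isotropic Gaussian
(default FWHM 240 nm ≈ 0.51λ/NA at λ = 660 nm, NA = 1.4); the depletion beam
is the first-order vortex-like doughnut I(r) ∝ (2e·r²/w²)e^(−2r²/w²),
exactly zero on axis with its crest at r = w/√2 (default w = 320 nm). The
simulator's claims are comparative (RESOLFT vs. confocal on the same
phantom), not absolute.

**Per-molecule kinetics.** At a fixed local intensity the two-state system
is linear, so each step of the pixel sequence has a closed form for the
on-state probability and for the time-integrated emission; this makes
persistent state propagation over a full raster tractable (every molecule's
state evolves through every pixel's illumination, evaluated at its true
position — neighbouring-pixel cross-talk is included). Multi-component
thermal sets are collapsed to their amplitude-weighted total rate inside the
scan loop; the full multi-pool treatment lives in the ODE module.

**Rate saturation.** Strictly linear kinetics cannot reconcile a ~70 µs
off-switching half-time at 1 kW/cm² with a readout step at ~80–100 kW/cm²
that preserves switching contrast: linearly extrapolated, the readout dose
(≈12 e-foldings) would erase the doughnut-encoded pattern within the first
microsecond of readout. In-cell measurements show the off-switching rate
stops increasing above roughly 1 kW/cm² — the microsecond-scale photocycle
intermediates bottleneck the turnover. The imaging layer therefore damps the
*switching* rates by I → I/(1 + I/I_sat), default I_sat = 1 kW/cm², while
absorption and emission stay linear (one-photon absorption does not saturate
at these intensities). With ε_Pr(660) = 51,300 M⁻¹cm⁻¹ this calibration
reproduces the 70.9 µs half-time at 1 kW/cm²; ε_Pfr(660) = 10,000 puts the
photostationary residual near 6%. These 660 nm extinctions are package
defaults calibrated to in-cell observables — the published spectra list only
the band maxima — and `saturation=None` recovers the pure linear model used
everywhere else in the package. Under the live-cell pixel sequence (5 ms
relax, 1.5 ms doughnut at 1.1 kW/cm², 15 µs readout at 82 kW/cm², 30 nm
pixels) the simulated effective PSF is ≈45 nm FWHM vs. 240 nm confocal, and
a 129 nm line pair is resolved in the RESOLFT channel only; the fixed-cell
sequence gives ≈80 nm.

**Detection** is Poisson with a default efficiency of 0.05; the 680–750 nm
emission band is metadata only. The confocal image is recorded interleaved
(relax + readout sub-sequence before the RESOLFT sub-sequence at each
pixel), mirroring simultaneous-recording practice; per-pixel dwell time and
light dose are reported in the image metadata. Bleaching during imaging is
not simulated (photobleaching is analysed as a per-frame survival model in
the trace module). The `independent_pixels` flag replaces finite dark
relaxation by full recovery — the relax→∞ idealization — and is used to
isolate state-persistence effects.

## Synthetic data (`phytoswitch.synthetic`)

Each generator draws from one explicitly seeded `numpy` Generator (no global
RNG state) and emits a truth record beside the data. Defaults encode the
study conditions of the corresponding measurements: off-switching traces
with an 86 µs half-time and 6.08% residual at a 5,000-count Poisson peak
sampled every 5 µs over 3 ms (bacterial-colony regime; the mammalian-cell
regime uses 70.9 µs / 4.8% / 2,000 counts); absorbance kinetics at
1–20 µmol m⁻² s⁻¹ through a 0.2 cm irradiation path at A ≈ 0.1; fatigue
series of 1,200 cycles with a 972-cycle half-life and 2% multiplicative
noise; logarithmic dark recovery crossing 50% at 6.8 ms on 30 log-spaced
points over 0.1–100 ms with 5% noise; 12-point titrations over pH 3–9 with
pKa 4.5 and 3% noise; 5,000-frame bleach series with a 2,300-frame
half-life; filament phantoms with Poisson-placed labels (default 100–200
per µm) including the canonical parallel-pair preset.

What the generators deliberately do *not* emulate: instrument drift,
background and out-of-focus light, detector afterpulsing, filament thickness
and orientation disorder, chromatic effects, or sample motion. Passing
recovery tests therefore demonstrates estimator correctness under the
assumed noise models, not robustness to every artefact of real recordings.

## Interface (`phytoswitch.io`, `phytoswitch.cli`)

Tables are UTF-8 comma-separated text with header rows (times in seconds);
schemas are validated on load, extra columns are preserved with a warning,
and a non-monotone ordering column is an error naming the offending row.
Configuration is YAML with explicit unit suffixes on physical keys
(`off_peak_kw_per_cm2`, `relax_time_ms`, ...) because protocol sources mix
mW, kW/cm² and µmol m⁻² s⁻¹ and silent unit mix-ups are the dominant failure
mode. Images are written as 16-bit TIFF with a JSON metadata sidecar.
Reports are JSON with sorted keys, so reruns at a fixed seed are
byte-identical.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
50-replicate Monte-Carlo batches for the switching fits, 20 replicates for
titration and recovery, 600-point traces, 60-point recovery grids, and scan
fields of a few µm² at 30 nm pixels. These sizes put the Monte-Carlo medians
well inside the tolerances being checked while keeping the whole suite in
the order of seconds.

## Known limitations

* The two-state model omits the micro/millisecond photocycle intermediates;
  saturation of the switching rate is captured phenomenologically, not
  mechanistically.
* Different dark- vs. light-driven recovery plateaus are parameterized, not
  explained.
* The scan simulator is 2-D scalar optics with radially symmetric beams; no
  vectorial high-NA PSF, no 3-D sectioning, no aberrated doughnut zero.
* Absolute filament FWHMs in real recordings depend on filament thickness
  and labeling density, which the phantoms idealize as zero-width lines.
* Aggregate light-dose figures over a full image depend on the scan-area
  accounting convention; the simulator reports per-pixel and per-area doses
  and leaves aggregation to the user.
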