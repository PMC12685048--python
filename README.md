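# phytoswitch

Photokinetic modelling and analysis for near-infrared, bacteriophytochrome-
derived **reversibly switchable fluorescent proteins** (NIR-RSFPs), and
simulation of the **single-wavelength RESOLFT** nanoscopy scheme these
proteins enable.

NIR-RSFPs cycle between a red-absorbing fluorescent on-state (**Pr**) and a
far-red-absorbing dark off-state (**Pfr**). Red light drives Pr → Pfr
(off-switching) and, in living cells, the protein relaxes thermally back to
Pr within milliseconds — so a single 660 nm laser can do off-switching *and*
fluorescence readout, with dark intervals replacing the on-switching laser.
This package is aimed at people characterizing such probes (switching quantum
yields, half-times, fatigue, recovery, pKa, spectra) and at people reasoning
about the imaging scheme itself.

## The model

Population kinetics under irradiation at wavelength λ follow the two-state
rate equation

```
d[Pr]/dt = −Φ_off · R_Pr + Φ_on · R_Pfr + Σ_i k_i [Pfr]_i
```

where Φ_off, Φ_on are switching quantum yields per absorbed photon, the k_i
are parallel first-order thermal recovery channels, and the absorption rates
share the photokinetic factor (1 − 10⁻ᴬ):

```
R_X = I₀ · (ε_X[X] / S) · (1 − 10⁻ᴬ) · 1000 / l ,   S = ε_Pr[Pr] + ε_Pfr[Pfr],  A = l·S
```

with I₀ the photon flux density (einstein cm⁻² s⁻¹) and l the optical path
(cm). In the optically thin limit this reduces to the per-molecule rate
Φ·σ·F with σ = ln10·ε·1000/N_A.

On top of this forward model the package implements:

* **Quantum-yield estimation** — the differential quantum yield from the
  initial slope of a probe-wavelength absorbance decay,
  `Φ_d = −(dA/dt)|₀ · l_irr / (ε_probe l_probe · 1000 · I₀ (1 − 10^(−l_irr ε_irr [Pr]₀)))`,
  with photon-flux calibration by chemical actinometry, and the on-switching
  yield from the photostationary switching contrast
  `C = 1 + ε_Pr Φ_off / (ε_Pfr Φ_on)`.
* **Characterization fitters** — off-switching half-time and residual
  fluorescence (exponential vs. gamma-survival decay, AICc-selected),
  switching fatigue (geometric decay of cycle maxima), thermal recovery
  (1–3 exponentials vs. logarithmic growth), photobleaching, pH titration,
  Lorentzian line-profile FWHM, molecular brightness (EC·QY/1000) and
  holo-protein fraction.
* **Spectral operations** — extinction anchoring at the biliverdin Soret band
  (ε(391 nm) = 39,900 M⁻¹cm⁻¹ per bound chromophore), pure-Pfr spectrum
  unmixing via the switching contrast, normalization.
* **RESOLFT scan simulation** — raster scanning of filament phantoms with the
  three-step pixel sequence (thermal relaxation → doughnut off-switching →
  Gaussian readout, all at 660 nm), persistent per-molecule state across
  pixels, interleaved confocal recording, Poisson detection.
* **Synthetic data** — seeded generators for every input class, each with a
  truth sidecar for recovery scoring.

## Worked example

Fit a noisy off-switching trace and estimate the off-switching quantum yield
from a simulated absorbance decay:

```python
from phytoswitch import synthetic as syn, traces as ta, qy

trace, truth = syn.generate_switching_trace(seed=42)   # 86 us / 6.08% truth
fit = ta.fit_off_switching(trace)
print(f"half-time: {fit.half_time*1e6:.1f} us")
print(f"residual:  {fit.residual_fraction*100:.2f} %")
print(f"model:     {fit.model_label}")

series, t = syn.generate_absorbance_series(phi_off=0.03, noise_sd=0.002,
                                           seed=42, conversion=0.4)
est = qy.estimate_differential_qy(series, t["eps_pr_probe"],
                                  t["eps_pr_irr"], t["initial_conc"])
print(f"phi_off:   {est.value:.4f} +/- {est.standard_error:.4f}")
```

prints

```
half-time: 85.6 us
residual:  6.04 %
model:     exponential
phi_off:   0.0295 +/- 0.0008
```

— the trace was generated with an 86 µs half-time and 6.08 % residual
off-state fluorescence at a 5,000-count peak, and the absorbance series with
Φ_off = 0.03; the fits recover all three within their counting-noise
uncertainty.

The same operations are available from the shell
(`phytoswitch fit-off trace.csv`, `phytoswitch qy config.yaml`,
`phytoswitch resolft-sim sim.yaml`, `phytoswitch make-synthetic --kind
titration --seed 1`, ...); every subcommand prints a JSON report.

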