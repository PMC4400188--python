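# Methods

This note documents the models, numerical choices and limitations behind
`cardiodnp`. The package reimplements the quantitative analysis chain of an
in-vivo hyperpolarized ¹³C-pyruvate cardiac study — dynamic spectral
quantification, label-flux kinetics, CINE volumetry and factorial cohort
statistics — and pairs every stage with a synthetic-data generator so the
whole chain is testable without animal data.

## Kinetic model

Hyperpolarized [1-¹³C]pyruvate label exchange is modelled as unidirectional
first-order flux from the pyruvate pool into each downstream pool
x ∈ {lactate, alanine, bicarbonate, CO₂}:

    dM_p/dt = u(t) − (ρ_p + Σ_x k_px) · M_p
    dM_x/dt = k_px · M_p − ρ_x · M_x

- `k_px` (s⁻¹) — label-flux rate into pool x. The bicarbonate rate is the
  pyruvate-dehydrogenase (PDH) flux proxy; the lactate rate reports
  glycolytic exchange via lactate dehydrogenase.
- `ρ_x`, `ρ_p` (s⁻¹) — effective decay rates lumping longitudinal (T₁)
  relaxation and any back-flux. Defaults: ρ_x = 1/30 s⁻¹ (T₁ ≈ 30 s for
  carbonyl ¹³C at 7 T), ρ_p = 0.05 s⁻¹ (shorter effective pyruvate decay,
  dominated by flow and exchange).
- `u(t)` — label arrival. Default: trapezoid over the 10 s intravenous
  injection (2 s ramps). A gamma-variate bolus is provided as an
  alternative; because the fitter conditions on the *measured* pyruvate
  curve, the simulator's injection shape is not load-bearing (verified by a
  dedicated test).
- The CO₂/bicarbonate pH equilibrium is represented by
  `co2_bicarbonate_ratio` (default 0.1, roughly the equilibrium share at
  myocardial pH): that fraction of PDH-derived label is diverted to a CO₂
  pool with its own resonance. Consequently the *observable* bicarbonate
  rate is (1 − ratio)·k_PDH; the fitter reports bicarbonate and CO₂
  separately by default, with an optional combined mode.

Radio-frequency sampling is the standard small-flip pulse-acquire physics:
each excitation reads out sin θ of the longitudinal magnetization and leaves
cos θ behind (θ = 5°, TR = 1 s, 60 repetitions, 13 593 Hz sweep width, 2048
complex points).

Integration is fixed-step RK4 with 10 sub-steps per TR (the system is linear
and non-stiff; RK4 at h = 0.1 s agrees with closed forms to better than
1e-9, comfortably inside the 1e-6 documented contract). The cos θ depletion
is applied instantaneously at each excitation.

## FID rendering and noise

Each repetition's FID is a sum of damped complex sinusoids, one per
metabolite: amplitude M·sin θ, Lorentzian damping π·linewidth, frequency
offset from the configured shift table, plus i.i.d. circular complex
Gaussian noise (thermal MR noise). The shift tables are editable defaults —
the study's own shifts are not published — with the [1-¹³C] table (lactate
+1000 Hz, alanine +570 Hz, hydrate +630 Hz, bicarbonate −1320 Hz, CO₂
−6130 Hz relative to pyruvate at 7 T) and a [2-¹³C] table derived from
standard ¹³C shift values scaled at 75 Hz/ppm. Simulator and fitter share
one table, which is what the recovery guarantees require; absolute
placement only matters for display.

"Peak SNR" throughout means: maximum pyruvate FID amplitude divided by the
per-channel noise standard deviation.

## Spectral quantification

The fitter follows the AMARES recipe (time-domain, prior-knowledge
constrained):

- Lorentzian lineshape only; frequencies bounded to the shift table ± 20 Hz
  (or fixed); linewidths bounded to [1, 100] Hz, started at 20 Hz; one
  zero-order phase shared across peaks; non-negative amplitudes.
- Bounded trust-region nonlinear least squares on the complex residual
  (real and imaginary parts stacked), with an analytic Jacobian. Amplitude
  starting values come from a matched-filter projection at the prior
  frequency; the shared phase starts at the phase of the strongest peak.
- Amplitude uncertainties are Cramér–Rao style: scaled inverse curvature at
  the solution.
- Stopping tolerances are 1e-10 (relative); noiseless oracle agreement is
  ~1e-8, two orders below the 1e-5 contract.

DC offset is corrected by subtracting the complex mean of the last half of
acquired points. Because a Lorentzian's own tail mean is not exactly zero,
the same tail-mean-removal operator is applied to the model inside the fit
(`dc_projected=True` in the series pipeline); without this the amplitudes
would carry an O(tail level) ≈ 1e-3 relative bias on offset-free data.
`fit_spectrum` called directly on raw FIDs leaves the projection off.

Per-repetition fits are warm-started from the previous repetition.
Repetitions that fail to converge (typically pure-noise pre-arrival frames)
are recorded as missing and excluded from kinetic fitting rather than
interpolated.

For [2-¹³C] data, spectra are summed over the 30 s following pyruvate
appearance and fitted once; metabolite amplitudes are normalized to
pyruvate. Appearance is the first repetition whose matched-filter pyruvate
amplitude exceeds 5× the amplitude-equivalent noise level estimated from
the first (pre-arrival) repetition; on noiseless data any numerically
nonzero amplitude counts.

## Kinetic fitting

Each product is fitted independently against the measured pyruvate curve:

    x̂(t_n) = k · ∫ P(s) e^(−ρ(t_n − s)) ds + x(t₀) e^(−ρ(t_n − t₀))

with P(s) interpolated linearly between repetitions. The convolution is
evaluated *segment-exactly* for piecewise-linear input (closed-form
coefficients per interval, with a Taylor guard for ρ·Δt < 1e-8): plain
trapezoid quadrature at TR/10 would leave ~1e-3 relative error at ρ ≈ 1 s⁻¹,
while the exact segment integral meets the 1e-6 closed-form contract and
needs no sub-grid at all.

The per-excitation RF loss is absorbed into ρ (−ln cos θ / TR ≈ 0.0038 s⁻¹
at 5°/1 s) rather than estimated separately — the two are not separately
identifiable at these settings. ρ is bounded to [0.01, 1] s⁻¹, started at
1/30 s⁻¹; k is non-negative. The fit window runs from pyruvate appearance
(first sample above 5% of the pyruvate maximum) to the last usable
repetition. A product whose signal is identically zero returns k = 0
flagged as a boundary solution.

Parameter recovery through the whole chain (simulate → render → quantify →
fit): noiseless relative bias ≈ 0.2% (residual bias from interpolating the
continuous pyruvate curve between 1 s samples and from the within-interval
cos θ drop); at peak pyruvate SNR 50 with 100 replicates, |bias| stays well
under 10% for the lactate and bicarbonate rates.

## CINE volumetry

Cavity volume per frame is the Simpson-style slice summation Σ endo-area ×
thickness (mm³ ≡ µL); no inter-slice gap or interpolation correction is
applied, matching contiguous full-coverage stacks. ED/ES are the frames of
largest/smallest cavity volume, ties broken by the earliest frame;
SV = EDV − ESV, EF = SV/EDV, CO = SV·HR (µL/min → mL/min), CI = CO/body
weight. LV mass is myocardial area × thickness × 1.05 mg/mm³, evaluated at
the ED frame by default (the source protocol does not state the frame; it
is configurable). Reporting precision (volumes to 10 µL, EF to integer %,
CO to 10 mL/min) is applied only in report output, never to stored values.

The synthetic generator models the ventricle as a prolate-ellipsoid slice
stack with a cosine contraction cycle and a constant (incompressible) wall
cross-section, plus optional Gaussian area jitter. It does not emulate
papillary muscles, through-plane motion, segmentation ambiguity at the apex
or base, or observer variability — so round-trip tests validate the index
arithmetic, not segmentation robustness.

## Cohort statistics

Per timepoint and measure: a two-factor (surgery × diet) ANOVA with
interaction, Type II sums of squares for unbalanced cells (the study's
group sizes are 6–11; Type II reduces to the classical decomposition when
balanced — asserted against a hand-rolled cell-means oracle). When the
interaction is significant at α = 0.05, the four within-level comparisons
(sham/banded within each diet, chow/Western within each surgery) are run as
pooled-variance two-sample t-tests with Bonferroni correction (m = 4,
adjusted p = min(1, 4p)). All tests two-sided; no correction across
measures or weeks (matching the per-timepoint framing). Summaries are mean
± sample SD (n−1); single-animal cells report SD as missing.

Type-I calibration: 2000 null replicates (all cells Normal(0,1), n = 8)
give rejection rates within [0.04, 0.06] for every effect.

## Full synthetic study

`run_study` draws a full factorial cohort using the published per-week
group sizes (37–40 animals per timepoint), with between-animal lognormal
variability (CV 12%) on the kinetic rates. Group effects emulate the
qualitative findings the package targets: banded (AAB) groups carry 1.3×
the lactate rate at 9 and 14 weeks only, Western-diet groups carry 0.75×
the PDH rate at all timepoints, and banded hearts have a 15% thicker wall.
Every animal's data pass through the full quantification and fitting chain
at peak SNR 50, then through the ANOVA layer. With these group sizes and a
±15% band on the banded:sham group-mean ratio, the pattern assertions sit
more than three Monte-Carlo standard errors from their thresholds, so the
qualitative checks are stable across seeds.

All randomness flows from one root seed through named substreams (stage
name hashed into a `SeedSequence` entropy pair); identical configurations
produce byte-identical CSV outputs.

Problem sizes used by the acceptance script: 3 noiseless and 100 SNR-50
recovery replicates, 2000 ANOVA null replicates, one full study
(all three timepoints, published group sizes).

## Known limitations

- The kinetic model is unidirectional with lumped decay; no reverse rate
  constants, no multi-compartment perfusion, no B₀/B₁ inhomogeneity, no
  spatial resolution.
- The spectral model is Lorentzian-only (no Voigt, no baseline splines,
  no first-order phase).
- Group-level in-vivo results of the original study (absolute flux values,
  the 26–30% lactate elevations, serum/Western-blot panels) depend on the
  animal data and are not reproducible from synthetic inputs; the package
  reproduces the printed-table arithmetic identities and the qualitative
  group pattern only.
- The cohort generator draws measures independently within animal (no
  between-measure correlation) and per week (no serial correlation across
  timepoints), consistent with the per-timepoint analysis layer but not
  with mixed-effects extensions.
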