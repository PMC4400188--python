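# cardiodnp

Quantitative analysis of hyperpolarized ¹³C-pyruvate cardiac MR studies —
implemented end-to-end on synthetic data.

Dynamic nuclear polarization boosts ¹³C polarization more than 10 000-fold,
so a bolus of [1-¹³C]pyruvate can be watched in real time as the heart
converts it to lactate, alanine and — via pyruvate dehydrogenase (PDH) —
bicarbonate/CO₂. Studies built on this readout need the same analysis chain
every time: quantify metabolite peaks in each of ~60 one-second spectra, fit
first-order label-flux rate constants against the measured pyruvate curve,
compute cardiac function indices from CINE-MRI segmentations, and compare
surgical × dietary groups with per-timepoint factorial statistics. This
package provides that chain as a tested library, plus generators that
simulate every input with known ground truth, so each stage can be verified
by parameter recovery rather than by eye.

Intended users: MR spectroscopists and cardiac physiologists who want a
reproducible, scriptable alternative to interactive tooling for this class
of experiment, and methodologists who want a sandbox with known truth.

## The models

**Label-flux kinetics.** Each downstream pool x (lactate, alanine,
bicarbonate, CO₂) follows

    dM_x/dt = k_px · M_p(t) − ρ_x · M_x(t)

with k_px the flux rate (s⁻¹; the bicarbonate rate proxies PDH flux) and
ρ_x an effective decay lumping T₁, back-flux and RF losses. The fitter
conditions on the *measured* pyruvate curve:

    x̂(t_n) = k_px ∫ P(s) e^(−ρ_x (t_n − s)) ds

evaluated segment-exactly for linearly interpolated P.

**Spectral quantification** is AMARES-style time-domain fitting: damped
complex sinusoids under prior knowledge (frequencies fixed to a shift table
± 20 Hz, bounded Lorentzian linewidths, one shared zero-order phase,
non-negative amplitudes), after DC-offset correction from the last half of
acquired points. [2-¹³C] runs are summed over the 30 s after pyruvate
appearance and reported as metabolite:pyruvate ratios.

**CINE volumetry**: cavity volume = Σ_slices endo-area × thickness;
ED/ES = frames of max/min volume; SV = EDV − ESV, EF = SV/EDV,
CO = SV × HR, CI = CO/body weight; LV mass = myocardial area × thickness ×
1.05 mg/mm³.

**Cohort statistics**: per-timepoint two-way ANOVA (surgery × diet, Type II
sums of squares), with Bonferroni-corrected pooled-variance t-tests
(m = 4) when the interaction is significant at α = 0.05.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a dynamic [1-¹³C] experiment, quantify it, and fit the kinetics:

```python
from cardiodnp import AcquisitionParams, C1_SHIFTS_HZ, peaks_from_shifts
from cardiodnp.synthetic import (KineticGroundTruth, simulate_kinetics,
                                 render_fids, noise_sd_for_peak_snr)
from cardiodnp.spectral import priors_from_shifts, quantify_series
from cardiodnp.kinetics import fit_kinetics

acq = AcquisitionParams()            # TR 1 s, 5 deg, 13593 Hz, 2048 pts, 60 reps
truth = KineticGroundTruth()         # k_lac 0.025, k_ala 0.008, k_bic 0.012 / s
M, names = simulate_kinetics(truth, acq)
noise = noise_sd_for_peak_snr(M, acq, snr=50)
fids = render_fids(M, peaks_from_shifts(C1_SHIFTS_HZ, names=names), acq,
                   noise_sd=noise, seed=1)
series = quantify_series(fids, priors_from_shifts(C1_SHIFTS_HZ, names=names))
fit = fit_kinetics(series)
print(fit.to_frame()[["product", "k_per_s", "rho_per_s"]].round(4))
```

```
       product  k_per_s  rho_per_s
0      lactate   0.0248     0.0366
1      alanine   0.0081     0.0366
2  bicarbonate   0.0112     0.0393
```

The fitted lactate rate recovers the simulated 0.025 s⁻¹ to within 1% at
this noise level; the bicarbonate rate recovers the observable share
0.9 × 0.012 = 0.0108 s⁻¹ (a tenth of the PDH-derived label appears as CO₂
at equilibrium); the fitted decays scatter around the simulated 1/30 s⁻¹
plus the RF sampling loss (−ln cos 5° ≈ 0.0038 s⁻¹ ⇒ 0.0372 s⁻¹). One
pre-arrival pure-noise repetition fails to converge and is logged and
excluded rather than interpolated.

Functional indices from published group means:

```python
from cardiodnp.cine import functional_indices, format_report
cf = functional_indices(550, 120, hr_bpm=350)   # EDV, ESV (uL), HR (bpm)
print(format_report(cf))
# {'edv_ul': 550, 'esv_ul': 120, 'sv_ul': 430, 'ef_pct': 78, 'co_ml_min': 150}
```

i.e. stroke volume 430 µL, ejection fraction 78%, cardiac output
150 mL/min at the reporting precision of the source table.

The same stages are scriptable from the shell (`cardiodnp --help`):
`simulate fids|cine|cohort`, `quantify`, `c2ratio`, `kinetics fit|recover`,
`cine`, `stats`, `run-study`.

## Analysis scripts

Numbered narrative drivers under `analysis/` run the study stages and write
tables under `results/`:

1. `01_table2_identities.py` — recompute SV/EF/CO from published group means
2. `02_parameter_recovery.py` — Monte-Carlo kinetic recovery through the
   full pipeline
3. `03_anova_calibration.py` — null type-I calibration and a power check on
   the published end-systolic-volume summaries
4. `04_full_study.py` — the full synthetic cohort study (several minutes)

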