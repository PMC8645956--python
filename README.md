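# vilipower

Respiratory mechanics, mechanical power of ventilation, dynamic FDG-PET lung
kinetics, quantitative-CT aeration, and cohort statistics — a tested analysis
pipeline for experimental studies of ventilator-induced lung injury (VILI),
e.g. multi-day large-animal ARDS models with paired PET/CT imaging.

## What it computes

**Mechanics and power.** From ventilator pressure/flow tracings, breaths are
segmented at inspiratory flow onsets and, per breath, the package computes
P_peak, P_mean, P_plat, measured PEEP, V_T, driving pressure ΔP = P_plat −
PEEP, transpulmonary pressures (P_trans = P_aw − P_eso), and equation-of-motion
fits

    P_aw = E·V + R·V̇ + P0                (linear)
    P_aw = E1·V + E2·V² + R·V̇ + P0       (volume-dependent elastance)

with %E2 = 100·E2·V_T/(E1 + E2·V_T). Mechanical energy per breath is the
numerical integral of the tidal PV loop, ME = ∫ P_aw dV over inspiration;
mechanical power is MP = ME × RR (J/min), decomposed into a resistive part
∫ R·V̇ dV and the elastic remainder so components always sum to the total.

**PET kinetics.** The ¹⁸F-FDG uptake rate Ki is the Patlak slope of
C_T(t)/C_p(t) against ∫C_p/C_p(t); the blood fraction V_b comes from an
irreversible two-tissue-compartment (Sokoloff) fit. Because lung voxels are
mostly gas and blood, Ki is normalized to the tissue fraction,
KiS = Ki/(1 − F_Gas − F_Blood), and scan-to-scan change is the difference of
ROI medians, ΔKiS.

**CT aeration.** Voxel gas fraction F_Gas = HU/−1000; lung mass, gas volume,
and the four aeration compartments (hyper < −900 HU, normal −900..−500,
poor −500..−100, non-aerated ≥ −100).

**Statistics.** Median (IQR) summaries, paired Wilcoxon signed-rank tests with
asymptotic two-sided significance (zeros dropped, midranks, tie-corrected
variance, no continuity correction), and Spearman correlations with
t-approximation p-values — the conventions of standard statistical software,
implemented explicitly.

**Synthetic data.** Every input can be generated with known ground truth:
volume-controlled ventilation waveforms from a one-compartment lung, Feng-model
plasma input plus closed-form two-tissue-compartment tissue curves over a
75-min scan, CT voxel mixtures with exact compartment mass fractions, and
n-animal two-timepoint cohorts with a controllable rank correlation between
median MP and ΔKiS.

## Worked example

```python
import numpy as np
from vilipower import (VentSettings, LungModelParams, simulate_ventilation,
                       segment_breaths, breath_pressures, fit_equation_of_motion,
                       decompose_power, summarize_power, CohortSpec, simulate_cohort,
                       spearman, wilcoxon_asymptotic, PairedSample)

settings = VentSettings(vt_ml_kg=6.0, body_mass_kg=50.0, rr=20.0, insp_flow_lpm=36.0)
lung = LungModelParams(E1=57.3, E2=0.0, R=12.4, PEEP=5.0, noise_sigma=0.3, seed=0)
rec = simulate_ventilation(settings, lung, n_breaths=10)

results = []
for breath in segment_breaths(rec):
    mech = breath_pressures(rec, breath)
    fit = fit_equation_of_motion(rec, breath, model="linear")
    results.append(decompose_power(rec, breath, fit))
print(f"breath 0: VT={mech.VT:.3f} L  Pplat={mech.Pplat:.1f}  dP={mech.dP:.1f} cmH2O")
print(f"fit: E={fit.E:.1f} cmH2O/L  R={fit.R:.1f} cmH2O*s/L  R2={fit.r_squared:.4f}")
mp = summarize_power(results)
print(f"median MP: total={mp['MP_total']:.2f}  elastic={mp['MP_elastic']:.2f}  "
      f"resistive={mp['MP_resistive']:.2f} J/min over {mp['n_breaths']} breaths")

tables = simulate_cohort(CohortSpec(seed=1))
cohort = tables["cohort"]
rho = spearman(cohort["MP"].to_numpy(), cohort["delta_KiS"].to_numpy())
wil = wilcoxon_asymptotic(PairedSample(ids=list(cohort["animal"]),
                                       a=cohort["KiS_first"].to_numpy(),
                                       b=cohort["KiS_second"].to_numpy()))
print(f"cohort: Spearman rho={rho.rho:.3f} (p={rho.p:.3f}); "
      f"paired KiS Wilcoxon Z={wil.Z:.3f}, p={wil.p:.3f}")
```

prints

```
breath 0: VT=0.300 L  Pplat=22.2  dP=17.0 cmH2O
fit: E=57.1 cmH2O/L  R=12.4 cmH2O*s/L  R2=0.9984
median MP: total=12.35  elastic=8.00  resistive=4.36 J/min over 10 breaths
cohort: Spearman rho=0.833 (p=0.010); paired KiS Wilcoxon Z=2.521, p=0.012
```

The noisy per-breath fit recovers the generating E = 57.3 cmH₂O/L and
R = 12.4 cmH₂O·s/L; the median MP of ~12.4 J/min matches the closed-form
PV-loop area for these settings; the cohort draw at seed 1 realizes a sample
rank correlation of 0.833 around the generator's target, and the all-positive
paired KiS differences give the n = 8 asymptotic Wilcoxon p of 0.012.

## Command line

```sh
vili-power simulate --scenario injured_vcv --seed 1 --out simulated/
vili-power mechanics --input simulated/injured_vcv_waveform.csv --out mechanics.csv
vili-power power --input simulated/injured_vcv_waveform.csv --reference atmospheric
vili-power patlak --tac tac.csv --plasma plasma.csv --t-star 20 --f-gas 0.5
vili-power aeration --ct ct.nii --mask mask.nii
vili-power gasx --input bloodgas.csv
vili-power stats --cohort cohort.csv
vili-power pipeline --scenario cohort8 --seed 1 --out results/
```

Shipped scenarios: `injured_vcv` (noisy volume-dependent-elastance waveforms),
`patlak_demo` (noisy dynamic PET curves), `cohort8` (8-animal two-timepoint
cohort). All flags can come from a YAML config; CLI flags take precedence.

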