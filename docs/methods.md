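# Methods

## Respiratory mechanics

The analysis treats the respiratory system as a single compartment obeying
the equation of motion

    P_aw(t) = E·V(t) + R·V̇(t) + P0,

optionally with volume-dependent elastance E(V) = E1 + E2·V. Flow is in L/s
(inspiration positive), pressures in cmH₂O, volume in L, so E is cmH₂O/L and
R cmH₂O·s/L. The fit is ordinary least squares over one breath cycle with the
zero-flow pause excluded: pause samples have V ≈ V_T and V̇ ≈ 0 and are nearly
collinear with the intercept, adding no information and distorting the fit
weighting. P0 is reported as fitted and is not constrained to the set PEEP.
%E2 = 100·E2·V_T/(E1 + E2·V_T) is signed: negative values indicate
elastance falling with inflation (recruitment-dominated), positive values
overdistension.

Breath onset is the upward flow crossing of +0.02 L/s preceded by 50 ms of
sub-threshold flow (hysteresis against sensor noise); both values are
configurable. A trailing breath is kept only if its expiration completed, so
recordings truncated mid-inspiration drop the partial cycle. Volume is the
cumulative trapezoidal integral of flow, re-zeroed at each onset — no global
leak correction, which matches the per-breath scope of all derived
quantities.

Window conventions (configurable, 100 ms defaults): P_plat is the mean airway
pressure over the last 100 ms of the inspiratory pause, measured PEEP the
mean over the last 100 ms of expiration. ΔP = P_plat − PEEP holds exactly by
construction. Transpulmonary pressure is P_aw − P_eso; ΔP_trans is the
plateau P_trans (same window as P_plat) minus the cycle minimum of P_trans.
End-expiratory P_trans may legitimately be negative in injured, heavy lungs.

## Mechanical energy and power

ME is the trapezoidal integral of (P_aw − P_ref) dV over the inspiratory limb
(onset through pause end), converted with 1 cmH₂O·L = 0.0980665 J, and
MP = ME × RR. Two references are first-class: `atmospheric` (P_ref = 0; the
work done against PEEP is included) and `peep` (P_ref = measured PEEP; tidal
work only). Published PV-loop power values differ in exactly this choice and
per-subject medians of either convention cannot be reconciled from printed
summary tables, so both are exposed and tagged in every result rather than
guessing a single intent. Expiratory (dissipated) energy is not subtracted.

The resistive component is ∫ R·V̇ dV with the fitted R, and the elastic
component is defined as the remainder ME − ME_res, making the decomposition
closed to machine precision on every breath — mirroring reports in which
elastic and resistive power sum to the total. For a constant-flow breath the
closed form is ME = PEEP·V_T + E·V_T²/2 + R·V̇·V_T (atmospheric reference);
at 100 Hz the numerical integral agrees within a few tenths of a percent.

## PET kinetics

Patlak analysis regresses y = C_T(t)/C_p(t) on x = ∫₀ᵗC_p dτ / C_p(t) over
frames with mid-time ≥ t\*; the slope is Ki (1/min). t\* defaults to 20 min
(configurable): by then the reversible compartment of lavage-injured lung
(k2 + k3 ≈ 0.25/min ⇒ transient half-life ≈ 2.8 min) has equilibrated.
Frames are unweighted; optional weights ∝ duration are available but not
default. The plasma curve is piecewise linear with an exact running
integral.

The blood fraction comes from nonlinear least squares of the irreversible
two-tissue-compartment model

    dC1/dt = K1·C_p − (k2 + k3)·C1,   dC2/dt = k3·C1,
    C_model = (1 − V_b)·(C1 + C2) + V_b·C_blood,

with C_blood = C_p (no hematocrit correction; the study species' blood data
are inputs, not modeled). The convolution is evaluated by an exact
exponential-filter recursion for piecewise-linear input on a 0.02-min grid —
a numerical route deliberately independent of the generator's closed-form
exponential-sum solution, so recovery tests exercise two separate code paths.
The macro-parameter K1·k3/(k2 + k3) equals the Patlak Ki.

Note one structural fact the normalization itself motivates: the measured
voxel curve contains the blood term, so its Patlak slope converges to
(1 − V_b)·Ki, not Ki. Recovery benchmarks therefore run on the pure tissue
curve (V_b = 0); pipeline results on realistic curves carry the ~5 %
attenuation that the KiS normalization (dividing by 1 − F_Gas − F_Blood)
is designed to compensate.

KiS = Ki/(1 − F_Gas − F_Blood) requires a positive tissue fraction and is
undefined (error) otherwise; ΔKiS is median(second ROI) − median(first ROI).

## CT aeration

F_Gas = HU/−1000 clipped to [0, 1]; tissue density is water-equivalent
1.0 g/ml, so voxel mass = voxel volume × (1 − F_Gas). Compartment bins are
left-closed on the denser side: hyper < −900, normal [−900, −500), poor
[−500, −100), non-aerated ≥ −100 HU. The upper poor-aeration bound is −100 HU
(the standard quantitative-CT convention). Masked voxels outside
[−1024, 100] HU are counted but flagged (metal/artifact guard). The partition
is exhaustive and exclusive, so compartment masses sum to the total exactly
and relative masses to 100 %.

## Gas exchange

PAO₂ = F_IO₂·(P_atm − P_H₂O) − PaCO₂/RQ with defaults 760/47 mmHg and
RQ 0.8; AaDO₂ = PAO₂ − PaO₂. O₂ content is 1.34·Hb·SO₂ + 0.0031·PO₂ (ml/dl);
venous admixture Qs/Qt = (CcO₂ − CaO₂)/(CcO₂ − CvO₂) with end-capillary
blood fully saturated at alveolar PO₂. All constants are configurable —
different "standard formula" constant sets exist, and none is asserted to be
the one used for any particular published table. SV = 1000·CO/HR (ml).

## Statistics

The conventions follow SPSS-style "asymptotic significance" reporting
exactly, because the downstream p-values depend on them:

* Wilcoxon signed-rank: zero differences dropped; midranks on tied |d|;
  Z = (W⁺ − n(n+1)/4)/√(n(n+1)(2n+1)/24 − Σ(t³−t)/48); no continuity
  correction; p = 2(1 − Φ(|Z|)). At n = 8 this yields p = 0.0117, 0.0173,
  0.0251, 0.0357 for minority-sign rank sums 0–3 — printed as 0.012, 0.017,
  0.025, 0.036.
* Spearman: Pearson correlation of midranks (the 6Σd²/(n(n²−1)) form when
  untied); p from t = ρ√((n−2)/(1−ρ²)) on n−2 df. |ρ| = 1 is flagged and
  reported at the machine floor.
* Quartiles: weighted-average position (n+1)p (the HAVERAGE convention of
  the named software); plain linear interpolation available via `method=`.
* No multiple-testing correction is applied anywhere.

scipy's `wilcoxon` and `spearmanr` serve as independent cross-checks in the
test suite; they are not the implementation.

## Synthetic-data generators

All generators are pure functions of their seed.

**Ventilation.** Volume-controlled: constant inspiratory flow, end-inspiratory
pause, passive expiration, defaults V_T 6 ml/kg at 48 kg, I:E 1:1, flow
35 L/min, PEEP 5 cmH₂O, 100 Hz. The sampled flow is constructed to be
*trapezoid-consistent*: the set flow is snapped to the sample grid so the
delivered V_T is exact, a half-amplitude sample marks flow cut-off, and
expiration integrates V̇ = −(E1·V + E2·V²)/R with the implicit trapezoid rule
(closed-form per step, stable for arbitrarily stiff E/R). Consequently the
analysis-side trapezoidal volume reproduces the generator volume exactly, the
equation of motion holds at every sample, airway pressure relaxes exactly to
PEEP in expiration, and noiseless fits recover E, R, P0 to machine precision
— discretization never masquerades as model error. Airway and esophageal
pressure receive independent white noise; P_eso = E_cw·V + baseline
(cardiogenic oscillation intentionally not modeled).

**Tracer.** Plasma input is the conventional Feng shape
C_p(t) = (A1·t − A2 − A3)e^{λ1 t} + A2 e^{λ2 t} + A3 e^{λ3 t} with defaults
(851.1, −4.13, 20.8, −0.12, 21.9, −0.01) in kBq/ml and 1/min. Tissue curves
are the closed-form convolution solution of the irreversible 2TC system
(exponential-sum algebra), frame means are exact integrals over a 75-min
schedule (12×10 s, 6×30 s, 5×2 min, 12×5 min), and Gaussian noise scales as
1/√(frame duration). Plasma is sampled every 10 s through the input peak,
then 1 min to 10 min, then 5 min — coarser-than-peak sampling (e.g. plain
0.5-min spacing) loses ~1.5 % of the input integral and is not used.

**CT.** Voxel HU are drawn from per-compartment truncated Gaussians (means
−950/−700/−300/0 HU, σ 30, truncated to the compartment bins so labels are
exact by construction). Target fractions are *mass* fractions: voxel counts
are weighted by the inverse expected tissue fraction of each compartment, so
a 10⁶-voxel volume reproduces the requested relative masses to ≪1 % absolute.

**Cohort.** n animals (default 8), Gaussian copula between median MP and
ΔKiS with copula correlation ρ_z = 2·sin(π·ρ_s/6) for a target population
Spearman ρ_s; marginals are lognormal maps matched to median/IQR targets
(MP 13.5/4.9 J/min declining over 0/6/12/18 h by a fixed profile; first-scan
KiS 0.0136/0.0041 min⁻¹; ΔKiS 0.0184/0.0180 min⁻¹). Because every marginal
map is strictly monotone, the rank structure of the copula is preserved
exactly, and lognormal ΔKiS makes all paired differences positive — the
configuration in which the n = 8 paired test prints p = 0.012. The
finite-sample expectation of the sample Spearman coefficient under the
copula, E[r_s] = 6/(π(n+1))·[arcsin ρ_z + (n−2)·arcsin(ρ_z/2)], is exposed
as `CohortSpec.expected_spearman()` and is the reference for recovery tests
(at n = 8 it is visibly below the population target: 0.675 for ρ_s = 0.74).
Aeration and blood-gas tables use plausible independent marginals and are
schema carriers, not correlated outcomes.

**What the generators do not emulate.** Real tracings contain cardiogenic
oscillations, secretions/coughs, leak drift, and ventilator valve dynamics;
real PET has scanner resolution, scatter/attenuation residuals, and motion;
real CT has beam hardening and segmentation error; real cohorts have
correlated physiology across all variables. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated forward models,
not robustness to every artifact of real data.

## Numerical choices and problem sizes

Recovery benchmarks run at sizes where Monte-Carlo error is comfortably below
the tolerances they check: 100 noisy breaths (σ = 0.5 cmH₂O) for mechanics,
100 noisy tracer seeds, 10⁶ CT voxels, 500 cohort seeds (the null-correlation
check uses 3000 seeds, since the n = 8 per-seed spread of r_s is ±0.38 and a
1000-seed mean still fluctuates by ~0.012). Rank-deficient regression designs
raise immediately with a diagnostic; boundary-pinned V_b and pressure-ordering
violations are flagged, not silently accepted; empty masks, all-zero
differences, and missing channels are errors or flagged unavailability per
operation.

## Known limitations

* Pause and PEEP windows, t\*, and frame weighting are configurable because
  the corresponding acquisition conventions vary between labs; defaults are
  reasonable, not canonical.
* The Patlak pathway reports the slope of the measured curve; blood-volume
  attenuation (1 − V_b) is handled downstream by the KiS normalization, not
  by blood-subtracting the TAC.
* Micro-parameters (K1, k2, k3) from the 2TC fit are well identified only
  with early dense plasma sampling; the macro Ki is robust.
* The closed-form MP formula family is intentionally not the primary path —
  power here is always the integral of the recorded PV loop.
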