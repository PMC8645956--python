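"""Synthetic inputs with known ground truth for every analysis stage.

Four generators, all pure functions of their seed:

* :func:`simulate_ventilation` — volume-controlled ventilation from a
  one-compartment lung with optional volume-dependent elastance.  Constant
  inspiratory flow, end-inspiratory pause, passive exponential expiration
  with the same E(V) and R, so the equation of motion holds over the whole
  cycle and fitted parameters must recover the generating values.
* :func:`simulate_tracer` — Feng-model arterial plasma input plus the
  closed-form solution of the irreversible two-tissue-compartment system,
  framed over a 75-min dynamic acquisition.
* :func:`simulate_ct` — voxel HU mixtures of the four aeration compartments
  drawn from truncated Gaussians, with voxel counts weighted so the target
  fractions are *mass* fractions.
* :func:`simulate_cohort` — an n-animal, two-timepoint cohort drawn from a
  Gaussian copula with a controllable rank correlation between median
  mechanical power and ΔKiS, lognormal marginals scaled to median/IQR
  targets, and strictly positive KiS differences on demand.

Default parameter values mirror the study conditions: VT 6 ml/kg at ~48 kg
body mass, I:E 1:1, inspiratory flow 35 L/min, PEEP 5 cmH2O, a 75-min
dynamic PET, and an 8-animal cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .pet_kinetics import PlasmaInput, TimeActivityCurve
from .resp_mechanics import WaveformRecording

__all__ = [
    "LungModelParams",
    "VentSettings",
    "TracerModelParams",
    "CohortSpec",
    "simulate_ventilation",
    "simulate_tracer",
    "simulate_ct",
    "simulate_cohort",
    "feng_plasma",
    "tissue_curve_closed_form",
    "default_frame_schedule",
    "SCENARIOS",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class LungModelParams:
    """One-compartment respiratory system for the forward waveform model."""

    E1: float = 57.3        # cmH2O/L, volume-independent elastance
    E2: float = 0.0         # cmH2O/L^2, volume-dependent term
    R: float = 12.4         # cmH2O·s/L
    E_cw: float = 10.0      # chest-wall elastance, cmH2O/L (drives Peso)
    peso_baseline: float = 5.0  # cmH2O
    PEEP: float = 5.0       # cmH2O
    noise_sigma: float = 0.0  # cmH2O white noise on Paw and Peso
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E1 <= 0 or self.R <= 0:
            raise ValueError("require E1 > 0 and R > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class VentSettings:
    """Volume-controlled ventilation settings."""

    vt_ml_kg: float = 6.0
    body_mass_kg: float = 48.0
    rr: float = 31.0            # breaths/min
    insp_flow_lpm: float = 35.0
    ie_ratio: float = 1.0       # inspiratory:expiratory time ratio (I/E)
    pause_fraction: float | None = None  # of inspiratory time; None = remainder
    sample_rate: float = 100.0  # Hz

    @property
    def vt_l(self) -> float:
        return self.vt_ml_kg * self.body_mass_kg / 1000.0

    def timing(self) -> tuple[float, float, float, float]:
        """(cycle, inspiratory, flow, pause) durations in seconds."""
        cycle = 60.0 / self.rr
        t_insp = cycle * self.ie_ratio / (1.0 + self.ie_ratio)
        t_flow = self.vt_l / (self.insp_flow_lpm / 60.0)
        if self.pause_fraction is None:
            t_pause = t_insp - t_flow
        else:
            t_pause = self.pause_fraction * t_insp
        if t_flow + t_pause > t_insp + 1e-9 or t_pause < 0:
            raise ValueError(
                f"infeasible timing: flow {t_flow:.3f}s + pause {t_pause:.3f}s "
                f"exceeds inspiratory time {t_insp:.3f}s"
            )
        return cycle, t_insp, t_flow, t_pause


#: Conventional FDG arterial-input shape (Feng model), kBq/ml with t in min.
FENG_DEFAULTS = (851.1, -4.13, 20.8, -0.12, 21.9, -0.01)


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """(starts, durations) in min for a 75-min dynamic scan."""
    durations = np.concatenate([
        np.full(12, 10.0 / 60.0),   # 12 x 10 s
        np.full(6, 30.0 / 60.0),    # 6 x 30 s
        np.full(5, 2.0),            # 5 x 2 min
        np.full(12, 5.0),           # 12 x 5 min
    ])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


@dataclass
class TracerModelParams:
    """Irreversible 2TC forward model + Feng input."""

    feng: tuple = FENG_DEFAULTS   # (A1, l1, A2, l2, A3, l3)
    K1: float = 0.01              # ml/ml/min
    k2: float = 0.2               # 1/min
    k3: float = 0.05              # 1/min
    Vb: float = 0.05
    frame_starts: np.ndarray | None = None
    frame_durations: np.ndarray | None = None
    plasma_times: np.ndarray | None = None
    noise_scale: float = 0.0      # kBq/ml at 1-min frame duration
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0 or not 0 <= self.Vb < 1:
            raise ValueError("rates must be >= 0 and Vb in [0, 1)")
        if self.frame_starts is None or self.frame_durations is None:
            self.frame_starts, self.frame_durations = default_frame_schedule()
        if self.plasma_times is None:
            end = float(self.frame_starts[-1] + self.frame_durations[-1])
            self.plasma_times = np.unique(np.concatenate([
                np.arange(0.0, 3.0, 10.0 / 60.0),
                np.arange(3.0, 10.0, 1.0),
                np.arange(10.0, end + 1e-9, 5.0),
            ]))

    @property
    def Ki_true(self) -> float:
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else 0.0


@dataclass
class CohortSpec:
    """Two-timepoint cohort with controllable MP–ΔKiS rank correlation."""

    n_animals: int = 8
    rank_correlation: float = 0.74   # target population Spearman rho
    mp_median: float = 13.5          # J/min at intervention start
    mp_iqr: float = 4.9
    mp_time_profile: tuple = (1.0, 0.726, 0.733, 0.630)  # 0/6/12/18 h ratios
    kis_first_median: float = 0.0136  # 1/min
    kis_first_iqr: float = 0.0041
    delta_kis_median: float = 0.0184
    delta_kis_iqr: float = 0.0180
    force_positive_deltas: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 3:
            raise ValueError("need >= 3 animals")
        if not -1.0 <= self.rank_correlation <= 1.0:
            raise ValueError("rank correlation must be in [-1, 1]")

    @property
    def copula_rho(self) -> float:
        """Gaussian-copula correlation giving the target population Spearman."""
        return 2.0 * math.sin(math.pi * self.rank_correlation / 6.0)

    def expected_spearman(self) -> float:
        """Exact finite-sample E[r_s] for bivariate-normal ranks (Moran)."""
        rho, n = self.copula_rho, self.n_animals
        return (6.0 / (math.pi * (n + 1))) * (
            math.asin(rho) + (n - 2) * math.asin(rho / 2.0)
        )


# ---------------------------------------------------------------------------
# Ventilator waveforms
# ---------------------------------------------------------------------------

def _passive_expiration(
    v0: float, n_steps: int, dt: float, lung: LungModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoid-consistent passive expiration of (E1 + E2·V)·V + R·V̇ = 0.

    Integrates V' = −(a·V + b·V²) (a = E1/R, b = E2/R) with the implicit
    trapezoid rule so that cumulative trapezoidal re-integration of the flow
    samples reproduces the volume samples exactly — the same convention the
    analysis side uses.  Returns (volume, flow) arrays of length n_steps.
    """
    a = lung.E1 / lung.R
    b = lung.E2 / lung.R
    vol = np.empty(n_steps)
    flow = np.empty(n_steps)
    v_prev, f_prev = v0, 0.0
    for k in range(n_steps):
        # closed-form solve of v = c − dt/2·(a·v + b·v²), c = v_prev + dt/2·f_prev
        # (stable for arbitrarily stiff a = E/R)
        c = v_prev + 0.5 * dt * f_prev
        lin = 1.0 + 0.5 * dt * a
        quad = 0.5 * dt * b
        if abs(quad) < 1e-15:
            v = c / lin
        else:
            disc = lin * lin + 4.0 * quad * c
            v = (-lin + math.sqrt(max(disc, 0.0))) / (2.0 * quad)
        f = -(a * v + b * v * v)
        vol[k], flow[k] = v, f
        v_prev, f_prev = v, f
    return vol, flow


def simulate_ventilation(
    settings: VentSettings = VentSettings(),
    lung: LungModelParams = LungModelParams(),
    n_breaths: int = 10,
    lead_in_s: float = 0.2,
    meta: dict | None = None,
) -> WaveformRecording:
    """Simulate a volume-controlled ventilation recording.

    Paw = (E1 + E2·V)·V + R·V̇ + PEEP + noise over the whole cycle (the
    passive-expiration flow satisfies the same equation of motion, so Paw
    relaxes exactly to PEEP); Peso = E_cw·V + baseline + noise.  Volume is
    re-zeroed at each onset; the ~1 % end-expiratory volume residual is
    discarded, mimicking a leak-free re-zeroed integrator.
    """
    fs = settings.sample_rate
    dt = 1.0 / fs
    cycle, t_insp, t_flow, t_pause = settings.timing()
    vt = settings.vt_l
    n_cycle = int(round(cycle * fs))
    n_flow = int(round(t_flow * fs))
    # snap the constant flow to the grid so the delivered VT is exact
    flow_rate = vt / (n_flow * dt)
    stop_pause = int(round(t_insp * fs))
    n_exp = n_cycle - stop_pause
    if stop_pause < n_flow + 2:
        raise ValueError("pause too short at this sample rate")
    if n_exp < 2:
        raise ValueError("expiratory phase too short at this sample rate")

    flw = np.empty(n_cycle)
    # constant-flow inspiration with a half-amplitude transition sample so
    # the trapezoidal volume integral hits VT exactly at flow cut-off
    flw[:n_flow] = flow_rate
    flw[n_flow] = flow_rate / 2.0
    flw[n_flow + 1 : stop_pause] = 0.0
    vol = np.empty(n_cycle)
    vol[: stop_pause] = np.minimum(
        np.cumsum(np.concatenate([[0.0], (flw[:stop_pause - 1] + flw[1:stop_pause]) / 2.0])) * dt,
        vt,
    )
    vol[stop_pause - 1] = vt
    # passive expiration (trapezoid-consistent with the same E(V), R)
    vol[stop_pause:], flw[stop_pause:] = _passive_expiration(
        vt, n_exp, dt, lung)

    n_lead = int(round(lead_in_s * fs))
    volume = np.concatenate([np.zeros(n_lead), np.tile(vol, n_breaths)])
    flow = np.concatenate([np.zeros(n_lead), np.tile(flw, n_breaths)])
    paw = (lung.E1 + lung.E2 * volume) * volume + lung.R * flow + lung.PEEP
    peso = lung.E_cw * volume + lung.peso_baseline

    rng = np.random.default_rng(lung.seed)
    if lung.noise_sigma > 0:
        paw = paw + rng.normal(0.0, lung.noise_sigma, paw.size)
        peso = peso + rng.normal(0.0, lung.noise_sigma, peso.size)

    n = paw.size
    info = {
        "set_PEEP_cmH2O": lung.PEEP,
        "set_RR_per_min": settings.rr,
        "body_mass_kg": settings.body_mass_kg,
        "VT_true_L": vt,
    }
    if meta:
        info.update(meta)
    return WaveformRecording(
        time=np.arange(n) * dt, paw=paw, flow=flow, peso=peso,
        sample_rate=fs, meta=info,
    )


# ---------------------------------------------------------------------------
# Tracer kinetics: exponential-sum algebra and the closed-form 2TC solution
# ---------------------------------------------------------------------------

class _ExpSum:
    """Sum of c·t^p·e^{λt} terms, p ∈ {0, 1}; closed under the operations
    needed here (convolution with a decaying exponential, antiderivative)."""

    _EPS = 1e-12

    def __init__(self, terms: list[tuple[int, float, float]]):
        self.terms = [(p, c, lam) for p, c, lam in terms if c != 0.0]

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for p, c, lam in self.terms:
            out = out + c * t**p * np.exp(lam * t)
        return out

    def scale(self, factor: float) -> "_ExpSum":
        return _ExpSum([(p, c * factor, lam) for p, c, lam in self.terms])

    def __add__(self, other: "_ExpSum") -> "_ExpSum":
        return _ExpSum(self.terms + other.terms)

    def convolve_exp(self, alpha: float) -> "_ExpSum":
        """Convolution with e^{−αt} on [0, t]."""
        out: list[tuple[int, float, float]] = []
        for p, c, lam in self.terms:
            s = lam + alpha
            if abs(s) < self._EPS:
                raise NotImplementedError("degenerate rate λ = −α")
            if p == 0:
                out += [(0, c / s, lam), (0, -c / s, -alpha)]
            else:  # p == 1
                out += [(1, c / s, lam), (0, -c / s**2, lam),
                        (0, c / s**2, -alpha)]
        return _ExpSum(out)

    def antiderivative(self) -> "_ExpSum":
        """F with F(0) = 0 and F' = self."""
        out: list[tuple[int, float, float]] = []
        for p, c, lam in self.terms:
            if abs(lam) < self._EPS:
                if p == 0:
                    out.append((1, c, 0.0))
                else:
                    raise NotImplementedError("t^2 term not supported")
            elif p == 0:
                out += [(0, c / lam, lam), (0, -c / lam, 0.0)]
            else:
                out += [(1, c / lam, lam), (0, -c / lam**2, lam),
                        (0, c / lam**2, 0.0)]
        return _ExpSum(out)


def feng_plasma(feng: tuple = FENG_DEFAULTS) -> _ExpSum:
    """Feng arterial input Cp(t) = (A1·t − A2 − A3)e^{λ1 t} + A2 e^{λ2 t} + A3 e^{λ3 t}."""
    a1, l1, a2, l2, a3, l3 = feng
    return _ExpSum([(1, a1, l1), (0, -(a2 + a3), l1), (0, a2, l2), (0, a3, l3)])


def tissue_curve_closed_form(params: TracerModelParams) -> _ExpSum:
    """Closed-form model curve (1−Vb)·(C1+C2) + Vb·Cp for the Feng input."""
    cp = feng_plasma(params.feng)
    alpha = params.k2 + params.k3
    c1 = cp.convolve_exp(alpha).scale(params.K1)
    c2 = c1.antiderivative().scale(params.k3)
    tissue = c1 + c2
    return tissue.scale(1.0 - params.Vb) + cp.scale(params.Vb)


def simulate_tracer(
    params: TracerModelParams = TracerModelParams(),
) -> tuple[PlasmaInput, TimeActivityCurve]:
    """Plasma samples and frame-mean tissue TAC for an irreversible 2TC lung.

    Frame means are exact integrals of the closed-form curve; Gaussian noise
    is scaled by 1/sqrt(frame duration) (counting statistics) times
    ``noise_scale``.
    """
    cp = feng_plasma(params.feng)
    plasma = PlasmaInput(times=params.plasma_times,
                         activity=np.maximum(cp(params.plasma_times), 0.0))

    model = tissue_curve_closed_form(params)
    anti = model.antiderivative()
    starts = params.frame_starts
    durs = params.frame_durations
    means = (anti(starts + durs) - anti(starts)) / durs

    if params.noise_scale > 0:
        rng = np.random.default_rng(params.seed)
        means = means + rng.normal(0.0, params.noise_scale / np.sqrt(durs))
    return plasma, TimeActivityCurve(
        frame_starts=starts, frame_durations=durs,
        activity=means, roi="synthetic_lung",
    )


# ---------------------------------------------------------------------------
# CT voxel fields
# ---------------------------------------------------------------------------

#: Per-compartment HU bin, mean, and sigma for the voxel mixture model.
_CT_BINS = {
    "hyper": (-1024.0, -900.0, -950.0, 30.0),
    "normal": (-900.0, -500.0, -700.0, 30.0),
    "poor": (-500.0, -100.0, -300.0, 30.0),
    "non": (-100.0, 100.0, 0.0, 30.0),
}


def _expected_tissue_fraction(lo: float, hi: float, mu: float, sd: float) -> float:
    """E[1 − clip(HU/−1000, 0, 1)] under a truncated Gaussian on [lo, hi)."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    grid = np.linspace(lo, hi, 2001)
    pdf = truncnorm.pdf(grid, a, b, loc=mu, scale=sd)
    tissue = 1.0 - np.clip(grid / -1000.0, 0.0, 1.0)
    return float(np.trapezoid(tissue * pdf, grid) / np.trapezoid(pdf, grid))


def simulate_ct(
    mass_fractions: dict,
    n_voxels: int = 100_000,
    voxel_dims_mm: tuple = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Voxel HU field with known compartment *mass* fractions.

    ``mass_fractions`` maps hyper/normal/poor/non to fractions summing to 1.
    HU are drawn from per-compartment truncated Gaussians (means −950/−700/
    −300/0 HU, sigma 30, truncated to the compartment bins so labels are
    exact); voxel counts are weighted by the inverse expected tissue fraction
    so the realized mass fractions match the targets.  Returns
    ``(hu_values, labels, voxel_volume_ml)``; order is shuffled.
    """
    fracs = np.array([mass_fractions.get(c, 0.0) for c in _CT_BINS], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mass fractions must be >= 0 and sum to 1")
    names = list(_CT_BINS)
    m_bar = np.array([_expected_tissue_fraction(*_CT_BINS[c]) for c in names])
    weights = np.where(fracs > 0, fracs / m_bar, 0.0)
    weights /= weights.sum()
    counts = np.floor(weights * n_voxels).astype(int)
    counts[np.argmax(weights)] += n_voxels - counts.sum()

    rng = np.random.default_rng(seed)
    hu_parts, lab_parts = [], []
    for c, n_c in zip(names, counts):
        if n_c == 0:
            continue
        lo, hi, mu, sd = _CT_BINS[c]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        hu_parts.append(truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_c,
                                      random_state=rng))
        lab_parts.append(np.full(n_c, c))
    hu = np.concatenate(hu_parts)
    labels = np.concatenate(lab_parts)
    perm = rng.permutation(hu.size)
    voxel_volume_ml = float(np.prod(voxel_dims_mm)) / 1000.0
    return hu[perm], labels[perm], voxel_volume_ml


# ---------------------------------------------------------------------------
# Multi-animal cohort
# ---------------------------------------------------------------------------

def _lognormal_from_median_iqr(z: np.ndarray, median: float, iqr: float
                               ) -> np.ndarray:
    """Monotone map of standard-normal draws to a lognormal with the target
    median and IQR (rank structure preserved exactly)."""
    q = norm.ppf(0.75)
    s = math.asinh(iqr / (2.0 * median)) / q
    return median * np.exp(s * z)


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> dict:
    """Per-animal tables for the cohort-level statistics.

    Returns a dict with:

    ``cohort`` — one row per animal: median MP (total/elastic/resistive),
    null respiratory variables, KiS at both scans, and ΔKiS.  MP and ΔKiS
    share a Gaussian copula at the spec's rank correlation; because the
    marginal maps are strictly monotone the population Spearman rho equals
    the copula target.
    ``mp_series`` — per-animal MP at 0/6/12/18 h (fixed decline profile).
    ``aeration`` — first/second lung mass and gas volume per animal.
    ``bloodgas`` — plausible per-animal blood-gas/hemodynamic panels.
    """
    n = spec.n_animals
    rng = np.random.default_rng(spec.seed)
    rho_z = spec.copula_rho
    cov = np.array([[1.0, rho_z], [rho_z, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n,
                                method="cholesky")
    mp0 = _lognormal_from_median_iqr(z[:, 0], spec.mp_median, spec.mp_iqr)
    delta = _lognormal_from_median_iqr(z[:, 1], spec.delta_kis_median,
                                       spec.delta_kis_iqr)
    if not spec.force_positive_deltas:
        delta = delta - np.median(delta) + spec.delta_kis_median

    kis_first = _lognormal_from_median_iqr(rng.standard_normal(n),
                                           spec.kis_first_median,
                                           spec.kis_first_iqr)
    kis_second = kis_first + delta

    animals = [f"animal_{i+1:02d}" for i in range(n)]
    # deterministic decline profile: the per-animal median over timepoints is
    # then strictly monotone in the copula draw, so the target rank
    # correlation is preserved exactly
    profile = np.asarray(spec.mp_time_profile)
    series = mp0[:, None] * profile[None, :]
    mp_median_per_animal = np.median(series, axis=1)

    # null respiratory variables: plausible marginals, independent of ΔKiS
    def null_var(median: float, iqr: float) -> np.ndarray:
        return _lognormal_from_median_iqr(rng.standard_normal(n), median, iqr)

    cohort = pd.DataFrame({
        "animal": animals,
        "MP": mp_median_per_animal,
        "MP_elastic": 0.674 * mp_median_per_animal,
        "MP_resistive": 0.326 * mp_median_per_animal,
        "Ppeak": null_var(29.6, 3.2),
        "Pplat": null_var(23.1, 3.4),
        "PEEP": null_var(7.0, 4.0),
        "dP": null_var(18.2, 3.5),
        "dPtrans": null_var(22.7, 3.4),
        "RR": null_var(22.0, 6.0),
        "E": null_var(56.0, 11.0),
        "R_aw": null_var(16.0, 3.0),
        "pctE2": null_var(28.5, 3.7) * -1.0,
        "KiS_first": kis_first,
        "KiS_second": kis_second,
        "delta_KiS": delta,
    })

    ratio_mass = rng.normal(635.6 / 854.1, 0.05, size=n)
    ratio_gas = rng.normal(780.2 / 850.7, 0.05, size=n)
    mass_first = null_var(854.1, 177.2)
    gas_first = null_var(850.7, 143.2)
    aeration = pd.DataFrame({
        "animal": animals,
        "lung_mass_first_g": mass_first,
        "lung_mass_second_g": mass_first * ratio_mass,
        "gas_volume_first_ml": gas_first,
        "gas_volume_second_ml": gas_first * ratio_gas,
    })

    bloodgas = pd.DataFrame({
        "animal": animals,
        "PaO2": null_var(105.5, 19.1),
        "PaCO2": null_var(55.0, 10.0),
        "pHa": rng.normal(7.35, 0.03, size=n),
        "SaO2": np.clip(rng.normal(0.96, 0.015, size=n), 0.0, 1.0),
        "Hb": null_var(9.5, 1.2),
        "PvO2": null_var(42.0, 6.0),
        "SvO2": np.clip(rng.normal(0.70, 0.05, size=n), 0.0, 1.0),
        "F_IO2": np.full(n, 0.32),
        "CO": null_var(7.1, 1.5),
        "HR": null_var(104.0, 20.0),
    })

    mp_series = pd.DataFrame(series, columns=["0h", "6h", "12h", "18h"])
    mp_series.insert(0, "animal", animals)
    return {"cohort": cohort, "mp_series": mp_series,
            "aeration": aeration, "bloodgas": bloodgas}


# ---------------------------------------------------------------------------
# Shipped scenarios
# ---------------------------------------------------------------------------

SCENARIOS: dict = {
    # intervention-start mechanics of the lavage-injured lung
    "injured_vcv": {
        "kind": "ventilation",
        "settings": dict(vt_ml_kg=6.5, body_mass_kg=47.7, rr=31.0,
                         insp_flow_lpm=35.0, ie_ratio=1.0, sample_rate=100.0),
        "lung": dict(E1=70.0, E2=-45.0, R=12.4, PEEP=9.0, noise_sigma=0.3),
        "n_breaths": 20,
    },
    "patlak_demo": {
        "kind": "tracer",
        "params": dict(K1=0.01, k2=0.2, k3=0.05, Vb=0.05, noise_scale=0.05),
    },
    "cohort8": {
        "kind": "cohort",
        "spec": dict(n_animals=8, rank_correlation=0.74),
    },
}
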