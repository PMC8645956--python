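"""Ventilator-waveform respiratory mechanics.

Reads synchronized airway pressure / flow (/ esophageal pressure) tracings,
segments them into breaths, and computes per-breath static and dynamic
mechanics: peak/mean/plateau pressures, measured PEEP, tidal volume, driving
pressure, transpulmonary quantities, and equation-of-motion fits

    Paw = E·V + R·V̇ + P0                      (linear single compartment)
    Paw = E1·V + E2·V²  + R·V̇ + P0            (volume-dependent elastance)

by ordinary least squares over the breath cycle.  The volume-dependent model
summarizes nonlinearity as %E2 = 100·E2·VT / (E1 + E2·VT): negative values
indicate intra-tidal recruitment (decreasing elastance), positive values
overdistension.

Conventions
-----------
* flow in L/s, inspiration positive; pressures in cmH2O; volume in L.
* A breath spans [onset, end) sample indices; the volume trace is zeroed at
  onset (per-breath re-zeroing, no global leak correction).
* Breath onset detection: upward flow crossing of +0.02 L/s that was preceded
  by sub-threshold flow for a 50 ms hysteresis window.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "WaveformRecording",
    "Breath",
    "BreathMechanics",
    "EoMFit",
    "WaveformFormatError",
    "WaveformDataError",
    "FitError",
    "read_waveform",
    "write_waveform",
    "segment_breaths",
    "integrate_volume",
    "breath_pressures",
    "transpulmonary",
    "fit_equation_of_motion",
    "analyze_recording",
]

# Default channel map for waveform CSV files.
DEFAULT_CHANNELS = {
    "time": "time_s",
    "paw": "paw_cmH2O",
    "flow": "flow_Lps",
    "peso": "peso_cmH2O",
    "flow_units": "L/s",  # or "L/min"
}

#: Breath-onset flow threshold (L/s) and hysteresis window (s).
ONSET_FLOW_THRESHOLD = 0.02
ONSET_HYSTERESIS_S = 0.050


class WaveformFormatError(ValueError):
    """Input file does not match the expected waveform CSV layout."""


class WaveformDataError(ValueError):
    """Waveform content is invalid (too short, non-monotone time, ...)."""


class FitError(RuntimeError):
    """Equation-of-motion regression could not be performed."""


@dataclass
class WaveformRecording:
    """Synchronized pressure/flow time series on a uniform grid.

    Attributes
    ----------
    time : array, s — strictly increasing uniform grid.
    paw : array, cmH2O — airway pressure.
    flow : array, L/s — inspiration positive.
    peso : array or None, cmH2O — esophageal pressure (optional channel).
    sample_rate : float, Hz.
    meta : dict — animal id, timepoint label, set PEEP (cmH2O), set RR
        (1/min), body mass (kg); free-form.
    """

    time: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    peso: np.ndarray | None = None
    sample_rate: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.peso is not None:
            self.peso = np.asarray(self.peso, dtype=float)
        n = self.time.size
        if n < 2:
            raise WaveformDataError("recording needs at least 2 samples")
        for name in ("paw", "flow", "peso"):
            ch = getattr(self, name)
            if ch is not None and ch.size != n:
                raise WaveformDataError(f"channel {name!r} length mismatch")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise WaveformDataError("time must be strictly increasing")
        if self.sample_rate <= 0:
            self.sample_rate = 1.0 / float(np.median(dt))
        if abs(np.median(dt) - 1.0 / self.sample_rate) > 1e-6:
            raise WaveformDataError("time step inconsistent with sample_rate")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class Breath:
    """One ventilatory cycle: half-open sample range [onset, end).

    ``insp_end`` marks the end of positive inspiratory flow; the pause window
    [pause_start, pause_end) is the zero-flow inspiratory hold (may be empty).
    ``volume`` is the cumulative inspired volume in L, zeroed at onset.
    """

    onset: int
    insp_end: int
    end: int
    pause_start: int = 0
    pause_end: int = 0
    volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.onset < self.insp_end <= self.end):
            raise ValueError("require onset < insp_end <= end")

    @property
    def has_pause(self) -> bool:
        return self.pause_end > self.pause_start

    def duration(self, rec: WaveformRecording) -> float:
        return (self.end - self.onset) * rec.dt

    def respiratory_rate(self, rec: WaveformRecording) -> float:
        """Breaths per minute implied by this cycle's duration."""
        return 60.0 / self.duration(rec)


@dataclass
class BreathMechanics:
    """Per-breath pressures and volumes (one row of the mechanics table)."""

    Ppeak: float = math.nan          # cmH2O
    Pmean: float = math.nan          # cmH2O
    Pplat: float = math.nan          # cmH2O; nan if no pause
    PEEP_measured: float = math.nan  # cmH2O
    VT: float = math.nan             # L
    VT_ml_kg: float = math.nan       # ml/kg if body mass known
    RR: float = math.nan             # 1/min
    dP: float = math.nan             # Pplat - PEEP_measured
    Ptrans_peak: float = math.nan    # cmH2O
    Ptrans_endex: float = math.nan   # cmH2O (may be negative)
    dPtrans: float = math.nan        # cmH2O
    flags: list = field(default_factory=list)


@dataclass
class EoMFit:
    """Equation-of-motion regression result.

    For the linear model E1 == E and E2/pctE2 are nan; pctE2 is signed and
    defined only for the volume-dependent model.
    """

    model: str                      # "linear" | "volume_dependent"
    E: float                        # cmH2O/L (E1 + E2·VT for vol-dep)
    R: float                        # cmH2O·s/L
    P0: float                       # cmH2O intercept
    E1: float = math.nan            # cmH2O/L
    E2: float = math.nan            # cmH2O/L^2
    pctE2: float = math.nan         # %, signed
    r_squared: float = math.nan


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_waveform(path: str | Path, config: dict | None = None) -> WaveformRecording:
    """Read a waveform CSV into a validated :class:`WaveformRecording`.

    ``config`` maps logical channels to column names and declares flow units
    (see :data:`DEFAULT_CHANNELS`); flow given in L/min is converted to L/s.
    ``config["meta"]`` is attached to the recording.
    """
    cfg = dict(DEFAULT_CHANNELS)
    if config:
        cfg.update(config)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("time", "paw", "flow"):
        if cfg[key] not in df.columns:
            raise WaveformFormatError(
                f"missing channel column {cfg[key]!r} in {path}"
            )
    flow = df[cfg["flow"]].to_numpy(dtype=float)
    if cfg.get("flow_units", "L/s") in ("L/min", "l/min"):
        flow = flow / 60.0
    peso = None
    if cfg.get("peso") and cfg["peso"] in df.columns:
        peso = df[cfg["peso"]].to_numpy(dtype=float)
    return WaveformRecording(
        time=df[cfg["time"]].to_numpy(dtype=float),
        paw=df[cfg["paw"]].to_numpy(dtype=float),
        flow=flow,
        peso=peso,
        meta=dict(cfg.get("meta", {})),
    )


def write_waveform(rec: WaveformRecording, path: str | Path) -> None:
    """Write a recording to CSV in the canonical column layout.

    Uses full float repr so a write/read round trip is bit-identical.
    """
    cols = {
        "time_s": rec.time,
        "paw_cmH2O": rec.paw,
        "flow_Lps": rec.flow,
    }
    if rec.peso is not None:
        cols["peso_cmH2O"] = rec.peso
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Breath segmentation
# ---------------------------------------------------------------------------

def segment_breaths(
    rec: WaveformRecording,
    min_duration: float = 0.5,
    flow_threshold: float = ONSET_FLOW_THRESHOLD,
    hysteresis: float = ONSET_HYSTERESIS_S,
) -> list[Breath]:
    """Detect breaths at inspiratory flow onsets.

    An onset is an upward crossing of ``flow_threshold`` preceded by
    sub-threshold flow over the ``hysteresis`` window.  Each breath ends at
    the next onset; the final onset yields a breath only if its expiration
    completed (flow went negative and returned near zero by the end of the
    recording), so a recording truncated mid-inspiration drops the partial
    breath.  Breaths shorter than ``min_duration`` seconds are discarded.
    Returns an empty list when no crossings are found.
    """
    flow = rec.flow
    n_hyst = max(1, int(round(hysteresis * rec.sample_rate)))
    above = flow >= flow_threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1

    onsets = []
    for i in rising:
        lo = max(0, i - n_hyst)
        if np.all(flow[lo:i] < flow_threshold):
            onsets.append(int(i))
    if not onsets:
        return []

    breaths: list[Breath] = []
    bounds = onsets + [len(flow)]
    for k, onset in enumerate(onsets):
        end = bounds[k + 1]
        if k == len(onsets) - 1:
            # close the trailing breath only if expiration completed
            seg = flow[onset:end]
            if not (seg.min() < -flow_threshold and abs(seg[-1]) < flow_threshold):
                break
        if (end - onset) * rec.dt < min_duration:
            continue
        breaths.append(_delimit_breath(rec, onset, end, flow_threshold))
    return breaths


def _delimit_breath(
    rec: WaveformRecording, onset: int, end: int, thr: float
) -> Breath:
    """Locate inspiratory-flow end, pause window, and expiration start."""
    flow = rec.flow[onset:end]
    # end of positive flow: first sample after onset with flow < threshold
    below = np.flatnonzero(flow[1:] < thr) + 1
    insp_end = onset + int(below[0]) if below.size else end
    # expiration: first sample with flow < -threshold
    neg = np.flatnonzero(flow < -thr)
    exp_start = onset + int(neg[0]) if neg.size else end
    exp_start = max(exp_start, insp_end)
    breath = Breath(
        onset=onset,
        insp_end=insp_end,
        end=end,
        pause_start=insp_end,
        pause_end=exp_start,
    )
    breath.volume = integrate_volume(rec, breath)
    return breath


# ---------------------------------------------------------------------------
# Volumes and pressures
# ---------------------------------------------------------------------------

def integrate_volume(rec: WaveformRecording, breath: Breath) -> np.ndarray:
    """Cumulative trapezoidal integral of flow over the breath, zeroed at onset.

    Returns the volume trace in L (length ``end - onset``).  Tidal volume is
    the trace maximum during inspiration (onset through pause end).
    """
    fl = rec.flow[breath.onset : breath.end]
    return cumulative_trapezoid(fl, dx=rec.dt, initial=0.0)


def tidal_volume(rec: WaveformRecording, breath: Breath) -> float:
    """VT in L: max of the volume trace during inspiration (incl. pause)."""
    vol = breath.volume if breath.volume is not None else integrate_volume(rec, breath)
    stop = max(breath.pause_end, breath.insp_end) - breath.onset
    return float(np.max(vol[: max(stop, 1)]))


def breath_pressures(
    rec: WaveformRecording,
    breath: Breath,
    pause_window: float = 0.100,
    peep_window: float = 0.100,
) -> BreathMechanics:
    """Per-breath pressure/volume summary.

    Ppeak/Pmean are the airway-pressure max/mean over the whole cycle.  Pplat
    is the mean over the last ``pause_window`` seconds of the zero-flow
    inspiratory pause (nan + flag when there is no pause), PEEP the mean over
    the last ``peep_window`` seconds of expiration, and dP = Pplat − PEEP.
    Windows in seconds.
    """
    paw = rec.paw[breath.onset : breath.end]
    mech = BreathMechanics(
        Ppeak=float(paw.max()),
        Pmean=float(paw.mean()),
        RR=breath.respiratory_rate(rec),
        VT=tidal_volume(rec, breath),
    )
    mass = rec.meta.get("body_mass_kg")
    if mass:
        mech.VT_ml_kg = mech.VT * 1000.0 / float(mass)

    n_peep = max(1, int(round(peep_window * rec.sample_rate)))
    peep_lo = max(breath.pause_end, breath.end - n_peep)
    mech.PEEP_measured = float(rec.paw[peep_lo : breath.end].mean())

    if breath.has_pause:
        n_plat = max(1, int(round(pause_window * rec.sample_rate)))
        plat_lo = max(breath.pause_start, breath.pause_end - n_plat)
        mech.Pplat = float(rec.paw[plat_lo : breath.pause_end].mean())
        mech.dP = mech.Pplat - mech.PEEP_measured
    else:
        mech.flags.append("no_pause:Pplat_unavailable")

    if not (mech.Ppeak >= mech.Pplat or math.isnan(mech.Pplat)) or not (
        math.isnan(mech.Pplat) or mech.Pplat >= mech.PEEP_measured
    ):
        mech.flags.append("pressure_ordering_violated")
    return mech


def transpulmonary(
    rec: WaveformRecording,
    breath: Breath,
    mech: BreathMechanics,
    pause_window: float = 0.100,
    peep_window: float = 0.100,
) -> BreathMechanics:
    """Add transpulmonary quantities (needs the esophageal channel).

    Ptrans = Paw − Peso.  Peak is the cycle max; the end-expiratory value is
    the mean over the trailing ``peep_window`` of expiration (negative values
    are physiologic in injured lungs); ΔPtrans = plateau Ptrans (mean over the
    Pplat window) − minimal Ptrans over the cycle.
    """
    if rec.peso is None:
        mech.flags.append("no_peso:transpulmonary_unavailable")
        return mech
    ptr = rec.paw[breath.onset : breath.end] - rec.peso[breath.onset : breath.end]
    mech.Ptrans_peak = float(ptr.max())

    n_peep = max(1, int(round(peep_window * rec.sample_rate)))
    lo = max(breath.pause_end, breath.end - n_peep) - breath.onset
    mech.Ptrans_endex = float(ptr[lo:].mean())

    if breath.has_pause:
        n_plat = max(1, int(round(pause_window * rec.sample_rate)))
        plat_lo = max(breath.pause_start, breath.pause_end - n_plat) - breath.onset
        plat_hi = breath.pause_end - breath.onset
        ptrans_plat = float(ptr[plat_lo:plat_hi].mean())
        mech.dPtrans = ptrans_plat - float(ptr.min())
    else:
        mech.flags.append("no_pause:dPtrans_unavailable")
    return mech


# ---------------------------------------------------------------------------
# Equation-of-motion fitting
# ---------------------------------------------------------------------------

def fit_equation_of_motion(
    rec: WaveformRecording,
    breath: Breath,
    model: str = "linear",
) -> EoMFit:
    """Least-squares fit of the equation of motion over the breath cycle.

    linear:            Paw = E·V + R·V̇ + P0
    volume_dependent:  Paw = E1·V + E2·V² + R·V̇ + P0

    The zero-flow pause samples are excluded (collinear with the intercept).
    %E2 = 100·E2·VT / (E1 + E2·VT), signed.
    """
    if model not in ("linear", "volume_dependent"):
        raise ValueError(f"unknown model {model!r}")
    vol = breath.volume if breath.volume is not None else integrate_volume(rec, breath)
    sl = slice(breath.onset, breath.end)
    paw, flow = rec.paw[sl], rec.flow[sl]

    keep = np.ones(len(paw), dtype=bool)
    if breath.has_pause:
        keep[breath.pause_start - breath.onset : breath.pause_end - breath.onset] = False
    v, vdot, y = vol[keep], flow[keep], paw[keep]
    if v.size < 20:
        raise FitError(f"breath too short for regression ({v.size} samples)")

    cols = [v, vdot, np.ones_like(v)]
    if model == "volume_dependent":
        cols.insert(1, v * v)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            "rank-deficient design matrix (constant volume/flow?); "
            f"model={model}, n={v.size}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)

    vt = tidal_volume(rec, breath)
    if model == "linear":
        e, r, p0 = beta
        return EoMFit(model=model, E=float(e), R=float(r), P0=float(p0),
                      E1=float(e), r_squared=r2)
    e1, e2, r, p0 = beta
    e_total = e1 + e2 * vt
    pct = 100.0 * e2 * vt / e_total if e_total != 0 else math.nan
    return EoMFit(model=model, E=float(e_total), R=float(r), P0=float(p0),
                  E1=float(e1), E2=float(e2), pctE2=float(pct), r_squared=r2)


# ---------------------------------------------------------------------------
# Convenience: full per-breath table
# ---------------------------------------------------------------------------

def analyze_recording(
    rec: WaveformRecording,
    model: str = "volume_dependent",
    min_duration: float = 0.5,
    pause_window: float = 0.100,
    peep_window: float = 0.100,
) -> pd.DataFrame:
    """Segment and analyze a recording; one tidy row per breath.

    Columns follow the standard respiratory-variable naming (Ppeak, Pplat,
    dP, E, R, pctE2, ...).  Fit failures leave nan mechanics rather than
    aborting the table.
    """
    rows = []
    for i, breath in enumerate(segment_breaths(rec, min_duration=min_duration)):
        mech = breath_pressures(rec, breath, pause_window, peep_window)
        mech = transpulmonary(rec, breath, mech, pause_window, peep_window)
        row = {"breath": i, **dataclasses.asdict(mech)}
        row["flags"] = ";".join(row["flags"])
        try:
            fit = fit_equation_of_motion(rec, breath, model=model)
            row.update(
                E=fit.E, R=fit.R, P0=fit.P0, E1=fit.E1, E2=fit.E2,
                pctE2=fit.pctE2, r_squared=fit.r_squared,
            )
        except FitError:
            row.update(E=math.nan, R=math.nan, P0=math.nan, E1=math.nan,
                       E2=math.nan, pctE2=math.nan, r_squared=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)
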