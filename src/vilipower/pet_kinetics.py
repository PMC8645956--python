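"""Dynamic FDG-PET kinetics: Patlak uptake rate and tissue normalization.

For an irreversibly trapped tracer the Patlak transformation

    C_T(t)/C_p(t)  =  Ki · [∫0..t C_p dτ]/C_p(t)  +  V0       (t ≥ t*)

is linear once the reversible compartments have equilibrated; the slope Ki
(1/min) is the net uptake-rate constant, a surrogate of neutrophilic
metabolic activity in the lung.  The blood fraction Vb is estimated with the
classical irreversible two-tissue-compartment (Sokoloff) model

    dC1/dt = K1·Cp − (k2+k3)·C1,   dC2/dt = k3·C1,
    C_model = (1−Vb)·(C1+C2) + Vb·Cp,

whose macro-parameter K1·k3/(k2+k3) equals the Patlak Ki.  Because lung
voxels are mostly gas and blood, Ki is normalized to the tissue fraction:

    KiS = Ki / (1 − F_Gas − F_Blood),

and treatment effects are summarized as the difference of ROI medians
(second scan − first scan), ΔKiS.

Whole blood is taken equal to the plasma input (no hematocrit correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "PlasmaInput",
    "TimeActivityCurve",
    "PatlakFit",
    "CompartmentFit",
    "KiSResult",
    "KineticsError",
    "interpolate_plasma",
    "patlak_fit",
    "fit_2tc_irreversible",
    "normalize_kis",
    "delta_kis",
    "roi_median_from_nifti",
    "patlak_map",
]


class KineticsError(RuntimeError):
    """Kinetic fit failed or inputs are unusable."""


@dataclass
class PlasmaInput:
    """Arterial plasma activity samples (kBq/ml) at minutes post injection."""

    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.times.size < 3:
            raise ValueError("plasma input needs >= 3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("plasma sample times must be strictly increasing")
        if np.any(self.activity < 0):
            raise ValueError("plasma activities must be >= 0")


@dataclass
class TimeActivityCurve:
    """Frame-mean tissue activity (kBq/ml) for one ROI."""

    frame_starts: np.ndarray   # min
    frame_durations: np.ndarray  # min
    activity: np.ndarray       # kBq/ml, frame means
    roi: str = ""

    def __post_init__(self) -> None:
        self.frame_starts = np.asarray(self.frame_starts, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if np.any(self.frame_durations <= 0):
            raise ValueError("frame durations must be > 0")
        ends = self.frame_starts + self.frame_durations
        if np.any(self.frame_starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must be non-overlapping and increasing")

    @property
    def mid_times(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0


@dataclass
class PatlakFit:
    Ki: float          # 1/min (slope)
    V0: float          # dimensionless intercept
    t_star: float      # min
    r_squared: float
    n_frames: int


@dataclass
class CompartmentFit:
    K1: float          # ml/ml/min
    k2: float          # 1/min
    k3: float          # 1/min
    Vb: float          # blood volume fraction
    residual_norm: float
    flags: tuple = ()

    @property
    def Ki(self) -> float:
        """Macro uptake rate K1·k3/(k2+k3)."""
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else 0.0


@dataclass
class KiSResult:
    Ki: float
    F_Gas: float
    F_Blood: float
    F_Tissue: float
    KiS: float
    roi: str = ""
    timepoint: str = ""


# ---------------------------------------------------------------------------
# Plasma interpolation
# ---------------------------------------------------------------------------

def interpolate_plasma(
    plasma: PlasmaInput, t: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear Cp(t) and its exact running integral from 0.

    Before the first sample Cp is held at the first value; requesting t
    beyond the last sample raises (no extrapolation).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > plasma.times[-1] + 1e-9):
        raise KineticsError("time outside plasma sampling range")
    # extend to t=0 with a flat segment so integrals start at injection
    if plasma.times[0] > 0:
        ts = np.concatenate([[0.0], plasma.times])
        cs = np.concatenate([[plasma.activity[0]], plasma.activity])
    else:
        ts, cs = plasma.times, plasma.activity
    cp = np.interp(t, ts, cs)
    cum = np.concatenate([[0.0], cumulative_trapezoid(cs, ts)])
    idx = np.searchsorted(ts, t, side="right") - 1
    idx = np.clip(idx, 0, len(ts) - 1)
    # exact integral of the linear segment from ts[idx] to t
    integral = cum[idx] + 0.5 * (cs[idx] + cp) * (t - ts[idx])
    return cp, integral


# ---------------------------------------------------------------------------
# Patlak graphical analysis
# ---------------------------------------------------------------------------

def patlak_fit(
    tac: TimeActivityCurve,
    plasma: PlasmaInput,
    t_star: float = 20.0,
) -> PatlakFit:
    """OLS Patlak fit over frames with mid-time >= t_star.

    y = C_T/Cp(mid) against x = ∫Cp/Cp(mid); Ki is the slope, V0 the
    intercept.  Unweighted, per the convention of routine ROI analysis.
    """
    mids = tac.mid_times
    use = mids >= t_star
    if use.sum() < 3:
        raise KineticsError(
            f"need >= 3 frames with mid-time >= t*={t_star}, have {use.sum()}"
        )
    cp, icp = interpolate_plasma(plasma, mids[use])
    if np.any(cp <= 0):
        raise KineticsError("non-positive plasma activity in Patlak frames")
    x = icp / cp
    y = tac.activity[use] / cp
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PatlakFit(Ki=float(slope), V0=float(intercept), t_star=t_star,
                     r_squared=min(max(r2, 0.0), 1.0), n_frames=int(use.sum()))


# ---------------------------------------------------------------------------
# Irreversible two-tissue-compartment fit
# ---------------------------------------------------------------------------

def _tissue_grid(
    plasma: PlasmaInput, t_end: float, dt: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Fine uniform grid over [0, t_end] and Cp sampled on it."""
    n = int(math.ceil(t_end / dt)) + 1
    grid = np.linspace(0.0, t_end, n)
    cp, _ = interpolate_plasma(plasma, grid)
    return grid, cp


def _solve_2tc(
    grid: np.ndarray, cp: np.ndarray, K1: float, k2: float, k3: float
) -> np.ndarray:
    """C1+C2 on the grid via the exact exponential-filter recursion.

    Treats Cp as piecewise linear between grid points, for which the
    convolution update of dC1/dt = K1·Cp − α·C1 is exact per step.
    """
    alpha = k2 + k3
    dt = grid[1] - grid[0]
    n = grid.size
    c1 = np.zeros(n)
    if alpha * dt > 1e-12:
        decay = math.exp(-alpha * dt)
        g0 = (1.0 - decay) / alpha            # ∫ e^{-α(dt-s)} ds
        g1 = (dt - g0) / alpha                # ∫ s·e^{-α(dt-s)} ds
    else:
        decay, g0, g1 = 1.0, dt, dt * dt / 2.0
    b = (cp[1:] - cp[:-1]) / dt
    for i in range(n - 1):
        c1[i + 1] = c1[i] * decay + K1 * (cp[i] * g0 + b[i] * g1)
    c2 = k3 * cumulative_trapezoid(c1, grid, initial=0.0)
    return c1 + c2


def _frame_means(
    grid: np.ndarray, curve: np.ndarray, starts: np.ndarray, durations: np.ndarray
) -> np.ndarray:
    """Average ``curve`` over each frame interval (trapezoid on the grid)."""
    out = np.empty(starts.size)
    for i, (a, d) in enumerate(zip(starts, durations)):
        lo = np.searchsorted(grid, a, side="left")
        hi = np.searchsorted(grid, a + d, side="right")
        seg = slice(max(lo, 0), max(hi, lo + 2))
        out[i] = np.trapezoid(curve[seg], grid[seg]) / (grid[seg][-1] - grid[seg][0])
    return out


def fit_2tc_irreversible(
    tac: TimeActivityCurve,
    plasma: PlasmaInput,
    init: tuple[float, float, float, float] = (0.01, 0.1, 0.05, 0.05),
    bounds: tuple = ((0.0, 0.0, 0.0, 0.0), (1.0, 5.0, 5.0, 0.5)),
    grid_dt: float = 0.02,
) -> CompartmentFit:
    """Nonlinear least squares of the irreversible 2TC model + blood term.

    Frames should cover the early vascular phase (first frame within the
    first minute) or Vb is poorly identified.  Boundary-pinned Vb is flagged,
    non-convergence raises with the residual diagnostics.
    """
    t_end = float(tac.frame_starts[-1] + tac.frame_durations[-1])
    grid, cp = _tissue_grid(plasma, t_end, dt=grid_dt)
    cp_frames = _frame_means(grid, cp, tac.frame_starts, tac.frame_durations)

    def model(theta: np.ndarray) -> np.ndarray:
        K1, k2, k3, Vb = theta
        tissue = _solve_2tc(grid, cp, K1, k2, k3)
        tis_frames = _frame_means(grid, tissue, tac.frame_starts, tac.frame_durations)
        return (1.0 - Vb) * tis_frames + Vb * cp_frames

    def resid(theta: np.ndarray) -> np.ndarray:
        return model(theta) - tac.activity

    sol = optimize.least_squares(resid, x0=np.asarray(init), bounds=bounds,
                                 xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise KineticsError(
            f"2TC fit did not converge: {sol.message}; "
            f"residual norm {np.linalg.norm(sol.fun):.4g}"
        )
    K1, k2, k3, Vb = (float(v) for v in sol.x)
    flags = []
    if Vb >= bounds[1][3] - 1e-6:
        flags.append("Vb_at_upper_bound")
    return CompartmentFit(K1=K1, k2=k2, k3=k3, Vb=Vb,
                          residual_norm=float(np.linalg.norm(sol.fun)),
                          flags=tuple(flags))


# ---------------------------------------------------------------------------
# Tissue-fraction normalization
# ---------------------------------------------------------------------------

def normalize_kis(
    Ki: float,
    F_Gas: float,
    F_Blood: float,
    roi: str = "",
    timepoint: str = "",
) -> KiSResult:
    """KiS = Ki / (1 − F_Gas − F_Blood); requires a positive tissue fraction."""
    f_tissue = 1.0 - F_Gas - F_Blood
    if f_tissue <= 0:
        raise ValueError(
            f"no tissue: F_Gas={F_Gas} + F_Blood={F_Blood} >= 1"
        )
    return KiSResult(Ki=Ki, F_Gas=F_Gas, F_Blood=F_Blood, F_Tissue=f_tissue,
                     KiS=Ki / f_tissue, roi=roi, timepoint=timepoint)


def delta_kis(first: np.ndarray, second: np.ndarray) -> float:
    """ΔKiS = median(second-scan ROI values) − median(first-scan values)."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.size == 0 or second.size == 0:
        raise ValueError("empty ROI")
    return float(np.median(second) - np.median(first))


# ---------------------------------------------------------------------------
# Voxel pathways (NIfTI Ki maps, small synthetic 4D volumes)
# ---------------------------------------------------------------------------

def roi_median_from_nifti(map_path: str | Path, mask_path: str | Path) -> float:
    """Median of a voxel map (e.g. a precomputed Ki map) within a lung mask."""
    import nibabel as nib

    img = np.asanyarray(nib.load(str(map_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.median(img[mask]))


def patlak_map(
    frames: np.ndarray,
    frame_starts: np.ndarray,
    frame_durations: np.ndarray,
    plasma: PlasmaInput,
    t_star: float = 20.0,
) -> np.ndarray:
    """Voxelwise Patlak slope for a small 4D array (..., n_frames).

    Intended for synthetic volumes; a vectorized OLS over the trailing axis.
    """
    tac_shape = frames.shape[:-1]
    mids = np.asarray(frame_starts) + np.asarray(frame_durations) / 2.0
    use = mids >= t_star
    if use.sum() < 3:
        raise KineticsError("need >= 3 frames beyond t*")
    cp, icp = interpolate_plasma(plasma, mids[use])
    x = icp / cp
    y = frames[..., use] / cp
    xm = x.mean()
    denom = ((x - xm) ** 2).sum()
    slope = ((y - y.mean(axis=-1, keepdims=True)) * (x - xm)).sum(axis=-1) / denom
    return slope.reshape(tac_shape)
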