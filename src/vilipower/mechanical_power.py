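"""Mechanical energy and power from the tidal pressure-volume curve.

Mechanical energy per breath (ME) is the numerical integral of airway
pressure over inspired volume — the area under the inspiratory limb of the
tidal PV curve.  Multiplying ME by respiratory rate gives mechanical power
(MP, J/min), the candidate unifying determinant of ventilator-induced lung
injury.  The resistive part of ME is obtained from the fitted airway
resistance, ∫ R·V̇ dV, and the elastic part as the residual ME − ME_res, so
the decomposition is closed by construction.

Two pressure references are supported and reported as first-class options:
``atmospheric`` integrates Paw itself (the work done against PEEP is
included); ``peep`` integrates Paw − PEEP (tidal work only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .resp_mechanics import (
    Breath,
    BreathMechanics,
    EoMFit,
    WaveformRecording,
    breath_pressures,
    fit_equation_of_motion,
    integrate_volume,
    segment_breaths,
)

__all__ = [
    "J_PER_CMH2O_L",
    "PowerResult",
    "mechanical_energy",
    "mechanical_power",
    "decompose_power",
    "summarize_power",
    "power_table",
]

#: 1 cmH2O·L in joules.
J_PER_CMH2O_L = 0.0980665


@dataclass
class PowerResult:
    """Per-breath energy/power with elastic/resistive split.

    ME in J, MP in J/min; MP = ME × RR for each component, and
    ME_elastic + ME_resistive == ME_total (residual-closed).
    """

    ME_total: float
    ME_elastic: float
    ME_resistive: float
    MP_total: float
    MP_elastic: float
    MP_resistive: float
    RR: float
    pressure_reference: str  # "atmospheric" | "peep"


def _insp_slice(breath: Breath) -> slice:
    """Inspiratory limb: onset through end of the zero-flow pause."""
    stop = max(breath.pause_end, breath.insp_end)
    return slice(breath.onset, stop)


def mechanical_energy(
    rec: WaveformRecording,
    breath: Breath,
    reference: str = "atmospheric",
    peep: float | None = None,
) -> float:
    """ME in J: trapezoidal ∫ (Paw − ref) dV over the inspiratory limb.

    ref = 0 for ``atmospheric``; for ``peep`` the measured PEEP is used
    (pass ``peep`` to avoid recomputing it).
    """
    if reference not in ("atmospheric", "peep"):
        raise ValueError(f"unknown pressure reference {reference!r}")
    sl = _insp_slice(breath)
    paw = rec.paw[sl]
    if not np.all(np.isfinite(paw)):
        raise ValueError("non-finite airway-pressure samples in breath")
    vol = breath.volume if breath.volume is not None else integrate_volume(rec, breath)
    vol = vol[: sl.stop - breath.onset]
    ref = 0.0
    if reference == "peep":
        if peep is None:
            peep = breath_pressures(rec, breath).PEEP_measured
        ref = peep
    energy_cmh2o_l = float(np.trapezoid(paw - ref, vol))
    return energy_cmh2o_l * J_PER_CMH2O_L


def mechanical_power(ME: float, RR: float) -> float:
    """MP = ME × RR (J/min); RR in breaths/min must be positive."""
    if RR <= 0:
        raise ValueError(f"respiratory rate must be > 0, got {RR}")
    return ME * RR


def decompose_power(
    rec: WaveformRecording,
    breath: Breath,
    fit: EoMFit,
    reference: str = "atmospheric",
    peep: float | None = None,
    rr: float | None = None,
) -> PowerResult:
    """Split ME/MP into resistive and elastic components.

    ME_resistive = ∫ R·V̇ dV over inspiration with the fitted R; the elastic
    component is the residual so that components always sum to the total.
    """
    me_total = mechanical_energy(rec, breath, reference=reference, peep=peep)
    sl = _insp_slice(breath)
    vol = breath.volume if breath.volume is not None else integrate_volume(rec, breath)
    vol = vol[: sl.stop - breath.onset]
    vdot = rec.flow[sl]
    me_res = float(np.trapezoid(fit.R * vdot, vol)) * J_PER_CMH2O_L
    me_el = me_total - me_res
    rr = breath.respiratory_rate(rec) if rr is None else rr
    return PowerResult(
        ME_total=me_total,
        ME_elastic=me_el,
        ME_resistive=me_res,
        MP_total=mechanical_power(me_total, rr),
        MP_elastic=mechanical_power(me_el, rr),
        MP_resistive=mechanical_power(me_res, rr),
        RR=rr,
        pressure_reference=reference,
    )


def summarize_power(results: list[PowerResult], window: slice | None = None) -> dict:
    """Median MP (total/elastic/resistive) over breaths in ``window``.

    Returns nan-filled dict for an empty window.  The per-recording median
    feeds the per-animal correlation input.
    """
    if window is not None:
        results = results[window]
    if not results:
        return {"MP_total": math.nan, "MP_elastic": math.nan,
                "MP_resistive": math.nan, "n_breaths": 0}
    return {
        "MP_total": float(np.median([r.MP_total for r in results])),
        "MP_elastic": float(np.median([r.MP_elastic for r in results])),
        "MP_resistive": float(np.median([r.MP_resistive for r in results])),
        "n_breaths": len(results),
    }


def power_table(
    rec: WaveformRecording,
    reference: str = "atmospheric",
    model: str = "linear",
    min_duration: float = 0.5,
) -> "pd.DataFrame":
    """Per-breath PowerResult table for a recording (tidy, one row/breath)."""
    import pandas as pd

    rows = []
    for i, breath in enumerate(segment_breaths(rec, min_duration=min_duration)):
        mech = breath_pressures(rec, breath)
        fit = fit_equation_of_motion(rec, breath, model=model)
        res = decompose_power(rec, breath, fit, reference=reference,
                              peep=mech.PEEP_measured)
        rows.append({
            "breath": i, "ME_total_J": res.ME_total,
            "ME_elastic_J": res.ME_elastic, "ME_resistive_J": res.ME_resistive,
            "MP_total_J_min": res.MP_total, "MP_elastic_J_min": res.MP_elastic,
            "MP_resistive_J_min": res.MP_resistive, "RR": res.RR,
            "reference": res.pressure_reference,
        })
    return pd.DataFrame(rows)
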