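"""Derived gas-exchange and hemodynamic indices from blood-gas panels.

Standard formulas: the alveolar gas equation for AaDO2, O2 contents with
Hb-bound (1.34 ml O2/g) and dissolved (0.0031 ml/dl/mmHg) terms for the
venous-admixture (shunt) fraction, PaO2/FiO2, and stroke volume CO/HR.
All constants are configurable; defaults are sea-level textbook values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GasConstants",
    "BloodGasPanel",
    "DerivedIndices",
    "pf_ratio",
    "aado2",
    "venous_admixture",
    "stroke_volume",
    "derive_indices",
]


@dataclass(frozen=True)
class GasConstants:
    Patm: float = 760.0      # mmHg barometric
    PH2O: float = 47.0       # mmHg water vapor at 37 °C
    RQ: float = 0.8          # respiratory quotient
    hb_o2_capacity: float = 1.34   # ml O2 per g Hb
    o2_solubility: float = 0.0031  # ml O2 / dl / mmHg


@dataclass
class BloodGasPanel:
    """Arterial/mixed-venous blood-gas values for one animal and timepoint."""

    PaO2: float            # mmHg
    PaCO2: float           # mmHg
    F_IO2: float           # fraction (0.21..1.0]
    pHa: float = float("nan")
    SaO2: float = float("nan")   # fraction
    Hb: float = float("nan")     # g/dl
    PvO2: float = float("nan")   # mmHg
    SvO2: float = float("nan")   # fraction
    CO: float = float("nan")     # L/min
    HR: float = float("nan")     # 1/min
    meta: dict = field(default_factory=dict)


@dataclass
class DerivedIndices:
    PF: float = float("nan")               # mmHg
    AaDO2: float = float("nan")            # mmHg
    venous_admixture: float = float("nan")  # fraction
    SV: float = float("nan")               # ml


def pf_ratio(PaO2: float, F_IO2: float) -> float:
    """Horovitz index PaO2/FiO2 in mmHg."""
    if F_IO2 <= 0:
        raise ValueError(f"F_IO2 must be > 0, got {F_IO2}")
    return PaO2 / F_IO2


def alveolar_po2(
    F_IO2: float, PaCO2: float, constants: GasConstants = GasConstants()
) -> float:
    """Alveolar gas equation: PAO2 = FiO2·(Patm − PH2O) − PaCO2/RQ."""
    return F_IO2 * (constants.Patm - constants.PH2O) - PaCO2 / constants.RQ


def aado2(panel: BloodGasPanel, constants: GasConstants = GasConstants()) -> float:
    """Alveolo-arterial oxygen difference PAO2 − PaO2 in mmHg."""
    return alveolar_po2(panel.F_IO2, panel.PaCO2, constants) - panel.PaO2


def _o2_content(
    Hb: float, SO2: float, PO2: float, constants: GasConstants
) -> float:
    """O2 content in ml/dl: Hb-bound + dissolved."""
    return constants.hb_o2_capacity * Hb * SO2 + constants.o2_solubility * PO2


def venous_admixture(
    panel: BloodGasPanel, constants: GasConstants = GasConstants()
) -> float:
    """Shunt fraction Qs/Qt = (CcO2 − CaO2)/(CcO2 − CvO2).

    End-capillary blood is assumed fully saturated at alveolar PO2.
    """
    pao2_alv = alveolar_po2(panel.F_IO2, panel.PaCO2, constants)
    cc = _o2_content(panel.Hb, 1.0, pao2_alv, constants)
    ca = _o2_content(panel.Hb, panel.SaO2, panel.PaO2, constants)
    cv = _o2_content(panel.Hb, panel.SvO2, panel.PvO2, constants)
    if cc <= cv:
        raise ValueError(
            f"capillary O2 content ({cc:.3f}) must exceed venous ({cv:.3f})"
        )
    return (cc - ca) / (cc - cv)


def stroke_volume(CO: float, HR: float) -> float:
    """SV in ml from cardiac output (L/min) and heart rate (1/min)."""
    if HR <= 0:
        raise ValueError(f"heart rate must be > 0, got {HR}")
    return 1000.0 * CO / HR


def derive_indices(
    panel: BloodGasPanel, constants: GasConstants = GasConstants()
) -> DerivedIndices:
    """All derivable indices for a panel; missing inputs leave nan fields."""
    import math

    out = DerivedIndices(PF=pf_ratio(panel.PaO2, panel.F_IO2),
                         AaDO2=aado2(panel, constants))
    if not any(math.isnan(v) for v in (panel.Hb, panel.SaO2, panel.SvO2,
                                       panel.PvO2)):
        out.venous_admixture = venous_admixture(panel, constants)
    if not (math.isnan(panel.CO) or math.isnan(panel.HR)):
        out.SV = stroke_volume(panel.CO, panel.HR)
    return out
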