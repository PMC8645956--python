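"""Quantitative-CT lung aeration within a lung mask.

Each voxel's gas fraction follows from its CT number, F_Gas = HU/−1000
(clipped to [0, 1]); the complement is the tissue fraction, converted to mass
with a water-equivalent tissue density of 1.0 g/ml.  Voxels are partitioned
into the four standard aeration compartments:

    hyper-aerated   HU < −900
    normally aerated −900 ≤ HU < −500
    poorly aerated  −500 ≤ HU < −100
    non-aerated     HU ≥ −100

(bins left-closed on the denser side).  Per-mask outputs are total lung
mass (g), total gas volume (ml), absolute and relative compartment masses,
and the net aerated relative mass (hyper + normal + poor).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "HU_BIN_EDGES",
    "CTVolume",
    "AerationSummary",
    "gas_fraction",
    "classify_aeration",
    "summarize_aeration",
    "summarize_aeration_nifti",
    "summarize_aeration_histogram",
    "delta_aeration",
]

COMPARTMENTS = ("hyper", "normal", "poor", "non")
#: Left-closed HU bin edges separating hyper/normal/poor/non-aerated tissue.
HU_BIN_EDGES = (-900.0, -500.0, -100.0)
TISSUE_DENSITY_G_ML = 1.0
#: HU values outside this range inside the mask are flagged (metal/artifact).
QC_HU_RANGE = (-1024.0, 100.0)


@dataclass
class CTVolume:
    """CT volume: voxel HU values plus geometry.

    ``hu`` may be any shape; ``voxel_dims_mm`` are the edge lengths of one
    voxel.  ``affine`` is carried through for NIfTI round trips.
    """

    hu: np.ndarray
    voxel_dims_mm: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if any(d <= 0 for d in self.voxel_dims_mm):
            raise ValueError("voxel dimensions must be > 0")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_dims_mm)) / 1000.0


@dataclass
class AerationSummary:
    """Masked-lung mass/volume bookkeeping (Fig.-7-style quantities)."""

    total_mass_g: float
    total_gas_volume_ml: float
    total_volume_ml: float
    mass_g: dict           # per compartment
    relative_mass_pct: dict  # per compartment, sums to 100
    net_aerated_pct: float   # hyper + normal + poor relative mass
    n_voxels: int
    n_flagged_voxels: int = 0


def gas_fraction(hu: np.ndarray | float) -> np.ndarray | float:
    """F_Gas = HU/−1000, clipped to [0, 1]."""
    return np.clip(np.asarray(hu, dtype=float) / -1000.0, 0.0, 1.0)


def classify_aeration(hu: np.ndarray | float) -> np.ndarray:
    """Compartment label per voxel (see :data:`HU_BIN_EDGES`)."""
    idx = np.digitize(np.asarray(hu, dtype=float), HU_BIN_EDGES, right=False)
    return np.asarray(COMPARTMENTS)[idx]


def summarize_aeration(
    ct: "CTVolume | np.ndarray",
    voxel_volume_ml: float | None = None,
    weights: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> AerationSummary:
    """Aeration summary for a CT volume (or raw HU values) within a mask.

    Pass a :class:`CTVolume` plus a boolean ``mask``, or an array of voxel
    CT numbers already inside the mask together with ``voxel_volume_ml``.
    ``weights`` (voxel counts) supports histogram input.  Voxel mass =
    voxel volume × (1 − F_Gas) × 1.0 g/ml.
    """
    if isinstance(ct, CTVolume):
        if mask is not None:
            mask = np.asarray(mask) > 0
            if mask.shape != ct.hu.shape:
                raise ValueError("mask and CT volume shapes differ")
            hu = ct.hu[mask]
        else:
            hu = ct.hu.ravel()
        voxel_volume_ml = ct.voxel_volume_ml
    else:
        hu = np.asarray(ct, dtype=float)
        if voxel_volume_ml is None:
            raise ValueError("voxel_volume_ml required with raw HU input")
    if hu.size == 0:
        raise ValueError("empty mask")
    w = np.ones_like(hu) if weights is None else np.asarray(weights, dtype=float)
    fgas = gas_fraction(hu)
    vox_mass = voxel_volume_ml * (1.0 - fgas) * TISSUE_DENSITY_G_ML * w
    total_mass = float(vox_mass.sum())
    gas_vol = float((voxel_volume_ml * fgas * w).sum())
    labels = classify_aeration(hu)
    mass = {c: float(vox_mass[labels == c].sum()) for c in COMPARTMENTS}
    rel = {
        c: (100.0 * m / total_mass if total_mass > 0 else 0.0)
        for c, m in mass.items()
    }
    flagged = int(w[(hu < QC_HU_RANGE[0]) | (hu > QC_HU_RANGE[1])].sum())
    return AerationSummary(
        total_mass_g=total_mass,
        total_gas_volume_ml=gas_vol,
        total_volume_ml=float((voxel_volume_ml * w).sum()),
        mass_g=mass,
        relative_mass_pct=rel,
        net_aerated_pct=rel["hyper"] + rel["normal"] + rel["poor"],
        n_voxels=int(w.sum()),
        n_flagged_voxels=flagged,
    )


def summarize_aeration_nifti(
    ct_path: str | Path, mask_path: str | Path
) -> AerationSummary:
    """Aeration summary from a NIfTI CT volume and binary lung mask."""
    import nibabel as nib

    img = nib.load(str(ct_path))
    hu = np.asanyarray(img.dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != hu.shape:
        raise ValueError("mask and CT volume shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    voxel_volume_ml = float(np.prod(img.header.get_zooms()[:3])) / 1000.0
    return summarize_aeration(hu[mask], voxel_volume_ml)


def summarize_aeration_histogram(
    hu: np.ndarray, counts: np.ndarray, voxel_volume_ml: float
) -> AerationSummary:
    """Aeration summary from an (hu, voxel_count) histogram (desk testing)."""
    return summarize_aeration(hu, voxel_volume_ml, weights=counts)


def delta_aeration(first: AerationSummary, second: AerationSummary) -> dict:
    """Per-field differences, second − first (scalar fields and compartments)."""
    out = {
        "total_mass_g": second.total_mass_g - first.total_mass_g,
        "total_gas_volume_ml": second.total_gas_volume_ml - first.total_gas_volume_ml,
        "net_aerated_pct": second.net_aerated_pct - first.net_aerated_pct,
    }
    for c in COMPARTMENTS:
        out[f"mass_g_{c}"] = second.mass_g[c] - first.mass_g[c]
        out[f"relative_mass_pct_{c}"] = (
            second.relative_mass_pct[c] - first.relative_mass_pct[c]
        )
    return out
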