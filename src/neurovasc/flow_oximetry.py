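"""Resting global physiology: phase-contrast flow, susceptibility-based
oximetry, and Fick-principle CMRO2.

Global CBF comes from velocity-encoded phase-contrast maps: the flow in
each feeding artery is mean velocity x vessel cross-sectional area, and
the summed flow is normalized to brain weight (volume x 1.05 g/ml).

Venous oxygen saturation (SvO2) in the sagittal sinus comes from
susceptibility-based oximetry: the inter-echo phase accrual of
intravascular spins relative to surrounding tissue scales with the
deoxyhemoglobin susceptibility shift.  For a long vessel modelled as an
infinite cylinder at angle theta to B0,

    dphi = gamma * B0 * dTE * (dchi_do * Hct * (1 - SvO2) / 6) * (3 cos^2 theta - 1)

which is inverted for SvO2.  Global CMRO2 then follows from the Fick
principle, gCMRO2 = [Hgb] * gCBF * (SaO2 - SvO2), with [Hgb] in the
monomer (mmol/l) convention so 1 mmol Hgb binds 1 mmol O2 and gCMRO2 is
in umol O2 / 100 g / min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GYROMAGNETIC_RATIO",
    "BRAIN_DENSITY",
    "VesselVelocityMap",
    "PhasePair",
    "OximetryCalibration",
    "RestingPhysiology",
    "vessel_flow",
    "total_gcbf",
    "susceptibility_phase",
    "svo2_from_phase",
    "forward_phase",
    "cmro2_fick",
]

GYROMAGNETIC_RATIO = 2.6752218744e8  # proton, rad / s / T
BRAIN_DENSITY = 1.05  # g / ml


@dataclass
class VesselVelocityMap:
    """2-D through-plane velocity map (cm/s) with named vessel ROIs."""

    velocity: np.ndarray
    voxel_area: float  # cm^2
    rois: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.voxel_area <= 0:
            raise ValueError("voxel area must be positive")
        total = np.zeros(self.velocity.shape, dtype=int)
        for name, m in self.rois.items():
            if m.shape != self.velocity.shape:
                raise ValueError(f"ROI {name!r} shape mismatch")
            total += m.astype(int)
        if np.any(total > 1):
            raise ValueError("vessel ROIs must be disjoint")


@dataclass
class PhasePair:
    """Dual-echo phase maps (radians, wrapped into (-pi, pi]) over a vessel."""

    phase_te1: np.ndarray
    phase_te2: np.ndarray
    delta_te: float  # ms
    field_strength: float  # T
    vessel_mask: np.ndarray
    tissue_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.delta_te <= 0:
            raise ValueError("delta TE must be positive")
        if not self.vessel_mask.any() or not self.tissue_mask.any():
            raise ValueError("vessel and tissue masks must be nonempty")
        if np.any(self.vessel_mask & self.tissue_mask):
            raise ValueError("vessel and tissue masks must be disjoint")


@dataclass(frozen=True)
class OximetryCalibration:
    """Constants of the susceptibility forward model.

    dchi_do is the volume susceptibility difference between fully
    deoxygenated and fully oxygenated erythrocytes per unit hematocrit
    (SI, dimensionless); the default is the standard literature value
    4*pi*0.27 ppm.  theta is the vessel angle from B0 (radians).
    """

    delta_chi_do: float = 4.0 * np.pi * 0.27e-6
    hct: float = 0.42
    vessel_angle: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.hct < 1:
            raise ValueError("hematocrit must be in (0, 1)")
        if self.delta_chi_do <= 0:
            raise ValueError("susceptibility difference must be positive")


@dataclass
class RestingPhysiology:
    """Per-subject resting physiology estimates."""

    gcbf: float  # ml / 100 g / min
    svo2: float
    sao2: float
    hgb: float  # mmol/l (monomer)
    gcmro2: float  # umol O2 / 100 g / min
    brain_weight: float  # g

    def __post_init__(self) -> None:
        if self.svo2 > self.sao2:
            raise ValueError("venous saturation cannot exceed arterial")
        if self.gcmro2 < 0:
            raise ValueError("gCMRO2 cannot be negative")


def vessel_flow(vmap: VesselVelocityMap, roi_name: str) -> float:
    """Blood flow through one vessel ROI in ml/min.

    flow = mean velocity over the ROI (cm/s) x ROI area (cm^2) x 60.
    """
    mask = vmap.rois[roi_name]
    if not mask.any():
        raise ValueError(f"ROI {roi_name!r} is empty")
    mean_v = float(vmap.velocity[mask].mean())
    area = float(mask.sum()) * vmap.voxel_area
    return mean_v * area * 60.0


def total_gcbf(flows, brain_volume: float, density: float = BRAIN_DENSITY) -> float:
    """Global CBF (ml/100g/min) from vessel flows and brain volume (ml)."""
    flows = np.asarray(flows, dtype=float)
    if np.any(flows < 0):
        raise ValueError("flows must be nonnegative")
    if brain_volume <= 0:
        raise ValueError("brain volume must be positive")
    brain_weight = brain_volume * density
    return 100.0 * float(flows.sum()) / brain_weight


def susceptibility_phase(pair: PhasePair) -> float:
    """Inter-echo intravascular-minus-tissue phase difference, radians.

    The per-voxel inter-echo difference phi2 - phi1 is alias-corrected in
    the vessel by adding the multiple of 2*pi that brings each value
    within pi of the tissue median; the corrected vessel mean minus the
    tissue mean is returned.  If any corrected vessel value sits within
    pi/100 of the +/-pi ambiguity boundary the case is refused.
    """
    d = pair.phase_te2 - pair.phase_te1
    tissue = d[pair.tissue_mask]
    vessel = d[pair.vessel_mask]
    ref = float(np.median(tissue))
    k = np.round((vessel - ref) / (2.0 * np.pi))
    corrected = vessel - 2.0 * np.pi * k
    resid = np.abs(corrected - ref)
    if np.any(np.abs(resid - np.pi) < np.pi / 100.0):
        raise ValueError("ambiguous phase aliasing: vessel phase near the pi boundary")
    return float(corrected.mean() - tissue.mean())


def forward_phase(
    svo2: float, delta_te_ms: float, field_strength: float, calib: OximetryCalibration
) -> float:
    """Forward oximetry model: inter-echo phase difference for a given SvO2."""
    if not 0.0 <= svo2 <= 1.0:
        raise ValueError("SvO2 must be within [0, 1]")
    geom = 3.0 * np.cos(calib.vessel_angle) ** 2 - 1.0
    return (
        GYROMAGNETIC_RATIO
        * field_strength
        * (delta_te_ms * 1e-3)
        * (calib.delta_chi_do * calib.hct * (1.0 - svo2) / 6.0)
        * geom
    )


def svo2_from_phase(
    delta_phi: float,
    delta_te_ms: float,
    field_strength: float,
    calib: OximetryCalibration,
) -> float:
    """Invert the infinite-cylinder model for venous oxygen saturation.

    Raises at the magic angle where the geometric factor vanishes; results
    outside [0, 1] are clamped with a warning.
    """
    if delta_te_ms <= 0:
        raise ValueError("delta TE must be positive")
    geom = 3.0 * np.cos(calib.vessel_angle) ** 2 - 1.0
    if abs(geom) < 1e-9:
        raise ValueError("vessel at the magic angle: oximetry model undefined")
    denom = (
        GYROMAGNETIC_RATIO
        * field_strength
        * (delta_te_ms * 1e-3)
        * calib.delta_chi_do
        * calib.hct
        * geom
        / 6.0
    )
    svo2 = 1.0 - delta_phi / denom
    if svo2 < 0.0 or svo2 > 1.0:
        warnings.warn(f"SvO2 estimate {svo2:.3f} outside [0, 1]; clamped", stacklevel=2)
        svo2 = float(np.clip(svo2, 0.0, 1.0))
    return float(svo2)


def cmro2_fick(hgb: float, gcbf: float, sao2: float, svo2: float) -> float:
    """Fick-principle oxygen consumption, umol O2 / 100 g / min.

    gCMRO2 = [Hgb] * gCBF * (SaO2 - SvO2) with [Hgb] in mmol/l under the
    monomer convention (no tetramer x4 factor).
    """
    if not (0.0 <= svo2 <= sao2 <= 1.0):
        raise ValueError("require 0 <= SvO2 <= SaO2 <= 1")
    return hgb * gcbf * (sao2 - svo2)
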