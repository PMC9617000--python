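"""Synthetic cohort generator.

Produces a fully synthetic study — dual-echo pCASL series, vessel
velocity maps, dual-echo phase maps over the sagittal sinus, combined
flow/oximetry breath-hold series, long-TE spectra, and a cognition/health
table — with known per-subject ground truth, so every estimator in the
package can be tested end to end without any scanner data.

Ground-truth population distributions default to the study conditions: a
77.1 +/- 30.5 % visual-activation CBF response, a 22.5 +/- 7.4 %
breath-hold CBF response, a 0.060 mmol/l mean lactate increment on a
~0.723 mmol/l resting level, and cognition scores linearly coupled to the
activation response (headline coupling: slope 0.112, R^2 0.13).  Values
the study does not print (BOLD amplitude, resting physiology spreads,
noise levels) default to field-typical magnitudes; see docs/methods.md.

The configured activation responses are defined operationally, as the
amplitude of the HRF-convolved percent modulation about the series
temporal mean at regressor height 1 — exactly the quantity the GLM
coefficient measures — so noise-free series are recovered exactly by the
downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AcqGeometry,
    BlockParadigm,
    BreathHoldParadigm,
    PCASL_GEOMETRY,
    SBO_GEOMETRY,
    child_seed,
)
from .asl import DualEchoASLSeries, build_block_regressor
from .flow_oximetry import OximetryCalibration, PhasePair, VesselVelocityMap, forward_phase
from .mrs import LACTATE_PPM, NAA_PPM, Spectrum, lorentzian

__all__ = [
    "SubjectTruth",
    "CohortConfig",
    "SyntheticCohort",
    "TRUTH_DEFAULTS",
    "COGNITION_DEFAULTS",
    "generate_cohort",
    "generate_pcasl_series",
    "generate_velocity_map",
    "generate_sbo_phase_maps",
    "generate_breath_hold_series",
    "breath_hold_response_curve",
    "generate_spectrum",
]

# Population (mean, SD) per ground-truth field.
TRUTH_DEFAULTS: dict[str, tuple[float, float]] = {
    "true_dcbf_visact": (77.1, 30.5),  # % CBF response to visual stimulation
    "true_dbold_visact": (2.0, 0.8),  # % BOLD response (typical 3 T visual)
    "true_dcbf_bh": (22.5, 7.4),  # % flow response to breath holding
    "true_dcmro2_bh": (5.0, 3.0),  # % CMRO2 response to breath holding
    "true_gcbf": (50.0, 8.0),  # ml/100g/min
    "true_svo2": (0.62, 0.04),
    "sao2": (0.975, 0.010),
    "hgb": (9.3, 0.7),  # mmol/l, monomer convention
    "brain_volume": (1150.0, 100.0),  # ml
    "lactate_rest": (0.723, 0.15),  # mmol/l
    "dlac_abs": (0.060, 0.126),  # mmol/l activation increment
    "naa": (10.0, 1.0),  # mmol/l
}

# (column, slope vs true_dcbf_visact, R^2, intercept)
COGNITION_DEFAULTS: list[tuple[str, float, float, float]] = [
    ("ist_2000r", 0.112, 0.13, 25.0),
    ("ace", 0.022, 0.04, 90.0),
    ("tmt_b", -0.205, 0.11, 80.0),
    ("sdmt", 0.058, 0.05, 45.0),
]

_HEALTH_BINARY = {
    "hypertension": 0.396,
    "diabetes": 0.070,
    "hypercholesterolemia": 0.273,
    "hyperlipidemia": 0.042,
    "heart_disease": 0.176,
    "stroke": 0.053,
    "exercise_weekly": 0.749,
}


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    true_dcbf_visact: float
    true_dbold_visact: float
    true_dcbf_bh: float
    true_dcmro2_bh: float
    true_gcbf: float
    true_svo2: float
    hgb: float
    sao2: float
    brain_volume: float
    lactate_rest: float
    lactate_stim: float
    naa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_svo2 <= self.sao2 <= 1.0:
            raise ValueError("require 0 <= SvO2 <= SaO2 <= 1")
        if min(self.lactate_rest, self.lactate_stim, self.naa, self.hgb) < 0:
            raise ValueError("concentrations cannot be negative")
        if self.brain_volume <= 0:
            raise ValueError("brain volume must be positive")


@dataclass
class CohortConfig:
    """Cohort size, population distributions, couplings, noise and seed."""

    n_subjects: int = 40
    truth_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRUTH_DEFAULTS)
    )
    cognition_couplings: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: list(COGNITION_DEFAULTS)
    )
    asl_noise_sd: float = 1.0  # a.u. on a 100 a.u. baseline (tSNR 100)
    bh_flow_noise_frac: float = 0.03
    bh_svo2_noise_sd: float = 0.01
    phase_noise_sd: float = 0.02  # rad
    velocity_noise_sd: float = 0.0  # cm/s
    mrs_noise_sd: float = 0.5  # a.u.
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("cohort size must be positive")
        for name, (_, sd) in self.truth_distributions.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")
        for name, _, r2, _ in self.cognition_couplings:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"R^2 for {name} must be in [0, 1]")
        for nm in ("asl_noise_sd", "bh_flow_noise_frac", "bh_svo2_noise_sd",
                   "phase_noise_sd", "velocity_noise_sd", "mrs_noise_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} cannot be negative")


def _truncated_normal(rng, mean, sd, low=None, high=None, size=None):
    """Rejection-sampled normal draws; used for physically bounded fields."""
    out = rng.normal(mean, sd, size=size)
    if low is None and high is None:
        return out
    arr = np.atleast_1d(out)
    for _ in range(1000):
        bad = np.zeros(arr.shape, dtype=bool)
        if low is not None:
            bad |= arr <= low
        if high is not None:
            bad |= arr >= high
        if not bad.any():
            break
        arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return arr if size is not None else float(arr[0])


def generate_cohort(config: CohortConfig) -> "SyntheticCohort":
    """Draw a cohort of subjects with ground truth and coupled cognition.

    Cognition scores are linear in the true activation CBF response with
    the configured slope; Gaussian noise is calibrated as
    sigma^2 = slope^2 * var(x) * (1 - R^2) / R^2 so the expected sample
    R^2 matches the configuration.  Identical config and seed give a
    byte-identical table.
    """
    rng = np.random.default_rng(config.random_seed)
    d = config.truth_distributions
    n = config.n_subjects

    cols: dict[str, np.ndarray] = {}
    cols["true_dcbf_visact"] = _truncated_normal(rng, *d["true_dcbf_visact"], low=0.0, size=n)
    cols["true_dbold_visact"] = _truncated_normal(rng, *d["true_dbold_visact"], low=0.0, size=n)
    cols["true_dcbf_bh"] = rng.normal(*d["true_dcbf_bh"], size=n)
    cols["true_dcmro2_bh"] = rng.normal(*d["true_dcmro2_bh"], size=n)
    cols["true_gcbf"] = _truncated_normal(rng, *d["true_gcbf"], low=10.0, size=n)
    cols["sao2"] = _truncated_normal(rng, *d["sao2"], low=0.8, high=1.0, size=n)
    svo2 = _truncated_normal(rng, *d["true_svo2"], low=0.3, high=0.85, size=n)
    cols["true_svo2"] = np.minimum(svo2, cols["sao2"] - 1e-3)
    cols["hgb"] = _truncated_normal(rng, *d["hgb"], low=4.0, size=n)
    cols["brain_volume"] = _truncated_normal(rng, *d["brain_volume"], low=600.0, size=n)
    cols["lactate_rest"] = _truncated_normal(rng, *d["lactate_rest"], low=0.05, size=n)
    dlac = rng.normal(*d["dlac_abs"], size=n)
    cols["lactate_stim"] = np.maximum(cols["lactate_rest"] + dlac, 0.0)
    cols["naa"] = _truncated_normal(rng, *d["naa"], low=1.0, size=n)

    x = cols["true_dcbf_visact"]
    var_x = d["true_dcbf_visact"][1] ** 2
    for name, slope, r2, intercept in config.cognition_couplings:
        if slope == 0.0 or r2 <= 0.0:
            cols[name] = intercept + rng.normal(0.0, 1.0, size=n)
        elif r2 >= 1.0:
            cols[name] = intercept + slope * x
        else:
            sigma = abs(slope) * np.sqrt(var_x * (1.0 - r2) / r2)
            cols[name] = intercept + slope * x + rng.normal(0.0, sigma, size=n)

    for name, p in _HEALTH_BINARY.items():
        cols[name] = (rng.random(n) < p).astype(int)
    cols["bmi"] = _truncated_normal(rng, 27.5, 3.7, low=15.0, size=n)
    cols["pack_years"] = np.maximum(rng.normal(9.7, 10.0, size=n), 0.0)
    cols["alcohol_units_week"] = np.maximum(rng.normal(10.5, 9.0, size=n), 0.0)
    cols["education_years"] = _truncated_normal(rng, 11.0, 1.5, low=7.0, size=n)

    table = pd.DataFrame({"subject": np.arange(n), **cols})
    return SyntheticCohort(config=config, truth=table)


@dataclass
class SyntheticCohort:
    """A drawn cohort: truth/cognition table plus lazy raw-data factories.

    Raw imaging series are generated on demand from per-subject,
    per-modality child seeds so the full cohort never has to be held in
    memory at once; repeated calls are deterministic.
    """

    config: CohortConfig
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.truth)

    def subject_truth(self, i: int) -> SubjectTruth:
        row = self.truth.iloc[i]
        return SubjectTruth(
            true_dcbf_visact=row["true_dcbf_visact"],
            true_dbold_visact=row["true_dbold_visact"],
            true_dcbf_bh=row["true_dcbf_bh"],
            true_dcmro2_bh=row["true_dcmro2_bh"],
            true_gcbf=row["true_gcbf"],
            true_svo2=row["true_svo2"],
            hgb=row["hgb"],
            sao2=row["sao2"],
            brain_volume=row["brain_volume"],
            lactate_rest=row["lactate_rest"],
            lactate_stim=row["lactate_stim"],
            naa=row["naa"],
        )

    def pcasl_series(self, i: int, geometry: AcqGeometry = PCASL_GEOMETRY,
                     paradigm: BlockParadigm = BlockParadigm()) -> DualEchoASLSeries:
        return generate_pcasl_series(
            geometry, paradigm, self.subject_truth(i),
            noise_sd=self.config.asl_noise_sd,
            seed=child_seed(self.config.random_seed, i, "pcasl"),
        )

    def velocity_map(self, i: int) -> VesselVelocityMap:
        t = self.subject_truth(i)
        total_flow = t.true_gcbf * t.brain_volume * 1.05 / 100.0  # ml/min
        vessels = _split_arterial_flow(total_flow)
        return generate_velocity_map(
            vessels, noise_sd=self.config.velocity_noise_sd,
            seed=child_seed(self.config.random_seed, i, "pcm"),
            exact_flow=True,
        )

    def sbo_phase_maps(self, i: int, calib: OximetryCalibration = OximetryCalibration()
                       ) -> PhasePair:
        return generate_sbo_phase_maps(
            self.subject_truth(i), SBO_GEOMETRY, calib,
            noise_sd=self.config.phase_noise_sd,
            seed=child_seed(self.config.random_seed, i, "sbo"),
        )

    def breath_hold_series(self, i: int,
                           paradigm: BreathHoldParadigm = BreathHoldParadigm()):
        return generate_breath_hold_series(
            paradigm, self.subject_truth(i),
            flow_noise_frac=self.config.bh_flow_noise_frac,
            svo2_noise_sd=self.config.bh_svo2_noise_sd,
            seed=child_seed(self.config.random_seed, i, "bh"),
        )

    def spectra(self, i: int) -> tuple[Spectrum, Spectrum]:
        """(resting, stimulated) visual-cortex spectra."""
        t = self.subject_truth(i)
        s_rest = generate_spectrum(
            {"lactate": t.lactate_rest, "naa": t.naa},
            noise_sd=self.config.mrs_noise_sd,
            seed=child_seed(self.config.random_seed, i, "mrs_rest"),
        )
        s_stim = generate_spectrum(
            {"lactate": t.lactate_stim, "naa": t.naa},
            noise_sd=self.config.mrs_noise_sd,
            seed=child_seed(self.config.random_seed, i, "mrs_stim"),
        )
        return s_rest, s_stim


def _split_arterial_flow(total_flow: float) -> list[dict]:
    """Two carotids (40 % each) and the basilar artery (20 %), as vessel
    specs with peak velocities solving the laminar flow relation."""
    specs = [
        ("left_carotid", (-15.0, 0.0), 2.5, 0.40),
        ("right_carotid", (15.0, 0.0), 2.5, 0.40),
        ("basilar", (0.0, 15.0), 1.6, 0.20),
    ]
    out = []
    for name, center, radius_mm, frac in specs:
        q_cm3_s = total_flow * frac / 60.0
        r_cm = radius_mm / 10.0
        vmax = 2.0 * q_cm3_s / (np.pi * r_cm**2)
        out.append({"name": name, "center_mm": center, "radius_mm": radius_mm,
                    "peak_velocity": vmax})
    return out


def generate_pcasl_series(
    geometry: AcqGeometry,
    paradigm: BlockParadigm,
    truth: SubjectTruth,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    region: Optional[np.ndarray] = None,
    m0: float = 100.0,
    perfusion_fraction: float = 0.01,
    hrf_mean: float = 6.0,
    hrf_sd: float = 3.0,
) -> DualEchoASLSeries:
    """Dual-echo pCASL series with a responding "visual cortex" region.

    One dynamic is one control+label volume pair at the scanner TR, so the
    perfusion-weighted grid has an effective TR of 2 x TR (9.1 s at
    default timing).  The first echo carries the perfusion contrast:
    control - label equals the local perfusion signal, which in the
    designated region is modulated by the configured dCBF convolved with
    the same gamma HRF the estimator assumes.  The second-echo volumes
    carry the configured dBOLD modulation.  White Gaussian noise of
    ``noise_sd`` (same arbitrary units as ``m0``) is added per volume.

    ``region`` is a boolean (X, Y, Z) mask; the default is a centered
    10 x 10 x 4 voxel block (the activation extent is not a measured
    quantity; it is configuration).
    """
    if noise_sd < 0:
        raise ValueError("noise SD cannot be negative")
    nx, ny, nz = geometry.matrix_dims
    tr_s = geometry.tr / 1000.0
    n_vol = 2 * geometry.n_dynamics
    if paradigm.total_duration > n_vol * tr_s:
        raise ValueError("paradigm longer than the acquisition")
    if region is None:
        region = np.zeros((nx, ny, nz), dtype=bool)
        cx, cy, cz = nx // 2, ny // 2, nz // 2
        region[cx - 5:cx + 5, cy - 5:cy + 5, max(cz - 2, 0):cz + 2] = True
    else:
        region = np.asarray(region, dtype=bool)
        if region.shape != (nx, ny, nz):
            raise ValueError("region mask does not match the matrix")
        if not region.any():
            raise ValueError("region mask is empty")

    rng = np.random.default_rng(seed)
    times = np.arange(n_vol) * tr_s
    is_label = np.zeros(n_vol, dtype=bool)
    is_label[1::2] = True  # control first
    pair_times = 0.5 * (times[0::2] + times[1::2])
    ctrl_times = times[~is_label]

    # Perfusion modulation on the pair grid, centered so the series
    # temporal mean equals the baseline perfusion signal exactly.
    r_cbf = build_block_regressor(paradigm, pair_times, hrf_mean, hrf_sd)
    r_cbf = r_cbf - r_cbf.mean()
    p0 = perfusion_fraction * m0
    perf = np.full((nx, ny, nz, geometry.n_dynamics), p0)
    perf[region] = p0 * (1.0 + (truth.true_dcbf_visact / 100.0) * r_cbf)

    # BOLD modulation per volume, centered over the control sample times
    # (the estimator only reads the non-labelled second-echo volumes).
    r_all = build_block_regressor(paradigm, times, hrf_mean, hrf_sd)
    r_all = r_all - build_block_regressor(paradigm, ctrl_times, hrf_mean, hrf_sd).mean()
    bold = np.full((nx, ny, nz, n_vol), m0)
    bold[region] = m0 * (1.0 + (truth.true_dbold_visact / 100.0) * r_all)

    echo1 = np.full((nx, ny, nz, n_vol), m0)
    echo1[..., 1::2] -= perf  # label volumes lose the perfusion signal
    echo2 = bold
    if noise_sd > 0:
        echo1 = echo1 + rng.normal(0.0, noise_sd, echo1.shape)
        echo2 = echo2 + rng.normal(0.0, noise_sd, echo2.shape)
    return DualEchoASLSeries(
        echo1=echo1, echo2=echo2, is_label=is_label,
        geometry=geometry, paradigm=paradigm,
    )


def generate_velocity_map(
    vessels: Sequence[dict],
    shape: tuple[int, int] = (96, 96),
    voxel_size_mm: tuple[float, float] = (0.75, 0.75),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    exact_flow: bool = False,
) -> VesselVelocityMap:
    """Render vessels as circular cross-sections with laminar profiles.

    Each vessel spec has ``name``, ``center_mm`` (relative to the field
    of view center), ``radius_mm`` and ``peak_velocity`` (cm/s); the
    velocity inside is the parabolic v_max (1 - rho^2/r^2), so the
    analytic flow is pi r^2 v_max / 2.  With ``exact_flow`` the rendered
    pixels are scaled so the discrete flow integral equals the analytic
    value (removing discretization bias for round-trip testing).
    """
    ny, nx = shape
    dy, dx = voxel_size_mm
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    velocity = np.zeros(shape)
    rois: dict[str, np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)
    voxel_area_cm2 = dx * dy / 100.0
    for v in vessels:
        cy, cx = v["center_mm"][1], v["center_mm"][0]
        r = v["radius_mm"]
        if abs(cx) + r > nx * dx / 2.0 or abs(cy) + r > ny * dy / 2.0:
            raise ValueError(f"vessel {v['name']!r} outside the field of view")
        rho2 = (Y - cy) ** 2 + (X - cx) ** 2
        mask = rho2 < r**2
        if np.any(mask & occupied):
            raise ValueError(f"vessel {v['name']!r} overlaps another vessel")
        profile = v["peak_velocity"] * (1.0 - rho2[mask] / r**2)
        if exact_flow and profile.size and v["peak_velocity"] != 0:
            analytic = np.pi * (r / 10.0) ** 2 * v["peak_velocity"] / 2.0  # cm^3/s
            discrete = profile.sum() * voxel_area_cm2
            if discrete > 0:
                profile *= analytic / discrete
        velocity[mask] = profile
        rois[v["name"]] = mask
        occupied |= mask
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        velocity = velocity + rng.normal(0.0, noise_sd, shape)
    return VesselVelocityMap(velocity=velocity, voxel_area=voxel_area_cm2, rois=rois)


def _wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap radians into (-pi, pi]."""
    w = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def generate_sbo_phase_maps(
    truth: SubjectTruth,
    geometry: AcqGeometry = SBO_GEOMETRY,
    calib: OximetryCalibration = OximetryCalibration(),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    wrap: bool = True,
    vessel_radius_mm: float = 3.0,
    echo_offsets: tuple[float, float] = (0.15, 0.35),
) -> PhasePair:
    """Dual-echo phase maps over a sagittal-sinus cross-section.

    Intravascular spins accrue extra phase Delta-omega * TE relative to
    tissue, with Delta-omega set by the forward oximetry model for the
    subject's true SvO2; subtracting the two echoes therefore yields the
    model's inter-echo phase difference.  ``echo_offsets`` are global
    (coil/B0) phase offsets per echo.  With ``wrap`` the stored maps are
    wrapped into (-pi, pi], exercising downstream alias correction.
    """
    if not 0.0 <= truth.true_svo2 <= 1.0:
        raise ValueError("SvO2 outside [0, 1]")
    ny, nx = geometry.matrix_dims[0], geometry.matrix_dims[1]
    dy, dx = geometry.voxel_size[0], geometry.voxel_size[1]
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    rho = np.hypot(Y, X)
    vessel = rho < vessel_radius_mm
    tissue = (rho >= vessel_radius_mm + 1.5) & (rho < vessel_radius_mm + 4.5)

    dphi = forward_phase(truth.true_svo2, geometry.delta_te, geometry.field_strength, calib)
    omega = dphi / (geometry.delta_te * 1e-3)  # rad/s
    phase1 = np.full((ny, nx), echo_offsets[0])
    phase2 = np.full((ny, nx), echo_offsets[1])
    phase1[vessel] += omega * geometry.te1 * 1e-3
    phase2[vessel] += omega * geometry.te2 * 1e-3
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        phase1 = phase1 + rng.normal(0.0, noise_sd, phase1.shape)
        phase2 = phase2 + rng.normal(0.0, noise_sd, phase2.shape)
    if wrap:
        phase1 = _wrap_phase(phase1)
        phase2 = _wrap_phase(phase2)
    return PhasePair(
        phase_te1=phase1, phase_te2=phase2, delta_te=geometry.delta_te,
        field_strength=geometry.field_strength, vessel_mask=vessel, tissue_mask=tissue,
    )


def breath_hold_response_curve(
    times: np.ndarray, paradigm: BreathHoldParadigm, tau: float = 20.0
) -> np.ndarray:
    """Smooth ramp-and-decay response, zero through baseline, sampled
    maximum normalized to exactly 1.

    During each hold the response rises along a smoothstep ramp; after
    the hold it decays exponentially with time constant ``tau``.
    """
    times = np.asarray(times, dtype=float)
    g = np.zeros_like(times)
    for start, end in paradigm.hold_windows():
        cur = np.zeros_like(times)
        s = np.clip((times - start) / (end - start), 0.0, 1.0)
        ramp = s * s * (3.0 - 2.0 * s)
        cur = np.where(times <= end, ramp, np.exp(-(times - end) / tau))
        cur[times < start] = 0.0
        g = np.maximum(g, cur)
    peak = g.max()
    if peak > 0:
        g = g / peak
    return g


def generate_breath_hold_series(
    paradigm: BreathHoldParadigm,
    truth: SubjectTruth,
    n_dynamics: int = 39,
    total_duration: float = 276.0,
    seed: Optional[int] = None,
    flow_noise_frac: float = 0.0,
    svo2_noise_sd: float = 0.0,
    avo2_peak_pct: Optional[float] = None,
    flow_baseline: Optional[float] = None,
    tau: float = 20.0,
):
    """Simultaneous sagittal-sinus flow and saturation breath-hold series.

    The flow series is baseline x (1 + peak/100 x g(t)) with g the
    ramp-and-decay response normalized to a sampled maximum of 1, so the
    true peak flow change is exactly ``truth.true_dcbf_bh`` percent.  The
    saturation series is chosen so the Fick-derived CMRO2 trajectory has
    true peak change ``truth.true_dcmro2_bh`` percent — or, when
    ``avo2_peak_pct`` is given, so the A-V.O2 series itself has that peak
    percent change.  Defaults give 39 dynamics over 276 s.
    """
    from .breath_hold import BreathHoldSeries  # local import avoids a cycle

    if paradigm.total_duration > total_duration:
        raise ValueError("paradigm longer than the series")
    dt = total_duration / n_dynamics
    times = (np.arange(n_dynamics) + 0.5) * dt
    g = breath_hold_response_curve(times, paradigm, tau=tau)

    if flow_baseline is None:
        # sagittal sinus drains roughly half the global flow
        flow_baseline = 0.5 * truth.true_gcbf * truth.brain_volume * 1.05 / 100.0
    flow_rel = 1.0 + (truth.true_dcbf_bh / 100.0) * g
    if avo2_peak_pct is not None:
        avo2_rel = 1.0 + (avo2_peak_pct / 100.0) * g
    else:
        avo2_rel = (1.0 + (truth.true_dcmro2_bh / 100.0) * g) / flow_rel
    avo2_base = truth.sao2 - truth.true_svo2
    flow = flow_baseline * flow_rel
    svo2 = truth.sao2 - avo2_base * avo2_rel

    if flow_noise_frac > 0 or svo2_noise_sd > 0:
        rng = np.random.default_rng(seed)
        if flow_noise_frac > 0:
            flow = flow * (1.0 + rng.normal(0.0, flow_noise_frac, n_dynamics))
        if svo2_noise_sd > 0:
            svo2 = svo2 + rng.normal(0.0, svo2_noise_sd, n_dynamics)
    svo2 = np.clip(svo2, 0.0, truth.sao2)
    return BreathHoldSeries(
        times=times, flow=flow, svo2=svo2, sao2=truth.sao2, hgb=truth.hgb,
        paradigm=paradigm,
    )


def generate_spectrum(
    concentrations: dict[str, float],
    ppm: Optional[np.ndarray] = None,
    linewidth: float = 0.02,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    calibration_scale: float = 1.0,
    echo_time: float = 288.0,
) -> Spectrum:
    """Long-TE spectrum: Lorentzian lactate (1.33 ppm) and NAA (2.01 ppm).

    Peak areas are concentration / calibration_scale; ``linewidth`` is the
    Lorentzian half width at half maximum in ppm.  Gaussian noise of
    ``noise_sd`` is added pointwise.
    """
    if linewidth <= 0:
        raise ValueError("linewidth must be positive")
    if noise_sd < 0:
        raise ValueError("noise SD cannot be negative")
    if any(v < 0 for v in concentrations.values()):
        raise ValueError("concentrations cannot be negative")
    if ppm is None:
        ppm = np.linspace(4.0, 0.5, 2048)
    ppm = np.asarray(ppm, dtype=float)
    centers = {"lactate": LACTATE_PPM, "naa": NAA_PPM}
    intensity = np.zeros_like(ppm)
    for name, conc in concentrations.items():
        amp = conc / (calibration_scale * np.pi * linewidth)
        intensity += lorentzian(ppm, amp, centers[name], linewidth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, ppm.shape)
    return Spectrum(ppm=ppm, intensity=intensity, echo_time=echo_time)
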