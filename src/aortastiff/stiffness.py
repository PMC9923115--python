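"""Sectional stress (Laplace and inverse-engineering routes), Young's
modulus, and parameter-recovery validation metrics.

Two stress routes feed the linearized modulus:

* Laplace hypothesis (LH): thin-wall hoop stress
  ``sigma = dP * rho_bar / delta`` with ``rho_bar`` the mean nodal radius
  of the *systolic* section — the same configuration the inverse route
  loads, so the two moduli are directly comparable.  Trustworthy where
  the curvature factor m is close to 1; a warning is attached to stations
  with m < 0.9.
* Inverse engineering (IE): ring average of the nodal maximal principal
  stress from the near-rigid membrane solve of the pressurized systolic
  surface.

The modulus is the Hooke ratio ``E = sigma / eps_theta`` per station,
masked where the strain falls below a floor (near-zero strain would
explode the ratio).  Validation against an imposed reference field
reports the per-station relative error RErr (%) and its root mean square
over interior stations (RMSPE, %).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centerline import Centerline, curvature_factor
from .kinematics import (
    CrossSection,
    circumferential_strain,
    extract_material_contour,
    extract_section,
    section_in_phase,
)
from .membrane import StressResult, inverse_stress_field
from .mesh import MMHG_TO_PA, PhaseSet
from .synthetic import StiffnessField, evaluate_field

__all__ = [
    "PressureSpec",
    "StiffnessProfile",
    "ValidationReport",
    "laplace_stress",
    "ie_sectional_stress",
    "young_modulus",
    "stiffness_profile",
    "validate_against_reference",
]

log = logging.getLogger("aortastiff")

#: strains below this are masked instead of divided by.
STRAIN_FLOOR = 1e-4
#: LH validity warning threshold on the curvature factor.
M_WARN = 0.9


@dataclass(frozen=True)
class PressureSpec:
    """Diastolic/systolic pressures (mmHg) and their difference."""

    p_dia_mmhg: float
    p_sys_mmhg: float

    def __post_init__(self) -> None:
        if self.p_sys_mmhg <= self.p_dia_mmhg:
            raise ValueError("systolic pressure must exceed diastolic")

    @classmethod
    def from_dp(cls, dp_mmhg: float) -> "PressureSpec":
        if dp_mmhg <= 0:
            raise ValueError("pressure difference must be positive")
        return cls(p_dia_mmhg=0.0, p_sys_mmhg=dp_mmhg)

    @property
    def dp_mmhg(self) -> float:
        return self.p_sys_mmhg - self.p_dia_mmhg

    @property
    def dp_pa(self) -> float:
        return self.dp_mmhg * MMHG_TO_PA


def laplace_stress(
    sys_section: CrossSection, pressure: PressureSpec, thickness_mm: float
) -> float:
    """Thin-wall hoop stress dP * rho_bar / delta (kPa).

    ``rho_bar`` is the mean nodal radial coordinate of the systolic
    section contour.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    rho_bar_m = sys_section.mean_radius_mm * 1e-3
    return pressure.dp_pa * rho_bar_m / (thickness_mm * 1e-3) / 1e3


def ie_sectional_stress(
    stress: StressResult,
    sys_section: CrossSection,
    theta_range: tuple[float, float] | None = None,
) -> float:
    """Ring mean of the nodal maximal principal stress (kPa).

    Averages over the full contour by default; ``theta_range`` restricts
    the mean to an angular sector ``[theta_min, theta_max]`` (radians in
    the section basis).
    """
    if len(stress.nodal_max_principal_pa) <= sys_section.node_indices.max():
        raise ValueError("stress field does not cover the section's mesh nodes")
    values = stress.nodal_max_principal_pa[sys_section.node_indices]
    if theta_range is not None:
        lo, hi = theta_range
        sel = (sys_section.theta >= lo) & (sys_section.theta <= hi)
        if not np.any(sel):
            raise ValueError("empty angular sector")
        values = values[sel]
    return float(values.mean()) / 1e3


def young_modulus(
    sigma_kpa: float, epsilon: float, strain_floor: float = STRAIN_FLOOR
) -> float:
    """Linearized circumferential modulus sigma/eps (MPa).

    Returns NaN (masked) where the strain is below ``strain_floor``; a
    zero stress is reported as 0 with a warning rather than raised.
    """
    if not np.isfinite(epsilon) or epsilon < strain_floor:
        return float("nan")
    if sigma_kpa == 0:
        log.warning("zero sectional stress; reporting E = 0")
        return 0.0
    return sigma_kpa / epsilon / 1e3


@dataclass
class StiffnessProfile:
    """Sectional stresses and moduli along the centerline.

    All arrays are per interior station; masked stations carry NaN.
    ``node_station`` maps every baseline node to its nearest station so
    per-node map arrays can be expanded on demand.
    """

    xi: np.ndarray
    stations: np.ndarray
    epsilon: np.ndarray
    sigma_lh_kpa: np.ndarray
    sigma_ie_kpa: np.ndarray
    e_lh_mpa: np.ndarray
    e_ie_mpa: np.ndarray
    mean_radius_mm: np.ndarray
    m_factor: np.ndarray
    thickness_mm: float
    phase_label: str
    node_station: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def modulus(self, method: str) -> np.ndarray:
        if method.upper() == "LH":
            return self.e_lh_mpa
        if method.upper() == "IE":
            return self.e_ie_mpa
        raise ValueError(f"unknown method {method!r} (use 'LH' or 'IE')")

    def node_map(self, values_per_station: np.ndarray) -> np.ndarray:
        """Expand a per-station array to a per-node map (NaN when masked)."""
        lookup = dict(zip(self.stations.tolist(), values_per_station))
        return np.array([lookup.get(int(s), np.nan) for s in self.node_station])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "xi": self.xi,
            "eps_theta": self.epsilon,
            "sigma_LH_kPa": self.sigma_lh_kpa,
            "sigma_IE_kPa": self.sigma_ie_kpa,
            "E_LH_MPa": self.e_lh_mpa,
            "E_IE_MPa": self.e_ie_mpa,
            "rho_bar_mm": self.mean_radius_mm,
            "m": self.m_factor,
        })


def stiffness_profile(
    phases: PhaseSet,
    cl: Centerline,
    pressure: PressureSpec,
    thickness_mm: float = 2.0,
    method: str = "both",
    systolic_label: str | None = None,
    tol: float | None = None,
    end_fraction: float | None = None,
    strain_floor: float = STRAIN_FLOOR,
    section_mode: str = "contour",
) -> StiffnessProfile:
    """Full sectional stiffness profile for the selected systolic phase.

    When ``systolic_label`` is None the phase with the highest strain is
    chosen.  ``method`` selects which stress routes to evaluate ("LH",
    "IE" or "both"); the unused route is NaN-filled.  ``section_mode``
    "contour" (default) evaluates sections on material plane-edge
    contours, "nodes" on node-threshold sections.
    """
    from .kinematics import strain_profile as _strain_profile
    from .kinematics import select_systolic_phase

    method = method.lower()
    if method not in ("lh", "ie", "both"):
        raise ValueError("method must be 'LH', 'IE' or 'both'")
    if section_mode not in ("contour", "nodes"):
        raise ValueError(f"unknown section mode {section_mode!r}")
    if systolic_label is None:
        profiles = [
            _strain_profile(phases, cl, lab, tol=tol, end_fraction=end_fraction,
                            section_mode=section_mode)
            for lab in phases.labels
        ]
        systolic_label = select_systolic_phase(profiles)
        log.info("selected systolic phase %r by maximum strain", systolic_label)
    sys_mesh = phases.phase(systolic_label)

    stress: StressResult | None = None
    if method in ("ie", "both"):
        stress = inverse_stress_field(
            sys_mesh, dp_mmhg=pressure.dp_mmhg, thickness_mm=thickness_mm,
            inflow_point=cl.points[0],
        )

    stations = np.flatnonzero(cl.interior_mask(end_fraction))
    n = len(stations)
    eps = np.full(n, np.nan)
    s_lh = np.full(n, np.nan)
    s_ie = np.full(n, np.nan)
    e_lh = np.full(n, np.nan)
    e_ie = np.full(n, np.nan)
    rho_bar = np.full(n, np.nan)
    m_fac = np.full(n, np.nan)
    warnings: list[str] = []
    for k, st in enumerate(stations):
        if section_mode == "contour":
            mc = extract_material_contour(phases.baseline, cl, int(st))
            eps[k] = mc.strain(phases.baseline, sys_mesh)
            rho_bar[k] = mc.mean_radius_mm(sys_mesh)
            r_dia = mc.mean_radius_mm(phases.baseline)
            ie_value = (
                mc.sample_mean(stress.nodal_max_principal_pa, sys_mesh) / 1e3
                if stress is not None else np.nan
            )
        else:
            dia_sec = extract_section(phases.baseline, cl, int(st), tol=tol)
            sys_sec = section_in_phase(dia_sec, sys_mesh)
            eps[k] = circumferential_strain(dia_sec, sys_sec)
            rho_bar[k] = sys_sec.mean_radius_mm
            r_dia = dia_sec.mean_radius_mm
            ie_value = (ie_sectional_stress(stress, sys_sec)
                        if stress is not None else np.nan)
        m_fac[k] = curvature_factor(cl.r0_mm[st], r_dia)
        if method in ("lh", "both"):
            s_lh[k] = pressure.dp_pa * (rho_bar[k] * 1e-3) / (thickness_mm * 1e-3) / 1e3
            e_lh[k] = young_modulus(s_lh[k], eps[k], strain_floor)
            if m_fac[k] < M_WARN:
                warnings.append(
                    f"station {st}: curvature factor m = {m_fac[k]:.3f} < "
                    f"{M_WARN}; Laplace-hypothesis stress may be biased"
                )
        if method in ("ie", "both"):
            s_ie[k] = ie_value
            e_ie[k] = young_modulus(s_ie[k], eps[k], strain_floor)
    for w in warnings[:3]:
        log.warning("%s", w)
    if len(warnings) > 3:
        log.warning("(%d further curvature warnings suppressed)",
                    len(warnings) - 3)
    return StiffnessProfile(
        xi=cl.xi[stations], stations=stations, epsilon=eps,
        sigma_lh_kpa=s_lh, sigma_ie_kpa=s_ie, e_lh_mpa=e_lh, e_ie_mpa=e_ie,
        mean_radius_mm=rho_bar, m_factor=m_fac, thickness_mm=thickness_mm,
        phase_label=systolic_label,
        node_station=cl.nearest_station(phases.baseline.nodes),
        warnings=warnings,
    )


@dataclass
class ValidationReport:
    """Per-station relative errors against an imposed reference field."""

    method: str
    xi: np.ndarray
    stations: np.ndarray
    rerr_percent: np.ndarray
    rmspe_percent: float
    max_rerr_percent: float
    reference: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "xi": self.xi, "RErr_percent": self.rerr_percent,
        })


def validate_against_reference(
    profile: StiffnessProfile,
    reference: StiffnessField,
    method: str,
) -> ValidationReport:
    """RErr per station and RMSPE of one estimation route.

    RErr(xi) = 100 |E_est - E_ref| / E_ref; RMSPE is the root mean square
    of the percentage errors over unmasked interior stations.
    """
    est = profile.modulus(method)
    ref = np.asarray(evaluate_field(reference, profile.xi), float)
    valid = np.isfinite(est)
    rerr = np.full_like(est, np.nan)
    rerr[valid] = 100.0 * np.abs(est[valid] - ref[valid]) / ref[valid]
    if not np.any(valid):
        raise ValueError("no unmasked stations to validate")
    rmspe = float(np.sqrt(np.mean(rerr[valid] ** 2)))
    return ValidationReport(
        method=method.upper(), xi=profile.xi, stations=profile.stations,
        rerr_percent=rerr, rmspe_percent=rmspe,
        max_rerr_percent=float(np.nanmax(rerr)),
        reference=reference.describe(),
    )
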