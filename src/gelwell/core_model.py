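"""Kinetic model of DNA hydrogel growth in a microwell-confined droplet.

A dextran-rich droplet sitting in a cylindrical microwell holds ``N_u``
unbound Y-motifs. Each motif can either leak out of the droplet across the
dextran/PEG interface (Fickian flux through an interfacial layer of
thickness ``w``) or collide with another motif and join the growing gel
aggregate (Smoluchowski coagulation with the monodisperse Brownian kernel).
Binding is irreversible within a round; a thermal annealing round returns
every gelled motif to the unbound pool while motifs already lost to the PEG
phase stay lost. The coupled ODEs are

    dN_u/dt = -a N_u - b N_u^2        a = D A / (V w),  D = kT / (6 pi eta r)
    dN_g/dt = +b N_u^2                b = 4 k T / (3 eta V) = alpha / (2 V)

with ``A`` the droplet interface area, ``V`` its volume and
``alpha = 8kT/(3 eta)`` the Brownian collision kernel. The final aggregate
radius follows from the motif concentration inside the gel phase,
``(4/3) pi r_g^3 rho_g = N_g``, shrunk by a compaction factor ``lambda``
that accounts for crowding agents and spermine condensing the network:

    r_g = (1/lambda) * (3 N_g / (4 pi rho_g))^(1/3)

The model is isothermal (298 K defaults) and treats the droplet as a
well-mixed compartment; no spatial gradients, no polydisperse aggregate
spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .units import AVOGADRO, BOLTZMANN, motif_count, number_density

__all__ = [
    "PhysicalParams",
    "MotifSpec",
    "InterfaceModel",
    "WellGeometry",
    "GelParams",
    "RateConstants",
    "Trajectory",
    "AnnealingSchedule",
    "IntegrationError",
    "make_well_geometry",
    "diffusion_coefficient",
    "collision_rate",
    "rate_constants",
    "solve_kinetics",
    "solve_to_steady_state",
    "closed_form_unbound",
    "final_gel_count",
    "gel_radius",
    "run_annealing",
    "sweep_model",
    "cooling_profile",
]


class IntegrationError(RuntimeError):
    """ODE solver failed to converge; carries the solver's diagnostic message."""


@dataclass(frozen=True)
class PhysicalParams:
    """Temperature and solvent viscosity entering every rate constant.

    Defaults are room temperature and the viscosity of the dextran phase
    (~10x water for concentrated dextran solutions).
    """

    temperature: float = 298.0  # K
    viscosity: float = 1e-2  # Pa*s

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be > 0 Pa*s, got {self.viscosity}")

    @property
    def kT(self) -> float:
        return BOLTZMANN * self.temperature


@dataclass(frozen=True)
class MotifSpec:
    """The diffusing species: a three-armed DNA Y-motif treated as a sphere.

    ``hydrodynamic_radius`` defaults to 5 nm, the scale of a ~20-bp motif arm.
    ``initial_concentration`` is the per-motif molar concentration, which for
    an equimolar Y1/Y2/Y3 mix equals the per-strand concentration.
    """

    hydrodynamic_radius: float = 5e-9  # m
    initial_concentration: float = 8e-6  # mol/L

    def __post_init__(self) -> None:
        if self.hydrodynamic_radius <= 0:
            raise ValueError("hydrodynamic_radius must be > 0")
        if self.initial_concentration < 0:
            raise ValueError("initial_concentration must be >= 0")


class InterfaceModel(str, Enum):
    """How the dextran/PEG interface spans the well mouth."""

    DISC_AT_MOUTH = "disc_at_mouth"
    SPHERICAL_CAP = "spherical_cap"


@dataclass(frozen=True)
class WellGeometry:
    """Cylindrical microwell holding a dextran droplet.

    ``interface_area`` is the droplet/PEG contact area through which unbound
    motifs leak; ``interface_thickness`` (default 40 nm) is the width of the
    interfacial region treated as a semi-permeable membrane.
    """

    diameter: float  # m
    depth: float  # m
    interface_thickness: float = 4e-8  # m
    interface_model: InterfaceModel = InterfaceModel.DISC_AT_MOUTH
    contact_angle: float = 0.0  # rad, used only by SPHERICAL_CAP
    interface_area: float = field(init=False)  # m^2
    volume: float = field(init=False)  # m^3

    def __post_init__(self) -> None:
        for name in ("diameter", "depth", "interface_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        mouth_radius = self.diameter / 2.0
        object.__setattr__(self, "volume", math.pi * mouth_radius**2 * self.depth)
        if self.interface_model is InterfaceModel.DISC_AT_MOUTH:
            area = math.pi * mouth_radius**2
        else:
            theta = self.contact_angle
            if not 0 < theta <= math.pi / 2:
                raise ValueError(
                    "spherical_cap interface needs contact_angle in (0, pi/2], "
                    f"got {theta}"
                )
            # Cap of a sphere meeting the well mouth at angle theta:
            # sphere radius R = a/sin(theta), cap height R(1-cos(theta)).
            area = 2 * math.pi * mouth_radius**2 * (1 - math.cos(theta)) / math.sin(theta) ** 2
        object.__setattr__(self, "interface_area", area)


@dataclass(frozen=True)
class GelParams:
    """Gel-phase composition mapping motif count to aggregate radius.

    ``gel_motif_concentration`` (rho_g) is the molar concentration of motifs
    inside the hydrogel; ``compaction_factor`` (lambda) is the linear
    shrinkage of the network caused by crowding agents and spermine.
    """

    gel_motif_concentration: float = 14e-6  # mol/L
    compaction_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.gel_motif_concentration <= 0:
            raise ValueError("gel_motif_concentration must be > 0")
        if self.compaction_factor <= 0:
            raise ValueError("compaction_factor must be > 0")


@dataclass(frozen=True)
class RateConstants:
    """Lumped coefficients of the two-ODE system.

    ``loss_rate_a`` [1/s] is the first-order diffusive escape rate
    D*A/(V*w); ``coalescence_rate_b`` [1/(s*count)] is the pairwise
    coagulation rate alpha/(2V) = 4kT/(3 eta V).
    """

    diffusion_coefficient: float  # m^2/s
    collision_rate: float  # m^3/s
    loss_rate_a: float  # 1/s
    coalescence_rate_b: float  # 1/(s*count)

    def __post_init__(self) -> None:
        for name in (
            "diffusion_coefficient",
            "collision_rate",
            "loss_rate_a",
            "coalescence_rate_b",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Time series of unbound, gelled and escaped motif counts.

    ``N_lost`` is the cumulative number of motifs that diffused into the PEG
    phase — a bookkeeping quantity that closes the balance
    N_u + N_g + N_lost = N_u(0).
    """

    times: np.ndarray  # s, ascending
    N_u: np.ndarray
    N_g: np.ndarray
    N_lost: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "N_u": self.N_u, "N_g": self.N_g, "N_lost": self.N_lost}
        )

    @property
    def final_gelled(self) -> float:
        return float(self.N_g[-1])


@dataclass(frozen=True)
class AnnealingSchedule:
    """Thermal annealing protocol: hold hot, then cool exponentially.

    Mirrors the experimental protocol (1 min at 75 C, 3 min cooling to room
    temperature); the kinetic model only uses ``n_rounds`` — each round
    boundary fully re-dissociates the aggregate — while the temperature
    profile itself is exposed for synthetic schedules via
    :func:`cooling_profile`.
    """

    n_rounds: int = 2
    hot_temperature: float = 348.15  # K (75 C)
    hold_seconds: float = 60.0
    cool_seconds: float = 180.0
    cooling_time_constant: float = 30.0  # s
    ambient_temperature: float = 298.0  # K
    round_duration: float | None = None  # s; None => integrate to quasi-steady state

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        for name in ("hold_seconds", "cool_seconds", "cooling_time_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.round_duration is not None and self.round_duration <= 0:
            raise ValueError("round_duration must be > 0 when given")


def make_well_geometry(
    diameter: float,
    depth: float,
    interface_thickness: float = 4e-8,
    interface_model: InterfaceModel | str = InterfaceModel.DISC_AT_MOUTH,
    contact_angle: float = 0.0,
) -> WellGeometry:
    """Build a :class:`WellGeometry` for a cylindrical well.

    Volume is pi (d/2)^2 h. With ``disc_at_mouth`` the interface is the flat
    disc closing the well mouth (A = pi (d/2)^2, so A/V = 1/h); with
    ``spherical_cap`` the droplet bulges into a cap meeting the mouth at
    ``contact_angle``.
    """
    return WellGeometry(
        diameter=diameter,
        depth=depth,
        interface_thickness=interface_thickness,
        interface_model=InterfaceModel(interface_model),
        contact_angle=contact_angle,
    )


def diffusion_coefficient(phys: PhysicalParams, motif: MotifSpec) -> float:
    """Stokes-Einstein diffusion coefficient kT / (6 pi eta r) of a motif."""
    return phys.kT / (6 * math.pi * phys.viscosity * motif.hydrodynamic_radius)


def collision_rate(phys: PhysicalParams) -> float:
    """Brownian coagulation kernel alpha = 8kT/(3 eta) for equal spheres [m^3/s]."""
    return 8 * phys.kT / (3 * phys.viscosity)


def rate_constants(
    phys: PhysicalParams, motif: MotifSpec, geom: WellGeometry
) -> RateConstants:
    """Lump physics and geometry into the ODE coefficients a and b."""
    D = diffusion_coefficient(phys, motif)
    alpha = collision_rate(phys)
    a = D * geom.interface_area / (geom.volume * geom.interface_thickness)
    b = alpha / (2 * geom.volume)
    return RateConstants(
        diffusion_coefficient=D, collision_rate=alpha, loss_rate_a=a, coalescence_rate_b=b
    )


def closed_form_unbound(a: float, b: float, N0: float, t) -> np.ndarray | float:
    """Analytic solution of dN_u/dt = -a N_u - b N_u^2 (a Riccati equation).

    N_u(t) = a N0 e^{-at} / (a + b N0 (1 - e^{-at}));
    for a = 0 this reduces to the coagulation hyperbola N0 / (1 + b N0 t),
    and for a = b = 0 the count is constant. Written with e^{-at} so large
    ``a*t`` never overflows. Serves as the independent oracle for the
    numerical integrator.
    """
    t = np.asarray(t, dtype=float)
    if N0 == 0:
        return np.zeros_like(t) if t.ndim else 0.0
    if a == 0 and b == 0:
        out = np.full_like(t, float(N0))
        return out if t.ndim else float(N0)
    if a == 0:
        out = N0 / (1.0 + b * N0 * t)
    else:
        decay = np.exp(-a * t)
        out = a * N0 * decay / (a + b * N0 * (1.0 - decay))
    return out if out.ndim else float(out)


def final_gel_count(a: float, b: float, N0: float) -> float:
    """Closed-form t -> infinity gelled count N0 - (a/b) ln(1 + b N0 / a).

    Obtained by integrating dN_g/dt = b N_u^2 over the analytic trajectory.
    Limits: a -> 0 gives N0 (everything gels); b -> 0 gives 0 (everything
    escapes).
    """
    if N0 == 0:
        return 0.0
    if b == 0:
        return 0.0
    if a == 0:
        return float(N0)
    return float(N0 - (a / b) * math.log1p(b * N0 / a))


def _steady_state_horizon(a: float, b: float, N0: float) -> float:
    """Integration time after which remaining gel growth is negligible."""
    if a > 0:
        # exponential tail: N_u ~ e^{-at}; 40/a drops it below 4e-18 N0
        return 40.0 / a
    if b > 0 and N0 > 0:
        # pure coagulation: N_g(t)/N0 = 1 - 1/(1 + b N0 t)
        return 1e8 / (b * N0)
    return 1.0


def solve_kinetics(
    rates: RateConstants,
    N0: float,
    t_end: float,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-3,
    t_eval: Sequence[float] | None = None,
) -> Trajectory:
    """Integrate the loss/coalescence ODEs from N_u(0)=N0, N_g(0)=N_lost(0)=0.

    Uses an adaptive stiff-capable integrator (LSODA). The returned
    trajectory satisfies N_u + N_g + N_lost = N0 to solver tolerance and
    N_g, N_lost are non-decreasing.
    """
    if N0 < 0:
        raise ValueError(f"N0 must be >= 0, got {N0}")
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    a, b = rates.loss_rate_a, rates.coalescence_rate_b

    def rhs(_t, y):
        nu = y[0]
        return (-a * nu - b * nu * nu, b * nu * nu, a * nu)

    def jac(_t, y):
        nu = y[0]
        return np.array(
            [[-a - 2 * b * nu, 0.0, 0.0], [2 * b * nu, 0.0, 0.0], [a, 0.0, 0.0]]
        )

    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        (float(N0), 0.0, 0.0),
        method="LSODA",
        jac=jac,
        rtol=rel_tol,
        atol=abs_tol,
        t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"kinetics integration failed: {sol.message}")
    # tiny negative undershoots from the solver are numerical noise
    y = np.clip(sol.y, 0.0, None)
    return Trajectory(times=sol.t, N_u=y[0], N_g=y[1], N_lost=y[2])


def solve_to_steady_state(
    rates: RateConstants, N0: float, rel_tol: float = 1e-9
) -> Trajectory:
    """Integrate until gel growth has effectively stopped."""
    t_end = _steady_state_horizon(rates.loss_rate_a, rates.coalescence_rate_b, N0)
    return solve_kinetics(rates, N0, t_end, rel_tol=rel_tol)


def gel_radius(N_g: float, gel: GelParams) -> float:
    """Compaction-corrected aggregate radius [m] holding ``N_g`` motifs.

    Inverts (4/3) pi r^3 rho_g = N_g with rho_g converted from mol/L to
    count/m^3, then divides by the compaction factor.
    """
    if N_g < 0:
        raise ValueError(f"N_g must be >= 0, got {N_g}")
    rho_counts = number_density(gel.gel_motif_concentration)  # count/m^3
    return (3.0 * N_g / (4.0 * math.pi * rho_counts)) ** (1.0 / 3.0) / gel.compaction_factor


def run_annealing(
    rates: RateConstants,
    N0: float,
    schedule: AnnealingSchedule,
    rel_tol: float = 1e-9,
) -> Trajectory:
    """Simulate repeated annealing rounds.

    Each round integrates the kinetics (to quasi-steady state by default,
    or for ``schedule.round_duration`` seconds), then the aggregate fully
    dissociates: N_u <- N_u + N_g, N_g <- 0. Motifs lost to the PEG phase
    never return, so extra rounds can only shrink the final aggregate when
    diffusive loss is active.
    """
    times: list[np.ndarray] = []
    nu_parts: list[np.ndarray] = []
    ng_parts: list[np.ndarray] = []
    nl_parts: list[np.ndarray] = []
    t_offset = 0.0
    nu0 = float(N0)
    lost0 = 0.0
    for rnd in range(schedule.n_rounds):
        if schedule.round_duration is not None:
            seg = solve_kinetics(rates, nu0, schedule.round_duration, rel_tol=rel_tol)
        else:
            seg = solve_to_steady_state(rates, nu0, rel_tol=rel_tol)
        times.append(seg.times + t_offset)
        nu_parts.append(seg.N_u)
        ng_parts.append(seg.N_g)
        nl_parts.append(seg.N_lost + lost0)
        t_offset = times[-1][-1]
        lost0 = nl_parts[-1][-1]
        nu0 = float(seg.N_u[-1] + seg.N_g[-1])  # full dissociation at the boundary
    return Trajectory(
        times=np.concatenate(times),
        N_u=np.concatenate(nu_parts),
        N_g=np.concatenate(ng_parts),
        N_lost=np.concatenate(nl_parts),
    )


def sweep_model(
    concentrations: Sequence[float],
    wells: Sequence[WellGeometry],
    phys: PhysicalParams | None = None,
    motif: MotifSpec | None = None,
    gel: GelParams | None = None,
    schedule: AnnealingSchedule | None = None,
) -> pd.DataFrame:
    """Predicted aggregate radius across (concentration, well geometry) grid.

    One row per combination with the rate constants, initial motif count,
    final gelled count and the compaction-corrected radius. ``schedule``
    defaults to a single round integrated to steady state.
    """
    if len(concentrations) == 0 or len(wells) == 0:
        raise ValueError("concentrations and wells must be non-empty")
    phys = phys or PhysicalParams()
    motif = motif or MotifSpec()
    gel = gel or GelParams()
    rows = []
    for geom in wells:
        rates = rate_constants(phys, motif, geom)
        for c in concentrations:
            n0 = motif_count(c, geom.volume)
            if schedule is None:
                traj = solve_to_steady_state(rates, n0)
            else:
                traj = run_annealing(rates, n0, schedule)
            ng = traj.final_gelled
            rows.append(
                {
                    "concentration_M": c,
                    "well_diameter_m": geom.diameter,
                    "a_per_s": rates.loss_rate_a,
                    "b_per_s_count": rates.coalescence_rate_b,
                    "N0": n0,
                    "Ng_final": ng,
                    "r_g_m": gel_radius(ng, gel),
                }
            )
    return pd.DataFrame(rows)


def cooling_profile(schedule: AnnealingSchedule, t) -> np.ndarray | float:
    """Device temperature during cooling: exponential decay to ambient.

    T(t) = T_amb + (T_hot - T_amb) exp(-t / tau).
    """
    if schedule.cooling_time_constant <= 0:
        raise ValueError("cooling_time_constant must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = schedule.ambient_temperature + (
        schedule.hot_temperature - schedule.ambient_temperature
    ) * np.exp(-t / schedule.cooling_time_constant)
    return out if out.ndim else float(out)
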