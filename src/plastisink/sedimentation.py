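"""Vertical transit of one microplastic size class through the water column.

A buoyant microplastic (MP) at the surface cannot sink on its own.  It is
exported by marine snow aggregates (MSAs): once an ambient aggregate
collides with it (shear + differential-settling collision kernels scaled
by the aggregate number concentration), the MP is incorporated and sinks
at the aggregate's Stokes velocity.  Below the euphotic zone the
aggregate attenuates -- its diameter shrinks at a first-order,
temperature-dependent (Q10) rate.  When the aggregate has lost more than
a set fraction of its mass, or has become too small to hold the MP
(incorporation-threshold rule), the MP detaches, regains buoyancy and
rises at its own Stokes velocity until the next ambient aggregate
captures it.  Repeated cycles ratchet the particle downward until it
reaches the seabed (transit complete) or a time cap.

Capture is modelled as an inhomogeneous encounter process with hazard
lambda(z) = beta_total(z) * N_MSA(z).  In the deterministic
``expected_time`` mode capture fires when the integrated hazard reaches 1
(the expected waiting time 1/(beta*N) when conditions are uniform); in
``stochastic_exponential`` mode the integrated-hazard target is a seeded
standard-exponential draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .ocean import OceanProfile, msa_number_concentration

__all__ = [
    "MsaState",
    "MpState",
    "SettlingParams",
    "Trajectory",
    "CollisionKernels",
    "threshold_size",
    "stokes_velocity",
    "collision_kernels",
    "attenuation_rate",
    "detachment_check",
    "settle_trajectory",
]

GRAVITY = 9.81  # m s^-2
BOLTZMANN = 1.380649e-23  # J K^-1
SECONDS_PER_DAY = 86400.0

PHASE_AT_SURFACE = "at_surface"
PHASE_INCORPORATED = "incorporated"
PHASE_RISING = "rising"

#: Threshold-curve constants: y = -0.0002 x^2 + 0.36 x for aggregates up to
#: 900 µm, constant 162 µm above (both branches meet at x = 900).
_THRESHOLD_A = -0.0002
_THRESHOLD_B = 0.36
_THRESHOLD_KNEE = 900.0
_THRESHOLD_PLATEAU = 162.0


def threshold_size(aggregate_size_um):
    """Largest MP (µm) an aggregate of the given size (µm) can hold."""
    x = np.asarray(aggregate_size_um, dtype=float)
    if np.any(x < 0):
        raise ValueError("aggregate size must be non-negative")
    y = np.where(
        x <= _THRESHOLD_KNEE,
        _THRESHOLD_A * x**2 + _THRESHOLD_B * x,
        _THRESHOLD_PLATEAU,
    )
    return float(y) if np.isscalar(aggregate_size_um) else y


def stokes_velocity(
    particle_density: float,
    sw_density: float,
    diameter_m: float,
    viscosity: float,
    g: float = GRAVITY,
) -> float:
    """Signed Stokes settling velocity (m s^-1, positive = sinking).

    v = (rho_p - rho_sw) d^2 g / (18 mu).  Buoyant particles (density
    below seawater) get a negative velocity, i.e. they rise.
    """
    if diameter_m < 0:
        raise ValueError("diameter must be non-negative")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return (particle_density - sw_density) * diameter_m**2 * g / (18.0 * viscosity)


class CollisionKernels(NamedTuple):
    """Collision kernels in m^3 s^-1."""

    shear: float
    settling: float
    brownian: float

    @property
    def total(self) -> float:
        return self.shear + self.settling + self.brownian


def collision_kernels(
    shear: float,
    r_msa: float,
    r_mp: float,
    v_msa: float,
    v_mp: float,
    temperature_C: float = 20.0,
    viscosity: float = 1.08e-3,
) -> CollisionKernels:
    """Shear, differential-settling and Brownian collision kernels.

    beta_shear = 1.3 gamma (r1+r2)^3; beta_settling = pi/2 r_msa^2 |dv|;
    beta_brownian is the Smoluchowski diffusion kernel
    (2 kB T / 3 mu) (r1+r2)^2 / (r1 r2), retained only to verify it is
    negligible against the other two.  Radii in m, velocities in m s^-1.
    """
    if r_msa <= 0 or r_mp <= 0:
        raise ValueError("radii must be positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    b_shear = 1.3 * shear * (r_msa + r_mp) ** 3
    b_settling = 0.5 * math.pi * r_msa**2 * abs(v_msa - v_mp)
    t_kelvin = temperature_C + 273.15
    b_brownian = (
        2.0 * BOLTZMANN * t_kelvin / (3.0 * viscosity) * (r_msa + r_mp) ** 2 / (r_msa * r_mp)
    )
    return CollisionKernels(b_shear, b_settling, b_brownian)


def attenuation_rate(temperature_C: float, r20a: float = 0.1, q10: float = 2.0) -> float:
    """Aggregate diameter-attenuation rate (d^-1): Q10^((T-20)/10) * R20A."""
    if r20a < 0:
        raise ValueError("r20a must be non-negative")
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return q10 ** ((temperature_C - 20.0) / 10.0) * r20a


@dataclass
class MsaState:
    """Marine snow aggregate carrying the MP.

    Attenuation acts on the diameter; the mass-loss fraction follows as
    1 - (d/d0)^3.
    """

    diameter_um: float
    initial_diameter_um: float
    effective_density_excess: float = 1.2  # rho_MSA - rho_sw, kg m^-3

    def __post_init__(self) -> None:
        if not (0.0 < self.diameter_um <= self.initial_diameter_um):
            raise ValueError("aggregate diameter must be in (0, initial diameter]")

    @property
    def mass_loss_fraction(self) -> float:
        return 1.0 - (self.diameter_um / self.initial_diameter_um) ** 3

    @classmethod
    def fresh(cls, diameter_um: float = 1000.0, effective_density_excess: float = 1.2):
        return cls(diameter_um, diameter_um, effective_density_excess)


@dataclass
class MpState:
    """One microplastic particle's instantaneous state."""

    diameter_um: float
    density_kgm3: float = 960.0
    depth_m: float = 0.0
    phase: str = PHASE_AT_SURFACE
    time_d: float = 0.0


def detachment_check(
    msa: MsaState, mp: MpState, detach_mass_loss: float = 0.4
) -> tuple[bool, str]:
    """Does the MP detach from its aggregate, and why.

    Fires when the aggregate can no longer hold the MP (incorporation
    threshold below the MP diameter) or when the aggregate has lost more
    than ``detach_mass_loss`` of its initial mass.  If both fire at once
    the mass-loss reason is reported.
    """
    if msa.mass_loss_fraction > detach_mass_loss:
        return True, "mass_loss"
    if threshold_size(msa.diameter_um) < mp.diameter_um:
        return True, "size_threshold"
    return False, "none"


@dataclass(frozen=True)
class SettlingParams:
    """Tunables of the settling-cycle integrator.

    ``r20a`` (d^-1) and ``q10`` set aggregate attenuation;
    ``detach_mass_loss`` is the fractional aggregate mass loss that
    triggers detachment; ``timestep_min`` is the fixed integration step
    (the reference resolution is 1 min); ``integrator`` may be ``fixed``
    or ``event`` (adaptive steps with analytic within-phase updates,
    several hundred times fewer steps at matching transit times);
    ``capture_mode`` selects deterministic expected-time capture or
    seeded exponential draws.
    """

    r20a: float = 0.1
    q10: float = 2.0
    detach_mass_loss: float = 0.4
    g: float = GRAVITY
    timestep_min: float = 1.0
    capture_mode: str = "expected_time"
    seed: int = 0
    msa_diameter_um: float = 1000.0
    msa_effective_density: float = 1.2
    tpm_per_aggregate_ug: float = 2.5
    mp_density: float = 960.0
    euphotic_depth_m: float = 100.0
    max_days: float = 3650.0
    integrator: str = "fixed"
    record_every_min: float = 60.0

    def __post_init__(self) -> None:
        if self.r20a < 0 or self.q10 <= 0 or self.g <= 0:
            raise ValueError("r20a must be >= 0; q10 and g positive")
        if not (0.0 < self.detach_mass_loss < 1.0):
            raise ValueError("detach_mass_loss must be in (0, 1)")
        if self.timestep_min <= 0 or self.max_days <= 0:
            raise ValueError("timestep and time cap must be positive")
        if self.capture_mode not in ("expected_time", "stochastic_exponential"):
            raise ValueError("unknown capture_mode")
        if self.integrator not in ("fixed", "event"):
            raise ValueError("integrator must be 'fixed' or 'event'")
        if self.msa_diameter_um <= 0 or self.msa_effective_density <= 0:
            raise ValueError("aggregate diameter and effective density must be positive")
        if self.tpm_per_aggregate_ug <= 0 or self.mp_density <= 0:
            raise ValueError("tpm_per_aggregate and mp density must be positive")


@dataclass
class Trajectory:
    """Time-stamped depth path of one MP size class.

    ``samples`` rows are (time_d, depth_m, phase, msa_diameter_um); the
    aggregate diameter is NaN outside incorporated phases.  ``events``
    rows are (time_d, depth_m, kind) with kind in {capture,
    detach:mass_loss, detach:size_threshold, bottom, time_cap}.
    ``transit_time_d`` is None when the bottom was not reached.
    """

    mp_diameter_um: float
    times_d: np.ndarray
    depths_m: np.ndarray
    phases: list[str]
    msa_diameter_um: np.ndarray
    events: list[tuple[float, float, str]] = field(default_factory=list)
    transit_time_d: float | None = None

    @property
    def n_cycles(self) -> int:
        return sum(1 for _, _, kind in self.events if kind == "capture")


class _ColumnInterpolator:
    """One-searchsorted linear interpolation of all profile fields."""

    def __init__(self, profile: OceanProfile):
        self.z = profile.depth_m
        self.fields = np.column_stack(
            [
                profile.temperature_C,
                profile.density_kgm3,
                profile.shear_s1,
                profile.tpm_ugL,
            ]
        )
        self.mu_scalar = np.isscalar(profile.viscosity)
        if not self.mu_scalar:
            self.fields = np.column_stack([self.fields, profile.viscosity])
        self.mu = profile.viscosity if self.mu_scalar else None
        self.bottom = profile.bottom_m

    def __call__(self, depth: float):
        z = self.z
        i = np.searchsorted(z, depth)
        if i <= 0:
            row = self.fields[0]
        elif i >= len(z):
            row = self.fields[-1]
        else:
            w = (depth - z[i - 1]) / (z[i] - z[i - 1])
            row = self.fields[i - 1] * (1.0 - w) + self.fields[i] * w
        mu = self.mu if self.mu_scalar else row[4]
        return row[0], row[1], row[2], row[3], mu


def _capture_hazard(
    interp: _ColumnInterpolator,
    depth: float,
    mp_diameter_um: float,
    params: SettlingParams,
) -> tuple[float, float]:
    """(hazard s^-1, MP Stokes velocity m s^-1) for a free MP at depth."""
    temp, rho_sw, shear, tpm, mu = interp(depth)
    d_mp = mp_diameter_um * 1e-6
    d_msa = params.msa_diameter_um * 1e-6
    v_mp = stokes_velocity(params.mp_density, rho_sw, d_mp, mu, params.g)
    v_msa = params.msa_effective_density * d_msa**2 * params.g / (18.0 * mu)
    beta = collision_kernels(
        shear, d_msa / 2.0, d_mp / 2.0, v_msa, v_mp, temp, mu
    )
    n_per_m3 = msa_number_concentration(tpm, params.tpm_per_aggregate_ug) * 1000.0
    return beta.total * n_per_m3, v_mp


def settle_trajectory(
    mp_diameter_um: float,
    profile: OceanProfile,
    params: SettlingParams | None = None,
) -> Trajectory:
    """Integrate one MP's journey from the surface to the seabed.

    The MP must be incorporable, i.e. no larger than the threshold size
    of a fresh ambient aggregate.  Phases alternate
    at_surface/rising -> incorporated -> rising -> ... until the bottom
    is reached (``transit_time_d`` set) or ``max_days`` elapses.
    """
    params = params or SettlingParams()
    if mp_diameter_um <= 0:
        raise ValueError("MP diameter must be positive")
    if mp_diameter_um > threshold_size(params.msa_diameter_um):
        raise ValueError(
            f"{mp_diameter_um} µm MP exceeds the incorporation threshold "
            f"{threshold_size(params.msa_diameter_um)} µm of a fresh "
            f"{params.msa_diameter_um} µm aggregate"
        )
    interp = _ColumnInterpolator(profile)
    rng = np.random.default_rng(params.seed)
    draw = (
        (lambda: rng.exponential())
        if params.capture_mode == "stochastic_exponential"
        else (lambda: 1.0)
    )
    event_mode = params.integrator == "event"

    bottom = interp.bottom
    d_detach_um = params.msa_diameter_um * (1.0 - params.detach_mass_loss) ** (1.0 / 3.0)
    d_msa_m = params.msa_diameter_um * 1e-6
    base_dt_d = params.timestep_min / 1440.0
    record_every_d = params.record_every_min / 1440.0

    t = 0.0
    depth = 0.0
    phase = PHASE_AT_SURFACE
    msa_d: float = math.nan
    hazard = 0.0
    target = draw()

    times = [0.0]
    depths = [0.0]
    phases = [phase]
    msa_ds = [math.nan]
    events: list[tuple[float, float, str]] = []
    transit: float | None = None
    last_record = 0.0

    def record(force: bool = False) -> None:
        nonlocal last_record
        if force or t - last_record >= record_every_d:
            times.append(t)
            depths.append(depth)
            phases.append(phase)
            msa_ds.append(msa_d)
            last_record = t

    while t < params.max_days:
        if phase == PHASE_INCORPORATED:
            temp, rho_sw, shear, tpm, mu = interp(depth)
            v = (
                params.msa_effective_density
                * (msa_d * 1e-6) ** 2
                * params.g
                / (18.0 * mu)
            )  # m s^-1, sinking
            in_twilight = depth > params.euphotic_depth_m
            loss = attenuation_rate(temp, params.r20a, params.q10) if in_twilight else 0.0
            dt = base_dt_d
            if event_mode:
                dt = min(0.25, params.max_days - t)
                if v > 0:
                    dt = min(dt, 5.0 / (v * SECONDS_PER_DAY))  # <=5 m per step
                    if not in_twilight:
                        # land just past the euphotic boundary so attenuation
                        # switches on at the right depth, not a step late
                        to_boundary = (
                            params.euphotic_depth_m * (1.0 + 1e-12) - depth
                        ) / (v * SECONDS_PER_DAY)
                        if 0.0 < to_boundary < dt:
                            dt = to_boundary
                if loss > 0:
                    # step at most 0.25% diameter shrink; when the
                    # detachment threshold falls inside the step, land just
                    # past it so the strict mass-loss test fires
                    dt = min(dt, 0.0025 / loss)
                    t_detach = math.log(msa_d / (d_detach_um * (1.0 - 1e-9))) / loss
                    if 0.0 < t_detach < dt:
                        dt = t_detach
                dt = max(dt, 1e-6)
            if loss > 0.0:
                if event_mode:
                    shrink = math.exp(-loss * dt)
                    # depth advance with v ~ d^2 decaying within the step
                    depth += v * SECONDS_PER_DAY * (1.0 - shrink**2) / (2.0 * loss)
                    msa_d *= shrink
                else:
                    depth += v * SECONDS_PER_DAY * dt
                    msa_d *= max(1.0 - loss * dt, 0.0)
            else:
                depth += v * SECONDS_PER_DAY * dt
            t += dt
            if depth >= bottom:
                depth = bottom
                transit = t
                record(force=True)
                events.append((t, depth, "bottom"))
                break
            msa = MsaState(
                min(msa_d, params.msa_diameter_um),
                params.msa_diameter_um,
                params.msa_effective_density,
            )
            mp = MpState(mp_diameter_um, params.mp_density, depth, phase, t)
            detach, reason = detachment_check(msa, mp, params.detach_mass_loss)
            if detach:
                events.append((t, depth, f"detach:{reason}"))
                phase = PHASE_RISING
                msa_d = math.nan
                hazard = 0.0
                target = draw()
                record(force=True)
            else:
                record()
        else:  # at_surface or rising: drift up while waiting for capture
            lam, v_mp = _capture_hazard(interp, depth, mp_diameter_um, params)
            dt = base_dt_d
            if event_mode:
                dt = min(0.1, params.max_days - t)
                if v_mp < 0 and depth > 0:
                    dt = min(dt, max(10.0 / (-v_mp * SECONDS_PER_DAY), 1e-6))
                    dt = min(dt, depth / (-v_mp * SECONDS_PER_DAY))  # stop at surface
                dt = max(dt, 1e-6)
                # trapezoidal hazard over the step; cut the step at the
                # capture crossing so event timing is second-order accurate
                trial_depth = depth
                if depth > 0.0:
                    trial_depth = min(max(depth + v_mp * SECONDS_PER_DAY * dt, 0.0), bottom)
                lam_end, _ = _capture_hazard(interp, trial_depth, mp_diameter_um, params)
                lam_avg = 0.5 * (lam + lam_end)
                gained = lam_avg * SECONDS_PER_DAY * dt
                if hazard + gained >= target and gained > 0:
                    dt *= (target - hazard) / gained
                lam = lam_avg
            t += dt
            hazard += lam * SECONDS_PER_DAY * dt
            if depth > 0.0:
                depth = min(max(depth + v_mp * SECONDS_PER_DAY * dt, 0.0), bottom)
            if depth == 0.0:
                phase = PHASE_AT_SURFACE
            if hazard >= target * (1.0 - 1e-12):
                events.append((t, depth, "capture"))
                phase = PHASE_INCORPORATED
                msa_d = params.msa_diameter_um
                hazard = 0.0
                record(force=True)
            else:
                record()
    else:
        events.append((t, depth, "time_cap"))
        record(force=True)

    return Trajectory(
        mp_diameter_um,
        np.asarray(times),
        np.asarray(depths),
        phases,
        np.asarray(msa_ds),
        events,
        transit,
    )
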