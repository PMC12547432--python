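"""Static 1-D water-column environment.

The sedimentation model needs, at every depth, the seawater temperature
(sets aggregate attenuation through a Q10 law), seawater density (sets
Stokes velocities), turbulent shear rate (collision kernel), total
particulate matter concentration (marine snow abundance) and dynamic
viscosity.  These are held on a regular depth grid and interpolated
linearly; the environment is static in time, which is what makes the
trajectory-template optimisation of the coupled driver exact.

A parametric generator emulates a subtropical-gyre column: a warm mixed
layer over an exponential thermocline decaying to abyssal temperatures,
density increasing monotonically toward the bottom, particulate matter
highest near the productive surface with a small deep floor, and shear at
a mixed-layer baseline decaying below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "OceanProfile",
    "LocalConditions",
    "LayerScheme",
    "DEFAULT_LAYERS",
    "synthetic_profile",
    "msa_number_concentration",
    "profile_lookup",
]

#: Default constant dynamic viscosity of near-surface seawater, kg m^-1 s^-1.
DEFAULT_VISCOSITY = 1.08e-3

#: Average particulate mass per marine snow aggregate, µg.
TPM_PER_AGGREGATE_UG = 2.5


class LocalConditions(NamedTuple):
    """Interpolated water properties at one depth."""

    temperature_C: float
    density_kgm3: float
    shear_s1: float
    tpm_ugL: float
    viscosity: float


@dataclass(frozen=True)
class LayerScheme:
    """Named contiguous depth intervals covering the column (m)."""

    boundaries: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for name, top, bottom in self.boundaries:
            if top != prev_end:
                raise ValueError(f"layer {name!r} does not start where the previous ends")
            if bottom <= top:
                raise ValueError(f"layer {name!r} has non-positive thickness")
            prev_end = bottom

    def layer_at(self, depth: float) -> str:
        for name, top, bottom in self.boundaries:
            if top <= depth <= bottom:
                return name
        raise ValueError(f"depth {depth} m outside the layered column")


DEFAULT_LAYERS = LayerScheme(
    (
        ("euphotic", 0.0, 100.0),
        ("upper_twilight", 100.0, 500.0),
        ("lower_twilight", 500.0, 1000.0),
        ("mid", 1000.0, 2000.0),
        ("deep", 2000.0, 5100.0),
    )
)


@dataclass
class OceanProfile:
    """Gridded depth column of the water properties the model consumes.

    ``viscosity`` may be a scalar (applied at all depths) or an array on
    the same grid.  Depths must increase strictly from 0 and seawater
    density must be non-decreasing (statically stable column).
    """

    depth_m: np.ndarray
    temperature_C: np.ndarray
    density_kgm3: np.ndarray
    shear_s1: np.ndarray
    tpm_ugL: np.ndarray
    viscosity: float | np.ndarray = DEFAULT_VISCOSITY
    layers: LayerScheme = field(default_factory=lambda: DEFAULT_LAYERS)

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        for name in ("temperature_C", "density_kgm3", "shear_s1", "tpm_ugL"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.depth_m.shape:
                raise ValueError(f"{name} must match the depth grid")
            setattr(self, name, arr)
        if self.depth_m[0] != 0.0 or not np.all(np.diff(self.depth_m) > 0):
            raise ValueError("depth grid must increase strictly from 0")
        if np.any(np.diff(self.density_kgm3) < 0):
            raise ValueError("seawater density must be non-decreasing with depth")
        if np.any(self.temperature_C < -2.0):
            raise ValueError("temperature below -2 degC is unphysical for seawater")
        if np.any(self.shear_s1 <= 0) or np.any(self.tpm_ugL <= 0):
            raise ValueError("shear and TPM must be positive everywhere")
        visc = np.asarray(self.viscosity, dtype=float)
        if visc.ndim == 0:
            if float(visc) <= 0:
                raise ValueError("viscosity must be positive")
            self.viscosity = float(visc)
        else:
            if visc.shape != self.depth_m.shape or np.any(visc <= 0):
                raise ValueError("per-depth viscosity must be positive on the grid")
            self.viscosity = visc

    @property
    def bottom_m(self) -> float:
        return float(self.depth_m[-1])

    def at(self, depth: float) -> LocalConditions:
        """Linearly interpolated conditions at ``depth`` (exact at nodes)."""
        if not (0.0 <= depth <= self.bottom_m):
            raise ValueError(
                f"depth {depth} m outside the column [0, {self.bottom_m}]"
            )
        z = self.depth_m
        mu = (
            self.viscosity
            if np.isscalar(self.viscosity)
            else float(np.interp(depth, z, self.viscosity))
        )
        return LocalConditions(
            float(np.interp(depth, z, self.temperature_C)),
            float(np.interp(depth, z, self.density_kgm3)),
            float(np.interp(depth, z, self.shear_s1)),
            float(np.interp(depth, z, self.tpm_ugL)),
            mu,
        )


def profile_lookup(profile: OceanProfile, depth: float) -> LocalConditions:
    """Functional alias for :meth:`OceanProfile.at`."""
    return profile.at(depth)


def synthetic_profile(
    surface_T: float = 24.0,
    deep_T: float = 1.5,
    thermocline_scale: float = 300.0,
    surface_rho: float = 1023.5,
    deep_rho: float = 1027.8,
    rho_scale: float = 400.0,
    tpm_surface: float = 25.0,
    tpm_deep: float = 10.0,
    tpm_decay_scale: float = 400.0,
    shear_baseline: float = 0.2,
    mixed_layer: float = 100.0,
    shear_scale: float = 200.0,
    shear_floor: float = 1e-3,
    bottom: float = 5100.0,
    grid_step: float = 10.0,
    viscosity: float = DEFAULT_VISCOSITY,
) -> OceanProfile:
    """Parametric subtropical-gyre water column on a regular grid.

    Temperature relaxes exponentially from ``surface_T`` to ``deep_T``
    over ``thermocline_scale``; density rises monotonically from
    ``surface_rho`` to ``deep_rho``; particulate matter decays from
    ``tpm_surface`` to a deep floor ``tpm_deep``; shear holds the
    mixed-layer ``shear_baseline`` down to ``mixed_layer`` and decays
    exponentially below, never dropping under ``shear_floor``.
    """
    if bottom <= 0:
        raise ValueError("bottom must be positive")
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    for name, value in (
        ("thermocline_scale", thermocline_scale),
        ("rho_scale", rho_scale),
        ("tpm_decay_scale", tpm_decay_scale),
        ("shear_scale", shear_scale),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    z = np.arange(0.0, bottom + 0.5 * grid_step, grid_step)
    z[-1] = bottom
    temp = deep_T + (surface_T - deep_T) * np.exp(-z / thermocline_scale)
    rho = deep_rho - (deep_rho - surface_rho) * np.exp(-z / rho_scale)
    tpm = tpm_deep + (tpm_surface - tpm_deep) * np.exp(-z / tpm_decay_scale)
    below = np.clip(z - mixed_layer, 0.0, None)
    shear = np.maximum(shear_baseline * np.exp(-below / shear_scale), shear_floor)
    return OceanProfile(z, temp, rho, shear, tpm, viscosity)


def msa_number_concentration(
    tpm_ugL: float, tpm_per_aggregate_ug: float = TPM_PER_AGGREGATE_UG
) -> float:
    """Marine snow aggregates per litre: TPM concentration / mass per aggregate."""
    if tpm_per_aggregate_ug <= 0:
        raise ValueError("mass per aggregate must be positive")
    if tpm_ugL < 0:
        raise ValueError("TPM concentration must be non-negative")
    return tpm_ugL / tpm_per_aggregate_ug
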