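"""Run configuration: defaults, YAML loading and validation.

A configuration file is a flat YAML mapping (plus an optional nested
``profile`` mapping forwarded to the synthetic-profile generator).  An
empty file yields the full default run: a 10 mm, 960 kg m^-3 polyethylene
particle, 0.45% mass loss per month, p = 0.3, f = 0.1, 1 mm aggregates of
1.2 kg m^-3 effective density, 2.5 µg particulate mass per aggregate,
R20A = 0.1 d^-1, Q10 = 2, 40% detachment mass loss, a 5100 m column, a
100 yr horizon and a 1 min settling timestep.  Unknown keys are rejected
by name; every field is validated against its owning parameter type.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .coupled import SnapshotSchedule
from .fragmentation import FragmentationParams
from .ocean import OceanProfile, synthetic_profile
from .sedimentation import SettlingParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "ConfigSyntaxError",
    "ConfigValidationError",
    "load_config",
]


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigSyntaxError(ConfigError):
    """The file is not valid YAML / not a mapping."""


class ConfigValidationError(ConfigError):
    """A key is unknown or a value violates an invariant."""


_PROFILE_KEYS = {
    "surface_T",
    "deep_T",
    "thermocline_scale",
    "surface_rho",
    "deep_rho",
    "rho_scale",
    "tpm_surface",
    "tpm_deep",
    "tpm_decay_scale",
    "shear_baseline",
    "mixed_layer",
    "shear_scale",
    "shear_floor",
    "bottom",
    "grid_step",
    "viscosity",
}


@dataclass
class RunConfig:
    """Fully resolved configuration of a coupled run."""

    particle_diameter_um: float = 10000.0
    particle_density_kgm3: float = 960.0
    degradation_rate: float = 0.0045
    p: float = 0.3
    f: float = 0.1
    k_convention: str = "from_smallest"
    msa_diameter_um: float = 1000.0
    msa_effective_density: float = 1.2
    tpm_per_aggregate_ug: float = 2.5
    r20a: float = 0.1
    q10: float = 2.0
    detach_mass_loss: float = 0.4
    bottom_m: float = 5100.0
    horizon_years: float = 100.0
    snapshot_years: tuple[float, ...] = (10.0, 30.0, 75.0, 100.0)
    timestep_min: float = 1.0
    integrator: str = "fixed"
    capture_mode: str = "expected_time"
    seed: int = 0
    max_days: float = 3650.0
    profile: dict = field(default_factory=dict)
    profile_path: str | None = None

    def __post_init__(self) -> None:
        if self.particle_diameter_um <= 0 or self.particle_density_kgm3 <= 0:
            raise ConfigValidationError(
                "particle_diameter_um and particle_density_kgm3 must be positive"
            )
        if self.bottom_m <= 0:
            raise ConfigValidationError("bottom_m must be positive")
        unknown = set(self.profile) - _PROFILE_KEYS
        if unknown:
            raise ConfigValidationError(
                f"unknown profile key(s): {', '.join(sorted(unknown))}"
            )
        # delegate to the owning parameter types so their invariants apply
        for build in (self.fragmentation_params, self.settling_params, self.schedule):
            try:
                build()
            except (ValueError, TypeError) as exc:
                raise ConfigValidationError(str(exc)) from exc

    def fragmentation_params(self) -> FragmentationParams:
        return FragmentationParams(
            degradation_rate=self.degradation_rate,
            p=self.p,
            f=self.f,
            k_convention=self.k_convention,
        )

    def settling_params(self) -> SettlingParams:
        return SettlingParams(
            r20a=self.r20a,
            q10=self.q10,
            detach_mass_loss=self.detach_mass_loss,
            timestep_min=self.timestep_min,
            capture_mode=self.capture_mode,
            seed=self.seed,
            msa_diameter_um=self.msa_diameter_um,
            msa_effective_density=self.msa_effective_density,
            tpm_per_aggregate_ug=self.tpm_per_aggregate_ug,
            mp_density=self.particle_density_kgm3,
            max_days=self.max_days,
            integrator=self.integrator,
        )

    def schedule(self) -> SnapshotSchedule:
        return SnapshotSchedule(tuple(self.snapshot_years), self.horizon_years)

    def build_profile(self) -> OceanProfile:
        """The configured water column (file takes precedence over generator)."""
        if self.profile_path:
            from .io import read_profile_table

            return read_profile_table(self.profile_path)
        kwargs = dict(self.profile)
        kwargs.setdefault("bottom", self.bottom_m)
        return synthetic_profile(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snapshot_years"] = list(self.snapshot_years)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None) -> RunConfig:
    """Parse, default and validate a YAML config file.

    ``None`` (or an empty file) gives the full defaults.  Raises
    ``FileNotFoundError`` for a missing file, :class:`ConfigSyntaxError`
    for malformed YAML and :class:`ConfigValidationError` for unknown
    keys or invariant violations, naming the offending key.
    """
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigSyntaxError(f"malformed YAML in {p}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigSyntaxError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ConfigValidationError(f"unknown key(s): {', '.join(sorted(unknown))}")
    if "snapshot_years" in raw:
        raw["snapshot_years"] = tuple(raw["snapshot_years"])
    try:
        return RunConfig(**raw)
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigValidationError(str(exc)) from exc
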