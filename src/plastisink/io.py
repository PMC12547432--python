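"""Delimited-text I/O for profiles, spectra, trajectories and budgets.

Every writer embeds the resolved run configuration (or the relevant
parameters) as ``# key: value`` comment lines above the CSV header, so
any output file carries its own provenance.  Readers skip comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ocean import DEFAULT_VISCOSITY, OceanProfile
from .sedimentation import Trajectory

__all__ = [
    "ProfileTableError",
    "read_profile_table",
    "write_profile_table",
    "write_table",
    "read_table",
    "trajectory_frame",
    "events_frame",
]

PROFILE_COLUMNS = ["depth_m", "temperature_C", "density_kgm3", "shear_s1", "tpm_ugL"]


class ProfileTableError(ValueError):
    """A profile table is malformed (missing column, bad values, ...)."""


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with ``# key: value`` provenance comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        # %.17g guarantees float round-trips bit-identically through text
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_profile_table(
    profile: OceanProfile, path: str | Path, meta: dict | None = None
) -> None:
    df = pd.DataFrame(
        {
            "depth_m": profile.depth_m,
            "temperature_C": profile.temperature_C,
            "density_kgm3": profile.density_kgm3,
            "shear_s1": profile.shear_s1,
            "tpm_ugL": profile.tpm_ugL,
        }
    )
    if not np.isscalar(profile.viscosity):
        df["viscosity_kgms"] = profile.viscosity
    else:
        meta = dict(meta or {})
        meta.setdefault("viscosity_kgms", profile.viscosity)
    write_table(df, path, meta)


def read_profile_table(path: str | Path) -> OceanProfile:
    """Read and validate a water-column table.

    Requires columns depth_m, temperature_C, density_kgm3, shear_s1,
    tpm_ugL (an optional viscosity_kgms column is honoured); rows are
    sorted by depth, so shuffled input yields the same profile.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile table not found: {path}")
    df = read_table(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileTableError(f"profile table missing column(s): {', '.join(missing)}")
    df = df.sort_values("depth_m").reset_index(drop=True)
    viscosity: float | np.ndarray = DEFAULT_VISCOSITY
    if "viscosity_kgms" in df.columns:
        viscosity = df["viscosity_kgms"].to_numpy(dtype=float)
    else:
        # a scalar viscosity may have been stashed in the comment header
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "viscosity_kgms:" in line:
                    viscosity = float(line.split(":", 1)[1])
    try:
        return OceanProfile(
            df["depth_m"].to_numpy(dtype=float),
            df["temperature_C"].to_numpy(dtype=float),
            df["density_kgm3"].to_numpy(dtype=float),
            df["shear_s1"].to_numpy(dtype=float),
            df["tpm_ugL"].to_numpy(dtype=float),
            viscosity,
        )
    except ValueError as exc:
        raise ProfileTableError(str(exc)) from exc


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_d": traj.times_d,
            "depth_m": traj.depths_m,
            "phase": traj.phases,
            "msa_diameter_um": traj.msa_diameter_um,
        }
    )


def events_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(traj.events, columns=["time_d", "depth_m", "event"])
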