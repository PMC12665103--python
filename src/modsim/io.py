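"""Configuration and table I/O, packaged defaults, run provenance."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .device import DeviceModel

TIMESERIES_COLUMNS = ["time_s", "compartment", "species", "concentration", "units"]

# reference diffusivities in culture medium (m^2/s)
DIFFUSIVITIES_M2_S = {
    "glucose": 9.58e-10,
    "dextran_4k": 1.35e-10,
    "dextran_70k": 2.30e-11,
}

MOLECULAR_WEIGHTS_KDA = {"glucose": 0.18, "dextran_4k": 4.0, "dextran_70k": 70.0}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def load_config(path: str | Path) -> DeviceModel:
    """Load and fully validate a device configuration JSON.

    Unknown keys are rejected with the offending location; all type
    invariants (positive volumes, porosity in (0, 1], closed convective loop
    under flow, ...) are enforced at load time.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}: not valid JSON ({e})") from e
    try:
        return DeviceModel.model_validate(raw)
    except ValidationError as e:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()
        )
        raise ConfigError(f"{path}: {details}") from e


def save_config(device: DeviceModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(device.model_dump(), indent=2) + "\n")


def default_device() -> DeviceModel:
    """The packaged device: printed geometry where available, calibrated
    effective geometry elsewhere."""
    with resources.as_file(resources.files("modsim.data") / "mod_default.json") as p:
        return load_config(p)


def reported_tracer_data() -> pd.DataFrame:
    """Reported tracer transport summaries (percent transferred, folds) with SDs."""
    with resources.as_file(resources.files("modsim.data") / "tracer_reported.csv") as p:
        return pd.read_csv(p)


def reported_gtt_data() -> pd.DataFrame:
    """Reported sparse GTT glucose/insulin values with SDs."""
    with resources.as_file(resources.files("modsim.data") / "gtt_reported.csv") as p:
        return pd.read_csv(p)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read and validate an observed/simulated concentration time-series CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return df
    key = ["time_s", "compartment", "species"] + (["replicate"] if "replicate" in df.columns else [])
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ConfigError(f"{path}: duplicated observation keys at rows {list(df.index[dup])}")
    for (comp, spec), grp in df.groupby(["compartment", "species"]):
        if grp["units"].nunique() > 1:
            raise ConfigError(f"{path}: mixed units within series ({comp}, {spec})")
        if not grp["time_s"].is_monotonic_increasing:
            grp_sorted = grp.sort_values("time_s")
            if not grp_sorted["time_s"].is_monotonic_increasing:
                raise ConfigError(f"{path}: non-monotone time within series ({comp}, {spec})")
    return df


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"refusing to write table missing columns {missing}")
    df.to_csv(path, index=False)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    command: str,
    parameters: dict,
    seed: int | None = None,
    inputs: list[str | Path] | None = None,
    outputs: list[str | Path] | None = None,
) -> dict:
    """Emit a run manifest sufficient to re-execute a CLI run."""
    from . import __version__

    manifest = {
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _digest(Path(p)) for p in (inputs or []) if Path(p).exists()},
        "outputs": {str(p): _digest(Path(p)) for p in (outputs or []) if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
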