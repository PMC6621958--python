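"""Configuration files, built-in fixtures and result serialization.

A run is described by one YAML document with up to three sections —
``train``, ``kinetics``, ``partition`` — whose keys mirror the dataclass
fields; anything unspecified takes the published defaults.  Results are
written as comma-delimited per-cycle tables plus a JSON summary and a
manifest that echoes every resolved parameter, so a run can be reproduced
bit-for-bit from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .engine import TrainConfig, TrainResult
from .kinetics import KineticParameters
from .partition import PartitionParameters

__all__ = [
    "ConfigError",
    "load_config",
    "resolve_config",
    "write_results",
    "read_per_cycle",
    "builtin_fixtures",
    "TABLE2_VALUES",
]

_SECTIONS = {"train": TrainConfig, "kinetics": KineticParameters,
             "partition": PartitionParameters}

#: steady-state validation data: experimental values and the model
#: predictions originally reported for the two enzyme loadings.
TABLE2_VALUES = {
    "train1": {"enzyme_loading_mg_per_g": 2.0,
               "glucose_experimental": 54.0, "glucose_predicted": 51.0,
               "conversion_experimental": 56.0, "conversion_predicted": 52.0},
    "train2": {"enzyme_loading_mg_per_g": 5.0,
               "glucose_experimental": 78.0, "glucose_predicted": 77.0,
               "conversion_experimental": 88.0, "conversion_predicted": 86.0},
}


class ConfigError(ValueError):
    """Configuration file fails schema validation."""


def _build_section(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(unknown)}")
    coerced: dict[str, Any] = {}
    for key, value in data.items():
        ftype = fields[key].type
        try:
            if ftype in ("float", float):
                value = float(value)
            elif ftype in ("int", int):
                value = int(value)
            elif ftype in ("bool", bool) and not isinstance(value, bool):
                raise TypeError("expected a boolean")
        except (TypeError, ValueError) as exc:
            raise ConfigError(
                f"bad value for [{section}] {key}: {value!r} ({exc})")
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{section}] configuration: {exc}")


def resolve_config(data: Optional[dict],
                   ) -> tuple[TrainConfig, KineticParameters,
                              PartitionParameters]:
    """Build the three parameter sets from a (possibly partial) mapping."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = sorted(set(data) - set(_SECTIONS))
    if unknown:
        raise ConfigError(
            f"unknown top-level section(s): {', '.join(unknown)} "
            f"(expected {', '.join(_SECTIONS)})")
    out = []
    for section, cls in _SECTIONS.items():
        payload = data.get(section) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"section [{section}] must be a mapping")
        out.append(_build_section(cls, payload, section))
    return tuple(out)  # type: ignore[return-value]


def load_config(path) -> tuple[TrainConfig, KineticParameters,
                               PartitionParameters]:
    """Read a YAML run configuration; unspecified fields take the published
    defaults."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}")
    return resolve_config(data)


def _package_version() -> str:
    try:
        return version("sacchsim")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def config_as_dict(cfg: TrainConfig, kp: KineticParameters,
                   pp: PartitionParameters) -> dict:
    return {"train": dataclasses.asdict(cfg),
            "kinetics": dataclasses.asdict(kp),
            "partition": dataclasses.asdict(pp)}


def per_cycle_table(result: TrainResult) -> pd.DataFrame:
    """Tidy per-cycle per-stage table of the recorded time series."""
    n_cycles, n_stages = result.stage_glucose.shape
    cycles = np.repeat(np.arange(n_cycles), n_stages)
    stages = np.tile(np.arange(1, n_stages + 1), n_cycles)
    return pd.DataFrame({
        "cycle": cycles,
        "time_days": np.repeat(result.time_days, n_stages),
        "stage": stages,
        "glucose_g_per_L": result.stage_glucose.ravel(),
        "stage_conversion_pct": result.stage_conversion.ravel(),
        "enzyme_g_per_L": result.stage_enzyme.ravel(),
    })


def write_results(result: TrainResult, out_dir,
                  kp: KineticParameters = KineticParameters(),
                  pp: PartitionParameters = PartitionParameters(),
                  ) -> dict[str, str]:
    """Write per-cycle table, ledger, summary and manifest; returns the
    file inventory (name -> path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory: dict[str, str] = {}

    table = per_cycle_table(result)
    table_path = out / "per_cycle.csv"
    # %.17g round-trips IEEE doubles exactly through the text file
    table.to_csv(table_path, index=False, float_format="%.17g")
    inventory["per_cycle"] = str(table_path)

    ledger_path = out / "ledger.csv"
    result.ledger.to_csv(ledger_path, index=False, float_format="%.17g")
    inventory["ledger"] = str(ledger_path)

    if len(result.time_days) == 0:
        summary: dict[str, Any] = {"n_cycles": 0}
    else:
        g1, conv = result.endpoint_metrics()
        summary = {
            "steady_stage_glucose_g_per_L":
                [float(v) for v in result.steady_stage_profile()],
            "product_concentration_g_per_L": result.product_concentration(),
            "system_conversion_pct": result.system_conversion(),
            "endpoint_glucose_g_per_L": g1,
            "endpoint_conversion_pct": conv,
            "steady_state_cycle": result.steady_state_cycle(),
            "n_cycles": int(len(result.time_days)),
        }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    inventory["summary"] = str(summary_path)

    manifest = {
        "package": "sacchsim",
        "version": _package_version(),
        "config": config_as_dict(result.cfg, kp, pp),
        "outputs": sorted(inventory),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    inventory["manifest"] = str(manifest_path)
    return inventory


def read_per_cycle(path) -> pd.DataFrame:
    """Read back a per-cycle table written by :func:`write_results`.

    Uses round-trip float parsing so the series are reproduced bit-exactly.
    """
    return pd.read_csv(path, float_precision="round_trip")


def builtin_fixtures() -> dict:
    """Named configurations of the two validation trains plus the
    steady-state values they are checked against.

    Both trains ran eight stages with 10 g dry solids and 90 mL liquid per
    48-h transfer; they differ in enzyme loading (2 vs 5 mg/g), addition
    stage (4 vs 5), wet-cake retention (85 vs 80 g) and duration (24 vs
    42 days).
    """
    train2 = TrainConfig()  # defaults are the 5 mg/g train
    train1 = train2.replace(enzyme_loading_mg_per_g=2.0, enzyme_stage=4,
                            wet_cake_target_g=85.0, operation_days=24.0)
    return {"train1": train1, "train2": train2,
            "kinetics": KineticParameters(),
            "partition": PartitionParameters(),
            "table2": TABLE2_VALUES}
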