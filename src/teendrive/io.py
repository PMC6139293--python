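"""Panel CSV and configuration-file handling.

The interchange format is a long-format CSV with one row per driver-month:
columns ``driver_id, month, events, miles`` and optionally ``collisions``.
Months are 1-based and must be contiguous per driver.  The event rate is
always derived (events/miles), never stored.

Run configuration is YAML with fixed top-level sections; unknown keys are
rejected so typos fail loudly rather than silently running defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import OptimizerSettings
from .model import ModelParameters, SimulationConfig, Trajectory
from .synthetic import CohortSpec, LognormalSpec, NoiseSpec, default_shared_parameters

__all__ = [
    "read_panel",
    "write_panel",
    "RunConfig",
    "read_config",
    "write_config",
    "default_config_path",
]

_COLUMNS = ["driver_id", "month", "events", "miles"]


def read_panel(path) -> list[Trajectory]:
    """Read and validate a long-format panel CSV into Trajectories.

    Raises ``ValueError`` naming the offending drivers for duplicate
    (driver, month) rows, negative values, or non-contiguous months.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} lacks columns {missing}")
    df["driver_id"] = df["driver_id"].astype(str)
    dup = df.duplicated(subset=["driver_id", "month"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["driver_id", "month"]].drop_duplicates()
        listing = ", ".join(f"({r.driver_id}, month {r.month})" for r in pairs.itertuples())
        raise ValueError(f"duplicate driver-month rows: {listing}")
    if (df["events"] < 0).any() or (df["miles"] < 0).any() or (df["month"] < 1).any():
        raise ValueError("events, miles must be non-negative and months >= 1")
    out = []
    for did, grp in df.sort_values(["driver_id", "month"]).groupby("driver_id", sort=True):
        months = grp["month"].to_numpy()
        expected = np.arange(1, len(months) + 1)
        if not np.array_equal(months, expected):
            gaps = sorted(set(expected) - set(months))
            raise ValueError(
                f"driver {did!r}: months not contiguous from 1 (missing {gaps})"
            )
        collisions = grp["collisions"].to_numpy(dtype=float) if "collisions" in grp else None
        if collisions is not None and (
            (collisions < 0).any() or (collisions > grp["events"].to_numpy()).any()
        ):
            raise ValueError(f"driver {did!r}: collisions must lie in [0, events]")
        out.append(
            Trajectory(
                driver_id=str(did),
                months=months,
                events=grp["events"].to_numpy(dtype=float),
                miles=grp["miles"].to_numpy(dtype=float),
                collisions=collisions,
            )
        )
    if not out:
        raise ValueError(f"panel file {path} contains no rows")
    return out


def write_panel(panel: list[Trajectory], path) -> None:
    """Write Trajectories as a long-format panel CSV (inverse of read_panel)."""
    frames = []
    for t in panel:
        d = {
            "driver_id": t.driver_id,
            "month": t.months,
            "events": t.events,
            "miles": t.miles,
        }
        if t.collisions is not None:
            d["collisions"] = t.collisions
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run (generate → calibrate → diagnose)."""

    parameters: ModelParameters
    simulation: SimulationConfig
    generator: CohortSpec
    optimizer: OptimizerSettings
    seed: int = 0
    log_level: str = "INFO"


_SECTIONS = {"parameters", "simulation", "generator", "optimizer", "seed", "log_level"}


def _build(cls, data: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in section for {cls.__name__} of {path}")
    return data


def read_config(path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown top-level keys {sorted(unknown)} in {path}")
    params = default_shared_parameters()
    if "parameters" in raw:
        params = ModelParameters(
            **{**dataclasses.asdict(params), **_build(ModelParameters, raw["parameters"], path)}
        )
    sim = SimulationConfig(**_build(SimulationConfig, raw.get("simulation", {}), path))
    gen_raw = dict(raw.get("generator", {}))
    for key, cls in (("need_distribution", LognormalSpec), ("rate_distribution", LognormalSpec), ("noise", NoiseSpec)):
        if key in gen_raw:
            gen_raw[key] = cls(**_build(cls, gen_raw[key], path))
    gen_raw.setdefault("shared", params)
    gen = CohortSpec(**_build(CohortSpec, {k: v for k, v in gen_raw.items()}, path))
    opt = OptimizerSettings(**_build(OptimizerSettings, raw.get("optimizer", {}), path))
    return RunConfig(
        parameters=params,
        simulation=sim,
        generator=gen,
        optimizer=opt,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def write_config(config: RunConfig, path) -> None:
    """Serialise a RunConfig back to YAML."""
    gen = dataclasses.asdict(config.generator)
    gen.pop("shared", None)  # shared parameters live in the parameters block
    data = {
        "parameters": dataclasses.asdict(config.parameters),
        "simulation": dataclasses.asdict(config.simulation),
        "generator": gen,
        "optimizer": dataclasses.asdict(config.optimizer),
        "seed": config.seed,
        "log_level": config.log_level,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_config_path() -> Path:
    """Reference configuration shipped with the package (all defaults)."""
    return Path(__file__).parent / "data" / "default_config.yaml"
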