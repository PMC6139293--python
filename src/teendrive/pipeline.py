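"""End-to-end pipeline: generate (or read) a panel, calibrate, diagnose.

Artifacts are written to an output directory and stamped with the
configuration hash and seed so any result can be traced to the exact run
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from .calibration import CalibrationProblem, calibrate
from .diagnostics import fit_report
from .io import RunConfig, read_panel, write_config, write_panel
from .synthetic import generate_cohort

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("teendrive")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        dataclasses.asdict(config), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    config: RunConfig, out_dir, panel_path=None
) -> dict[str, Path]:
    """Run generate (or read) → calibrate → diagnose; return artifact paths.

    When ``panel_path`` is given the generation stage is skipped and the
    panel is read from disk.  Every artifact records the config hash and
    seed.  A failing stage raises :class:`PipelineError` naming the stage,
    and partially written artifacts of that run are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stamp = {"config_hash": _config_hash(config), "seed": config.seed}
    artifacts: dict[str, Path] = {}

    def stage(name, fn):
        log.info("stage %s starting", name)
        try:
            return fn()
        except Exception as exc:
            for p in artifacts.values():
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def _generate():
        if panel_path is not None:
            return read_panel(panel_path), None
        spec = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(spec)
        return cohort.panel, cohort.truth

    panel, truth = stage("generate", _generate)
    panel_file = out / "panel.csv"
    write_panel(panel, panel_file)
    artifacts["panel"] = panel_file
    if truth is not None:
        truth_file = out / "truth.json"
        truth_file.write_text(
            json.dumps({**stamp, "drivers": truth.to_dict(orient="records")}, indent=2)
        )
        artifacts["truth"] = truth_file

    def _calibrate():
        problem = CalibrationProblem(
            panel=tuple(panel),
            config=config.simulation,
            fixed={"risky_fraction": config.parameters.risky_fraction},
        )
        settings = dataclasses.replace(config.optimizer, seed=config.seed)
        return calibrate(problem, settings)

    result = stage("calibrate", _calibrate)
    fitted_file = out / "fitted.csv"
    write_panel(result.per_driver_fit, fitted_file)
    artifacts["fitted"] = fitted_file
    result_file = out / "calibration.json"
    result_file.write_text(
        json.dumps(
            {
                **stamp,
                "estimates": result.estimates,
                "objective": result.objective,
                "n_converged": result.n_converged,
                "n_starts": result.n_starts,
                "warnings": result.warnings,
            },
            indent=2,
        )
    )
    artifacts["calibration"] = result_file
    for w in result.warnings:
        log.warning("calibration: %s", w)

    def _diagnose():
        per_driver, summary = fit_report(list(panel), result.per_driver_fit)
        return per_driver, summary

    per_driver, summary = stage("diagnose", _diagnose)
    report_file = out / "diagnostics.csv"
    summary.to_csv(report_file)
    per_driver.to_csv(out / "diagnostics_per_driver.csv", index=False)
    artifacts["diagnostics"] = report_file

    config_file = out / "run_config.yaml"
    write_config(config, config_file)
    artifacts["config"] = config_file
    log.info("pipeline complete: %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts
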