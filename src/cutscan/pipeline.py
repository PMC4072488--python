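"""End-to-end study pipeline: cohort -> table 1 -> scans -> groups -> curves.

One RunConfig drives the whole replica: simulate a cohort (or load one
from CSV), build the baseline table, run the HbA1c and BMI cutpoint
scans with spline bands and threshold calls, fit the four-group BMI
model, export adjusted survival curves, and write a manifest with
checksums so a re-run with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import GeneratorConfig, generate_cohort, load_cohort, write_cohort
from .exceptions import ConfigError, CutscanError
from .km import adjusted_curves, curves_to_frame
from .scan import CutpointScan, ScanSpec, group_cox
from .studies import bmi_scan_spec, hba1c_scan_spec
from .tables import build_table1, glucose_breakdown

logger = logging.getLogger("cutscan")

__all__ = ["RunConfig", "run_study"]


@dataclass
class RunConfig:
    """Configuration of one full study run."""

    outdir: str | Path
    mode: str = "simulate"  # simulate | load
    input_path: str | Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    hba1c_spec: ScanSpec = field(default_factory=hba1c_scan_spec)
    bmi_spec: ScanSpec = field(default_factory=bmi_scan_spec)
    group_bounds: tuple[float, ...] = (20.0, 24.0, 35.0)
    group_adjust: tuple[str, ...] = ("apache2", "hba1c")
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.mode not in ("simulate", "load"):
            raise ConfigError("mode: must be 'simulate' or 'load'")
        if self.mode == "load" and self.input_path is None:
            raise ConfigError("input_path: required in load mode")
        if self.mode == "simulate" and self.seed is not None:
            self.generator.seed = int(self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Any stage failure removes the partial outputs of this run and
    re-raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    stage = "setup"

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        t0 = time.perf_counter()
        stage = "cohort"
        if config.mode == "simulate":
            cohort = generate_cohort(config.generator)
            emit("cohort.csv", lambda p: write_cohort(cohort, p))
            emit("generator_config.json", lambda p: config.generator.to_json(p))
        else:
            cohort = load_cohort(config.input_path)
        logger.info("cohort: n=%d, events=%d", len(cohort), int(cohort["event"].sum()))
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "table1"
        t1 = build_table1(cohort)
        emit("table1.csv", t1.to_csv)
        emit("table1.txt", lambda p: Path(p).write_text(t1.to_text() + "\n"))
        breakdown = glucose_breakdown(cohort)
        timings[stage] = time.perf_counter() - t0

        thresholds = {}
        for label, spec in (("hba1c", config.hba1c_spec), ("bmi", config.bmi_spec)):
            t0 = time.perf_counter()
            stage = f"scan_{label}"
            spec.alpha = config.alpha
            res = CutpointScan(cohort, spec).fit()
            emit(f"scan_{label}.csv", lambda p, r=res: r.points_frame.to_csv(p, index=False))
            emit(f"band_{label}.csv", lambda p, r=res: r.band.to_frame().to_csv(p, index=False))
            thresholds[label] = res.threshold_call.to_dict()
            logger.info("scan %s:\n%s", label, res.summary())
            timings[stage] = time.perf_counter() - t0
        emit(
            "thresholds.json",
            lambda p: Path(p).write_text(json.dumps(thresholds, indent=2) + "\n"),
        )

        t0 = time.perf_counter()
        stage = "groups"
        groups = group_cox(
            cohort, "bmi", config.group_bounds, list(config.group_adjust)
        )
        emit(
            "group_cox.json",
            lambda p: Path(p).write_text(json.dumps(groups.to_dict(), indent=2) + "\n"),
        )
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "curves"
        curves = adjusted_curves(
            cohort, "bmi", config.group_bounds, list(config.group_adjust), fit=groups
        )
        emit("curves.csv", lambda p: curves_to_frame(curves).to_csv(p, index=False))
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        manifest = {
            "mode": config.mode,
            "seed": config.generator.seed if config.mode == "simulate" else None,
            "alpha": config.alpha,
            "group_bounds": list(config.group_bounds),
            "n": len(cohort),
            "n_events": int(cohort["event"].sum()),
            "glucose_breakdown": breakdown,
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except CutscanError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc
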