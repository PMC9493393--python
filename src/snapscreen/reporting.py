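"""End-to-end orchestration: run the full screen analysis and write artifacts.

`run_screen` reads and validates the three input tables, normalizes, scores,
runs QC and category enrichment, and only then writes the artifact set
(normalized readings, scores, waterfall, QC report, enrichment table, run
log) to the output directory -- a validation failure therefore leaves no
partial outputs.  Outputs carry no timestamps, so reruns on identical
inputs produce identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import __version__
from .differential_scoring import (
    DEFAULT_DZ_CUT,
    DEFAULT_Z_CUT,
    Classification,
    ScreenResult,
    score_screen,
    waterfall_table,
)
from .enrichment import HIT_DEFINITIONS, category_enrichment
from .normalization import normalize_design
from .qc import control_check, replicate_qc, screen_verdict
from .screen_model import (
    PlateFormat,
    assemble_design,
    read_library,
    read_plate_maps,
    read_readings,
)

logger = logging.getLogger("snapscreen")


@dataclasses.dataclass
class RunConfig:
    """Paths, condition labels and thresholds for one pipeline run."""

    plate_map: Path
    readings: Path
    library: Path
    condition_a: str = "duplex"
    condition_b: str = "triplex"
    z_cut: float = DEFAULT_Z_CUT
    dz_cut: float = DEFAULT_DZ_CUT
    plate_format: int = int(PlateFormat.WELLS_384)
    hit_definitions: tuple[str, ...] = ("recruited_any", "test_selective", "reference_selective")
    outdir: Path = Path("screen_output")
    seed: int | None = None  # recorded in the run log when inputs are simulated

    def __post_init__(self) -> None:
        self.plate_map = Path(self.plate_map)
        self.readings = Path(self.readings)
        self.library = Path(self.library)
        self.outdir = Path(self.outdir)
        if self.z_cut < 0 or self.dz_cut < 0:
            raise ValueError("thresholds must be non-negative")
        for hd in self.hit_definitions:
            if hd not in HIT_DEFINITIONS:
                raise ValueError(f"unknown hit definition {hd!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "hit_definitions" in data:
            data["hit_definitions"] = tuple(data["hit_definitions"])
        return cls(**data)


def _check_inputs(config: RunConfig) -> None:
    for name in ("plate_map", "readings", "library"):
        path = getattr(config, name)
        if not path.is_file():
            raise FileNotFoundError(f"{name} file not found: {path}")


def run_screen(config: RunConfig) -> ScreenResult:
    """Execute the full pipeline; returns the ScreenResult and writes artifacts."""
    _check_inputs(config)

    logger.info("reading inputs: %s", config.plate_map)
    plates = read_plate_maps(config.plate_map, config.plate_format)
    readings = read_readings(config.readings)
    library = read_library(config.library)
    design = assemble_design(
        plates, readings, library, config.condition_a, config.condition_b
    )
    logger.info("design assembled: %s", design.summary())

    normalized, backgrounds = normalize_design(design)
    logger.info("normalized %d wells on %d plates", len(normalized), len(backgrounds))

    result = score_screen(
        normalized,
        library,
        config.condition_a,
        config.condition_b,
        config.z_cut,
        config.dz_cut,
    )
    logger.info("scored screen: %s", result.partition())

    qc_all = replicate_qc(result)
    qc_sections = {"all": dataclasses.asdict(qc_all)}
    for cls in (Classification.TEST_SELECTIVE, Classification.REFERENCE_SELECTIVE):
        try:
            qc_sections[cls.value] = dataclasses.asdict(replicate_qc(result, subset=cls))
        except ValueError:
            qc_sections[cls.value] = None  # fewer than 3 factors in the subset
    controls = control_check(result, library)
    verdict = screen_verdict(controls)
    logger.info("replicate R^2 = %.3f; controls %s", qc_all.r_squared,
                "pass" if verdict else "FAIL")

    enrich_rows = []
    for hd in config.hit_definitions:
        enrich_rows.extend(
            dataclasses.asdict(e) for e in category_enrichment(result, library, hd)
        )

    # All computation succeeded; now write artifacts.
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    normalized.to_csv(outdir / "normalized_readings.csv", index=False)
    result.to_frame().to_csv(outdir / "screen_scores.csv", index=False)
    waterfall_table(result).to_csv(outdir / "waterfall.csv", index=False)
    qc_report = {
        "replicate_regression": qc_sections,
        "controls": [dataclasses.asdict(c) for c in controls],
        "controls_pass": verdict,
    }
    (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2, default=str))
    pd.DataFrame(enrich_rows).to_csv(outdir / "enrichment.csv", index=False)
    run_log = {
        "snapscreen_version": __version__,
        "inputs": {
            "plate_map": str(config.plate_map),
            "readings": str(config.readings),
            "library": str(config.library),
        },
        "conditions": {"reference": config.condition_a, "test": config.condition_b},
        "thresholds": {"z_cut": config.z_cut, "dz_cut": config.dz_cut},
        "seed": config.seed,
        "partition": result.partition(),
        "controls_pass": verdict,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    logger.info("artifacts written to %s", outdir)
    return result
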