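"""Replicate QC, control checks and category enrichment for the scored screen.

Regression of replicate-2 on replicate-1 z-scores (all factors and the
test-selective subset), pass/fail status of the GFP/XPA/RPA2 controls, and
the exact hypergeometric depletion/enrichment of hit frequency across the
three library categories, under all three hit definitions.
"""

import argparse
import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from snapscreen import (
    Classification,
    assemble_design,
    category_enrichment,
    control_check,
    normalize_design,
    replicate_qc,
    score_screen,
    screen_verdict,
)

import importlib.util

ROOT = Path(__file__).resolve().parents[1]
_spec = importlib.util.spec_from_file_location(
    "score_step", Path(__file__).with_name("02_score_screen.py")
)
_score_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_score_step)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument(
        "--datadir", type=Path, default=ROOT / "results" / "simulated_screen"
    )
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    logging.getLogger("snapscreen").setLevel(logging.ERROR)

    plates, readings, library, _ = _score_step.load_or_simulate(args.datadir, args.seed)
    design = assemble_design(plates, readings, library, "duplex", "triplex")
    normalized, _ = normalize_design(design)
    result = score_screen(normalized, library, "duplex", "triplex")

    qc_all = replicate_qc(result)
    qc_sel = replicate_qc(result, subset=Classification.TEST_SELECTIVE)
    controls = control_check(
        result, library, expected_condition={"XPA": "triplex", "RPA2": "triplex"}
    )
    report = {
        "replicate_regression": {
            "all": dataclasses.asdict(qc_all),
            "test_selective": dataclasses.asdict(qc_sel),
        },
        "controls": [dataclasses.asdict(c) for c in controls],
        "controls_pass": screen_verdict(controls),
    }
    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "qc_report.json").write_text(
        json.dumps(report, indent=2, default=str)
    )

    rows = []
    for hit_def in ("recruited_any", "test_selective", "reference_selective"):
        rows += [dataclasses.asdict(e) for e in category_enrichment(result, library, hit_def)]
    enrichment = pd.DataFrame(rows)
    enrichment.to_csv(args.outdir / "enrichment.csv", index=False)

    print(
        f"replicate R^2 (all, n={qc_all.n}): {qc_all.r_squared:.3f} "
        f"(p = {qc_all.p_value:.2e})"
    )
    print(
        f"replicate R^2 (test-selective, n={qc_sel.n}): {qc_sel.r_squared:.3f}"
    )
    for c in controls:
        print(f"control {c.factor_id} [{c.role.value}]: {c.status} ({c.detail})")
    print("category enrichment (recruited_any):")
    print(
        enrichment[enrichment.hit_definition == "recruited_any"]
        [["category", "n", "k", "expected", "direction", "p_value"]]
        .to_string(index=False)
    )
    print(f"reports written to {args.outdir}/qc_report.json and enrichment.csv")


if __name__ == "__main__":
    main()
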