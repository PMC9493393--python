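"""Replicate-correlation scoring and control-behaviour checks.

Reproducibility between biological replicates is scored by simple linear
regression of replicate-2 z-scores on replicate-1 z-scores across factors
(ordinary least squares; R^2 is the squared Pearson correlation, the
p-value tests the zero-slope null two-sidedly).  A classification filter
allows subset QC, e.g. correlation among test-selective hits only.

Control checks: negative controls (GFP) pass when not recruited in either
condition; positive controls (XPA, RPA2) pass when recruited in their
expected condition (or in either, if no expectation is given).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .differential_scoring import Classification, ScreenResult
from .screen_model import ControlRole, LibraryAnnotation

logger = logging.getLogger("snapscreen")


@dataclasses.dataclass(frozen=True)
class ReplicateQC:
    """OLS regression of replicate 2 on replicate 1 over a factor subset."""

    label: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def replicate_regression(
    z_rep1: Sequence[float], z_rep2: Sequence[float], label: str = "all"
) -> ReplicateQC:
    """Simple linear regression of paired replicate z-scores.

    Requires equal-length vectors, n >= 3 and non-constant replicate 1.
    """
    x = np.asarray(z_rep1, dtype=float)
    y = np.asarray(z_rep2, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError(f"replicate regression needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("replicate 1 has zero variance")
    fit = stats.linregress(x, y)
    return ReplicateQC(
        label=label,
        n=int(x.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def replicate_pairs(
    result: ScreenResult,
    subset: Classification | None = None,
    condition: str | None = None,
    include_controls: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (rep1, rep2) z-scores across factors.

    By default both conditions are pooled (one pair per factor-condition, as
    in whole-screen replicate scatter plots); ``condition`` restricts to one
    structure and ``subset`` to one classification.
    """
    xs: list[float] = []
    ys: list[float] = []
    for s in result.scores:
        if s.is_control and not include_controls:
            continue
        if subset is not None and s.classification is not subset:
            continue
        for cond, reps in (
            (result.condition_a, s.z_by_replicate_a),
            (result.condition_b, s.z_by_replicate_b),
        ):
            if condition is not None and cond != condition:
                continue
            if len(reps) >= 2:
                xs.append(reps[0])
                ys.append(reps[1])
    return np.asarray(xs), np.asarray(ys)


def replicate_qc(
    result: ScreenResult,
    subset: Classification | None = None,
    condition: str | None = None,
    include_controls: bool = False,
) -> ReplicateQC:
    """Replicate regression over the selected factor subset."""
    x, y = replicate_pairs(result, subset, condition, include_controls)
    parts = [condition or "both conditions"]
    if subset is not None:
        parts.append(subset.value)
    return replicate_regression(x, y, label=", ".join(parts))


@dataclasses.dataclass(frozen=True)
class ControlStatus:
    """Pass/fail verdict for one dedicated control lysate."""

    factor_id: str
    role: ControlRole
    status: str  # "pass" | "fail" | "missing"
    detail: str

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def control_check(
    result: ScreenResult,
    library: Sequence[LibraryAnnotation],
    expected_condition: Mapping[str, str] | None = None,
) -> list[ControlStatus]:
    """Check every annotated control against its expected behaviour.

    ``expected_condition`` maps a positive control's factor_id to the
    condition in which it must be recruited; positives without an entry pass
    when recruited in either condition.  A control absent from the screen
    yields a "missing" status (and a log warning) rather than an error.
    """
    expected_condition = expected_condition or {}
    by_id = {s.factor_id: s for s in result.scores}
    statuses: list[ControlStatus] = []
    for ann in library:
        if ann.control_role is ControlRole.NONE:
            continue
        score = by_id.get(ann.factor_id)
        if score is None:
            logger.warning("control %s absent from scored screen", ann.factor_id)
            statuses.append(
                ControlStatus(
                    ann.factor_id, ann.control_role, "missing",
                    "control not present in screen",
                )
            )
            continue
        detail = (
            f"z_{result.condition_a}={score.z_a:.2f}, "
            f"z_{result.condition_b}={score.z_b:.2f}"
        )
        if ann.control_role is ControlRole.NEGATIVE:
            ok = score.classification is Classification.NOT_RECRUITED
            if not ok:
                detail += " (negative control recruited)"
        else:
            want = expected_condition.get(ann.factor_id)
            if want == result.condition_a:
                ok = score.z_a >= result.z_cut
            elif want == result.condition_b:
                ok = score.z_b >= result.z_cut
            else:
                ok = max(score.z_a, score.z_b) >= result.z_cut
            if not ok:
                detail += " (positive control not recruited"
                detail += f" in {want})" if want else ")"
        statuses.append(
            ControlStatus(ann.factor_id, ann.control_role, "pass" if ok else "fail", detail)
        )
    return statuses


def screen_verdict(statuses: Sequence[ControlStatus]) -> bool:
    """Screen-level QC verdict: every control present and passing."""
    return bool(statuses) and all(s.passed for s in statuses)
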