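"""Replicate aggregation, differential (delta-z) scoring and hit classification.

For each library factor, per-replicate z-scores are averaged within each
structure condition, giving z_a (reference, e.g. duplex) and z_b (test,
e.g. triplex).  The differential binding statistic is

    delta_z = z_b - z_a.

Dual-threshold classification (both thresholds inclusive):

* recruited      iff max(z_a, z_b) >= z_cut   (default 5),
* among recruited: test-selective  iff delta_z >= dz_cut (default 2.5),
  reference-selective iff delta_z <= -dz_cut, else recruited-nonselective.

Fold change is reported on the log2 scale as the difference of mean log2
luminescence (test minus reference); it is a reporting/sorting quantity
only and plays no role in classification.  No per-factor p-values or
multiple-testing correction are computed: hit calling uses the fixed
z/delta-z thresholds.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError
from .screen_model import ControlRole, LibraryAnnotation, WellKind

logger = logging.getLogger("snapscreen")

DEFAULT_Z_CUT = 5.0
DEFAULT_DZ_CUT = 2.5


class Classification(str, enum.Enum):
    NOT_RECRUITED = "not_recruited"
    RECRUITED_NONSELECTIVE = "recruited_nonselective"
    TEST_SELECTIVE = "test_selective"
    REFERENCE_SELECTIVE = "reference_selective"


def aggregate_replicates(values: Sequence[float]) -> tuple[float, list[float]]:
    """Arithmetic mean of replicate z-scores; per-replicate values preserved.

    A single replicate is allowed (with a log notice); an empty list is an
    error.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise DesignError("cannot aggregate an empty replicate list")
    if len(vals) == 1:
        logger.warning("single-replicate aggregation: no reproducibility information")
    return float(np.mean(vals)), vals


def classify_factor(
    z_a: float,
    z_b: float,
    z_cut: float = DEFAULT_Z_CUT,
    dz_cut: float = DEFAULT_DZ_CUT,
) -> Classification:
    """Dual-threshold classification of one factor from its mean z-scores."""
    if math.isnan(z_a) or math.isnan(z_b):
        raise ValueError("NaN z-score passed to classify_factor")
    if z_cut < 0 or dz_cut < 0:
        raise ValueError("thresholds must be non-negative")
    if max(z_a, z_b) < z_cut:
        return Classification.NOT_RECRUITED
    delta = z_b - z_a
    if delta >= dz_cut:
        return Classification.TEST_SELECTIVE
    if delta <= -dz_cut:
        return Classification.REFERENCE_SELECTIVE
    return Classification.RECRUITED_NONSELECTIVE


def fold_change(mean_log2_a: float, mean_log2_b: float) -> float:
    """log2 fold change of test over reference signal (difference of means)."""
    return float(mean_log2_b) - float(mean_log2_a)


@dataclasses.dataclass(frozen=True)
class FactorScore:
    """Per-factor screen statistics and classification."""

    factor_id: str
    category: str
    z_by_replicate_a: tuple[float, ...]
    z_by_replicate_b: tuple[float, ...]
    z_a: float
    z_b: float
    delta_z: float
    log2_fc: float
    classification: Classification
    is_control: bool = False


@dataclasses.dataclass
class ScreenResult:
    """All factor scores plus the thresholds used and partition tallies.

    Dedicated control lysates are scored and carried in ``scores`` but are
    excluded from partition tallies by default (``controls_excluded``).
    """

    scores: list[FactorScore]
    z_cut: float
    dz_cut: float
    condition_a: str
    condition_b: str
    controls_excluded: bool = True

    def tallied_scores(self) -> list[FactorScore]:
        if self.controls_excluded:
            return [s for s in self.scores if not s.is_control]
        return list(self.scores)

    @property
    def counts(self) -> dict[Classification, int]:
        tallies = {c: 0 for c in Classification}
        for s in self.tallied_scores():
            tallies[s.classification] += 1
        return tallies

    @property
    def library_size(self) -> int:
        return len(self.tallied_scores())

    @property
    def recruited_count(self) -> int:
        return self.library_size - self.counts[Classification.NOT_RECRUITED]

    @property
    def recruitment_rate(self) -> float:
        """Percentage of tallied factors recruited to either structure."""
        size = self.library_size
        return 100.0 * self.recruited_count / size if size else float("nan")

    def partition(self) -> dict[str, float]:
        counts = self.counts
        return {
            "library_size": self.library_size,
            "recruited": self.recruited_count,
            "test_selective": counts[Classification.TEST_SELECTIVE],
            "reference_selective": counts[Classification.REFERENCE_SELECTIVE],
            "recruited_nonselective": counts[Classification.RECRUITED_NONSELECTIVE],
            "not_recruited": counts[Classification.NOT_RECRUITED],
            "recruitment_rate_pct": self.recruitment_rate,
        }

    def to_frame(self) -> pd.DataFrame:
        n_rep = max((len(s.z_by_replicate_a) for s in self.scores), default=0)
        rows = []
        for s in self.scores:
            row = {
                "factor_id": s.factor_id,
                "category": s.category,
                "z_a": s.z_a,
                "z_b": s.z_b,
                "delta_z": s.delta_z,
                "log2_fc": s.log2_fc,
                "classification": s.classification.value,
                "is_control": s.is_control,
            }
            for i in range(n_rep):
                row[f"z_a_rep{i + 1}"] = (
                    s.z_by_replicate_a[i] if i < len(s.z_by_replicate_a) else np.nan
                )
                row[f"z_b_rep{i + 1}"] = (
                    s.z_by_replicate_b[i] if i < len(s.z_by_replicate_b) else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)


def score_screen(
    normalized: pd.DataFrame,
    library: Sequence[LibraryAnnotation],
    condition_a: str,
    condition_b: str,
    z_cut: float = DEFAULT_Z_CUT,
    dz_cut: float = DEFAULT_DZ_CUT,
    exclude_controls: bool = True,
) -> ScreenResult:
    """Score every library factor from a normalized well table.

    ``normalized`` must carry columns ``factor_id, kind, condition, replicate,
    log2_lum, z`` (the output of :func:`snapscreen.normalization.normalize_design`).
    Control wells (dedicated control lysates, which may occupy several wells
    per plate) are averaged per (condition, replicate) before aggregation.
    """
    annotations: Mapping[str, LibraryAnnotation] = {a.factor_id: a for a in library}

    fac = normalized[normalized["factor_id"].notna()].copy()
    if fac.empty:
        raise DesignError("normalized table contains no factor wells")

    per_rep = (
        fac.groupby(["factor_id", "condition", "replicate"], sort=True)
        .agg(z=("z", "mean"), log2_lum=("log2_lum", "mean"))
        .reset_index()
    )
    both = per_rep[per_rep["condition"].isin([condition_a, condition_b])]
    z_piv = both.pivot(index="factor_id", columns=["condition", "replicate"], values="z")
    l_piv = both.pivot(
        index="factor_id", columns=["condition", "replicate"], values="log2_lum"
    )
    for cond in (condition_a, condition_b):
        if cond not in z_piv.columns.get_level_values(0):
            raise DesignError(f"no factor wells for condition {cond!r}")

    replicates = sorted(both["replicate"].unique())
    if len(replicates) == 1:
        logger.warning("single-replicate screen: no reproducibility information")

    # Vectorized aggregation: (n_factors, n_replicates) matrices per condition.
    za_mat = z_piv[condition_a].sort_index(axis=1).to_numpy(dtype=float)
    zb_mat = z_piv[condition_b].sort_index(axis=1).to_numpy(dtype=float)
    la_mat = l_piv[condition_a].sort_index(axis=1).to_numpy(dtype=float)
    lb_mat = l_piv[condition_b].sort_index(axis=1).to_numpy(dtype=float)
    missing = np.isnan(za_mat).all(axis=1) | np.isnan(zb_mat).all(axis=1)
    if missing.any():
        fid = z_piv.index[missing][0]
        raise DesignError(f"factor {fid} lacks z-scores in one condition")
    with np.errstate(invalid="ignore"):
        z_a_all = np.nanmean(za_mat, axis=1)
        z_b_all = np.nanmean(zb_mat, axis=1)
        la_all = np.nanmean(la_mat, axis=1)
        lb_all = np.nanmean(lb_mat, axis=1)

    scores: list[FactorScore] = []
    for i, fid in enumerate(z_piv.index):
        za_reps = [float(v) for v in za_mat[i] if not np.isnan(v)]
        zb_reps = [float(v) for v in zb_mat[i] if not np.isnan(v)]
        z_a, z_b = float(z_a_all[i]), float(z_b_all[i])
        la, lb = float(la_all[i]), float(lb_all[i])
        ann = annotations.get(fid)
        is_control = ann is not None and ann.control_role is not ControlRole.NONE
        scores.append(
            FactorScore(
                factor_id=str(fid),
                category=ann.category.value if ann else "",
                z_by_replicate_a=tuple(za_reps),
                z_by_replicate_b=tuple(zb_reps),
                z_a=z_a,
                z_b=z_b,
                delta_z=z_b - z_a,
                log2_fc=fold_change(la, lb),
                classification=classify_factor(z_a, z_b, z_cut, dz_cut),
                is_control=is_control,
            )
        )

    return ScreenResult(
        scores=scores,
        z_cut=z_cut,
        dz_cut=dz_cut,
        condition_a=condition_a,
        condition_b=condition_b,
        controls_excluded=exclude_controls,
    )


def waterfall_table(result: ScreenResult, include_controls: bool = False) -> pd.DataFrame:
    """Factors ranked by delta_z (descending), ties broken by log2_fc.

    The table shape matches a waterfall plot: one row per factor with the
    classification and the +/- dz_cut cutoff lines as constant columns.
    """
    scores = result.scores if include_controls else [
        s for s in result.scores if not s.is_control
    ]
    df = pd.DataFrame(
        [
            {
                "factor_id": s.factor_id,
                "category": s.category,
                "z_a": s.z_a,
                "z_b": s.z_b,
                "delta_z": s.delta_z,
                "log2_fc": s.log2_fc,
                "classification": s.classification.value,
            }
            for s in scores
        ]
    )
    if df.empty:
        return df
    df = df.sort_values(
        ["delta_z", "log2_fc"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["dz_cutoff_upper"] = result.dz_cut
    df["dz_cutoff_lower"] = -result.dz_cut
    return df
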