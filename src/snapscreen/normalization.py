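"""Log2 transformation and per-plate background z-score normalization.

Raw luminescence from every well is log2 transformed.  On each plate the
empty background wells define a background model (arithmetic mean and
sample SD of log2 RLU), and every well on that plate -- factors, controls
and the empties themselves -- receives

    z = (log2 RLU - mu_bg) / sigma_bg.

The background is fitted per physical plate, never pooled across plates or
conditions, so additive per-plate effects on the log2 scale (plate-to-plate
reader and coating variation) cancel exactly.  By construction the empty
wells of any plate have z-scores with mean 0 and sample SD 1 (with the same
n-1 convention), an identity the test suite asserts to 1e-9.

No spatial (row/column/edge) correction is applied.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import BackgroundError
from .screen_model import PlateLayout, RawReading, ScreenDesign, WellAddress, WellKind


@dataclasses.dataclass(frozen=True)
class BackgroundModel:
    """Per-plate background: mean/sample-SD of log2 RLU over empty wells."""

    plate_id: str
    mu_bg: float
    sigma_bg: float
    n_empty: int

    def __post_init__(self) -> None:
        if self.n_empty < 2:
            raise BackgroundError(
                f"plate {self.plate_id}: background needs >= 2 empty wells, "
                f"got {self.n_empty}"
            )
        if not self.sigma_bg > 0:
            raise BackgroundError(
                f"plate {self.plate_id}: degenerate background "
                f"(sigma_bg = {self.sigma_bg}); empty wells are identical"
            )


@dataclasses.dataclass(frozen=True)
class NormalizedReading:
    """One well after normalization: log2 luminescence and background z-score."""

    plate_id: str
    well: WellAddress
    log2_lum: float
    z: float


def fit_background(
    readings: Sequence[RawReading], layout: PlateLayout
) -> BackgroundModel:
    """Fit the background model from a plate's empty wells.

    mu_bg is the arithmetic mean and sigma_bg the sample SD (n-1 denominator)
    of log2 RLU over the layout's empty_background wells.
    """
    empties = layout.empty_addresses
    values = [
        math.log2(r.luminescence)
        for r in readings
        if r.plate_id == layout.plate_id and r.well in empties
    ]
    n = len(values)
    if n < 2:
        raise BackgroundError(
            f"plate {layout.plate_id}: {n} empty-well reading(s); >= 2 required"
        )
    mu = float(np.mean(values))
    sigma = float(np.std(values, ddof=1))
    return BackgroundModel(layout.plate_id, mu, sigma, n)


def zscore_plate(
    readings: Sequence[RawReading], background: BackgroundModel
) -> list[NormalizedReading]:
    """z-score every reading of one plate against its background model."""
    out = []
    for r in readings:
        if r.plate_id != background.plate_id:
            raise BackgroundError(
                f"reading from plate {r.plate_id} scored against background "
                f"of plate {background.plate_id}"
            )
        log2_lum = math.log2(r.luminescence)
        out.append(
            NormalizedReading(
                r.plate_id,
                r.well,
                log2_lum,
                (log2_lum - background.mu_bg) / background.sigma_bg,
            )
        )
    return out


def normalize_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, BackgroundModel]]:
    """Vectorized normalization of a joined well table.

    ``table`` must carry columns ``plate_id, kind, rlu`` (as produced by
    :meth:`ScreenDesign.well_table`).  Returns a copy with ``log2_lum`` and
    ``z`` columns added, plus the per-plate background models.
    """
    df = table.copy()
    if (df["rlu"] <= 0).any():
        raise BackgroundError("non-positive luminescence in table; rejected upstream")
    df["log2_lum"] = np.log2(df["rlu"].to_numpy(dtype=float))

    empties = df[df["kind"] == WellKind.EMPTY.value]
    stats = empties.groupby("plate_id")["log2_lum"].agg(["mean", "std", "size"])
    models: dict[str, BackgroundModel] = {}
    for plate_id in df["plate_id"].unique():
        if plate_id not in stats.index:
            raise BackgroundError(f"plate {plate_id}: no empty background wells")
        mu, sigma, n = stats.loc[plate_id]
        models[plate_id] = BackgroundModel(plate_id, float(mu), float(sigma), int(n))

    mu_map = df["plate_id"].map({p: m.mu_bg for p, m in models.items()})
    sd_map = df["plate_id"].map({p: m.sigma_bg for p, m in models.items()})
    df["z"] = (df["log2_lum"] - mu_map) / sd_map
    return df, models


def normalize_design(
    design: ScreenDesign,
) -> tuple[pd.DataFrame, dict[str, BackgroundModel]]:
    """Normalize every well of an assembled design (see :func:`normalize_table`)."""
    return normalize_table(design.table)
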