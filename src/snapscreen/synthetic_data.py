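"""Synthetic screen generator with the statistical structure the analysis assumes.

The generator emits complete screens -- plate maps, luminescence readings,
library annotations and a ground-truth table -- in exactly the CSV dialects
:mod:`snapscreen.screen_model` reads, so every pipeline stage is testable
without any external data.

Noise model.  The RLU of well w on plate p is

    RLU = 2 ** (mu + plate_effect_p + effect(factor, condition) + eps_w)

with plate effects ~ Normal(0, plate_effect_sd) shared by *all* wells of a
plate (including the empties, so per-plate background normalization removes
them exactly), well noise eps_w ~ Normal(0, well_noise_sd), and empty wells
carrying effect 0.  Because noise is Normal on the log2 scale, factor-well
z-scores on a null screen are standard normal up to background-estimation
error, which gives clean oracles for every downstream statistic.

Binding effects are additive log2 shifts composed of (i) planted effects for
designated binders and (ii) an optional random per-factor-per-condition
baseline (``baseline_effect_sd``) shared across replicates, which sets the
replicate-to-replicate correlation.

Layout.  Following the original assay design, each (condition, replicate)
pair occupies its own plate set; factors are chunked across as many plates
as the format capacity requires, and every plate carries the dedicated
control lysates plus ``n_empty_per_plate`` background wells.

All randomness flows from ``config.seed`` through one generator; the same
seed reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .differential_scoring import (
    DEFAULT_DZ_CUT,
    DEFAULT_Z_CUT,
    Classification,
    classify_factor,
)
from .exceptions import ScreenError
from .screen_model import (
    Category,
    ControlRole,
    LibraryAnnotation,
    PlateFormat,
    PlateLayout,
    RawReading,
    ScreenDesign,
    TagTerminus,
    WellAddress,
    WellContent,
    WellKind,
    ROW_LETTERS,
    assemble_design,
    write_library,
    write_plate_map,
    write_readings,
)


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A designated binder: additive log2 shifts per condition."""

    factor_id: str
    effect_a: float
    effect_b: float


@dataclasses.dataclass(frozen=True)
class ControlSpec:
    """A dedicated control lysate present on every plate."""

    factor_id: str
    role: ControlRole
    category: Category
    effect_a: float
    effect_b: float


@dataclasses.dataclass
class SynthConfig:
    """Everything needed to simulate one screen, reproducibly.

    Category fractions follow the screened library composition: 336/520 DNA
    repair factors, 64/520 chromatin-associated controls, 120/520 other
    controls with no known chromatin association.  Effect sizes are additive
    log2 shifts; divide by ``well_noise_sd`` to express them as true
    z-scores.
    """

    seed: int = 0
    n_factors: int = 520
    category_fractions: tuple[float, float, float] = (336 / 520, 64 / 520, 120 / 520)
    plate_format: PlateFormat = PlateFormat.WELLS_384
    n_empty_per_plate: int = 64
    replicates: int = 2
    condition_a: str = "duplex"
    condition_b: str = "triplex"
    background_mu_log2: float = 14.0
    plate_effect_sd: float = 0.5
    well_noise_sd: float = 0.25
    baseline_effect_sd: float = 0.0
    planted: tuple[PlantedEffect, ...] = ()
    controls: tuple[ControlSpec, ...] | None = None
    z_cut: float = DEFAULT_Z_CUT
    dz_cut: float = DEFAULT_DZ_CUT

    def __post_init__(self) -> None:
        self.plate_format = PlateFormat(int(self.plate_format))
        if not math.isclose(sum(self.category_fractions), 1.0, abs_tol=1e-9):
            raise ScreenError("category fractions must sum to 1")
        for name in ("plate_effect_sd", "well_noise_sd"):
            if getattr(self, name) <= 0:
                raise ScreenError(f"{name} must be positive")
        if self.baseline_effect_sd < 0:
            raise ScreenError("baseline_effect_sd must be non-negative")
        if self.n_factors < 1 or self.replicates < 1:
            raise ScreenError("n_factors and replicates must be >= 1")
        if self.controls is None:
            s = self.well_noise_sd
            # Dedicated control lysates, true z-effects scaled to log2 shifts:
            # GFP binds nothing; XPA and RPA2 are recruited to the test
            # structure (triplex), RPA2 most strongly.
            self.controls = (
                ControlSpec("GFP", ControlRole.NEGATIVE, Category.OTHER_CONTROL, 0.0, 0.0),
                ControlSpec("XPA", ControlRole.POSITIVE, Category.DNA_REPAIR, 2 * s, 8 * s),
                ControlSpec("RPA2", ControlRole.POSITIVE, Category.DNA_REPAIR, 2 * s, 10 * s),
            )

    @property
    def factor_ids(self) -> list[str]:
        return [f"F{i:04d}" for i in range(1, self.n_factors + 1)]

    def category_counts(self) -> tuple[int, int, int]:
        c0 = round(self.category_fractions[0] * self.n_factors)
        c1 = round(self.category_fractions[1] * self.n_factors)
        c2 = self.n_factors - c0 - c1
        if min(c0, c1, c2) < 0:
            raise ScreenError("category fractions produce a negative count")
        return c0, c1, c2

    def plate_capacity(self) -> int:
        cap = int(self.plate_format) - self.n_empty_per_plate - len(self.controls)
        if cap < 1:
            raise ScreenError(
                f"plate capacity exceeded: {int(self.plate_format)} wells cannot "
                f"hold {self.n_empty_per_plate} empties + {len(self.controls)} "
                "controls + at least one factor"
            )
        return cap


# ---------------------------------------------------------------------------
# Truth table: expected classification and noise margins
# ---------------------------------------------------------------------------


def _mean_z_variance(true_z: float, n_empty: int, replicates: int) -> float:
    """Delta-method variance of a replicate-mean z-score.

    Per replicate, z = (effect + eps - mu_hat)/sigma_hat carries unit well
    noise, background-mean noise 1/n_empty, and multiplicative
    background-SD estimation noise ~ true_z^2 / (2(n_empty-1)).
    """
    per_rep = 1.0 + 1.0 / n_empty + true_z**2 / (2.0 * (n_empty - 1))
    return per_rep / replicates


def classification_margin(
    true_z_a: float,
    true_z_b: float,
    n_empty: int,
    replicates: int,
    z_cut: float = DEFAULT_Z_CUT,
    dz_cut: float = DEFAULT_DZ_CUT,
) -> float:
    """Distance (in combined-noise SDs) from the truth to the nearest threshold.

    A factor whose margin exceeds ~4 is classified correctly essentially
    always; the margin is the minimum over every threshold its class depends
    on (recruitment and the relevant delta-z cutoff).
    """
    var_a = _mean_z_variance(true_z_a, n_empty, replicates)
    var_b = _mean_z_variance(true_z_b, n_empty, replicates)
    sd_a, sd_b = math.sqrt(var_a), math.sqrt(var_b)
    sd_d = math.sqrt(var_a + var_b)
    delta = true_z_b - true_z_a
    cls = classify_factor(true_z_a, true_z_b, z_cut, dz_cut)
    if cls is Classification.NOT_RECRUITED:
        return min((z_cut - true_z_a) / sd_a, (z_cut - true_z_b) / sd_b)
    # Recruited: to flip to not_recruited both conditions must drop below the
    # cut, so the recruitment margin is the best-supported condition's.
    recruit_margin = max((true_z_a - z_cut) / sd_a, (true_z_b - z_cut) / sd_b)
    if cls is Classification.TEST_SELECTIVE:
        dz_margin = (delta - dz_cut) / sd_d
    elif cls is Classification.REFERENCE_SELECTIVE:
        dz_margin = (-delta - dz_cut) / sd_d
    else:
        dz_margin = (dz_cut - abs(delta)) / sd_d
    return min(recruit_margin, dz_margin)


def _truth_table(config: SynthConfig, effects: dict[str, tuple[float, float]],
                 categories: dict[str, Category],
                 roles: dict[str, ControlRole]) -> pd.DataFrame:
    rows = []
    s = config.well_noise_sd
    for fid, (ea, eb) in effects.items():
        tz_a, tz_b = ea / s, eb / s
        rows.append(
            {
                "factor_id": fid,
                "category": categories[fid].value,
                "control_role": roles[fid].value,
                "effect_a": ea,
                "effect_b": eb,
                "true_z_a": tz_a,
                "true_z_b": tz_b,
                "expected_class": classify_factor(
                    tz_a, tz_b, config.z_cut, config.dz_cut
                ).value,
                "margin_sd": classification_margin(
                    tz_a, tz_b, config.n_empty_per_plate, config.replicates,
                    config.z_cut, config.dz_cut,
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimulatedScreen:
    """A complete synthetic screen plus its ground truth."""

    plates: list[PlateLayout]
    readings: list[RawReading]
    library: list[LibraryAnnotation]
    truth: pd.DataFrame
    config: SynthConfig

    def design(self) -> ScreenDesign:
        return assemble_design(
            self.plates,
            self.readings,
            self.library,
            self.config.condition_a,
            self.config.condition_b,
        )

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "plate_map": outdir / "plate_map.csv",
            "readings": outdir / "readings.csv",
            "library": outdir / "library.csv",
            "truth": outdir / "truth.csv",
        }
        write_plate_map(self.plates, paths["plate_map"])
        write_readings(self.readings, paths["readings"])
        write_library(self.library, paths["library"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _addresses(fmt: PlateFormat) -> list[WellAddress]:
    return [
        WellAddress(ROW_LETTERS[r], c + 1)
        for r in range(fmt.n_rows)
        for c in range(fmt.n_cols)
    ]


def simulate_screen(config: SynthConfig) -> SimulatedScreen:
    """Generate a full two-condition screen from a config, deterministically."""
    rng = np.random.default_rng(config.seed)
    ids = config.factor_ids
    c_repair, c_chrom, _ = config.category_counts()
    categories: dict[str, Category] = {}
    for i, fid in enumerate(ids):
        if i < c_repair:
            categories[fid] = Category.DNA_REPAIR
        elif i < c_repair + c_chrom:
            categories[fid] = Category.CHROMATIN_ASSOCIATED
        else:
            categories[fid] = Category.OTHER_CONTROL
    roles: dict[str, ControlRole] = {fid: ControlRole.NONE for fid in ids}

    # Binding effects: random shared baseline + planted shifts.
    effects: dict[str, tuple[float, float]] = {}
    if config.baseline_effect_sd > 0:
        baseline = rng.normal(0.0, config.baseline_effect_sd, size=(len(ids), 2))
    else:
        baseline = np.zeros((len(ids), 2))
    for i, fid in enumerate(ids):
        effects[fid] = (float(baseline[i, 0]), float(baseline[i, 1]))
    id_set = set(ids)
    for p in config.planted:
        if p.factor_id not in id_set:
            raise ScreenError(f"planted factor {p.factor_id!r} not in library")
        ea, eb = effects[p.factor_id]
        effects[p.factor_id] = (ea + p.effect_a, eb + p.effect_b)
    for ctl in config.controls:
        if ctl.factor_id in id_set:
            raise ScreenError(f"control id {ctl.factor_id!r} collides with a factor")
        effects[ctl.factor_id] = (ctl.effect_a, ctl.effect_b)
        categories[ctl.factor_id] = ctl.category
        roles[ctl.factor_id] = ctl.role

    library = [
        LibraryAnnotation(fid, categories[fid], TagTerminus.C, ControlRole.NONE)
        for fid in ids
    ] + [
        LibraryAnnotation(c.factor_id, c.category, TagTerminus.C, c.role)
        for c in config.controls
    ]

    # Plate construction: chunk factors, one plate set per (condition, replicate).
    capacity = config.plate_capacity()
    chunks = [ids[i : i + capacity] for i in range(0, len(ids), capacity)]
    addresses = _addresses(config.plate_format)
    conditions = (config.condition_a, config.condition_b)

    plate_specs = []  # (plate_id, condition, cond_index, replicate, chunk)
    for ci, cond in enumerate(conditions):
        for rep in range(1, config.replicates + 1):
            for pi, chunk in enumerate(chunks, start=1):
                plate_specs.append((f"{cond}_r{rep}_p{pi}", cond, ci, rep, chunk))

    plate_effects = rng.normal(0.0, config.plate_effect_sd, size=len(plate_specs))

    plates: list[PlateLayout] = []
    readings: list[RawReading] = []
    for (plate_id, cond, ci, rep, chunk), p_eff in zip(plate_specs, plate_effects):
        wells: dict[WellAddress, WellContent] = {}
        well_effects: list[float] = []
        cursor = 0
        for fid in chunk:
            wells[addresses[cursor]] = WellContent(WellKind.FACTOR, fid, cond, rep)
            well_effects.append(effects[fid][ci])
            cursor += 1
        for ctl in config.controls:
            kind = (
                WellKind.NEGATIVE_CONTROL
                if ctl.role is ControlRole.NEGATIVE
                else WellKind.POSITIVE_CONTROL
            )
            wells[addresses[cursor]] = WellContent(kind, ctl.factor_id, cond, rep)
            well_effects.append(effects[ctl.factor_id][ci])
            cursor += 1
        for _ in range(config.n_empty_per_plate):
            wells[addresses[cursor]] = WellContent(WellKind.EMPTY, None, cond, rep)
            well_effects.append(0.0)
            cursor += 1
        noise = rng.normal(0.0, config.well_noise_sd, size=cursor)
        log2_rlu = (
            config.background_mu_log2 + p_eff + np.asarray(well_effects) + noise
        )
        plates.append(PlateLayout(plate_id, config.plate_format, wells))
        for addr, value in zip(wells, 2.0**log2_rlu):
            readings.append(RawReading(plate_id, addr, float(value)))

    truth = _truth_table(config, effects, categories, roles)
    return SimulatedScreen(plates, readings, library, truth, config)


# ---------------------------------------------------------------------------
# Ready-made configurations
# ---------------------------------------------------------------------------


def paper_scale_config(seed: int = 0, well_noise_sd: float = 0.25) -> SynthConfig:
    """A 520-factor screen in the published library proportions.

    336 DNA-repair factors, 64 chromatin-associated and 120 other controls,
    assayed in biological duplicate on 384-well plates per structure.  126
    binders are planted -- 16 test(triplex)-selective, 17 reference(duplex)-
    selective and 93 nonselective -- with hits spread so the non-chromatin
    control category carries a 12.5% hit rate (15/120) against 24.2%
    overall, the depletion regime the category-enrichment test probes.

    True effect sizes (z-units): selective binders 9 on the preferred and 1
    on the other structure; nonselective binders 8 on both.  With 64 empty
    background wells per plate these margins put null and selective factors
    beyond 4 combined-noise SDs of every threshold; nonselective binders sit
    exactly on delta-z = 0 and are recovered at the rate their 2.5-cut
    margin allows.
    """
    n = 520
    ids = [f"F{i:04d}" for i in range(1, n + 1)]
    s = well_noise_sd
    planted: list[PlantedEffect] = []
    # DNA repair (indices 0..335): 16 test-selective, 17 reference-selective,
    # 60 nonselective -> 93 repair hits (27.7%).
    for fid in ids[0:16]:
        planted.append(PlantedEffect(fid, 1 * s, 9 * s))
    for fid in ids[16:33]:
        planted.append(PlantedEffect(fid, 9 * s, 1 * s))
    for fid in ids[33:93]:
        planted.append(PlantedEffect(fid, 8 * s, 8 * s))
    # Chromatin-associated (336..399): 18 nonselective hits (28.1%).
    for fid in ids[336:354]:
        planted.append(PlantedEffect(fid, 8 * s, 8 * s))
    # Other controls (400..519): 15 nonselective hits (12.5%).
    for fid in ids[400:415]:
        planted.append(PlantedEffect(fid, 8 * s, 8 * s))
    return SynthConfig(
        seed=seed,
        n_factors=n,
        n_empty_per_plate=64,
        replicates=2,
        well_noise_sd=well_noise_sd,
        planted=tuple(planted),
    )


def null_config(seed: int = 0, n_factors: int = 520) -> SynthConfig:
    """A screen with no binders at all: every factor-well z is standard normal."""
    return SynthConfig(seed=seed, n_factors=n_factors, n_empty_per_plate=64)


def expected_replicate_correlation(config: SynthConfig) -> float:
    """Predicted inter-replicate correlation of factor z-scores.

    With shared per-factor effect SD s (z-units) and per-replicate noise
    variance v = 1 + 1/n_empty + s^2/(2(n_empty-1)) (well noise, background-
    mean error, background-SD estimation error averaged over factors),

        corr(z_rep1, z_rep2) = s^2 / (s^2 + v),

    and the regression R^2 is the square of this correlation.
    """
    s2 = (config.baseline_effect_sd / config.well_noise_sd) ** 2
    n = config.n_empty_per_plate
    v = 1.0 + 1.0 / n + s2 / (2.0 * (n - 1))
    return s2 / (s2 + v)


def expected_replicate_r_squared(config: SynthConfig) -> float:
    return expected_replicate_correlation(config) ** 2


def reproducibility_config(
    seed: int = 0,
    target_r_squared: float = 0.92,
    n_factors: int = 520,
) -> SynthConfig:
    """A screen calibrated to a target replicate R^2 (default the 0.92 regime).

    Solves corr = sqrt(R^2) = s^2/(s^2 + v(s)) for the shared per-factor
    effect SD s (see :func:`expected_replicate_correlation`); binding
    signal is a random shared log2 shift per factor and condition, with no
    planted hit structure.
    """
    if not 0 < target_r_squared < 1:
        raise ScreenError("target_r_squared must lie in (0, 1)")
    base = SynthConfig(seed=seed, n_factors=n_factors, n_empty_per_plate=64)
    r = math.sqrt(target_r_squared)
    n = base.n_empty_per_plate
    denom = 1.0 - r - r / (2.0 * (n - 1))
    if denom <= 0:
        raise ScreenError(
            f"target R^2 {target_r_squared} unreachable with {n} empty wells "
            "(background estimation noise dominates)"
        )
    s2 = r * (1.0 + 1.0 / n) / denom
    return dataclasses.replace(
        base, baseline_effect_sd=math.sqrt(s2) * base.well_noise_sd
    )


# ---------------------------------------------------------------------------
# Synthetic ChIP-qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_chip_table(
    seed: int = 0,
    input_fraction: float = 0.02,
    n_biological: int = 3,
    n_technical: int = 3,
    technical_ct_sd: float = 0.05,
) -> pd.DataFrame:
    """A synthetic Ct table for the percent-input validation workflow.

    Emulates a locus-occupancy experiment: anti-FLAG IP in structure-treated
    cells enriches the target locus ~10-fold over mock, IgG shows no
    enrichment, and an off-target locus shows none in any condition.  Ct
    values are generated by inverting the percent-input relation from true
    occupancy fractions (perfect doubling), plus technical replicate noise
    on the Ct scale.  Purely synthetic; occupancies are round numbers chosen
    for a clean fold-enrichment readout, not measured values.
    """
    rng = np.random.default_rng(seed)
    # (locus, antibody, treatment) -> true occupancy fraction of input chromatin
    occupancy = {
        ("target", "anti_FLAG", "PNA"): 0.040,
        ("target", "anti_FLAG", "mock"): 0.004,
        ("target", "IgG", "PNA"): 0.0008,
        ("target", "IgG", "mock"): 0.0008,
        ("off_target", "anti_FLAG", "PNA"): 0.004,
        ("off_target", "anti_FLAG", "mock"): 0.004,
        ("off_target", "IgG", "PNA"): 0.0008,
        ("off_target", "IgG", "mock"): 0.0008,
    }
    dilution = math.log2(1.0 / input_fraction)
    rows = []
    for (locus, antibody, treatment), occ in occupancy.items():
        for b in range(1, n_biological + 1):
            sid = f"{locus}_{antibody}_{treatment}_b{b}"
            ct_input = 20.0 + rng.normal(0.0, 0.3)
            ct_ip_true = (ct_input - dilution) - math.log2(occ)
            for t in range(1, n_technical + 1):
                rows.append(
                    {
                        "sample_id": sid,
                        "locus": locus,
                        "antibody": antibody,
                        "treatment": treatment,
                        "replicate": t,
                        "ct_ip": ct_ip_true + rng.normal(0.0, technical_ct_sd),
                        "ct_input": ct_input + rng.normal(0.0, technical_ct_sd),
                        "input_fraction": input_fraction,
                    }
                )
    return pd.DataFrame(rows)
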