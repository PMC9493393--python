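"""Percent-input quantification and fold enrichment for ChIP-qPCR data.

The percent-input method expresses immunoprecipitated DNA as a percentage of
the chromatin put into the IP.  The input aliquot is only a fraction f of
the IP chromatin (e.g. 2%), so its Ct is first adjusted by the dilution:

    adjusted input Ct = Ct_input - log_E(1/f)        (E = amplification
    percent input    = 100 * E^(adjusted input Ct - Ct_ip)   efficiency)

Fold enrichment divides a sample's percent input by the mean percent input
of a reference group (e.g. the averaged mock-treatment condition for the
same locus and antibody).  Amplification efficiency defaults to perfect
doubling (E = 2); technical replicates are averaged on the Ct scale before
exponentiation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .exceptions import ChipError


def _check_fraction(input_fraction: float) -> float:
    f = float(input_fraction)
    if not 0 < f <= 1:
        raise ChipError(f"input_fraction must lie in (0, 1], got {input_fraction!r}")
    return f


@dataclasses.dataclass(frozen=True)
class ChipSample:
    """One ChIP-qPCR measurement (technical replicates already Ct-averaged)."""

    sample_id: str
    locus: str
    antibody: str  # e.g. "anti_FLAG" or "IgG"
    treatment: str  # e.g. "PNA" or "mock"
    ct_ip: float
    ct_input: float
    input_fraction: float = 0.02

    def __post_init__(self) -> None:
        _check_fraction(self.input_fraction)
        for name, ct in (("ct_ip", self.ct_ip), ("ct_input", self.ct_input)):
            if not (math.isfinite(ct) and ct > 0):
                raise ChipError(f"{name} must be a positive finite Ct, got {ct!r}")


@dataclasses.dataclass(frozen=True)
class ChipResult:
    sample_id: str
    locus: str
    antibody: str
    treatment: str
    percent_input: float
    fold_enrichment: float


def adjusted_input_ct(
    ct_input: float, input_fraction: float, efficiency: float = 2.0
) -> float:
    """Dilution-adjust the input Ct to the full chromatin amount."""
    f = _check_fraction(input_fraction)
    if not efficiency > 1:
        raise ChipError(f"amplification efficiency must exceed 1, got {efficiency!r}")
    return float(ct_input) - math.log(1.0 / f, efficiency)


def percent_input(
    ct_ip: float, ct_input: float, input_fraction: float, efficiency: float = 2.0
) -> float:
    """IP signal as a percentage of (dilution-adjusted) input chromatin."""
    adj = adjusted_input_ct(ct_input, input_fraction, efficiency)
    return 100.0 * efficiency ** (adj - float(ct_ip))


def fold_enrichment(
    sample_percent: float, reference_percents: Sequence[float]
) -> float:
    """Sample percent input over the mean of the reference group."""
    refs = [float(r) for r in reference_percents]
    if not refs:
        raise ChipError("fold enrichment needs a non-empty reference group")
    mean_ref = sum(refs) / len(refs)
    if not mean_ref > 0:
        raise ChipError(f"reference group mean must be positive, got {mean_ref}")
    return float(sample_percent) / mean_ref


_CT_COLUMNS = [
    "sample_id",
    "locus",
    "antibody",
    "treatment",
    "replicate",
    "ct_ip",
    "ct_input",
    "input_fraction",
]


def read_ct_table(path: Union[str, Path]) -> list[ChipSample]:
    """Read a Ct CSV and average technical replicates on the Ct scale.

    Expected columns: sample_id, locus, antibody, treatment, replicate,
    ct_ip, ct_input, input_fraction (one row per technical replicate).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise ChipError(f"{path}: missing required columns {missing}")
    samples = []
    grouped = df.groupby(["sample_id", "locus", "antibody", "treatment"], sort=True)
    for (sid, locus, antibody, treatment), g in grouped:
        fractions = g["input_fraction"].unique()
        if len(fractions) != 1:
            raise ChipError(f"sample {sid}: inconsistent input_fraction {fractions}")
        samples.append(
            ChipSample(
                sample_id=str(sid),
                locus=str(locus),
                antibody=str(antibody),
                treatment=str(treatment),
                ct_ip=float(g["ct_ip"].mean()),
                ct_input=float(g["ct_input"].mean()),
                input_fraction=float(fractions[0]),
            )
        )
    return samples


def summarize_chip(
    samples: Sequence[ChipSample],
    reference_treatment: str = "mock",
    efficiency: float = 2.0,
) -> list[ChipResult]:
    """Percent input per sample and fold enrichment vs the reference group.

    The reference group for each (locus, antibody) stratum is the set of
    samples with ``treatment == reference_treatment``; every sample in the
    stratum (including the references themselves) is expressed relative to
    the reference group mean.
    """
    if not samples:
        raise ChipError("no ChIP samples provided")
    percents = {
        s.sample_id: percent_input(s.ct_ip, s.ct_input, s.input_fraction, efficiency)
        for s in samples
    }
    results: list[ChipResult] = []
    strata: dict[tuple[str, str], list[ChipSample]] = {}
    for s in samples:
        strata.setdefault((s.locus, s.antibody), []).append(s)
    for (locus, antibody), group in strata.items():
        refs = [percents[s.sample_id] for s in group if s.treatment == reference_treatment]
        if not refs:
            raise ChipError(
                f"no {reference_treatment!r} reference samples for "
                f"locus={locus}, antibody={antibody}"
            )
        for s in group:
            results.append(
                ChipResult(
                    sample_id=s.sample_id,
                    locus=s.locus,
                    antibody=s.antibody,
                    treatment=s.treatment,
                    percent_input=percents[s.sample_id],
                    fold_enrichment=fold_enrichment(percents[s.sample_id], refs),
                )
            )
    return results


def results_frame(results: Sequence[ChipResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
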