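"""Censoring substitution, multi-dilution aggregation, unit normalization.

One environmental sample is assayed on one tray per dilution (up to three
dilutions).  The study's aggregation rules for the per-tray MPNs are:

* every tray non-detect  → substitute 0.5 MPN on the *lowest* dilution
  (left-censored result);
* every tray over-range  → substitute 2419.6 MPN on the *highest* dilution
  (right-censored result);
* otherwise              → average the dilution-corrected concentrations of
  the quantifiable trays, ignoring censored trays.

The averaged concentration refers to 100 mL of undiluted assay fluid —
the water sample itself, a swab or soil eluate, a food homogenate, or a
produce rinse.  For solid matrices the assay-fluid concentration is then
rescaled to the matrix reporting unit (per swab, per gram, per serving)
using the recorded elution / homogenate volumes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .config import SAMPLE_TYPES, WATER_TYPES
from .mpn import CensoringStatus, TrayEstimate, TrayObservation, mpn_mle

__all__ = [
    "MatrixMetadata",
    "SampleRecord",
    "ConcentrationResult",
    "SampleCensoring",
    "substitute_censored",
    "combine_dilutions",
    "unit_for_sample_type",
    "reporting_unit_factor",
    "normalize_units",
    "process_sample",
    "process_dataset",
]


class SampleCensoring(str, enum.Enum):
    """Censoring status of the aggregated per-sample concentration."""

    LEFT = "left"
    INTERVAL_OK = "interval_ok"
    RIGHT = "right"


@dataclass(frozen=True)
class MatrixMetadata:
    """Elution / homogenate volumes used to process solid matrices.

    Defaults follow the field protocol: 10 g soil in 20 mL PBST, swabs in
    14 mL PBST, 10 g street food in 90 mL distilled water, whole produce
    rinsed in 500 mL PBST.  ``soil_water_fraction`` is the water content of
    the soil aliquot contributing to the eluate volume (no moisture data
    were collected, hence 0 by default).  ``produce_weight`` is recorded
    for reporting only; the reporting unit for produce is one serving
    (one rinsed batch).
    """

    soil_mass: float = 10.0
    soil_eluate_volume: float = 20.0
    soil_water_fraction: float = 0.0
    swab_eluate_volume: float = 14.0
    food_mass: float = 10.0
    food_diluent_volume: float = 90.0
    produce_rinse_volume: float = 500.0
    produce_weight: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "soil_mass",
            "soil_eluate_volume",
            "swab_eluate_volume",
            "food_mass",
            "food_diluent_volume",
            "produce_rinse_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.soil_water_fraction < 1:
            raise ValueError("soil_water_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SampleRecord:
    """One environmental sample: metadata plus its dilution series."""

    sample_id: str
    sample_type: str
    neighborhood: str
    category: str
    corporation: str
    trays: Tuple[Tuple[float, TrayObservation], ...]
    matrix: MatrixMetadata = field(default_factory=MatrixMetadata)
    qc_flag: str = "pass"  # field/lab blank status, carried through only
    true_log10: Optional[float] = None  # set by the simulator, else None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if not self.trays:
            raise ValueError("sample must carry at least one tray")
        factors = [d for d, _ in self.trays]
        if len(set(factors)) != len(factors):
            raise ValueError("dilution factors must be distinct")
        if any(d < 1 for d in factors):
            raise ValueError("dilution factors must be >= 1")


@dataclass(frozen=True)
class ConcentrationResult:
    """Final per-sample concentration in matrix reporting units."""

    sample_id: str
    sample_type: str
    neighborhood: str
    category: str
    corporation: str
    value: float
    log10_value: float
    unit: str
    censoring: SampleCensoring
    n_trays_used: int
    flags: Tuple[str, ...] = ()


def substitute_censored(
    est: TrayEstimate, low: float = 0.5, high: float = 2419.6
) -> float:
    """Numeric per-tray MPN after the study's censoring substitution.

    Non-detect trays become ``low`` (0.5 MPN), over-range trays become
    ``high`` (2419.6 MPN); quantifiable trays keep their MLE.
    """
    if est.status is CensoringStatus.NONDETECT:
        return low
    if est.status is CensoringStatus.OVERRANGE:
        return high
    assert est.mpn is not None
    return est.mpn


def combine_dilutions(
    trays: Sequence[Tuple[float, TrayEstimate]],
    low: float = 0.5,
    high: float = 2419.6,
    averaging: str = "arithmetic",
) -> Tuple[float, SampleCensoring, int, Tuple[str, ...]]:
    """Aggregate the dilution series into one assay-fluid concentration.

    Returns ``(value per 100 mL of undiluted assay fluid, censoring,
    n_trays_used, flags)``.  Censored trays are ignored whenever at least
    one tray is quantifiable; an all-non-detect series is substituted at
    the lowest dilution, an all-over-range series at the highest.
    """
    if not trays:
        raise ValueError("empty dilution series")
    statuses = [est.status for _, est in trays]
    flags: List[str] = []

    if all(s is CensoringStatus.NONDETECT for s in statuses):
        d_min = min(d for d, _ in trays)
        return low * d_min, SampleCensoring.LEFT, len(trays), ()
    if all(s is CensoringStatus.OVERRANGE for s in statuses):
        d_max = max(d for d, _ in trays)
        return high * d_max, SampleCensoring.RIGHT, len(trays), ()

    quant = [(d, est) for d, est in trays if est.quantifiable]
    if not quant:
        # Some trays non-detect and the rest over-range: a pattern the
        # aggregation rules do not cover and the assay design makes
        # near-impossible.  Substitute both limits and average.
        scaled = [substitute_censored(est, low, high) * d for d, est in trays]
        flags.append("inconsistent_censoring")
        value = _average(scaled, averaging)
        return value, SampleCensoring.INTERVAL_OK, len(trays), tuple(flags)

    if any(
        est.status is CensoringStatus.NONDETECT and d < dq
        for d, est in trays
        for dq, _ in quant
    ):
        # non-detect at a lower dilution than a quantifiable tray is
        # logically inconsistent; rule (c) still applies but is flagged
        flags.append("nondetect_below_quantifiable")

    scaled = [est.mpn * d for d, est in quant]  # type: ignore[operator]
    value = _average(scaled, averaging)
    return value, SampleCensoring.INTERVAL_OK, len(quant), tuple(flags)


def _average(values: Sequence[float], averaging: str) -> float:
    if averaging == "arithmetic":
        return sum(values) / len(values)
    if averaging == "geometric":
        return math.exp(sum(math.log(v) for v in values) / len(values))
    raise ValueError(f"unknown averaging scale {averaging!r}")


def unit_for_sample_type(sample_type: str) -> str:
    """Reporting unit mandated by the matrix."""
    if sample_type in WATER_TYPES:
        return "per_100mL"
    if sample_type == "latrine_swab":
        return "per_swab"
    if sample_type == "produce":
        return "per_serving"
    if sample_type in ("street_food", "soil"):
        return "per_gram"
    raise ValueError(f"unknown sample_type {sample_type!r}")


def reporting_unit_factor(sample_type: str, matrix: MatrixMetadata) -> float:
    """Multiplier converting MPN/100 mL of assay fluid to reporting units.

    Water is assayed directly (factor 1).  A swab's organisms are spread
    over ``swab_eluate_volume`` mL of eluate; a produce serving's over the
    rinse volume.  For street food the assayed homogenate volume is
    ``food_mass + food_diluent_volume`` (the food contributes its own
    volume) and the result is divided by the food mass; soil is analogous
    with only the water fraction of the aliquot joining the eluate.
    """
    if sample_type in WATER_TYPES:
        return 1.0
    if sample_type == "latrine_swab":
        return matrix.swab_eluate_volume / 100.0
    if sample_type == "produce":
        return matrix.produce_rinse_volume / 100.0
    if sample_type == "street_food":
        vol = matrix.food_mass + matrix.food_diluent_volume
        return (vol / 100.0) / matrix.food_mass
    if sample_type == "soil":
        vol = (
            matrix.soil_mass * matrix.soil_water_fraction
            + matrix.soil_eluate_volume
        )
        return (vol / 100.0) / matrix.soil_mass
    raise ValueError(f"unknown sample_type {sample_type!r}")


def normalize_units(
    assay_conc: float, sample_type: str, matrix: MatrixMetadata
) -> Tuple[float, float, str]:
    """Rescale an assay-fluid concentration to matrix reporting units.

    Parameters
    ----------
    assay_conc
        MPN per 100 mL of undiluted assay fluid; must be positive.

    Returns
    -------
    (value, log10_value, unit) — ``log10_value`` may be negative (swab
    counts below one organism per swab occur in practice).
    """
    if assay_conc <= 0:
        raise ValueError("assay concentration must be positive")
    factor = reporting_unit_factor(sample_type, matrix)
    value = assay_conc * factor
    return value, math.log10(value), unit_for_sample_type(sample_type)


def process_sample(
    rec: SampleRecord,
    low: float = 0.5,
    high: float = 2419.6,
    averaging: str = "arithmetic",
) -> ConcentrationResult:
    """Estimate, aggregate and normalize one sample's dilution series."""
    estimates = [(d, mpn_mle(obs)) for d, obs in rec.trays]
    assay_conc, censoring, n_used, flags = combine_dilutions(
        estimates, low=low, high=high, averaging=averaging
    )
    value, log10_value, unit = normalize_units(
        assay_conc, rec.sample_type, rec.matrix
    )
    return ConcentrationResult(
        sample_id=rec.sample_id,
        sample_type=rec.sample_type,
        neighborhood=rec.neighborhood,
        category=rec.category,
        corporation=rec.corporation,
        value=value,
        log10_value=log10_value,
        unit=unit,
        censoring=censoring,
        n_trays_used=n_used,
        flags=flags,
    )


def process_dataset(
    records: Iterable[SampleRecord],
    low: float = 0.5,
    high: float = 2419.6,
    averaging: str = "arithmetic",
) -> pd.DataFrame:
    """Process every sample and tabulate one row per sample."""
    rows = []
    for rec in records:
        res = process_sample(rec, low=low, high=high, averaging=averaging)
        rows.append(
            {
                "sample_id": res.sample_id,
                "sample_type": res.sample_type,
                "neighborhood": res.neighborhood,
                "category": res.category,
                "corporation": res.corporation,
                "value": res.value,
                "log10_value": res.log10_value,
                "unit": res.unit,
                "censoring": res.censoring.value,
                "n_trays_used": res.n_trays_used,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)
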