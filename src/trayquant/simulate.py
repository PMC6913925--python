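"""Seeded synthetic studies with the sampling design's statistical structure.

Contamination is modeled per (sample type × stratum) as log10-normal:
the true log10 concentration of a sample, in its matrix reporting unit,
is drawn from Normal(mu, sigma).  The draw is converted back to an
assay-fluid concentration (inverting the unit normalization), the fluid
is serially diluted per the matrix's dilution scheme, and each tray well
turns positive independently with probability ``1 - exp(-(lam/D) * v)``
— the same Poisson-dilution model under which the MPN is the MLE.

The packaged default calibration carries the observed per-matrix means
and SDs of the 2017 Dhaka study (overall and per socio-economic
category), so a default simulated study reproduces the 10 neighborhoods
× 10 sample types × 10 samples design with realistic censoring rates.

Seeding: one study seed spawns per-sample child seeds through
``numpy.random.SeedSequence(study_seed).spawn``, so any subset of the
study is reproducible from the study seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_DILUTION_SCHEMES, SAMPLE_TYPES
from .mpn import QUANTI_TRAY_2000, TrayGeometry, TrayObservation
from .pipeline import MatrixMetadata, SampleRecord, reporting_unit_factor

__all__ = [
    "ContaminationProfile",
    "StudyDesign",
    "DEFAULT_NEIGHBORHOODS",
    "load_calibration",
    "default_profiles",
    "simulate_sample",
    "simulate_study",
]


@dataclass(frozen=True)
class ContaminationProfile:
    """Log10-normal contamination level for one sample type and stratum."""

    sample_type: str
    stratum: str  # "overall", a category, or a neighborhood name
    mu: float  # mean log10 concentration, reporting units
    sigma: float  # SD of log10 concentration

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


#: The ten study neighborhoods as (name, category, city corporation).
DEFAULT_NEIGHBORHOODS: Tuple[Tuple[str, str, str], ...] = (
    ("Gabtoli", "floating", "DNCC"),
    ("Kamalapur", "floating", "DSCC"),
    ("Kalshi", "low_income", "DNCC"),
    ("Shampur", "low_income", "DSCC"),
    ("Badda", "low_income", "DNCC"),
    ("Hazaribagh", "low_income", "DSCC"),
    ("Uttarkhan", "high_income", "DNCC"),
    ("Motijheel", "high_income", "DSCC"),
    ("Gulshan", "high_income", "DNCC"),
    ("Dhanmondi", "high_income", "DSCC"),
)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling frame: which cells exist and how many samples per cell."""

    neighborhoods: Tuple[Tuple[str, str, str], ...] = DEFAULT_NEIGHBORHOODS
    sample_types: Tuple[str, ...] = tuple(SAMPLE_TYPES)
    samples_per_cell: int = 10
    dilution_schemes: Dict[str, List[float]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_DILUTION_SCHEMES.items()
        }
    )

    def __post_init__(self) -> None:
        if self.samples_per_cell <= 0:
            raise ValueError("samples_per_cell must be positive")
        for st in self.sample_types:
            if st not in self.dilution_schemes:
                raise ValueError(f"no dilution scheme for {st!r}")

    @property
    def n_samples(self) -> int:
        return (
            len(self.neighborhoods)
            * len(self.sample_types)
            * self.samples_per_cell
        )


def load_calibration(path: Optional[str] = None) -> pd.DataFrame:
    """Load a calibration table (sample_type, stratum, mu, sigma).

    Without ``path``, the packaged default calibration is used.
    """
    if path is None:
        ref = resources.files("trayquant.data").joinpath("calibration.csv")
        with ref.open() as fh:
            return pd.read_csv(fh, comment="#")
    return pd.read_csv(path, comment="#")


def default_profiles(
    stratum: str = "overall", path: Optional[str] = None
) -> Dict[str, ContaminationProfile]:
    """Packaged profiles for one stratum, keyed by sample type."""
    cal = load_calibration(path)
    sub = cal[cal["stratum"] == stratum]
    if sub.empty:
        raise ValueError(f"no calibration rows for stratum {stratum!r}")
    return {
        row.sample_type: ContaminationProfile(
            sample_type=row.sample_type,
            stratum=stratum,
            mu=float(row.mu),
            sigma=float(row.sigma),
        )
        for row in sub.itertuples()
    }


def _simulate_trays(
    lam: float,
    scheme: Sequence[float],
    rng: np.random.Generator,
    geometry: TrayGeometry,
) -> Tuple[Tuple[float, TrayObservation], ...]:
    """Well outcomes for each dilution of assay fluid at ``lam`` per mL."""
    trays = []
    for d in scheme:
        rate = lam / d
        p_large = 1.0 - math.exp(-rate * geometry.v_large)
        p_small = 1.0 - math.exp(-rate * geometry.v_small)
        obs = TrayObservation(
            p_large=int(rng.binomial(geometry.n_large, p_large)),
            p_small=int(rng.binomial(geometry.n_small, p_small)),
            geometry=geometry,
        )
        trays.append((float(d), obs))
    return tuple(trays)


def simulate_sample(
    profile: ContaminationProfile,
    scheme: Sequence[float],
    seed: int | np.random.SeedSequence,
    matrix: Optional[MatrixMetadata] = None,
    geometry: TrayGeometry = QUANTI_TRAY_2000,
    sample_id: str = "sim-0",
    neighborhood: str = "synthetic",
    category: str = "low_income",
    corporation: str = "DNCC",
) -> SampleRecord:
    """Draw one synthetic sample and its tray well patterns.

    The true log10 concentration (reporting units) is Normal(mu, sigma);
    it is stored on the returned record as ``true_log10`` so recovery can
    be measured.  Two calls with the same seed yield identical records.
    """
    matrix = matrix if matrix is not None else MatrixMetadata()
    rng = np.random.default_rng(seed)
    true_log10 = float(rng.normal(profile.mu, profile.sigma))
    # invert unit normalization: reporting units -> per 100 mL assay fluid
    assay_conc = 10.0**true_log10 / reporting_unit_factor(
        profile.sample_type, matrix
    )
    lam = assay_conc / geometry.reference_volume  # per mL of assay fluid
    trays = _simulate_trays(lam, scheme, rng, geometry)
    return SampleRecord(
        sample_id=sample_id,
        sample_type=profile.sample_type,
        neighborhood=neighborhood,
        category=category,
        corporation=corporation,
        trays=trays,
        matrix=matrix,
        true_log10=true_log10,
    )


def simulate_study(
    design: Optional[StudyDesign] = None,
    calibration: Optional[pd.DataFrame] = None,
    seed: int = 0,
    geometry: TrayGeometry = QUANTI_TRAY_2000,
) -> List[SampleRecord]:
    """Simulate a full study; one record per design cell sample.

    Each cell's profile is looked up in ``calibration`` by the
    neighborhood name first, then the neighborhood's category, then
    ``"overall"`` — so a category-level calibration covers a
    neighborhood-level design.  A cell with no matching profile raises a
    ``ValueError`` naming the cell.
    """
    design = design if design is not None else StudyDesign()
    cal = calibration if calibration is not None else load_calibration()
    by_key = {
        (r.sample_type, r.stratum): (float(r.mu), float(r.sigma))
        for r in cal.itertuples()
    }

    root = np.random.SeedSequence(seed)
    children = root.spawn(design.n_samples)
    records: List[SampleRecord] = []
    i = 0
    for name, cat, corp in design.neighborhoods:
        for st in design.sample_types:
            key = next(
                (
                    k
                    for k in ((st, name), (st, cat), (st, "overall"))
                    if k in by_key
                ),
                None,
            )
            if key is None:
                raise ValueError(
                    f"no calibration profile for cell "
                    f"(sample_type={st!r}, neighborhood={name!r})"
                )
            mu, sigma = by_key[key]
            profile = ContaminationProfile(
                sample_type=st, stratum=key[1], mu=mu, sigma=sigma
            )
            for j in range(design.samples_per_cell):
                records.append(
                    simulate_sample(
                        profile,
                        design.dilution_schemes[st],
                        seed=children[i],
                        geometry=geometry,
                        sample_id=f"{name}-{st}-{j:03d}",
                        neighborhood=name,
                        category=cat,
                        corporation=corp,
                    )
                )
                i += 1
    return records
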