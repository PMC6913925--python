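"""Run configuration: every numeric constant of the workflow in one place.

The censoring substitution constants (0.5 below the detection limit,
2419.6 above it), the per-matrix serial-dilution schemes, the tray
geometry preset, and the matrix elution/homogenate volumes are all study
design choices, so they live here — not hard-coded in the estimation or
pipeline code — and are echoed (with a hash) into every output artifact
for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import yaml

from .mpn import QUANTI_TRAY_2000, TrayGeometry

__all__ = [
    "SAMPLE_TYPES",
    "WATER_TYPES",
    "CATEGORIES",
    "CORPORATIONS",
    "DEFAULT_DILUTION_SCHEMES",
    "GEOMETRY_PRESETS",
    "RunConfig",
]

#: The ten environmental sample types (matrices) of the study design.
SAMPLE_TYPES: List[str] = [
    "latrine_swab",
    "soil",
    "drain_water",
    "bathing_water",
    "municipal_water",
    "non_municipal_water",
    "surface_water",
    "produce",
    "street_food",
    "floodwater",
]

#: Matrices assayed directly as water and reported per 100 mL.
WATER_TYPES = frozenset(
    {
        "drain_water",
        "bathing_water",
        "municipal_water",
        "non_municipal_water",
        "surface_water",
        "floodwater",
    }
)

CATEGORIES = ("low_income", "high_income", "floating")
CORPORATIONS = ("DNCC", "DSCC")

#: Fold-dilutions of the assay fluid loaded per tray, by sample type:
#: drinking/bathing water undiluted + 1:10; surface and floodwater
#: 1:10^2..10^4; drain water 1:10^5 + 1:10^6; street-food homogenate
#: 1:10 + 1:10^2; soil eluate 1:10^2..10^4; swab eluate 1:10 + 1:10^3;
#: produce rinse 1:10..10^3.
DEFAULT_DILUTION_SCHEMES: Dict[str, List[float]] = {
    "municipal_water": [1.0, 10.0],
    "non_municipal_water": [1.0, 10.0],
    "bathing_water": [1.0, 10.0],
    "surface_water": [1e2, 1e3, 1e4],
    "floodwater": [1e2, 1e3, 1e4],
    "drain_water": [1e5, 1e6],
    "street_food": [10.0, 1e2],
    "soil": [1e2, 1e3, 1e4],
    "latrine_swab": [10.0, 1e3],
    "produce": [10.0, 1e2, 1e3],
}

GEOMETRY_PRESETS: Dict[str, TrayGeometry] = {
    "quanti_tray_2000": QUANTI_TRAY_2000,
}


@dataclass
class RunConfig:
    """Serializable configuration for a full run.

    Attributes
    ----------
    geometry_preset
        Key into :data:`GEOMETRY_PRESETS`.
    substitution_low, substitution_high
        MPN values substituted for non-detect / over-range trays
        (0.5 and 2419.6 per tray by default).
    dilution_schemes
        Dilution factors assayed per sample type.
    averaging
        ``"arithmetic"`` (default; used for table replication) or
        ``"geometric"`` — scale on which multi-dilution tray
        concentrations are averaged.
    ci_multiplier
        ``"normal"`` (1.96) or ``"t"`` (Student quantile) for group
        comparison intervals.
    """

    geometry_preset: str = "quanti_tray_2000"
    substitution_low: float = 0.5
    substitution_high: float = 2419.6
    dilution_schemes: Dict[str, List[float]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in DEFAULT_DILUTION_SCHEMES.items()
        }
    )
    averaging: str = "arithmetic"
    ci_multiplier: str = "normal"
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.substitution_low <= 0 or self.substitution_high <= 0:
            raise ValueError("substitution constants must be positive")
        if self.averaging not in ("arithmetic", "geometric"):
            raise ValueError("averaging must be 'arithmetic' or 'geometric'")
        if self.ci_multiplier not in ("normal", "t"):
            raise ValueError("ci_multiplier must be 'normal' or 't'")
        if self.geometry_preset not in GEOMETRY_PRESETS:
            raise ValueError(f"unknown geometry preset {self.geometry_preset!r}")
        for st, scheme in self.dilution_schemes.items():
            if not scheme:
                raise ValueError(f"empty dilution scheme for {st!r}")
            if len(set(scheme)) != len(scheme):
                raise ValueError(f"duplicate dilution factors for {st!r}")

    @property
    def geometry(self) -> TrayGeometry:
        return GEOMETRY_PRESETS[self.geometry_preset]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        """Short content hash used to stamp output artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
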