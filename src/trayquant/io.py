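"""Reading and writing the long (tidy) sample CSV schema.

Input schema — one row per tray (sample × dilution):

    sample_id, sample_type, neighborhood, category, corporation,
    dilution_factor, p_large, p_small
    [+ optional matrix columns: soil_mass, soil_eluate_volume,
       swab_eluate_volume, food_mass, food_diluent_volume,
       produce_rinse_volume, produce_weight, qc_flag]

Output artifacts are CSVs whose header comment lines embed the config
hash and seed so reruns are auditable.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import pandas as pd

from .config import RunConfig
from .mpn import TrayGeometry, TrayObservation, QUANTI_TRAY_2000
from .pipeline import MatrixMetadata, SampleRecord

__all__ = ["read_samples", "write_samples", "write_table", "read_stata_samples"]

_REQUIRED = [
    "sample_id",
    "sample_type",
    "neighborhood",
    "category",
    "corporation",
    "dilution_factor",
    "p_large",
    "p_small",
]

_MATRIX_FIELDS = [f.name for f in dataclasses.fields(MatrixMetadata)]


def _records_from_frame(
    df: pd.DataFrame, geometry: TrayGeometry
) -> List[SampleRecord]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["sample_id", "dilution_factor"])
    if dup.any():
        lines = [str(i + 2) for i in df.index[dup]]  # +2: header + 1-based
        raise ValueError(
            f"duplicate (sample_id, dilution_factor) at line(s) {', '.join(lines)}"
        )
    records: List[SampleRecord] = []
    errors: List[str] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        first = grp.iloc[0]
        trays = []
        for idx, row in grp.iterrows():
            try:
                obs = TrayObservation(
                    p_large=int(row["p_large"]),
                    p_small=int(row["p_small"]),
                    geometry=geometry,
                )
                trays.append((float(row["dilution_factor"]), obs))
            except (ValueError, TypeError) as exc:
                errors.append(f"line {idx + 2} (sample {sid!r}): {exc}")
        if errors:
            continue
        matrix_kwargs = {
            k: first[k]
            for k in _MATRIX_FIELDS
            if k in grp.columns and pd.notna(first[k])
        }
        try:
            records.append(
                SampleRecord(
                    sample_id=str(sid),
                    sample_type=str(first["sample_type"]),
                    neighborhood=str(first["neighborhood"]),
                    category=str(first["category"]),
                    corporation=str(first["corporation"]),
                    trays=tuple(trays),
                    matrix=MatrixMetadata(**matrix_kwargs),
                    qc_flag=str(first.get("qc_flag", "pass")),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"sample {sid!r}: {exc}")
    if errors:
        raise ValueError("malformed input:\n  " + "\n  ".join(errors))
    return records


def read_samples(
    path: str, geometry: TrayGeometry = QUANTI_TRAY_2000
) -> List[SampleRecord]:
    """Parse a long-format tray CSV into validated sample records.

    Malformed rows are reported together with their (1-based, header
    included) line numbers.
    """
    df = pd.read_csv(path, comment="#")
    return _records_from_frame(df, geometry)


def read_stata_samples(
    path: str,
    column_map: Dict[str, str],
    geometry: TrayGeometry = QUANTI_TRAY_2000,
) -> List[SampleRecord]:
    """Ingest a Stata (.dta) dataset via a column-mapping dict.

    ``column_map`` maps the schema names (``sample_id`` … ``p_small``,
    optional matrix columns) to the Stata file's variable names.
    """
    raw = pd.read_stata(path)
    rename = {v: k for k, v in column_map.items()}
    df = raw.rename(columns=rename)
    return _records_from_frame(df, geometry)


def write_samples(records: List[SampleRecord], path: str) -> None:
    """Write records back out in the long input schema (lossless)."""
    rows = []
    for rec in records:
        for d, obs in rec.trays:
            row = {
                "sample_id": rec.sample_id,
                "sample_type": rec.sample_type,
                "neighborhood": rec.neighborhood,
                "category": rec.category,
                "corporation": rec.corporation,
                "dilution_factor": d,
                "p_large": obs.p_large,
                "p_small": obs.p_small,
                "qc_flag": rec.qc_flag,
            }
            row.update(
                {k: getattr(rec.matrix, k) for k in _MATRIX_FIELDS}
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table(
    df: pd.DataFrame, path: str, config: Optional[RunConfig] = None
) -> None:
    """Write an output table with a provenance comment header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()}\n")
            fh.write(f"# seed={config.seed}\n")
        df.to_csv(fh, index=False)
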