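"""Per-sample metadata: fraction labels, pairing, covariates and assays.

Each bronchoalveolar-lavage aliquot appears once per sorted fraction
(``raw``, ``igg_bound`` or ``igg_unbound``); aliquots of one participant
share a ``pair_id``.  Optional columns carry participant covariates (sex,
age, pack-years), Luminex cytokine concentrations (pg/mL, columns named
``cytokine_<name>``), 16S qPCR copy numbers and flow-cytometry
double-positive event counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "FRACTIONS",
    "SampleMetadata",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
]

FRACTIONS = ("raw", "igg_bound", "igg_unbound")
_REQUIRED = ("sample_id", "fraction", "pair_id", "group")
_OPTIONAL_NUMERIC = ("age", "pack_years", "qpcr_copies", "flow_events")
_NA = ""


@dataclass
class SampleMetadata:
    """One sequenced aliquot and its participant-level covariates."""

    sample_id: str
    fraction: str
    pair_id: str
    group: str
    sex: str | None = None
    age: float | None = None
    pack_years: float | None = None
    cytokines: dict[str, float] = field(default_factory=dict)
    qpcr_copies: float | None = None
    flow_events: float | None = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown fraction {self.fraction!r}; "
                f"expected one of {FRACTIONS}"
            )
        if self.age is not None and self.age < 0:
            raise ValidationError(f"sample {self.sample_id!r}: age must be >= 0")
        for name, value in self.cytokines.items():
            if value is not None and value < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: cytokine {name!r} must be >= 0"
                )


def _validate_records(records: list[SampleMetadata]) -> list[SampleMetadata]:
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, str]] = set()
    for rec in records:
        if rec.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample id {rec.sample_id!r}")
        seen_ids.add(rec.sample_id)
        key = (rec.pair_id, rec.fraction)
        if key in seen_pairs:
            raise ValidationError(
                f"pair {rec.pair_id!r} has more than one {rec.fraction!r} sample"
            )
        seen_pairs.add(key)
    return records


def _parse_float(cell: str, where: str) -> float | None:
    if cell == _NA or cell.upper() == "NA":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"non-numeric value {cell!r} for {where}") from None


def read_metadata(path) -> list[SampleMetadata]:
    """Read and validate a sample-metadata TSV.

    Optional columns may be missing wholesale; blanks or ``NA`` inside a
    present column are treated as missing values.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    cytokine_cols = [c for c in df.columns if c.startswith("cytokine_")]
    records: list[SampleMetadata] = []
    for _, row in df.iterrows():
        sid = row["sample_id"]
        kwargs: dict = {}
        for col in _OPTIONAL_NUMERIC:
            if col in df.columns:
                kwargs[col] = _parse_float(row[col], f"{col} of sample {sid!r}")
        if "sex" in df.columns:
            kwargs["sex"] = None if row["sex"] in (_NA, "NA") else row["sex"]
        cytokines = {}
        for col in cytokine_cols:
            value = _parse_float(row[col], f"{col} of sample {sid!r}")
            if value is not None:
                cytokines[col.removeprefix("cytokine_")] = value
        records.append(
            SampleMetadata(
                sample_id=sid,
                fraction=row["fraction"],
                pair_id=row["pair_id"],
                group=row["group"],
                cytokines=cytokines,
                **kwargs,
            )
        )
    return _validate_records(records)


def write_metadata(records: list[SampleMetadata], path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", index=True, na_rep="NA")


def metadata_frame(records: list[SampleMetadata]) -> pd.DataFrame:
    """Flatten records to a DataFrame indexed by sample_id."""
    cytokine_names = sorted({name for r in records for name in r.cytokines})
    rows = []
    for r in records:
        row = {
            "fraction": r.fraction,
            "pair_id": r.pair_id,
            "group": r.group,
            "sex": r.sex,
            "age": r.age,
            "pack_years": r.pack_years,
            "qpcr_copies": r.qpcr_copies,
            "flow_events": r.flow_events,
        }
        for name in cytokine_names:
            row[f"cytokine_{name}"] = r.cytokines.get(name, math.nan)
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index([r.sample_id for r in records], name="sample_id"))
    return df
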