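"""Taxa-by-sample count tables and relative-abundance profiles.

The on-disk format is plain TSV (UTF-8, header row): the first column holds
taxon names, the remaining columns one sample each, cells are non-negative
integer read counts.  In memory a :class:`TaxaCountTable` wraps a pandas
DataFrame (taxa as rows, samples as columns); a :class:`TaxaProfile` is a
relative-abundance vector over a taxon set, summing to one unless the sample
is empty (the all-zero sentinel used for zero-read samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "TaxaProfile",
    "TaxaCountTable",
    "read_count_table",
    "write_count_table",
    "to_profile",
    "relative_abundance",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class TaxaProfile:
    """Relative-abundance vector over an ordered taxon set.

    Abundances are dimensionless fractions in [0, 1] summing to one, or all
    zero for the empty-sample sentinel.
    """

    series: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        s = self.series
        if not s.index.is_unique:
            dup = s.index[s.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxa in profile: {dup}")
        vals = s.to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("profile abundances must be finite and non-negative")
        total = vals.sum()
        if total != 0.0 and abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(f"profile must sum to 1 (got {total!r}) or be all zero")
        object.__setattr__(self, "series", s.astype(float))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_counts(cls, counts) -> "TaxaProfile":
        """Normalise raw counts (mapping or Series) to a profile.

        An all-zero vector yields the empty-sample sentinel.
        """
        s = pd.Series(counts, dtype=float)
        total = s.sum()
        if total > 0:
            s = s / total
        return cls(s)

    @classmethod
    def from_dict(cls, mapping) -> "TaxaProfile":
        return cls(pd.Series(mapping, dtype=float))

    # -- views -------------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.series.index)

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy(dtype=float)

    @property
    def is_empty(self) -> bool:
        return bool(self.series.sum() == 0.0)

    def support(self) -> pd.Index:
        """Taxa with strictly positive abundance."""
        return self.series.index[self.series.to_numpy() > 0]

    def get(self, taxon: str) -> float:
        return float(self.series.get(taxon, 0.0))

    def allclose(self, other: "TaxaProfile", atol: float = 1e-12) -> bool:
        a, b = self.series.align(other.series, fill_value=0.0)
        return bool(np.allclose(a.to_numpy(), b.to_numpy(), atol=atol))

    def __len__(self) -> int:
        return len(self.series)


@dataclass(eq=False)
class TaxaCountTable:
    """Integer read counts, taxa (rows) by samples (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon names: {dup}")
        if not df.columns.is_unique:
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        arr = df.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integers")
        if arr.size and np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = df.astype(np.int64)
        self.counts.index.name = "taxon"

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def depth(self, sample: str) -> int:
        if sample not in self.counts.columns:
            raise ValidationError(f"unknown sample id: {sample!r}")
        return int(self.counts[sample].sum())

    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(int)

    def profile(self, sample: str) -> TaxaProfile:
        return to_profile(self, sample)

    def subset_samples(self, samples) -> "TaxaCountTable":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return TaxaCountTable(self.counts[list(samples)].copy())


def to_profile(table: TaxaCountTable, sample: str) -> TaxaProfile:
    """Relative abundances count/depth for one sample.

    A zero-read column yields the all-zero sentinel profile.
    """
    if sample not in table.counts.columns:
        raise ValidationError(f"unknown sample id: {sample!r}")
    return TaxaProfile.from_counts(table.counts[sample])


def relative_abundance(table: TaxaCountTable) -> pd.DataFrame:
    """Taxa-by-sample relative abundances; zero-read columns stay all-zero."""
    depths = table.depths().to_numpy(dtype=float)
    safe = np.where(depths > 0, depths, 1.0)
    return table.counts.astype(float).div(safe, axis=1)


def _reject_reserved(name: str, what: str) -> None:
    if "\t" in name or "\n" in name:
        raise ValidationError(f"{what} {name!r} contains a reserved delimiter character")


def read_count_table(path) -> TaxaCountTable:
    """Read a TSV count table; errors name the offending row/column."""
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    data = np.zeros((raw.shape[0], raw.shape[1]), dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, (taxon, cell) in enumerate(raw[col].items()):
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer count {cell!r} at taxon {taxon!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}: negative count {value} at taxon {taxon!r}, sample {col!r}"
                )
            data[i, j] = value
    parsed = pd.DataFrame(data, index=raw.index, columns=raw.columns)
    return TaxaCountTable(parsed)


def write_count_table(table: TaxaCountTable, path) -> None:
    """Write TSV so that a re-read reproduces the table bit-identically."""
    for taxon in table.taxa:
        _reject_reserved(str(taxon), "taxon name")
    for sample in table.samples:
        _reject_reserved(str(sample), "sample id")
    out = table.counts.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")
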