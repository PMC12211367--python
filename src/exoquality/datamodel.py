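"""Core data model for replicated multi-assay EV characterization studies.

The study design is fully crossed: biological samples x isolation methods x
characterization assays x technical replicates, one numeric value per cell.
Everything downstream (quantile transformation, EVI, EQI) consumes the
long-format table held by :class:`StudyDataset`.
"""

from __future__ import annotations

import dataclasses
import numbers
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Assay labels recognized for reporting.  The vocabulary is open: any label
#: is accepted, but these five form the canonical MISEV-style characterization
#: panel (size, yield, protein, RNA, dispersity).
CANONICAL_ASSAYS: tuple[str, ...] = (
    "size_mean_nm",
    "particle_concentration_per_mL",
    "protein_total",
    "rna_total",
    "pdi",
)

RECORD_COLUMNS: tuple[str, ...] = (
    "sample_id", "group", "method", "assay", "replicate", "value",
)
KEY_COLUMNS: tuple[str, ...] = ("sample_id", "method", "assay", "replicate")


class ExoQualityError(Exception):
    """Base class for all package errors."""


class SchemaError(ExoQualityError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(ExoQualityError):
    """A value or record violates a data-model invariant."""


class DegenerateProfileError(ExoQualityError):
    """A size profile has zero spread, so PDI = max/sd is undefined."""


class UndefinedEVIError(ExoQualityError):
    """No assay in a (method, sample) cell has >= 2 replicates."""


class ConfigError(ExoQualityError):
    """An option or simulation configuration is invalid."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One replicate-level observation of one assay under one isolation method.

    Parameters
    ----------
    sample_id
        Opaque sample identifier.
    group
        Categorical sample label, e.g. ``"tumor"`` or ``"healthy"``.
    method
        Isolation-method label (categorical).
    assay
        Measurement label; see :data:`CANONICAL_ASSAYS` for the recognized
        panel.  Other labels are allowed.
    replicate
        1-based replicate index.  Indices need not be consecutive; only
        their multiplicity matters.
    value
        Finite, non-negative measurement (all five canonical assays are
        magnitudes).
    """

    sample_id: str
    group: str
    method: str
    assay: str
    replicate: int
    value: float

    def __post_init__(self) -> None:
        if not isinstance(self.replicate, numbers.Integral) or self.replicate < 1:
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate!r}"
            )
        if not isinstance(self.value, numbers.Real) or not np.isfinite(self.value):
            raise ValidationError(f"value must be finite, got {self.value!r}")
        if self.value < 0:
            raise ValidationError(f"value must be non-negative, got {self.value!r}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.sample_id, self.method, self.assay, int(self.replicate))


def _as_frame(records: pd.DataFrame | Iterable[MeasurementRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


class StudyDataset:
    """A validated crossed study: samples x methods x assays x replicates.

    The constructor canonicalizes row order (sorted by sample, method,
    assay, replicate), so two datasets built from the same records in any
    order compare equal.
    """

    def __init__(self, records: pd.DataFrame | Iterable[MeasurementRecord]):
        df = _as_frame(records)
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise ValidationError("a StudyDataset must contain at least one record")

        df = df.loc[:, list(RECORD_COLUMNS)]
        for col in ("sample_id", "group", "method", "assay"):
            df[col] = df[col].astype(str)

        rep = pd.to_numeric(df["replicate"], errors="coerce")
        if rep.isna().any() or (rep != rep.round()).any() or (rep < 1).any():
            bad = df.loc[rep.isna() | (rep != rep.round()) | (rep < 1)]
            raise ValidationError(
                f"replicate must be a positive integer; offending rows: "
                f"{bad.index.tolist()[:5]}"
            )
        df["replicate"] = rep.astype(int)

        val = pd.to_numeric(df["value"], errors="coerce")
        if not np.isfinite(val.to_numpy(dtype=float)).all():
            bad = df.index[~np.isfinite(val.to_numpy(dtype=float))].tolist()
            raise ValidationError(f"non-finite value(s) at rows {bad[:5]}")
        if (val < 0).any():
            bad = df.index[(val < 0)].tolist()
            raise ValidationError(f"negative value(s) at rows {bad[:5]}")
        df["value"] = val.astype(float)

        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            keys = (
                df.loc[dup, list(KEY_COLUMNS)]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise ValidationError(
                "duplicate (sample_id, method, assay, replicate) key(s): "
                + "; ".join(map(str, list(keys)[:5]))
            )

        groups = df.groupby("sample_id")["group"].nunique()
        if (groups > 1).any():
            raise ValidationError(
                f"sample(s) with inconsistent group labels: "
                f"{groups.index[groups > 1].tolist()}"
            )

        df = df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)
        self._df = df

    # -- accessors ---------------------------------------------------------

    @property
    def records(self) -> pd.DataFrame:
        """The canonical long-format table (a copy)."""
        return self._df.copy()

    @property
    def assays(self) -> tuple[str, ...]:
        """Assay labels, canonical panel first, extras sorted after."""
        present = set(self._df["assay"])
        head = [a for a in CANONICAL_ASSAYS if a in present]
        tail = sorted(present - set(CANONICAL_ASSAYS))
        return tuple(head + tail)

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(sorted(self._df["method"].unique()))

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted(self._df["sample_id"].unique()))

    @property
    def groups(self) -> Mapping[str, str]:
        """Map sample_id -> group label."""
        return dict(
            self._df.drop_duplicates("sample_id")[["sample_id", "group"]]
            .itertuples(index=False, name=None)
        )

    @property
    def nonstandard_assays(self) -> tuple[str, ...]:
        return tuple(a for a in self.assays if a not in CANONICAL_ASSAYS)

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"StudyDataset({len(self)} records: {len(self.samples)} samples x "
            f"{len(self.methods)} methods x {len(self.assays)} assays)"
        )

    def iter_records(self) -> Iterable[MeasurementRecord]:
        for row in self._df.itertuples(index=False):
            yield MeasurementRecord(
                row.sample_id, row.group, row.method, row.assay,
                int(row.replicate), float(row.value),
            )

    def merged_with(self, other: "StudyDataset") -> "StudyDataset":
        """Union of two datasets; raises on key collision."""
        return StudyDataset(pd.concat([self._df, other._df], ignore_index=True))


@dataclass(frozen=True)
class NTAProfile:
    """A particle size distribution for one (sample, method, replicate).

    Exactly one representation is set: per-particle ``sizes`` (nm), or
    binned ``bin_sizes`` / ``bin_concentrations`` (bin centers in nm with a
    non-negative concentration per bin, at least one strictly positive).
    """

    sample_id: str
    method: str
    replicate: int
    sizes: np.ndarray | None = None
    bin_sizes: np.ndarray | None = None
    bin_concentrations: np.ndarray | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")
        binned = self.bin_sizes is not None or self.bin_concentrations is not None
        if (self.sizes is None) == (not binned):
            raise ValidationError(
                "exactly one of per-particle sizes or binned representation "
                "must be provided"
            )
        if self.sizes is not None:
            s = np.asarray(self.sizes, dtype=float)
            if s.size == 0:
                raise ValidationError("empty size profile")
            if not np.isfinite(s).all() or (s <= 0).any():
                raise ValidationError("sizes must be strictly positive and finite")
            object.__setattr__(self, "sizes", s)
        else:
            b = np.asarray(self.bin_sizes, dtype=float)
            c = np.asarray(self.bin_concentrations, dtype=float)
            if b.size == 0 or b.shape != c.shape:
                raise ValidationError(
                    "binned profile needs equal-length, non-empty size and "
                    "concentration vectors"
                )
            if not np.isfinite(b).all() or (b <= 0).any():
                raise ValidationError("bin sizes must be strictly positive and finite")
            if not np.isfinite(c).all() or (c < 0).any():
                raise ValidationError("concentrations must be finite and >= 0")
            if not (c > 0).any():
                raise ValidationError(
                    "binned profile must have at least one positive concentration"
                )
            object.__setattr__(self, "bin_sizes", b)
            object.__setattr__(self, "bin_concentrations", c)

    @property
    def is_binned(self) -> bool:
        return self.sizes is None

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.sample_id, self.method, int(self.replicate))


def warn(message: str) -> None:
    """Single funnel for data-quality warnings."""
    warnings.warn(message, UserWarning, stacklevel=3)
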