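"""Reading and writing the long-format measurement CSV and NTA profile CSVs.

Schemas
-------
measurements.csv
    ``sample_id, group, method, assay, replicate, value`` — one row per
    replicate-level observation.
nta_binned.csv
    ``sample_id, method, replicate, size_nm, concentration`` — one row per
    size bin.
nta_particles.csv
    ``sample_id, method, replicate, size_nm`` — one row per tracked particle.

All files are UTF-8, comma-separated with a '.' decimal point and a
mandatory header.  ``read_measurements`` accepts a ``column_map`` so that
differently named exports (e.g. spreadsheet dumps of a deposited dataset)
can be read without editing the file.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CANONICAL_ASSAYS,
    KEY_COLUMNS,
    RECORD_COLUMNS,
    NTAProfile,
    SchemaError,
    StudyDataset,
    ValidationError,
    warn,
)


def read_measurements(
    path: str | os.PathLike,
    *,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> StudyDataset:
    """Read a long-format measurement CSV into a validated StudyDataset.

    Parameters
    ----------
    path
        CSV file with a header row and the six required columns.
    sep
        Field separator (default comma).
    column_map
        Optional mapping ``{required_name: name_in_file}`` for files whose
        headers differ from the canonical schema.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    ValidationError
        For non-numeric/non-finite values or duplicate keys; row-level
        errors report the 1-based file line number (header = line 1).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    df = df.loc[:, list(RECORD_COLUMNS)]

    def _parse(s: str) -> float:
        try:
            return float(s)
        except ValueError:
            return float("nan")

    # python float() is correctly rounded, so repr-precision CSVs round-trip
    values = np.array([_parse(s) for s in df["value"]], dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 zero-based
        raise ValidationError(
            f"{path}: non-numeric or non-finite 'value' at line(s) {lines[:10]}"
        )
    reps = pd.to_numeric(df["replicate"], errors="coerce")
    badr = reps.isna() | (reps != reps.round()) | (reps < 1)
    if badr.any():
        lines = (df.index[badr] + 2).tolist()
        raise ValidationError(
            f"{path}: 'replicate' must be a positive integer at line(s) {lines[:10]}"
        )

    df["value"] = values
    df["replicate"] = reps.astype(int)
    dataset = StudyDataset(df)
    if dataset.nonstandard_assays:
        warn(
            f"{path}: assay label(s) outside the canonical panel kept as-is: "
            f"{', '.join(dataset.nonstandard_assays)}"
        )
    return dataset


def write_dataset(dataset: StudyDataset, path: str | os.PathLike) -> None:
    """Write a StudyDataset to CSV so that ``read_measurements`` round-trips it.

    Values are written with full ``repr`` precision, so the write -> read
    cycle is the identity at full numeric precision.
    """
    df = dataset.records
    df.to_csv(path, index=False)


_NTA_KEYS = ("sample_id", "method", "replicate")


def read_nta_profiles(path: str | os.PathLike, *, sep: str = ",") -> list[NTAProfile]:
    """Read NTA size profiles from a binned or per-particle CSV.

    The layout is detected from the header: a ``concentration`` column means
    binned bins, otherwise one row per tracked particle.  Returns one
    :class:`NTAProfile` per (sample_id, method, replicate) key, in sorted
    key order.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (*_NTA_KEYS, "size_nm") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    binned = "concentration" in df.columns
    if len(df) == 0:
        raise ValidationError(f"{path}: empty profile file")

    has_group = "group" in df.columns
    profiles: list[NTAProfile] = []
    df = df.sort_values(list(_NTA_KEYS) + ["size_nm"], kind="mergesort")
    for (sample_id, method, replicate), sub in df.groupby(list(_NTA_KEYS), sort=True):
        group = str(sub["group"].iloc[0]) if has_group else ""
        try:
            if binned:
                profiles.append(
                    NTAProfile(
                        sample_id=str(sample_id),
                        method=str(method),
                        replicate=int(replicate),
                        bin_sizes=sub["size_nm"].to_numpy(dtype=float),
                        bin_concentrations=sub["concentration"].to_numpy(dtype=float),
                        group=group,
                    )
                )
            else:
                profiles.append(
                    NTAProfile(
                        sample_id=str(sample_id),
                        method=str(method),
                        replicate=int(replicate),
                        sizes=sub["size_nm"].to_numpy(dtype=float),
                        group=group,
                    )
                )
        except ValidationError as exc:
            raise ValidationError(
                f"{path}: profile ({sample_id}, {method}, {replicate}): {exc}"
            ) from exc
    return profiles


def write_nta_profiles(
    profiles: Sequence[NTAProfile], path: str | os.PathLike
) -> None:
    """Write per-particle or binned profiles back to their CSV layout."""
    if not profiles:
        raise ValidationError("nothing to write: empty profile collection")
    binned = profiles[0].is_binned
    if any(p.is_binned != binned for p in profiles):
        raise ValidationError("cannot mix binned and per-particle profiles in one file")
    rows = []
    for p in profiles:
        if binned:
            for s, c in zip(p.bin_sizes, p.bin_concentrations):
                rows.append((p.sample_id, p.method, p.replicate, s, c))
        else:
            for s in p.sizes:
                rows.append((p.sample_id, p.method, p.replicate, s))
    cols = list(_NTA_KEYS) + (["size_nm", "concentration"] if binned else ["size_nm"])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
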