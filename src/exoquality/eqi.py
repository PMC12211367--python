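"""EV Inconsistency value (EVI) and ExoQuality Index (EQI).

For one isolation method and one sample, each assay's quantile-transformed
replicate values have an across-replicate standard deviation; the EVI for
that (method, sample) cell aggregates those per-assay standard deviations
across the n assays.  Because the values live on the equal-likelihood
(0, 1) scale, an EVI of 0.2 reads as: the isolate is expected to differ by
about 20% of the pooled distribution on re-isolation.

The per-method ExoQuality Index is

    EQI = 1 - mean over samples of EVI,

reported as a percentage: the expected likelihood of re-isolating a
consistent EV population with that method.

Aggregation across assays defaults to the MEAN of per-assay standard
deviations, which keeps EVI in [0, ~0.58] for 4 replicates and EQI on the
percentage scale of its interpretation; the literal SUM over assays is
available via ``aggregation="sum"`` for comparison.  The replicate standard
deviation defaults to the sample (n-1) estimator — the small-sample
convention for 4 replicates — with the population form behind
``sd_mode="population"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ConfigError, UndefinedEVIError, warn
from .transform import TransformedDataset

AGGREGATIONS = ("mean", "sum")
SD_MODES = ("sample", "population")


@dataclass
class EVIMatrix:
    """EVI per (method, sample): the content of the inconsistency heatmap.

    ``table`` has columns ``method, sample_id, evi, n_assays`` in sorted
    key order; ``n_assays`` is the number of assays that contributed (cells
    with fewer than 2 replicates are dropped, reducing n for that cell).
    """

    table: pd.DataFrame
    aggregation: str
    sd_mode: str

    def to_wide(self) -> pd.DataFrame:
        """Pivot to methods x samples, the layout of the heatmap."""
        return self.table.pivot(index="method", columns="sample_id", values="evi")


@dataclass
class EQIResult:
    """Per-method ExoQuality Index with its averaging provenance.

    ``table`` columns: ``method, mean_evi, eqi, eqi_percent, n_samples``.
    ``eqi = 1 - mean_evi`` exactly; ``eqi_percent`` is rounded to 2
    decimals for reporting.
    """

    table: pd.DataFrame
    aggregation: str
    sd_mode: str

    def eqi_percent(self, method: str) -> float:
        row = self.table.loc[self.table["method"] == method]
        if row.empty:
            raise KeyError(f"no EQI for method {method!r}")
        return float(row["eqi_percent"].iloc[0])


def _check_settings(aggregation: str, sd_mode: str) -> int:
    if aggregation not in AGGREGATIONS:
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    if sd_mode not in SD_MODES:
        raise ConfigError(f"unknown sd_mode {sd_mode!r}")
    return 1 if sd_mode == "sample" else 0


def compute_evi(
    transformed: TransformedDataset,
    method: str,
    sample: str,
    *,
    aggregation: str = "mean",
    sd_mode: str = "sample",
) -> float:
    """EVI of one (method, sample) cell.

    Per assay, the standard deviation of that cell's transformed replicate
    values is computed; assays with fewer than 2 replicates are dropped
    with a warning and the assay count reduced.  The per-assay standard
    deviations are then aggregated by ``aggregation`` (mean or sum).

    Raises
    ------
    UndefinedEVIError
        If no assay in the cell has at least 2 replicates.
    """
    ddof = _check_settings(aggregation, sd_mode)
    df = transformed.records
    cell = df[(df["method"] == method) & (df["sample_id"] == sample)]
    sds = []
    dropped = []
    for assay, sub in cell.groupby("assay", sort=True):
        vals = sub["value"].to_numpy()
        if vals.size < 2:
            dropped.append(assay)
            continue
        sds.append(float(np.std(vals, ddof=ddof)))
    if dropped:
        warn(
            f"cell ({method}, {sample}): assay(s) with < 2 replicates "
            f"dropped from EVI: {', '.join(dropped)}"
        )
    if not sds:
        raise UndefinedEVIError(
            f"cell ({method}, {sample}): no assay has >= 2 replicates"
        )
    return float(np.mean(sds)) if aggregation == "mean" else float(np.sum(sds))


def evi_matrix(
    transformed: TransformedDataset,
    *,
    aggregation: str = "mean",
    sd_mode: str = "sample",
) -> EVIMatrix:
    """EVI for every (method, sample) cell with a computable value.

    Deterministic given input and settings: cells are processed in sorted
    (method, sample) order and each cell goes through the same per-assay
    path as :func:`compute_evi`.
    """
    ddof = _check_settings(aggregation, sd_mode)
    df = transformed.records
    g = df.groupby(["method", "sample_id", "assay"], sort=True)["value"]
    counts = g.size()
    sds = g.apply(lambda v: float(np.std(v.to_numpy(), ddof=ddof)))
    keep = counts >= 2
    if (~keep).any():
        n_drop = int((~keep).sum())
        warn(f"{n_drop} (method, sample, assay) cell(s) with < 2 replicates dropped")
    sds = sds[keep]
    per_cell = sds.groupby(level=["method", "sample_id"]).agg(
        [aggregation, "size"]
    )
    per_cell.columns = ["evi", "n_assays"]
    table = per_cell.reset_index()
    table["n_assays"] = table["n_assays"].astype(int)
    table = table[["method", "sample_id", "evi", "n_assays"]]
    return EVIMatrix(table=table, aggregation=aggregation, sd_mode=sd_mode)


def compute_eqi(matrix: EVIMatrix) -> EQIResult:
    """Per-method EQI: 1 minus the mean EVI over that method's samples.

    Methods without any computable EVI entry are excluded with a warning.
    EQI is reported both as a fraction (``eqi``) and as a percentage
    rounded to 2 decimals (``eqi_percent``).
    """
    if matrix.table.empty:
        raise UndefinedEVIError("EVI matrix has no entries")
    per_method = (
        matrix.table.groupby("method", sort=True)["evi"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_evi", "size": "n_samples"})
    )
    per_method["eqi"] = 1.0 - per_method["mean_evi"]
    per_method["eqi_percent"] = (100.0 * per_method["eqi"]).round(2)
    per_method["n_samples"] = per_method["n_samples"].astype(int)
    table = per_method[["method", "mean_evi", "eqi", "eqi_percent", "n_samples"]]
    return EQIResult(
        table=table, aggregation=matrix.aggregation, sd_mode=matrix.sd_mode
    )
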