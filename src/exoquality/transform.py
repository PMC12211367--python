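"""Rank-based quantile transformation onto a common (0, 1) scale.

Each assay's measurements — pooled across methods, samples and replicates —
are mapped through their own empirical CDF onto an equal-likelihood uniform
scale.  After this probabilistic rescaling a difference of 0.1 means the
same thing for a size in nm as for an RNA yield in ng: one tenth of the
pooled distribution.  This is what makes across-replicate spread comparable
between assays, and hence what the inconsistency index is built on.

The plotting position is the mid-rank ``(r - 0.5) / N`` with averaged ranks
for ties, so outputs lie strictly inside (0, 1), ties map together, and the
map is monotone in the raw value.  A Weibull position ``r / (N + 1)`` is
available for sensitivity analysis.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ConfigError, StudyDataset, ValidationError

RANK_CONVENTIONS = ("midrank", "weibull")
SCOPES = ("all", "per-group", "per-method")


@dataclass
class EmpiricalQuantileMap:
    """Empirical-CDF map fitted on a reference set of values.

    On the reference values the map returns their (tie-averaged) plotting
    positions exactly and is idempotent in the sense that refitting on the
    transformed values reproduces them.  Out-of-reference queries
    interpolate linearly between reference positions and are clamped to
    the open interval spanned by the plotting positions, so no query ever
    maps to exactly 0 or 1.
    """

    rank_convention: str = "midrank"
    reference_values: np.ndarray = field(default=None, repr=False)
    reference_positions: np.ndarray = field(default=None, repr=False)
    _bounds: tuple[float, float] = field(default=None, repr=False)

    def fit(self, values: Iterable[float]) -> "EmpiricalQuantileMap":
        v = np.asarray(list(values) if not hasattr(values, "__array__") else values,
                       dtype=float)
        if v.size == 0:
            raise ValidationError("cannot fit a quantile map on empty input")
        if not np.isfinite(v).all():
            raise ValidationError("cannot fit a quantile map on non-finite input")
        n = v.size
        ranks = rankdata(v, method="average")
        if self.rank_convention == "midrank":
            pos = (ranks - 0.5) / n
            lo, hi = 0.5 / n, 1.0 - 0.5 / n
        elif self.rank_convention == "weibull":
            pos = ranks / (n + 1.0)
            lo, hi = 1.0 / (n + 1.0), n / (n + 1.0)
        else:
            raise ConfigError(f"unknown rank convention {self.rank_convention!r}")
        # ties share one averaged rank, so the position at the first
        # occurrence of each distinct value is the shared position
        uniq, first = np.unique(v, return_index=True)
        self.reference_values = uniq
        self.reference_positions = pos[first]
        self._bounds = (lo, hi)
        return self

    def __call__(self, x: Iterable[float] | float) -> np.ndarray | float:
        if self.reference_values is None:
            raise ValidationError("quantile map is not fitted")
        scalar = np.isscalar(x)
        xv = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.interp(xv, self.reference_values, self.reference_positions)
        lo, hi = self._bounds
        out = np.clip(out, lo, hi)
        return float(out[0]) if scalar else out


def fit_ecdf(
    values: Iterable[float], rank_convention: str = "midrank"
) -> EmpiricalQuantileMap:
    """Fit an empirical-CDF quantile map on a set of finite values."""
    return EmpiricalQuantileMap(rank_convention=rank_convention).fit(values)


@dataclass
class TransformedDataset:
    """A StudyDataset with every assay mapped onto its (0, 1) uniform scale.

    ``records`` keeps the original keys, the raw value and the transformed
    ``value``; ``maps`` holds the fitted per-assay (per scope-cell)
    quantile maps, so raw values remain recoverable and held-out data can
    be pushed through the same transform.
    """

    records: pd.DataFrame
    maps: dict[tuple, EmpiricalQuantileMap]
    scope: str
    rank_convention: str

    def as_dataset(self) -> StudyDataset:
        """Re-wrap the transformed values as a StudyDataset."""
        df = self.records[
            ["sample_id", "group", "method", "assay", "replicate", "value"]
        ]
        return StudyDataset(df)

    def to_frame(self) -> pd.DataFrame:
        """Export with an explicit ``transformed_value`` column."""
        df = self.records.rename(columns={"value": "transformed_value"})
        return df[
            ["sample_id", "group", "method", "assay", "replicate",
             "raw_value", "transformed_value"]
        ]


def transform_dataset(
    dataset: StudyDataset,
    *,
    scope: str = "all",
    rank_convention: str = "midrank",
) -> TransformedDataset:
    """Quantile-transform every assay of a study onto the (0, 1) scale.

    Parameters
    ----------
    dataset
        The raw study.
    scope
        Pooling scope for fitting each assay's reference distribution:
        ``"all"`` (default) pools every method, sample and replicate of the
        assay — the setting under which methods are directly comparable;
        ``"per-group"`` and ``"per-method"`` fit separate maps within each
        group or method for sensitivity analysis.
    rank_convention
        ``"midrank"`` or ``"weibull"`` plotting positions.

    Returns
    -------
    TransformedDataset
        Same keys, values strictly inside (0, 1), monotone per assay, ties
        mapped together.
    """
    if scope not in SCOPES:
        raise ConfigError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if rank_convention not in RANK_CONVENTIONS:
        raise ConfigError(
            f"unknown rank convention {rank_convention!r}; "
            f"expected one of {RANK_CONVENTIONS}"
        )
    df = dataset.records
    df["raw_value"] = df["value"]
    if scope == "all":
        keys = ["assay"]
    elif scope == "per-group":
        keys = ["assay", "group"]
    else:
        keys = ["assay", "method"]

    maps: dict[tuple, EmpiricalQuantileMap] = {}
    out = np.empty(len(df), dtype=float)
    for key, sub in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        m = fit_ecdf(sub["value"].to_numpy(), rank_convention)
        maps[key] = m
        out[sub.index.to_numpy()] = m(sub["value"].to_numpy())
    df["value"] = out
    return TransformedDataset(
        records=df, maps=maps, scope=scope, rank_convention=rank_convention
    )
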