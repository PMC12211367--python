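"""End-to-end pipeline and tabular/graphical reports.

``run_pipeline`` executes read -> (optional NTA derivation) -> quantile
transform -> EVI -> EQI and writes a reproducible bundle to an output
directory: stratified raw summaries, the transformed table (pairplot data),
the EVI matrix, the EQI table, and a manifest with every setting plus
SHA-256 digests of the inputs — enough to regenerate the bundle exactly.
All files are built in a temporary directory and moved in only on success,
so a failed run leaves no partial outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import os
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from collections.abc import Sequence

import pandas as pd

from . import __version__
from .datamodel import StudyDataset, warn
from .eqi import EQIResult, EVIMatrix, compute_eqi, evi_matrix
from .io import read_measurements, read_nta_profiles
from .nta import derive_measurements
from .transform import transform_dataset


@dataclass
class PipelineSettings:
    """Every convention the metric leaves open, in one record."""

    aggregation: str = "mean"
    sd_mode: str = "sample"
    rank_convention: str = "midrank"
    scope: str = "all"
    max_def: str = "max_size"

    def as_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "sd_mode": self.sd_mode,
            "rank_convention": self.rank_convention,
            "scope": self.scope,
            "max_def": self.max_def,
        }


@dataclass
class ReportBundle:
    """In-memory result of one pipeline run."""

    raw_summaries: pd.DataFrame
    pairplot_data: pd.DataFrame
    evi: EVIMatrix
    eqi: EQIResult
    manifest: dict
    sweep: pd.DataFrame | None = None


def summarize_raw(dataset: StudyDataset) -> pd.DataFrame:
    """Replicate-pooled mean, sd and n per (group, method, assay).

    The stratified summary tables: one row per cell, pooling all samples
    of a group and their replicates; deterministic row order.
    """
    df = dataset.records
    out = (
        df.groupby(["group", "method", "assay"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def pairplot_table(transformed) -> pd.DataFrame:
    """Transformed values in wide form, one column per assay — the data
    behind the scatter-plot matrix of assay associations."""
    df = transformed.records
    wide = df.pivot_table(
        index=["sample_id", "group", "method", "replicate"],
        columns="assay",
        values="value",
        aggfunc="first",
        sort=True,
    ).reset_index()
    wide.columns.name = None
    return wide


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


SWEEP_AXES = {
    "aggregation": ("mean", "sum"),
    "sd_mode": ("sample", "population"),
    "rank_convention": ("midrank", "weibull"),
    "scope": ("all", "per-group"),
    "max_def": ("max_size", "mode_size"),
}


def run_convention_sweep(
    dataset: StudyDataset,
    *,
    nta_paths: Sequence[str | os.PathLike] = (),
) -> pd.DataFrame:
    """EQI per method under every combination of the open conventions.

    ``dataset`` must be the measurement table WITHOUT NTA-derived records;
    when ``nta_paths`` are given, size/PDI/concentration records are
    re-derived per ``max_def`` setting.  Without profiles the ``max_def``
    axis is held at its default.  Returns one row per (convention
    combination, method) with the EQI percentage.
    """
    axes = dict(SWEEP_AXES)
    if not nta_paths:
        axes["max_def"] = ("max_size",)
    names = list(axes)
    rows = []
    for combo in itertools.product(*(axes[n] for n in names)):
        settings = PipelineSettings(**dict(zip(names, combo)))
        ds = dataset
        if nta_paths:
            ds = _merge_nta(dataset, nta_paths, settings.max_def)
        transformed = transform_dataset(
            ds, scope=settings.scope, rank_convention=settings.rank_convention
        )
        result = compute_eqi(
            evi_matrix(
                transformed,
                aggregation=settings.aggregation,
                sd_mode=settings.sd_mode,
            )
        )
        for row in result.table.itertuples(index=False):
            rows.append((*combo, row.method, row.eqi_percent, row.mean_evi))
    return pd.DataFrame(
        rows, columns=[*names, "method", "eqi_percent", "mean_evi"]
    )


def _merge_nta(
    dataset: StudyDataset,
    nta_paths: Sequence[str | os.PathLike],
    max_def: str,
) -> StudyDataset:
    profiles = []
    for p in nta_paths:
        profiles.extend(read_nta_profiles(p))
    derived = derive_measurements(profiles, groups=dataset.groups, max_def=max_def)
    return dataset.merged_with(StudyDataset(pd.DataFrame([r.__dict__ for r in derived])))


def run_pipeline(
    measurements_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    *,
    nta_paths: Sequence[str | os.PathLike] = (),
    settings: PipelineSettings | None = None,
    sweep: bool = False,
    figures: bool = False,
) -> ReportBundle:
    """Execute the full pipeline and write the report bundle.

    Parameters
    ----------
    measurements_path
        Long-format measurement CSV.
    out_dir
        Output directory (created if needed).  Files written:
        ``raw_summaries.csv``, ``transformed.csv``, ``evi_matrix.csv``,
        ``eqi.csv``, ``manifest.json``; plus ``eqi_sweep.csv`` with
        ``sweep=True`` and PNG figures with ``figures=True``.
    nta_paths
        Optional NTA profile CSVs whose derived size/PDI/concentration
        records are merged in before the transform.
    settings
        Conventions for the run (defaults: mean aggregation, sample sd,
        midrank positions, pooled scope, max-size PDI numerator).
    sweep
        Also compute the EQI under every convention combination.
    figures
        Also write heatmap / pairplot / bar-chart PNGs.

    Reruns with identical inputs and settings produce byte-identical CSV
    and manifest files.
    """
    settings = settings or PipelineSettings()
    base = read_measurements(measurements_path)
    dataset = base
    if nta_paths:
        dataset = _merge_nta(base, nta_paths, settings.max_def)
    from .datamodel import CANONICAL_ASSAYS
    absent = [a for a in CANONICAL_ASSAYS if a not in dataset.assays]
    if absent:
        warn(
            f"canonical assay(s) absent, EQI computed over "
            f"{len(dataset.assays)} assay(s): missing {', '.join(absent)}"
        )

    transformed = transform_dataset(
        dataset, scope=settings.scope, rank_convention=settings.rank_convention
    )
    matrix = evi_matrix(
        transformed, aggregation=settings.aggregation, sd_mode=settings.sd_mode
    )
    result = compute_eqi(matrix)
    raw = summarize_raw(dataset)
    pair = pairplot_table(transformed)
    sweep_table = (
        run_convention_sweep(base, nta_paths=nta_paths) if sweep else None
    )

    manifest = {
        "package": "exoquality",
        "version": __version__,
        "settings": settings.as_dict(),
        "inputs": {
            str(Path(p).name): _sha256(p)
            for p in [measurements_path, *nta_paths]
        },
        "outputs": ["raw_summaries.csv", "transformed.csv", "evi_matrix.csv",
                    "eqi.csv", "manifest.json"]
        + (["eqi_sweep.csv"] if sweep else []),
    }

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(dir=out_dir.parent, prefix=".exoquality-tmp-"))
    try:
        raw.to_csv(tmp / "raw_summaries.csv", index=False)
        pair.to_csv(tmp / "transformed.csv", index=False)
        matrix.table.to_csv(tmp / "evi_matrix.csv", index=False)
        result.table.to_csv(tmp / "eqi.csv", index=False)
        if sweep_table is not None:
            sweep_table.to_csv(tmp / "eqi_sweep.csv", index=False)
        with open(tmp / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if figures:
            _write_figures(tmp, transformed, matrix, result)
        for name in sorted(os.listdir(tmp)):
            os.replace(tmp / name, out_dir / name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)

    return ReportBundle(
        raw_summaries=raw,
        pairplot_data=pair,
        evi=matrix,
        eqi=result,
        manifest=manifest,
        sweep=sweep_table,
    )


def _write_figures(out_dir: Path, transformed, matrix: EVIMatrix,
                   result: EQIResult) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    fig, ax = plt.subplots(figsize=(10, 4))
    sns.heatmap(matrix.to_wide(), annot=True, fmt=".2f", cmap="viridis", ax=ax)
    ax.set_title("EV Inconsistency value per method and sample")
    fig.tight_layout()
    fig.savefig(out_dir / "evi_heatmap.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    t = result.table.sort_values("eqi_percent", ascending=False)
    ax.bar(t["method"], t["eqi_percent"])
    ax.set_ylabel("ExoQuality Index (%)")
    ax.set_ylim(0, 100)
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out_dir / "eqi_bar.png", dpi=150)
    plt.close(fig)

    wide = pairplot_table(transformed)
    assay_cols = [c for c in wide.columns
                  if c not in ("sample_id", "group", "method", "replicate")]
    grid = sns.pairplot(
        wide, vars=assay_cols, hue="method", corner=True,
        plot_kws={"s": 12, "alpha": 0.6},
    )
    grid.savefig(out_dir / "pairplot.png", dpi=150)
    plt.close("all")
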