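"""EV Inconsistency values and the ExoQuality Index against first principles."""

import math

import numpy as np
import pandas as pd
import pytest

from exoquality import (
    StudyDataset,
    UndefinedEVIError,
    compute_eqi,
    compute_evi,
    evi_matrix,
    transform_dataset,
)
from conftest import make_dataset


def brute_force_evi(transformed, method, sample, aggregation, sd_mode):
    """Independent oracle: explicit loops computing variance from first
    principles, no numpy statistics."""
    df = transformed.records
    sds = []
    for assay in sorted(df["assay"].unique()):
        vals = [
            float(row.value)
            for row in df.itertuples(index=False)
            if row.method == method and row.sample_id == sample
            and row.assay == assay
        ]
        n = len(vals)
        if n < 2:
            continue
        mean = sum(vals) / n
        ss = sum((v - mean) ** 2 for v in vals)
        denom = n - 1 if sd_mode == "sample" else n
        sds.append(math.sqrt(ss / denom))
    if not sds:
        raise ValueError("no computable assay")
    return sum(sds) / len(sds) if aggregation == "mean" else sum(sds)


def dataset_from_cell(values_by_assay):
    """One sample, one method; values_by_assay: {assay: [replicates]}."""
    rows = []
    for assay, vals in values_by_assay.items():
        for r, v in enumerate(vals, start=1):
            rows.append(("s1", "g", "m1", assay, r, v))
    return StudyDataset(pd.DataFrame(
        rows, columns=["sample_id", "group", "method", "assay",
                       "replicate", "value"]))


def test_identical_replicates_give_zero_evi():
    ds = dataset_from_cell({"a": [5.0, 5.0, 5.0], "b": [9.0, 9.0, 9.0]})
    t = transform_dataset(ds)
    assert compute_evi(t, "m1", "s1") == 0.0


def test_single_assay_evi_is_replicate_sd():
    # two transformed replicates always map to {0.25, 0.75}; sample sd
    # = 0.5/sqrt(2) ~ 0.3536; with raw values chosen so transformed are
    # {0.25, 0.75}, EVI = sd regardless of aggregation
    ds = dataset_from_cell({"a": [1.0, 2.0]})
    t = transform_dataset(ds)
    expected = np.std([0.25, 0.75], ddof=1)
    assert compute_evi(t, "m1", "s1", aggregation="mean") == pytest.approx(expected)
    assert compute_evi(t, "m1", "s1", aggregation="sum") == pytest.approx(expected)


def test_mean_vs_sum_aggregation():
    """Per-assay sds of 0.1 and 0.3 aggregate to 0.2 (mean) or 0.4 (sum)."""
    class Fake:
        pass

    records = pd.DataFrame(
        [("s1", "g", "m1", "a", 1, 0.4), ("s1", "g", "m1", "a", 2, 0.4 + 0.1 * math.sqrt(2)),
         ("s1", "g", "m1", "b", 1, 0.3), ("s1", "g", "m1", "b", 2, 0.3 + 0.3 * math.sqrt(2))],
        columns=["sample_id", "group", "method", "assay", "replicate", "value"],
    )
    t = Fake()
    t.records = records  # already on the (0,1) scale
    assert compute_evi(t, "m1", "s1", aggregation="mean") == pytest.approx(0.2)
    assert compute_evi(t, "m1", "s1", aggregation="sum") == pytest.approx(0.4)


def test_undefined_evi_without_replicates():
    ds = dataset_from_cell({"a": [1.0, 2.0]})
    t = transform_dataset(ds)
    t.records = t.records[t.records["replicate"] == 1]
    with pytest.raises(UndefinedEVIError):
        compute_evi(t, "m1", "s1")


def test_oracle_equivalence_on_random_small_datasets(rng):
    """evi_matrix agrees with the first-principles loop to 1e-12 across
    aggregations and sd conventions."""
    for i in range(25):
        ds = make_dataset(
            rng,
            n_samples=int(rng.integers(1, 4)),
            n_methods=int(rng.integers(1, 4)),
            n_assays=int(rng.integers(1, 4)),
            n_replicates=int(rng.integers(2, 4)),
        )
        t = transform_dataset(ds)
        aggregation = ("mean", "sum")[i % 2]
        sd_mode = ("sample", "population")[(i // 2) % 2]
        mat = evi_matrix(t, aggregation=aggregation, sd_mode=sd_mode)
        for row in mat.table.itertuples(index=False):
            expected = brute_force_evi(t, row.method, row.sample_id,
                                       aggregation, sd_mode)
            assert row.evi == pytest.approx(expected, abs=1e-12)
            assert compute_evi(
                t, row.method, row.sample_id,
                aggregation=aggregation, sd_mode=sd_mode,
            ) == pytest.approx(expected, abs=1e-12)


def test_evi_matrix_shape_and_determinism(study_dataset):
    t = transform_dataset(study_dataset)
    m1 = evi_matrix(t)
    m2 = evi_matrix(transform_dataset(study_dataset))
    assert len(m1.table) == 4 * 11
    assert (m1.table["n_assays"] == 5).all()
    pd.testing.assert_frame_equal(m1.table, m2.table)
    assert (m1.table["evi"] >= 0).all()
    # mean aggregation is bounded by the max sd of [0,1] values, 4 replicates
    assert (m1.table["evi"] <= math.sqrt(1.0 / 3.0) + 1e-12).all()


def test_copied_method_gives_identical_rows(rng):
    ds = make_dataset(rng, n_methods=1, n_samples=2, n_assays=2)
    df = ds.records
    copy = df.copy()
    copy["method"] = "m_copy"
    both = StudyDataset(pd.concat([df, copy], ignore_index=True))
    m = evi_matrix(transform_dataset(both))
    wide = m.to_wide()
    np.testing.assert_allclose(wide.loc["m0"], wide.loc["m_copy"])


def test_method_label_permutation_equivariance(rng):
    ds = make_dataset(rng, n_methods=3, n_samples=2, n_assays=2)
    renames = {"m0": "zzz", "m1": "aaa", "m2": "mmm"}
    df = ds.records
    df["method"] = df["method"].map(renames)
    m0 = evi_matrix(transform_dataset(ds))
    m1 = evi_matrix(transform_dataset(StudyDataset(df)))
    for old, new in renames.items():
        np.testing.assert_allclose(
            m0.to_wide().loc[old].to_numpy(), m1.to_wide().loc[new].to_numpy()
        )


def test_eqi_from_evi_entries():
    table = pd.DataFrame(
        {"method": ["m1", "m1"], "sample_id": ["s1", "s2"],
         "evi": [0.1, 0.3], "n_assays": [2, 2]}
    )
    from exoquality import EVIMatrix
    result = compute_eqi(EVIMatrix(table=table, aggregation="mean",
                                   sd_mode="sample"))
    assert result.table["eqi"].iloc[0] == pytest.approx(0.8)
    assert result.eqi_percent("m1") == 80.0
    assert result.table["n_samples"].iloc[0] == 2


def test_zero_evi_gives_hundred_percent():
    from exoquality import EVIMatrix
    table = pd.DataFrame(
        {"method": ["m1"], "sample_id": ["s1"], "evi": [0.0], "n_assays": [3]}
    )
    result = compute_eqi(EVIMatrix(table=table, aggregation="mean",
                                   sd_mode="sample"))
    assert result.table["eqi"].iloc[0] == 1.0
    assert result.eqi_percent("m1") == 100.0
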