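"""Drift correction, the three compound filters, transforms, volcano
statistics, PCA and the platform-overlap accounting."""

import numpy as np
import pandas as pd
import pytest

from hrgcms.stats import (
    FeatureTable,
    blank_filter,
    drift_correct,
    match_compounds_across_platforms,
    missing_value_filter,
    overlap_percent,
    pca,
    platform_overlap,
    qc_rsd_filter,
    transform,
    volcano,
)


def make_table(compound_rows: dict, classes: list[str]) -> FeatureTable:
    ids = [f"s{i}" for i in range(len(classes))]
    areas = pd.DataFrame(compound_rows, index=ids).T
    samples = pd.DataFrame(
        {"cls": classes, "order": range(1, len(classes) + 1)}, index=ids
    )
    return FeatureTable(areas=areas, samples=samples)


def two_group_table(rng, n_compounds, n_per_group=5, cv=0.1, planted=(), fc=4.0):
    """Control/stress table with log-normal noise and optional planted
    fold changes — the independent construction used as oracle for the
    volcano statistics."""
    sigma = np.sqrt(np.log(1 + cv**2))
    classes = ["control"] * n_per_group + ["stress"] * n_per_group
    rows = {}
    for i in range(n_compounds):
        mu = 10 ** rng.uniform(5, 6)
        eff = fc if i in planted else 1.0
        ctrl = mu * np.exp(rng.normal(0, sigma, n_per_group))
        strs = mu * eff * np.exp(rng.normal(0, sigma, n_per_group))
        rows[f"c{i:03d}"] = np.concatenate([ctrl, strs])
    return make_table(rows, classes)


# ---------------------------------------------------------------------------
# drift correction


def test_drift_free_table_unchanged():
    t = make_table(
        {"a": [100.0, 110.0, 90.0, 105.0, 100.0, 100.0, 100.0]},
        ["control", "control", "stress", "stress", "QC", "QC", "QC"],
    )
    out = drift_correct(t)
    pd.testing.assert_frame_equal(out.areas, t.areas.astype(float), rtol=1e-9)


def test_monotone_drift_reduces_qc_rsd():
    rng = np.random.default_rng(1)
    n = 12
    classes = ["control"] * 4 + ["stress"] * 4 + ["QC"] * 4
    drift = np.linspace(1.0, 2.0, n)
    rows = {f"c{i}": 1000.0 * drift * np.exp(rng.normal(0, 0.02, n)) for i in range(5)}
    t = make_table(rows, classes)
    # interleave QCs across the run
    t.samples.loc[:, "order"] = [2, 5, 8, 11, 3, 6, 9, 12, 1, 4, 7, 10]
    t = FeatureTable(areas=t.areas[t.samples.index], samples=t.samples)
    out = drift_correct(t)
    qc_cols = t.columns_of("QC")
    for cid in rows:
        before = t.areas.loc[cid, qc_cols]
        after = out.areas.loc[cid, qc_cols]
        assert after.std() / after.mean() < before.std() / before.mean()


def test_drift_midpoint_interpolation():
    t = make_table(
        {"a": [150.0, 100.0, 200.0, 100.0]},
        ["control", "QC", "QC", "QC"],
    )
    # QCs at orders 1 and 10 with values 100 and 200; sample midway
    t.samples.loc[:, "order"] = [5, 1, 10, 11]
    t.samples.loc["s3", "cls"] = "QC"
    t2 = FeatureTable(areas=t.areas, samples=t.samples)
    out = drift_correct(t2)
    # trend at order 5 = 100 + (200-100)*(4/9) = 144.4; anchor = median QC
    trend = np.interp(5, [1, 10, 11], [100, 200, 100])
    anchor = np.median([100, 200, 100])
    assert out.areas.loc["a", "s0"] == pytest.approx(150.0 / trend * anchor)


def test_too_few_qcs_rejected():
    t = make_table({"a": [1, 2, 3]}, ["control", "stress", "QC"])
    with pytest.raises(ValueError, match="QC"):
        drift_correct(t)


# ---------------------------------------------------------------------------
# QC RSD filter


@pytest.mark.parametrize(
    "qc_areas, kept",
    [
        ([100.0, 100.0, 100.0], True),   # RSD 0
        ([90.0, 100.0, 110.0], True),    # RSD 10%
        ([80.0, 100.0, 120.0], True),    # RSD exactly 20% -> kept
        ([50.0, 100.0, 150.0], False),   # RSD 50%
    ],
)
def test_qc_rsd_boundaries(qc_areas, kept):
    t = make_table({"a": [100.0, 100.0] + qc_areas}, ["control", "stress", "QC", "QC", "QC"])
    kept_t, removed_t = qc_rsd_filter(t, 20.0)
    assert ("a" in kept_t.areas.index) is kept
    assert len(kept_t.areas) + len(removed_t.areas) == 1


def test_unmeasurable_qc_rsd_removed():
    t = make_table(
        {"a": [100.0, 100.0, np.nan, np.nan, 50.0]},
        ["control", "stress", "QC", "QC", "QC"],
    )
    kept_t, removed_t = qc_rsd_filter(t)
    assert list(removed_t.areas.index) == ["a"]


# ---------------------------------------------------------------------------
# blank filter


@pytest.mark.parametrize(
    "ctrl, strs, kept",
    [
        (400.0, 100.0, False),  # 4x < 5x
        (600.0, 50.0, True),    # 6x in one group suffices
        (500.0, 100.0, True),   # exactly 5x -> kept
    ],
)
def test_blank_fold_rule(ctrl, strs, kept):
    t = make_table(
        {"a": [ctrl, ctrl, strs, strs, 100.0, 100.0]},
        ["control", "control", "stress", "stress", "blank", "blank"],
    )
    kept_t, _ = blank_filter(t, 5.0)
    assert ("a" in kept_t.areas.index) is kept


def test_compound_absent_from_blanks_always_kept():
    t = make_table(
        {"a": [10.0, 10.0, 10.0, 10.0, np.nan, 0.0]},
        ["control", "control", "stress", "stress", "blank", "blank"],
    )
    kept_t, _ = blank_filter(t, 5.0)
    assert "a" in kept_t.areas.index


# ---------------------------------------------------------------------------
# missing-value filter


def test_missing_value_filter_group_presence():
    classes = ["control"] * 5 + ["stress"] * 5
    rows = {
        "all": np.full(10, 5.0),
        "none": np.full(10, np.nan),
        "stress_only": [np.nan] * 5 + [4.0, 4.0, 4.0, 4.0, np.nan],  # 4/5 stress
    }
    t = make_table(rows, classes)
    kept_t, removed_t = missing_value_filter(t, 0.8)
    assert set(kept_t.areas.index) == {"all", "stress_only"}
    assert set(removed_t.areas.index) == {"none"}


def test_filters_partition_input(twin):
    table = twin.hr.features
    corrected = drift_correct(table)
    kept, removed = qc_rsd_filter(corrected)
    assert set(kept.areas.index) | set(removed.areas.index) == set(table.areas.index)
    assert not (set(kept.areas.index) & set(removed.areas.index))


# ---------------------------------------------------------------------------
# transform


def test_transform_rows_are_autoscaled():
    rng = np.random.default_rng(2)
    t = two_group_table(rng, 10)
    m = transform(t)
    np.testing.assert_allclose(m.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(m.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_constant_compound_becomes_zero_row():
    t = make_table({"a": [5.0, 5.0, 5.0, 5.0]}, ["control", "control", "stress", "stress"])
    with pytest.warns(UserWarning):
        m = transform(t)
    assert (m.loc["a"] == 0).all()


def test_transform_invariant_to_global_scale():
    rng = np.random.default_rng(3)
    t = two_group_table(rng, 6)
    t10 = FeatureTable(areas=t.areas * 10.0, samples=t.samples)
    pd.testing.assert_frame_equal(transform(t), transform(t10), rtol=1e-9)


# ---------------------------------------------------------------------------
# volcano


def test_planted_effect_is_significant_up():
    rng = np.random.default_rng(4)
    t = two_group_table(rng, 30, planted={0, 1, 2}, fc=4.0)
    res = volcano(t)
    assert res.table.loc["c000", "significant"]
    assert res.table.loc["c000", "direction"] == "up"
    assert {"c000", "c001", "c002"} <= set(res.significant_ids)


def test_fold_change_exactly_two_not_significant():
    t = make_table(
        {"a": [100.0, 100.0, 100.0, 200.0, 200.0, 200.0]},
        ["control"] * 3 + ["stress"] * 3,
    )
    res = volcano(t, fc_threshold=2.0)
    assert res.table.loc["a", "fold_change"] == pytest.approx(2.0)
    assert not res.table.loc["a", "significant"]


def test_null_table_controls_false_positives():
    rng = np.random.default_rng(5)
    t = two_group_table(rng, 100)
    res = volcano(t)
    assert len(res.significant_ids) / 100 <= 0.05


def test_bh_adjustment_dominates_raw_p():
    rng = np.random.default_rng(6)
    t = two_group_table(rng, 40, planted={0}, fc=5.0)
    res = volcano(t)
    assert (res.table["p_adjusted"] >= res.table["p_raw"] - 1e-12).all()


def test_zero_control_mean_gives_infinite_fc():
    t = make_table(
        {"a": [np.nan, np.nan, np.nan, 50.0, 55.0, 60.0]},
        ["control"] * 3 + ["stress"] * 3,
    )
    res = volcano(t)
    assert np.isinf(res.table.loc["a", "fold_change"])


# ---------------------------------------------------------------------------
# PCA


def test_pca_duplicated_samples_collapse():
    rng = np.random.default_rng(7)
    t = two_group_table(rng, 10, n_per_group=3)
    m = transform(t)
    m2 = pd.concat([m, m.iloc[:, [0]].rename(columns={m.columns[0]: "dup"})], axis=1)
    scores, ev = pca(m2, 2)
    np.testing.assert_allclose(scores.loc["dup"], scores.iloc[0], atol=1e-9)
    assert all(b <= a + 1e-12 for a, b in zip(ev, ev[1:]))


def test_pca_separates_planted_groups_on_pc1():
    rng = np.random.default_rng(8)
    t = two_group_table(rng, 40, planted=set(range(20)), fc=6.0)
    m = transform(t)
    scores, _ = pca(m, 2)
    ctrl = scores.loc[t.columns_of("control"), "PC1"]
    strs = scores.loc[t.columns_of("stress"), "PC1"]
    # group centroids separate beyond within-group spread (silhouette > 0)
    gap = abs(ctrl.mean() - strs.mean())
    assert gap > ctrl.std() + strs.std()


def test_pca_components_truncated_to_rank():
    t = make_table(
        {"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]},
        ["control", "control", "stress", "stress"],
    )
    with pytest.warns(UserWarning):
        scores, ev = pca(transform(t), 4)
    assert scores.shape[1] < 4


# ---------------------------------------------------------------------------
# platform overlap


def test_overlap_percent_from_printed_counts():
    """9 unique on one platform, 46 on the other, 21 shared -> 28%."""
    assert overlap_percent(21, 9, 46) == 28


def test_overlap_identical_and_disjoint_sets():
    pairing = [("x", "x"), ("y", "y")]
    full = platform_overlap({"x", "y"}, {"x", "y"}, pairing, {"x", "y"}, {"x", "y"})
    assert full.percent == 100 and full.shared == 2
    none = platform_overlap({"x"}, {"y"}, pairing, {"x", "y"}, {"x", "y"})
    assert none.percent == 0


def test_overlap_cause_codes():
    pairing = [("a", "a")]
    report = platform_overlap(
        significant_a={"a", "b", "c", "d"},
        significant_b=set(),
        pairing=pairing,
        present_a={"a", "b", "c", "d"},
        present_b={"a"},
        blank_removed_b={"c"},
    )
    assert report.causes_a["a"] == "threshold-fail"   # paired, present, not significant
    assert report.causes_a["b"] == "below-LOD"        # absent from other table
    assert report.causes_a["c"] == "blank-excluded"


# ---------------------------------------------------------------------------
# cross-platform pairing


def test_identical_compound_sets_pair_perfectly(truth_and_library):
    from hrgcms.spectra import Spectrum, to_unit_mass

    truth, _ = truth_and_library
    spectra = {}
    for c in truth:
        s = Spectrum(
            mz=np.array([m for _, m, _ in c.fragments]),
            intensity=np.array([i for _, _, i in c.fragments]),
            resolution="accurate",
            identifier=c.cid,
            retention_index=c.retention_index,
        )
        spectra[c.cid] = to_unit_mass(s)
    pairs = match_compounds_across_platforms(spectra, spectra)
    assert len(pairs) == len(spectra)
    assert all(a == b for a, b, _ in pairs)


def test_ri_window_blocks_pairing():
    from hrgcms.spectra import Spectrum

    a = {"x": Spectrum(mz=np.array([50.0, 60.0]), intensity=np.array([1.0, 1.0]),
                       resolution="unit", retention_index=1000.0)}
    b = {"y": Spectrum(mz=np.array([50.0, 60.0]), intensity=np.array([1.0, 1.0]),
                       resolution="unit", retention_index=1100.0)}
    assert match_compounds_across_platforms(a, b, ri_tol=5.0) == []
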