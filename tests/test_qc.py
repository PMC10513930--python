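import numpy as np
import pandas as pd
import pytest

from lipidyn.qc import (FilterThresholds, ImputationModel, apply_filters,
                        class_detection_limits, compute_cv,
                        impute_adjacent_mean, impute_truncated_knn)


def _meta(samples, participants, qc=(), dates=None):
    return pd.DataFrame({
        "participant": participants,
        "is_qc": [s in qc for s in samples],
        "collection_date": dates if dates is not None else range(len(samples)),
    }, index=samples)


def test_cv_closed_form():
    """(90, 100, 110) has sample sd 10 and mean 100 -> 10%."""
    samples = [f"S{i}" for i in range(3)]
    mat = pd.DataFrame({"A": [90.0, 100.0, 110.0],
                        "B": [5.0, 5.0, 5.0]}, index=samples)
    meta = _meta(samples, ["P1"] * 3)
    rep = compute_cv(mat, meta)
    assert rep.cv_intra["A"] == pytest.approx(10.0)
    assert rep.cv_intra["B"] == 0.0
    assert rep.cv_inter["A"] == pytest.approx(10.0)


def test_cv_participant_eligibility_and_same_day_dupes():
    samples = [f"S{i}" for i in range(7)]
    # P1: 3 distinct days (one duplicated day), P2: only 2 timepoints
    meta = _meta(samples, ["P1"] * 4 + ["P2"] * 3,
                 dates=[0, 0, 1, 2, 0, 0, 1])
    mat = pd.DataFrame({"A": [100.0, 999.0, 100.0, 100.0, 1.0, 1.0, 2.0]},
                       index=samples)
    rep = compute_cv(mat, meta)
    # the same-day duplicate (999) is excluded, P2 has <3 timepoints
    assert rep.cv_intra["A"] == 0.0
    assert rep.n_participants_used["A"] == 1


def test_cv_zero_mean_flagged():
    samples = ["S0", "S1", "S2"]
    mat = pd.DataFrame({"A": [-1.0, 0.0, 1.0]}, index=samples)
    rep = compute_cv(mat, _meta(samples, ["P1"] * 3))
    assert np.isnan(rep.cv_inter["A"])


def _toy_matrix():
    samples = [f"B{i}" for i in range(8)] + ["QC1", "QC2", "QC3"]
    rng = np.random.default_rng(0)
    mat = pd.DataFrame(rng.uniform(50, 150, (11, 4)),
                       index=samples,
                       columns=["PC(16:0/18:1)", "PC(18:0/18:2)",
                                "PG(16:0/18:1)", "PI(16:0/18:3)"])
    # stable QC stock: low technical CV so the robust-CV rule keeps species
    mat.iloc[8:] = rng.normal(100.0, 2.0, (3, 4))
    return samples, mat


def test_filters_order_and_reasons():
    samples, mat = _toy_matrix()
    mat.loc["B0", mat.columns[:2]] = np.nan            # 50% missing sample
    mat.loc[samples[1:], "PC(18:0/18:2)"] = np.nan     # <10% valid species
    meta = _meta(samples, ["P%d" % i for i in range(8)] + ["QC"] * 3,
                 qc=("QC1", "QC2", "QC3"))
    rep_cv = compute_cv(mat, meta)
    out, report = apply_filters(mat, rep_cv, qc_samples=["QC1", "QC2", "QC3"])
    assert list(report.dropped_samples["sample_id"]) == ["B0"]
    reasons = dict(zip(report.dropped_species["species"],
                       report.dropped_species["reason"]))
    assert reasons["PC(18:0/18:2)"] == "low_validity"
    assert reasons["PG(16:0/18:1)"] == "excluded_class"
    assert reasons["PI(16:0/18:3)"] == "excluded_species"
    assert report.robust_species == ["PC(16:0/18:1)"]


def test_filters_qc_cv_rules():
    samples, mat = _toy_matrix()
    meta = _meta(samples, ["P%d" % i for i in range(8)] + ["QC"] * 3,
                 qc=("QC1", "QC2", "QC3"))
    cv = compute_cv(mat, meta)
    cv.cv_qc["PC(16:0/18:1)"] = 25.0   # above the 20% QC CV cap
    cv.cv_qc["PC(18:0/18:2)"] = 15.0
    cv.cv_inter["PC(18:0/18:2)"] = 10.0  # QC CV above biosample CV
    _, report = apply_filters(mat, cv, qc_samples=["QC1", "QC2", "QC3"])
    reasons = dict(zip(report.dropped_species["species"],
                       report.dropped_species["reason"]))
    assert reasons["PC(16:0/18:1)"] == "high_qc_cv"
    assert reasons["PC(18:0/18:2)"] == "qc_cv_exceeds_bio_cv"


def test_filter_thresholds_validated():
    with pytest.raises(ValueError):
        FilterThresholds(max_sample_missing=1.5)


def test_filters_idempotent(study, pipeline_result):
    res = pipeline_result
    qc_ids = [s for s in res.filtered.index if study.samples.loc[s, "is_qc"]]
    again, report = apply_filters(res.filtered, res.cv_report,
                                  qc_samples=qc_ids)
    assert report.dropped_samples.empty
    assert report.dropped_species.empty
    pd.testing.assert_frame_equal(again, res.filtered)


def test_impute_identity_when_complete():
    mat = pd.DataFrame({"PC(16:0/18:1)": [1.0, 2.0, 3.0]},
                       index=["S0", "S1", "S2"])
    out = impute_truncated_knn(mat, ImputationModel(k=2, seed=0))
    pd.testing.assert_frame_equal(out, mat)


def test_impute_degenerate_sigma_uses_min_of_mu_and_limit():
    """A zero-variance species imputes at min(mu, log D) back-transformed."""
    idx = [f"S{i}" for i in range(6)]
    mat = pd.DataFrame({
        "PC(16:0/18:1)": [8.0, 8.0, 8.0, 8.0, 8.0, np.nan],
        "PC(18:0/18:2)": [2.0, 2.1, 1.9, 2.0, 2.05, 1.95],
    }, index=idx)
    out = impute_truncated_knn(mat, ImputationModel(k=2, seed=0))
    # class detection limit is 1.9 (< 8), so the imputed value clips there
    assert out.loc["S5", "PC(16:0/18:1)"] == pytest.approx(1.9)


def test_imputed_never_exceeds_class_limit(pipeline_result):
    res = pipeline_result
    limits = res.detection_limits
    from lipidyn.annotation import parse_lipid_name
    for sp in res.imputed.columns:
        was_missing = res.filtered[sp].reindex(res.imputed.index).isna()
        if not was_missing.any():
            continue
        d_c = limits[parse_lipid_name(sp).subclass]
        assert (res.imputed.loc[was_missing, sp] <= d_c * (1 + 1e-12)).all()


def test_truncated_knn_beats_constant_minimum(study, pipeline_result):
    """On left-censored synthetic data the truncated-KNN scheme has lower
    mean absolute log error than imputing the per-species minimum."""
    res = pipeline_result
    bio = [s for s in res.imputed.index]
    truth = study.true_conc.loc[bio, res.imputed.columns]
    filt = res.filtered.loc[bio]
    errs_knn, errs_min = [], []
    for sp in res.imputed.columns:
        miss = filt[sp].isna()
        if miss.sum() == 0:
            continue
        t = np.log(truth.loc[miss, sp])
        knn = np.log(res.imputed.loc[miss, sp])
        cmin = np.log(filt[sp].min())
        errs_knn.extend(np.abs(knn - t))
        errs_min.extend(np.abs(cmin - t))
    assert len(errs_knn) > 50
    assert np.mean(errs_knn) < np.mean(errs_min)


def test_impute_fallback_sparse_species_seeded():
    idx = [f"S{i}" for i in range(10)]
    col = [5.0, 4.0] + [np.nan] * 8
    mat = pd.DataFrame({"PC(16:0/18:1)": col,
                        "PC(18:0/18:2)": np.linspace(4, 6, 10)}, index=idx)
    out1 = impute_truncated_knn(mat, ImputationModel(k=3, seed=7))
    out2 = impute_truncated_knn(mat, ImputationModel(k=3, seed=7))
    pd.testing.assert_frame_equal(out1, out2)
    d_c = class_detection_limits(mat)["PC"]
    filled = out1.loc[mat["PC(16:0/18:1)"].isna(), "PC(16:0/18:1)"]
    assert ((filled >= 0.5 * d_c) & (filled <= d_c)).all()


@pytest.mark.parametrize("series,expected", [
    ([70.0, np.nan, 74.0], [70.0, 72.0, 74.0]),     # interior gap: mean
    ([np.nan, 68.0, 70.0], [68.0, 68.0, 70.0]),     # leading gap: nearest
    ([68.0, 70.0, np.nan], [68.0, 70.0, 70.0]),     # trailing gap: nearest
])
def test_impute_adjacent_mean(series, expected):
    out = impute_adjacent_mean(pd.Series(series))
    assert list(out) == expected


def test_impute_adjacent_mean_all_missing_unchanged():
    s = pd.Series([np.nan, np.nan])
    out = impute_adjacent_mean(s)
    assert out.isna().all()
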