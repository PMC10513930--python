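import numpy as np
import pandas as pd
import pytest

from lipidyn.models import (classify_ir, cytokine_lipid_lmm, delta_age_model,
                            differential_correlation, infection_differential,
                            sspg_regression)


@pytest.mark.parametrize("sspg,expected", [
    (150.0, "IS"), (150.1, "IR"), (149.9, "IS"), (260.0, "IR"),
])
def test_ir_classification_boundary(sspg, expected):
    assert classify_ir(sspg) == expected


def _sspg_meta(rng, n=70):
    sspg = rng.uniform(60, 260, n)
    return pd.DataFrame({
        "participant": [f"P{i}" for i in range(n)],
        "sspg": sspg, "age": rng.uniform(30, 70, n),
        "bmi": rng.uniform(20, 35, n),
        "sex": rng.choice(["M", "F"], n),
        "ethnicity": rng.choice(["A", "B"], n),
    }, index=[f"S{i}" for i in range(n)])


def test_sspg_exact_linear_species():
    rng = np.random.default_rng(0)
    meta = _sspg_meta(rng)
    sspg_z = (meta["sspg"] - meta["sspg"].mean()) / meta["sspg"].std()
    conc = pd.DataFrame({"PC(16:0/18:1)": np.exp(0.7 * sspg_z)},
                        index=meta.index)
    res = sspg_regression(conc, meta)
    assert res["p"].iloc[0] < 1e-20
    assert res["beta"].iloc[0] == pytest.approx(1.0, abs=0.01)  # z-scaled


def test_sspg_constant_species_skipped():
    rng = np.random.default_rng(1)
    meta = _sspg_meta(rng)
    conc = pd.DataFrame({"PC(16:0/18:1)": np.ones(len(meta)),
                         "PC(18:0/18:2)": np.exp(rng.normal(size=len(meta)))},
                        index=meta.index)
    res = sspg_regression(conc, meta)
    assert list(res["species"]) == ["PC(18:0/18:2)"]


def _infection_data(rng, n_part=15, effect=0.0):
    rows, meta = {}, []
    sids = []
    for p in range(n_part):
        for v, phase in enumerate(["baseline"] * 3 + ["early", "early",
                                                      "late", "recovery"]):
            sid = f"P{p}_V{v}"
            sids.append(sid)
            meta.append({"sample_id": sid, "participant": f"P{p}",
                         "phase": phase, "sex": "M" if p % 2 else "F",
                         "ethnicity": "A", "age": 50 + p, "bmi": 25.0})
    meta = pd.DataFrame(meta).set_index("sample_id")
    n = len(meta)
    u = rng.normal(0, 0.5, n_part)
    vals = {}
    for sp, eff in (("PC(16:0/18:1)", effect), ("PC(18:0/18:2)", 0.0)):
        y = np.array([u[int(s.split("_")[0][1:])] for s in meta.index])
        y = y + rng.normal(0, 0.5, n)
        y = y + np.where(meta["phase"] == "early", eff, 0.0)
        vals[sp] = np.exp(y)
    conc = pd.DataFrame(vals, index=meta.index)
    return conc, meta


def test_infection_detects_planted_early_drop():
    rng = np.random.default_rng(2)
    conc, meta = _infection_data(rng, effect=-1.5)
    res = infection_differential(conc, meta).set_index("species")
    assert res.loc["PC(16:0/18:1)", "significant"]
    assert res.loc["PC(16:0/18:1)", "beta_early"] < 0
    assert not res.loc["PC(18:0/18:2)", "significant"]


def test_infection_requires_two_phases():
    rng = np.random.default_rng(3)
    conc, meta = _infection_data(rng)
    meta["phase"] = "baseline"
    with pytest.raises(ValueError):
        infection_differential(conc, meta)


def test_cytokine_identical_to_lipid():
    rng = np.random.default_rng(4)
    n = 120
    meta = pd.DataFrame({
        "participant": np.repeat([f"P{i}" for i in range(30)], 4),
        "bmi": rng.uniform(20, 35, n), "sex": rng.choice(["M", "F"], n),
        "ethnicity": rng.choice(["A", "B"], n),
    }, index=[f"S{i}" for i in range(n)])
    lipid = np.exp(rng.normal(size=n))
    conc = pd.DataFrame({"PC(16:0/18:1)": lipid}, index=meta.index)
    lz = np.log(lipid)
    cyt = pd.DataFrame({"CYT01": (lz - lz.mean()) / lz.std()},
                       index=meta.index)
    res = cytokine_lipid_lmm(cyt, conc, meta)
    assert res["beta"].iloc[0] == pytest.approx(1.0, abs=0.01)
    assert res["p"].iloc[0] < 1e-20
    assert res["significant"].iloc[0]


def test_cytokine_mostly_missing_skipped():
    rng = np.random.default_rng(5)
    n = 60
    meta = pd.DataFrame({
        "participant": np.repeat([f"P{i}" for i in range(15)], 4),
        "bmi": rng.uniform(20, 35, n), "sex": rng.choice(["M", "F"], n),
        "ethnicity": rng.choice(["A", "B"], n),
    }, index=[f"S{i}" for i in range(n)])
    conc = pd.DataFrame({"PC(16:0/18:1)": np.exp(rng.normal(size=n))},
                        index=meta.index)
    cyt = pd.DataFrame({"CYT01": [1.0] * 20 + [np.nan] * 40,
                        "CYT02": rng.normal(size=n)}, index=meta.index)
    res = cytokine_lipid_lmm(cyt, conc, meta)
    assert set(res["cytokine"]) == {"CYT02"}


def _ageing_data(rng, slope=0.02, n_part=30, visits=8, interval=0.5,
                 extra=None, noise=0.02):
    rows = []
    enroll = rng.uniform(0, 3, n_part)  # staggered enrolment: storage length
    for p in range(n_part):             # is not collinear with delta-years
        nv = visits + (extra if (extra and p == 0) else 0)
        for v in range(nv):
            sid = f"P{p}_V{v}"
            rows.append({"sample_id": sid, "participant": f"P{p}",
                         "years_since_baseline": v * interval,
                         "bmi": 25.0 + 0.1 * p,
                         "storage_length": 10.0 - enroll[p] - v * interval,
                         "sex": "M" if p % 2 else "F",
                         "ir_status": "IR" if p % 2 else "IS"})
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    n = len(meta)
    base = rng.normal(0, 0.3, n_part)
    y = np.array([base[int(s.split("_")[0][1:])] for s in meta.index])
    y = y + slope * meta["years_since_baseline"].to_numpy() \
        + rng.normal(0, noise, n)
    conc = pd.DataFrame({"SM(16:0)": np.exp(y),
                         "SM(18:1)": np.exp(y + rng.normal(0, noise, n))},
                        index=meta.index)
    return conc, meta


def test_delta_age_recovers_planted_slope():
    rng = np.random.default_rng(6)
    conc, meta = _ageing_data(rng, slope=0.02)
    res = delta_age_model(conc, meta, level="class",
                          exclude_top_participant=False)
    row = res.set_index("feature").loc["SM"]
    assert row["beta"] == pytest.approx(0.02, abs=0.005)
    assert row["percent_change_5yr"] == pytest.approx(
        100 * (np.exp(5 * row["beta"]) - 1))


def test_delta_age_excludes_late_samples_and_top_participant():
    rng = np.random.default_rng(7)
    conc, meta = _ageing_data(rng, slope=0.0, visits=14, extra=6)
    res = delta_age_model(conc, meta, level="species")
    # 29 regular participants x delta rows within 5 years; participant P0
    # (uniquely many samples) contributes nothing
    n_expected = 29 * sum(1 for v in range(1, 14) if v * 0.5 <= 5.0)
    assert res["n"].iloc[0] == n_expected


def test_delta_age_strata():
    rng = np.random.default_rng(8)
    conc, meta = _ageing_data(rng, slope=0.02)
    res_m = delta_age_model(conc, meta, stratum="male", level="class",
                            exclude_top_participant=False)
    res_ir = delta_age_model(conc, meta, stratum="IR", level="class",
                             exclude_top_participant=False)
    assert (res_m["stratum"] == "male").all()
    assert res_ir["n"].iloc[0] < 30 * 7


def test_delta_age_single_visit_errors():
    conc = pd.DataFrame({"SM(16:0)": [1.0, 2.0]}, index=["A", "B"])
    meta = pd.DataFrame({
        "sample_id": ["A", "B"], "participant": ["P0", "P1"],
        "years_since_baseline": [0.0, 0.0], "bmi": [25.0, 26.0],
        "storage_length": [8.0, 8.0], "sex": ["M", "F"],
        "ir_status": ["IR", "IS"]}, index=["A", "B"])
    with pytest.raises(ValueError):
        delta_age_model(conc, meta)


def _corr_pair(rng, r, n):
    x = rng.normal(size=n)
    y = r * x + np.sqrt(1 - r ** 2) * rng.normal(size=n)
    return x, y


def test_differential_correlation_strong_contrast_reported():
    rng = np.random.default_rng(9)
    x_ir, y_ir = _corr_pair(rng, 0.8, 30)
    x_is, y_is = _corr_pair(rng, -0.8, 30)
    conc = pd.DataFrame({"PC(16:0/18:1)": np.exp(np.r_[x_ir, x_is])},
                        index=[f"S{i}" for i in range(60)])
    clinical = pd.DataFrame({"GLU": np.r_[y_ir, y_is]}, index=conc.index)
    labels = pd.Series(["IR"] * 30 + ["IS"] * 30, index=conc.index)
    res = differential_correlation(conc, clinical, labels)
    assert res["reported"].iloc[0]
    assert abs(res["delta_r"].iloc[0]) > 1.0


def test_differential_correlation_small_delta_not_reported():
    rng = np.random.default_rng(10)
    x = rng.normal(size=120)
    y = 0.3 * x + rng.normal(0, 1, 120) * 0.95
    conc = pd.DataFrame({"PC(16:0/18:1)": np.exp(x)},
                        index=[f"S{i}" for i in range(120)])
    clinical = pd.DataFrame({"GLU": y}, index=conc.index)
    labels = pd.Series(["IR"] * 60 + ["IS"] * 60, index=conc.index)
    res = differential_correlation(conc, clinical, labels)
    # identical generating process in both groups: delta near 0
    assert not res["reported"].iloc[0]
    assert abs(res["delta_r"].iloc[0]) < 0.5


def test_differential_correlation_min_group_size():
    conc = pd.DataFrame({"PC(16:0/18:1)": np.exp(np.random.default_rng(0).normal(size=12))},
                        index=[f"S{i}" for i in range(12)])
    clinical = pd.DataFrame({"GLU": np.zeros(12)}, index=conc.index)
    labels = pd.Series(["IR"] * 6 + ["IS"] * 6, index=conc.index)
    with pytest.raises(ValueError):
        differential_correlation(conc, clinical, labels)


def test_fdr_always_at_least_p(study):
    rng = np.random.default_rng(11)
    meta = _sspg_meta(rng, n=40)
    conc = pd.DataFrame(
        np.exp(rng.normal(size=(40, 30))),
        index=meta.index, columns=[f"PC(16:{i % 2}/18:1)" for i in range(30)])
    conc.columns = [f"PC({14 + i}:0/18:1)" for i in range(30)]
    res = sspg_regression(conc, meta)
    assert (res["fdr"] >= res["p"] - 1e-12).all()
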