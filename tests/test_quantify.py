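import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidyn.quantify import (SpikeStandard, estimate_concentration,
                              reassign_spikes, regress_method3_concentration,
                              select_surrogate_standards)


@pytest.mark.parametrize("analyte,spike,conc,identical,expected", [
    (2000.0, 1000.0, 5.0, False, 10.0),
    (2000.0, 1000.0, 5.0, True, 5.0),  # fragment signal doubled -> halved
    (0.0, 1000.0, 5.0, False, 0.0),
])
def test_estimate_concentration(analyte, spike, conc, identical, expected):
    assert estimate_concentration(analyte, spike, conc, identical) == expected


def test_estimate_concentration_rejects_bad_spike():
    with pytest.raises(ValueError):
        estimate_concentration(100.0, 0.0, 5.0)
    with pytest.raises(ValueError):
        estimate_concentration(100.0, np.nan, 5.0)


def _std(name, missingness, sub=None, subclass="DAG"):
    n = 100
    areas = pd.Series(1000.0, index=[f"S{i}" for i in range(n)])
    areas.iloc[:int(round(missingness * n))] = np.nan
    return SpikeStandard(name, subclass, 5.0, areas, substitute_name=sub)


def test_reassign_threshold_strictly_greater():
    stds = [
        _std("dDAG(16:0/18:3)", 0.21, sub="dDAG(16:0/18:2)"),
        _std("dDAG(16:0/18:2)", 0.0),
        _std("dDAG(16:0/20:5)", 0.04),
        _std("dDAG(17:0/17:0)", 0.05),  # exactly at threshold: kept
    ]
    used = reassign_spikes(stds)
    assert used["dDAG(16:0/18:3)"] == "dDAG(16:0/18:2)"
    assert used["dDAG(16:0/20:5)"] == "dDAG(16:0/20:5)"
    assert used["dDAG(17:0/17:0)"] == "dDAG(17:0/17:0)"


def test_reassign_missing_substitute_is_hard_error():
    with pytest.raises(ValueError):
        reassign_spikes([_std("dPE(18:0/22:5)", 0.44, subclass="PE")])


def test_reassign_cross_class_substitute_rejected():
    stds = [_std("dDAG(16:0/18:3)", 0.21, sub="dPE(18:0/20:4)"),
            _std("dPE(18:0/20:4)", 0.0, subclass="PE")]
    with pytest.raises(ValueError):
        reassign_spikes(stds)


def _qc_table(rng, n=40):
    """QC log10 intensities with a shared per-sample factor."""
    shared = rng.normal(0, 0.3, n)
    return shared


def test_surrogate_rule1_completeness_filter_precedes_ranking():
    """A better-correlating standard below 50% completeness loses to an
    eligible one."""
    rng = np.random.default_rng(0)
    shared = _qc_table(rng)
    qc = pd.DataFrame({
        "PI(16:0/18:1)": shared + rng.normal(0, 0.05, 40),
        "stdA": shared + rng.normal(0, 0.10, 40),
        "stdB": shared + rng.normal(0, 0.01, 40),
    })
    qc.loc[qc.index[:25], "stdB"] = np.nan  # 37.5% complete
    res = select_surrogate_standards(
        qc, ["PI(16:0/18:1)"], {"PI(16:0/18:1)": "PI"}, ["stdA", "stdB"])
    a = res["PI(16:0/18:1)"]
    assert a.standard == "stdA"
    assert a.rule_used == "corr_rule_1"
    assert a.correlation > 0.9


def test_surrogate_rule2_uses_classmate_match():
    rng = np.random.default_rng(1)
    shared = _qc_table(rng)
    qc = pd.DataFrame({
        "PI(16:0/18:1)": shared + rng.normal(0, 0.05, 40),
        "PI(18:0/20:4)": np.nan,  # no defined correlation at all
        "stdC": shared + rng.normal(0, 0.05, 40),
    })
    res = select_surrogate_standards(
        qc, ["PI(16:0/18:1)", "PI(18:0/20:4)"],
        {"PI(16:0/18:1)": "PI", "PI(18:0/20:4)": "PI"}, ["stdC"])
    assert res["PI(18:0/20:4)"].rule_used == "corr_rule_2"
    assert res["PI(18:0/20:4)"].standard == "stdC"


def test_surrogate_rule3_global_fallback():
    rng = np.random.default_rng(2)
    shared = _qc_table(rng)
    qc = pd.DataFrame({
        "PG(16:0/18:1)": shared + rng.normal(0, 0.05, 40),
        "PS(16:0/18:1)": np.nan,  # isolated: no classmate either
        "stdD": shared + rng.normal(0, 0.05, 40),
    })
    res = select_surrogate_standards(
        qc, ["PG(16:0/18:1)", "PS(16:0/18:1)"],
        {"PG(16:0/18:1)": "PG", "PS(16:0/18:1)": "PS"}, ["stdD"])
    assert res["PS(16:0/18:1)"].rule_used == "corr_rule_3"
    assert res["PS(16:0/18:1)"].standard == "stdD"


def test_surrogate_no_candidates_is_config_error():
    qc = pd.DataFrame({"PI(16:0/18:1)": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        select_surrogate_standards(qc, ["PI(16:0/18:1)"],
                                   {"PI(16:0/18:1)": "PI"}, [])


def test_regression_recovers_noiseless_line():
    intensity = np.array([1.0, 10.0, 100.0, 1e3, 1e4, 1e5, 2.0, 20.0, 200.0, 2e3])
    conc = 3.0 * intensity ** 0.9
    norm = pd.DataFrame({"PI(16:0/18:1)": [5.0, 50.0]})
    pred, (intercept, slope) = regress_method3_concentration(norm, intensity, conc)
    assert slope == pytest.approx(0.9, abs=1e-9)
    assert pred.iloc[0, 0] == pytest.approx(3.0 * 5.0 ** 0.9, rel=1e-9)
    # monotone transform preserves between-sample ordering
    assert pred.iloc[1, 0] > pred.iloc[0, 0]


def test_regression_slope_recovery_under_noise():
    """sigma=0.1 log10 noise at n=200 recovers the slope within 0.05."""
    rng = np.random.default_rng(0)
    x = 10 ** rng.uniform(0, 4, 200)
    y = 10 ** (0.3 + 1.0 * np.log10(x) + rng.normal(0, 0.1, 200))
    _, (_, slope) = regress_method3_concentration(
        pd.DataFrame({"PI(16:0/18:1)": [1.0]}), x, y)
    assert abs(slope - 1.0) < 0.05


def test_regression_degenerate_design():
    with pytest.raises(ValueError):
        regress_method3_concentration(
            pd.DataFrame({"PI(16:0/18:1)": [1.0]}),
            np.full(20, 7.0), np.linspace(1, 2, 20))


def test_surrogate_normalization_preserves_fold_changes():
    """With constant standards, between-sample ratios of a species equal the
    raw intensity ratios."""
    idx = [f"S{i}" for i in range(12)]
    intensity = pd.Series(np.linspace(100, 1200, 12), index=idx)
    area = pd.Series(500.0, index=idx)
    norm = intensity / area
    ratio_raw = intensity / intensity.iloc[0]
    ratio_norm = norm / norm.iloc[0]
    assert np.allclose(ratio_raw, ratio_norm)


def test_direct_spike_provenance_and_roundtrip(study, pipeline_result):
    """Direct-spike species recover planted truth within replicate noise."""
    res = pipeline_result
    direct = [s for s in res.filtered.columns
              if res.provenance[s] == "direct_spike"]
    assert direct and (res.provenance.dropna() != "").all()
    method3 = [s for s in res.filtered.columns
               if res.provenance[s] == "regression_estimated"]
    assert all(s.startswith("PI") for s in method3)
    bio = [s for s in res.filtered.index if not study.samples.loc[s, "is_qc"]]
    est = res.filtered.loc[bio, direct]
    tru = study.true_conc.loc[bio, direct]
    rel = ((est - tru).abs() / tru).to_numpy()
    assert np.nanmedian(rel) < 0.05
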