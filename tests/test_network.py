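import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lipidyn.network import (CoModule, compute_tom, detect_modules,
                             merge_modules, module_clinical_correlation,
                             module_eigengene, pick_soft_threshold)


def test_tom_complete_graph():
    a = np.ones((3, 3)) - np.eye(3)
    tom = compute_tom(a)
    assert np.allclose(tom[np.triu_indices(3, 1)], 1.0)


def test_tom_single_edge_hand_computed():
    """a_12 = 0.5 only: TOM_12 = (0 + 0.5) / (min(0.5, 0.5) + 1 - 0.5)."""
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = 0.5
    tom = compute_tom(a)
    assert tom[0, 1] == pytest.approx(0.5)
    assert tom[0, 2] == 0.0


def test_tom_zero_matrix():
    tom = compute_tom(np.zeros((4, 4)))
    assert np.allclose(tom - np.eye(4), 0.0)


def test_tom_rejects_invalid_adjacency():
    with pytest.raises(ValueError):
        compute_tom(np.full((3, 3), 1.5))


@given(arrays(np.float64, (6, 6), elements=st.floats(0, 1)))
def test_tom_bounded_and_symmetric(raw):
    a = (raw + raw.T) / 2
    np.fill_diagonal(a, 0.0)
    tom = compute_tom(a)
    assert np.allclose(tom, tom.T)
    assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12


def _block_data(rng, sizes=(10, 10), r=0.9, n=120):
    cols, truth = [], []
    for b, size in enumerate(sizes):
        driver = rng.normal(size=n)
        for _ in range(size):
            noise_sd = np.sqrt(1 / r - 1)
            cols.append(driver + rng.normal(0, noise_sd, n))
            truth.append(b)
    names = [f"PC(16:{i % 2}/18:1)x{i}" for i in range(len(cols))]
    data = pd.DataFrame(np.array(cols).T, columns=names)
    return data, np.array(truth), names


def test_module_detection_recovers_planted_blocks():
    rng = np.random.default_rng(0)
    data, truth, names = _block_data(rng)
    corr = np.abs(np.corrcoef(data.to_numpy().T))
    np.fill_diagonal(corr, 0.0)
    adj = corr ** 6
    tom = compute_tom(adj)
    modules, unassigned = detect_modules(1.0 - tom, names, min_size=5)
    assert len(modules) == 2
    assert not unassigned
    for mod in modules:
        labels = {truth[names.index(m)] for m in mod.members}
        assert len(labels) == 1  # each module is one planted block


def test_small_cluster_goes_unassigned():
    rng = np.random.default_rng(1)
    data, truth, names = _block_data(rng, sizes=(10, 4))
    corr = np.abs(np.corrcoef(data.to_numpy().T))
    np.fill_diagonal(corr, 0.0)
    tom = compute_tom(corr ** 6)
    modules, unassigned = detect_modules(1.0 - tom, names, min_size=5)
    assert len(modules) == 1
    assert len(unassigned) == 4


def test_soft_threshold_chooses_smallest_passing_power():
    rng = np.random.default_rng(2)
    data, _, _ = _block_data(rng, sizes=(8, 8, 8, 8), r=0.6, n=150)
    corr = np.abs(np.corrcoef(data.to_numpy().T))
    np.fill_diagonal(corr, 0.0)
    scan = pick_soft_threshold(corr)
    if not scan.warning:
        passing = [b for b, r2 in zip(scan.powers, scan.r_squared) if r2 >= 0.8]
        assert scan.chosen_power == passing[0]
    else:
        assert scan.chosen_power == \
            scan.powers[int(np.argmax(scan.r_squared))]


def test_soft_threshold_uniform_correlations_warns():
    corr = np.full((20, 20), 0.5)
    np.fill_diagonal(corr, 0.0)
    scan = pick_soft_threshold(corr)
    assert scan.warning


def test_soft_threshold_too_few_species():
    with pytest.raises(ValueError):
        pick_soft_threshold(np.zeros((2, 2)))


def test_eigengene_sign_oriented():
    rng = np.random.default_rng(3)
    driver = rng.normal(size=60)
    data = pd.DataFrame({f"s{i}": driver + rng.normal(0, 0.3, 60)
                         for i in range(6)})
    e = module_eigengene(data)
    assert np.corrcoef(e, data.mean(axis=1))[0, 1] > 0.9


def test_merge_modules_threshold_and_chain():
    rng = np.random.default_rng(4)
    d1 = rng.normal(size=80)
    d2 = 0.93 * d1 + np.sqrt(1 - 0.93 ** 2) * rng.normal(size=80)
    d3 = rng.normal(size=80)
    data = {}
    for name, drv in (("a", d1), ("b", d2), ("c", d3)):
        for i in range(5):
            data[f"{name}{i}"] = drv + rng.normal(0, 0.1, 80)
    df = pd.DataFrame(data)
    modules = [CoModule("M1", [f"a{i}" for i in range(5)]),
               CoModule("M2", [f"b{i}" for i in range(5)]),
               CoModule("M3", [f"c{i}" for i in range(5)])]
    merged = merge_modules(modules, df, cor_threshold=0.8)
    sizes = sorted(len(m.members) for m in merged)
    assert sizes == [5, 10]  # correlated pair merged, independent kept


def test_merge_terminates_and_decreases():
    rng = np.random.default_rng(5)
    drv = rng.normal(size=50)
    df = pd.DataFrame({f"s{i}": drv + rng.normal(0, 0.05, 50)
                       for i in range(9)})
    mods = [CoModule(f"M{k}", [f"s{3 * k + i}" for i in range(3)])
            for k in range(3)]
    merged = merge_modules(mods, df, cor_threshold=0.8)
    assert len(merged) == 1  # chain collapses via iterative recompute


def test_module_clinical_partial_correlation():
    rng = np.random.default_rng(6)
    n = 150
    bmi = rng.normal(size=n)
    covariates = pd.DataFrame({"sex": rng.choice(["M", "F"], n),
                               "age": rng.normal(50, 8, n),
                               "ethnicity": rng.choice(["A", "B"], n),
                               "bmi": bmi})
    signal = rng.normal(size=n)
    eig = pd.DataFrame({"M1": signal + 0.8 * bmi,
                        "M2": 0.9 * bmi + 0.1 * rng.normal(size=n)})
    clinical = pd.DataFrame({"meas": signal + 0.8 * bmi + 0.05 * rng.normal(size=n),
                             "bmi_driven": 0.9 * bmi + 0.1 * rng.normal(size=n),
                             "flat": np.ones(n)})
    res = module_clinical_correlation(eig, clinical, covariates)
    r_true = res.set_index(["module", "measure"]).loc[("M1", "meas"), "partial_r"]
    r_conf = res.set_index(["module", "measure"]).loc[("M2", "bmi_driven"), "partial_r"]
    assert r_true > 0.95
    assert abs(r_conf) < 0.3  # association vanishes after residualizing BMI
    flat = res[res["measure"] == "flat"]
    assert flat["flag"].eq("constant_or_sparse").all()
    assert (res["fdr"].dropna() >= res.loc[res["fdr"].notna(), "p"] - 1e-12).all()
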