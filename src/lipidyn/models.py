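"""Association layers: SSPG, infection, cytokine-lipid, ageing, IR/IS contrasts.

All layers work on log-transformed concentrations and return tidy result
tables with coefficient, standard error, p-value and BH FDR computed within
the declared hypothesis family:

* SSPG: one sample per participant at the SSPG visit, so the participant
  random intercept is unidentifiable and the model reduces to OLS of the
  scaled log concentration on scaled SSPG plus age, sex, ethnicity and BMI
  (FDR < 5%).
* Infection: per species, log concentration on event phase (baseline/early/
  late/recovery) plus covariates with a participant random intercept; the
  overall phase effect is a likelihood-ratio test against the phase-free
  model (FDR < 10%).
* Cytokine-lipid: scaled cytokine on scaled lipid plus BMI, sex, ethnicity
  with a participant random intercept (ML, Wald p on the lipid coefficient,
  FDR < 5%); surviving pairs form the cytokine network edge list.
* Ageing (delta-age): per participant, visit-minus-baseline changes in
  natural-log concentration regressed by OLS on years since baseline, BMI
  and storage length; at the class level species are summed untransformed
  first and the 5-year percent change is ``100 (exp(5 beta) - 1)``.
* IR/IS differential correlations: per (species, measure), Pearson r within
  each group compared by a Fisher z test; reported when FDR < 5% and
  ``|delta r| > 0.2``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import classify_tag_size, parse_lipid_name
from .lmm import fit_random_intercept, lrt

logger = logging.getLogger(__name__)

__all__ = [
    "classify_ir",
    "sspg_regression",
    "infection_differential",
    "cytokine_lipid_lmm",
    "delta_age_model",
    "differential_correlation",
    "detailed_class",
]

SSPG_IR_THRESHOLD = 150.0  # mg/dl; IR strictly above, IS at or below


def classify_ir(sspg: float) -> str:
    """Insulin resistance status from steady-state plasma glucose (mg/dl)."""
    return "IR" if sspg > SSPG_IR_THRESHOLD else "IS"


def _zscore(x: np.ndarray) -> np.ndarray:
    s = np.nanstd(x)
    return (x - np.nanmean(x)) / (s if s > 0 else 1.0)


def _covariate_design(meta: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Intercept + numeric/z-scaled and dummy-coded covariate columns."""
    parts = [np.ones(len(meta))]
    for col in columns:
        v = meta[col]
        if v.dtype == object or str(v.dtype) == "category" or v.dtype == bool:
            dummies = pd.get_dummies(v, drop_first=True).astype(float)
            for c in dummies.columns:
                parts.append(dummies[c].to_numpy())
        else:
            x = v.to_numpy(dtype=float)
            if np.nanstd(x) > 0:  # constant covariates add nothing
                parts.append(_zscore(x))
    return np.column_stack(parts)


def _ols_by_species(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of Y on the shared design X.

    Returns (beta, se, p) for every coefficient: arrays (p_coef, n_species).
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, pvals


def sspg_regression(
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-species association of log concentration with SSPG.

    ``conc`` holds untransformed concentrations of the SSPG-visit samples
    (one per participant); ``metadata`` must carry ``sspg``, ``age``,
    ``sex``, ``ethnicity`` and ``bmi``.
    """
    meta = metadata.loc[conc.index]
    cov = _covariate_design(meta, ["age", "sex", "ethnicity", "bmi"])
    sspg = _zscore(meta["sspg"].to_numpy(dtype=float))
    X = np.column_stack([cov, sspg])
    logY = np.log(conc.to_numpy(dtype=float))
    keep = [i for i in range(logY.shape[1]) if np.ptp(logY[:, i]) > 0
            and np.isfinite(logY[:, i]).all()]
    skipped = [conc.columns[i] for i in range(logY.shape[1]) if i not in keep]
    if skipped:
        logger.info("skipping %d constant/incomplete species", len(skipped))
    Y = np.column_stack([_zscore(logY[:, i]) for i in keep])
    beta, se, p = _ols_by_species(Y, X)
    idx = X.shape[1] - 1  # SSPG coefficient
    out = pd.DataFrame({
        "species": [conc.columns[i] for i in keep],
        "beta": beta[idx], "se": se[idx], "p": p[idx],
        "n": len(conc), "model": "sspg_ols",
    })
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def infection_differential(
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-species differential abundance across infection phases.

    ``metadata`` must carry ``participant``, ``phase`` (baseline/early/late/
    recovery), ``sex``, ``ethnicity``, ``age``, ``bmi``.  The overall phase
    effect is a likelihood-ratio test of the mixed model with phase terms
    against the phase-free model; with a single participant the random
    intercept collapses and the fit degenerates to OLS-like behaviour.
    """
    meta = metadata.loc[conc.index].copy()
    phase = meta["phase"].replace({"pre_baseline": "baseline",
                                   "post_baseline": "baseline"})
    phases = [p for p in ["early", "late", "recovery"] if (phase == p).any()]
    if len(phases) + 1 < 2 or phase.nunique() < 2:
        raise ValueError("need >= 2 phases observed")
    if meta["participant"].nunique() < 2:
        logger.warning("single participant: random intercept degenerate")
    cov = _covariate_design(meta, ["sex", "ethnicity", "age", "bmi"])
    phase_cols = np.column_stack([(phase == p).to_numpy(float) for p in phases])
    X_full = np.column_stack([cov, phase_cols])
    groups = meta["participant"].to_numpy()
    rows = []
    for sp in conc.columns:
        y = np.log(conc[sp].to_numpy(dtype=float))
        if not np.isfinite(y).all() or np.ptp(y) == 0:
            continue
        y = _zscore(y)
        full = fit_random_intercept(y, X_full, groups)
        reduced = fit_random_intercept(y, cov, groups)
        p = lrt(full, reduced, df=len(phases))
        effects = {f"beta_{ph}": full.beta[cov.shape[1] + i]
                   for i, ph in enumerate(phases)}
        rows.append({"species": sp, "p": p, "n": full.n,
                     "model": "infection_lmm_lrt", **effects})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def cytokine_lipid_lmm(
    cytokines: pd.DataFrame,
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr_threshold: float = 0.05,
    max_cytokine_missing: float = 0.5,
) -> pd.DataFrame:
    """Mixed-model association of each cytokine with each lipid.

    Scaled cytokine on scaled log lipid + BMI + sex + ethnicity with a
    participant random intercept, fitted by ML; Wald p on the lipid
    coefficient; BH at 5% across all pairs.  Pairs surviving FDR form the
    network edge list (columns ``source``, ``target``, ``beta``).
    """
    meta = metadata.loc[conc.index]
    cov = _covariate_design(meta, ["bmi", "sex", "ethnicity"])
    groups = meta["participant"].to_numpy()
    lipid_z = {sp: _zscore(np.log(conc[sp].to_numpy(dtype=float)))
               for sp in conc.columns}
    rows = []
    for cyt in cytokines.columns:
        yraw = cytokines[cyt].reindex(conc.index).to_numpy(dtype=float)
        miss = ~np.isfinite(yraw)
        if miss.mean() > max_cytokine_missing:
            logger.info("cytokine %s missing in %.0f%% of samples; skipped",
                        cyt, 100 * miss.mean())
            continue
        ok = ~miss
        y = _zscore(yraw[ok])
        for sp, lz in lipid_z.items():
            X = np.column_stack([cov[ok], lz[ok]])
            fit = fit_random_intercept(y, X, groups[ok])
            idx = X.shape[1] - 1
            rows.append({"cytokine": cyt, "species": sp,
                         "beta": fit.beta[idx], "se": fit.se[idx],
                         "p": fit.wald_p(idx), "n": fit.n,
                         "model": "cytokine_lmm"})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def detailed_class(species: str) -> str:
    """Subclass label with small/large TAG kept distinct."""
    sp = parse_lipid_name(species)
    if sp.subclass == "TAG":
        return f"{classify_tag_size(sp.total_carbons)} TAG"
    return sp.subclass


def delta_age_model(
    conc: pd.DataFrame,
    metadata: pd.DataFrame,
    stratum: str = "all",
    level: str = "species",
    max_delta_years: float = 5.0,
    exclude_top_participant: bool = True,
) -> pd.DataFrame:
    """Ageing (delta-age) model on baseline-subtracted log concentrations.

    Per participant the baseline is the first recorded visit; each later
    visit contributes ``delta ln(conc)`` regressed by OLS on years since
    baseline, BMI and storage length.  Samples more than ``max_delta_years``
    after baseline are excluded, as is the participant with a uniquely large
    number of samples.  ``stratum`` restricts the rows (all/male/female/
    IR/IS); ``level`` is ``species`` or ``class`` (summed untransformed
    concentrations per detailed subclass before the log).
    """
    meta = metadata.loc[conc.index].copy()
    if stratum == "male":
        sel = meta["sex"] == "M"
    elif stratum == "female":
        sel = meta["sex"] == "F"
    elif stratum == "IR":
        sel = meta["ir_status"] == "IR"
    elif stratum == "IS":
        sel = meta["ir_status"] == "IS"
    elif stratum == "all":
        sel = pd.Series(True, index=meta.index)
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    meta = meta.loc[sel]
    mat = conc.loc[meta.index]

    if level == "class":
        grouped = {}
        for sp in mat.columns:
            grouped.setdefault(detailed_class(sp), []).append(sp)
        mat = pd.DataFrame({cls: mat[cols].sum(axis=1)
                            for cls, cols in sorted(grouped.items())})

    if exclude_top_participant:
        counts = meta["participant"].value_counts()
        if len(counts) > 1 and counts.iloc[0] > counts.iloc[1]:
            drop = counts.index[0]
            keep = meta["participant"] != drop
            meta, mat = meta.loc[keep], mat.loc[keep]
            logger.info("excluded participant %s with uniquely many samples",
                        drop)

    rows_y, rows_x = [], []
    names = list(mat.columns)
    for pid, grp in meta.groupby("participant"):
        grp = grp.sort_values("years_since_baseline")
        base_idx = grp.index[0]
        base = np.log(mat.loc[base_idx].to_numpy(dtype=float))
        base_years = grp["years_since_baseline"].iloc[0]
        for sid in grp.index[1:]:
            dy = grp.loc[sid, "years_since_baseline"] - base_years
            if dy > max_delta_years:
                continue
            rows_y.append(np.log(mat.loc[sid].to_numpy(dtype=float)) - base)
            rows_x.append([dy, meta.loc[sid, "bmi"],
                           meta.loc[sid, "storage_length"]])
    if not rows_y:
        raise ValueError("no delta rows: every participant has a single visit")
    Y = np.asarray(rows_y)
    Xr = np.asarray(rows_x, dtype=float)
    X = np.column_stack([np.ones(len(Xr)), Xr])
    beta, se, p = _ols_by_species(Y, X)
    out = pd.DataFrame({
        "feature": names,
        "beta": beta[1], "se": se[1], "p": p[1],
        "n": len(Y), "stratum": stratum, "level": level,
        "model": "delta_age_ols",
    })
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    if level == "class":
        out["percent_change_5yr"] = 100.0 * (np.exp(5.0 * out["beta"]) - 1.0)
    return out


def differential_correlation(
    conc: pd.DataFrame,
    clinical: pd.DataFrame,
    ir_is_labels: pd.Series,
    fdr_threshold: float = 0.05,
    min_group_n: int = 10,
    delta_r_threshold: float = 0.2,
) -> pd.DataFrame:
    """IR-vs-IS contrast of lipid-clinical correlations (healthy samples).

    Both sides are standardized; Pearson r is computed within each group and
    the difference tested by the two-sided Fisher z test.  A pair is reported
    when its BH FDR < 5% and ``|r_IR - r_IS| > 0.2``; the pooled correlation
    over both groups is returned as reference.
    """
    labels = ir_is_labels.loc[conc.index]
    masks = {g: (labels == g).to_numpy() for g in ("IR", "IS")}
    for g, m in masks.items():
        if m.sum() < min_group_n:
            raise ValueError(f"group {g} has fewer than {min_group_n} samples")
    logc = np.log(conc.to_numpy(dtype=float))
    logc = (logc - logc.mean(axis=0)) / np.where(logc.std(axis=0) == 0, 1,
                                                 logc.std(axis=0))
    clin = clinical.loc[conc.index].to_numpy(dtype=float)
    clin = (clin - np.nanmean(clin, axis=0)) / np.where(
        np.nanstd(clin, axis=0) == 0, 1, np.nanstd(clin, axis=0))
    rows = []
    for i, sp in enumerate(conc.columns):
        for j, meas in enumerate(clinical.columns):
            rs = {}
            skip = False
            for g, m in masks.items():
                x, y = logc[m, i], clin[m, j]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_group_n or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    skip = True
                    break
                rs[g] = (float(np.corrcoef(x[ok], y[ok])[0, 1]), int(ok.sum()))
            if skip:
                continue
            (r_ir, n_ir), (r_is, n_is) = rs["IR"], rs["IS"]
            z = ((np.arctanh(np.clip(r_ir, -0.999999, 0.999999))
                  - np.arctanh(np.clip(r_is, -0.999999, 0.999999)))
                 / np.sqrt(1 / (n_ir - 3) + 1 / (n_is - 3)))
            p = float(2 * stats.norm.sf(abs(z)))
            both = masks["IR"] | masks["IS"]
            x, y = logc[both, i], clin[both, j]
            ok = np.isfinite(x) & np.isfinite(y)
            overall = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"species": sp, "measure": meas, "r_IR": r_ir,
                         "r_IS": r_is, "delta_r": r_ir - r_is, "p": p,
                         "overall_r": overall})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["reported"] = (out["fdr"] < fdr_threshold) & (
        out["delta_r"].abs() > delta_r_threshold)
    return out
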