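"""Co-abundance lipid modules: soft threshold, topological overlap, clustering.

A weighted, unsigned correlation network is built on log-transformed healthy
samples: adjacency ``a = |r|^beta`` with the soft-threshold power chosen as
the smallest beta achieving approximate scale-free topology (R^2 >= 0.8 for
the log-log fit of the connectivity distribution).  Topological overlap
converts shared-neighbour structure into a similarity; modules are branches of
an average-linkage dendrogram of ``1 - TOM`` with a minimum size of 5,
summarized by their eigengene (first principal component of the standardized
member profiles) and merged when eigengenes correlate above 0.8.  Module
eigengenes are then correlated with clinical measures, partialling out sex,
age, ethnicity and BMI, with BH correction across all module x measure pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdScan",
    "CoModule",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "module_clinical_correlation",
]


@dataclass
class SoftThresholdScan:
    powers: list[int]
    r_squared: list[float]
    mean_connectivity: list[float]
    chosen_power: int
    warning: str = ""


def _scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k fit over equal-count bins."""
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return 0.0
    order = np.sort(k)
    edges = np.quantile(order, np.linspace(0, 1, n_bins + 1))
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (k >= lo) & (k <= hi) if hi == edges[-1] else (k >= lo) & (k < hi)
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r ** 2)


def pick_soft_threshold(
    corr_abs: pd.DataFrame | np.ndarray,
    powers: range = range(1, 21),
    r2_target: float = 0.8,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    Chooses the smallest power with fit R^2 >= 0.8; if none reaches the
    target, the power maximizing R^2 is chosen with a warning.
    """
    c = np.asarray(corr_abs, dtype=float)
    if c.shape[0] < 3:
        raise ValueError("need >= 3 species")
    r2s, ks = [], []
    for beta in powers:
        a = c ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2s.append(_scale_free_r2(k))
        ks.append(float(k.mean()))
    warning = ""
    chosen = None
    for beta, r2 in zip(powers, r2s):
        if r2 >= r2_target:
            chosen = beta
            break
    if chosen is None:
        chosen = list(powers)[int(np.argmax(r2s))]
        warning = f"no power reached R^2 >= {r2_target}; using argmax"
        logger.warning(warning)
    return SoftThresholdScan(list(powers), r2s, ks, chosen, warning)


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    unit diagonal; symmetric with entries in [0, 1] for any valid adjacency
    (symmetric, entries in [0, 1], zero diagonal).
    """
    a = np.asarray(adjacency, dtype=float)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class CoModule:
    """A co-abundance module with its eigengene."""

    module_id: str
    members: list[str]
    eigengene: pd.Series = field(default=None, repr=False)


def detect_modules(
    dissimilarity: np.ndarray,
    species: list[str],
    min_size: int = 5,
) -> tuple[list[CoModule], list[str]]:
    """Cut an average-linkage dendrogram of ``1 - TOM`` into modules.

    The cut height is chosen from a fixed grid of 99 quantile steps of the
    merge heights, maximizing the number of clusters with at least
    ``min_size`` members (ties resolved toward the lower height).  Clusters
    below the minimum size form the unassigned pool.
    """
    d = np.asarray(dissimilarity, dtype=float)
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    heights = link[:, 2]
    grid = np.quantile(heights, np.linspace(0.01, 0.99, 99))
    best = None
    for h in sorted(set(grid)):
        labels = hierarchy.fcluster(link, t=h, criterion="distance")
        sizes = np.bincount(labels)
        n_big = int((sizes >= min_size).sum())
        n_unassigned = int(sizes[sizes < min_size].sum())
        score = (n_big, -n_unassigned)
        if best is None or score > best[0]:
            best = (score, h, labels)
    _, _, labels = best
    modules = []
    unassigned: list[str] = []
    idx = 1
    for lab in np.unique(labels):
        members = [species[i] for i in np.flatnonzero(labels == lab)]
        if len(members) >= min_size:
            modules.append(CoModule(f"M{idx}", sorted(members)))
            idx += 1
        else:
            unassigned.extend(members)
    return modules, sorted(unassigned)


def module_eigengene(profiles: pd.DataFrame) -> pd.Series:
    """First principal component of z-scaled member profiles (samples score).

    Sign is oriented to correlate positively with the mean member profile.
    """
    x = profiles.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    pc = u[:, 0] * s[0]
    mean_profile = x.mean(axis=1)
    if np.corrcoef(pc, mean_profile)[0, 1] < 0:
        pc = -pc
    return pd.Series(pc, index=profiles.index)


def merge_modules(
    modules: list[CoModule],
    data: pd.DataFrame,
    cor_threshold: float = 0.8,
) -> list[CoModule]:
    """Iteratively merge the most-correlated eigengene pair above threshold.

    After each merge the combined eigengene is recomputed; iteration stops at
    a fixpoint (module count strictly decreases on every merge, so it
    terminates).
    """
    mods = [CoModule(m.module_id, list(m.members),
                     module_eigengene(data[m.members])) for m in modules]
    while len(mods) > 1:
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = np.corrcoef(mods[i].eigengene, mods[j].eigengene)[0, 1]
                if r > cor_threshold and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        members = sorted(mods[i].members + mods[j].members)
        merged = CoModule(mods[i].module_id, members,
                          module_eigengene(data[members]))
        mods = [m for k, m in enumerate(mods) if k not in (i, j)] + [merged]
    mods.sort(key=lambda m: m.module_id)
    for idx, m in enumerate(mods, start=1):
        m.module_id = f"M{idx}"
    return mods


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def module_clinical_correlation(
    eigengenes: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Partial Pearson correlation of eigengenes with clinical measures.

    Both sides are residualized on the covariates (categorical columns are
    dummy-coded); BH correction spans all module x measure pairs.  Constant
    measures are skipped with a flag row (NaN correlation).
    """
    from scipy import stats as sps

    cov = pd.get_dummies(covariates, drop_first=True).astype(float).to_numpy()
    rows = []
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy(dtype=float)
        e_res = _residualize(e, cov)
        for meas in clinical.columns:
            y = clinical[meas].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if np.ptp(y[ok]) == 0 or ok.sum() < 3:
                rows.append((mod, meas, np.nan, np.nan, "constant_or_sparse"))
                continue
            y_res = _residualize(y[ok], cov[ok])
            r, p = sps.pearsonr(e_res[ok], y_res)
            rows.append((mod, meas, r, p, ""))
    out = pd.DataFrame(rows, columns=["module", "measure", "partial_r", "p", "flag"])
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
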