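"""QC precision estimation, filtering and left-censored imputation.

Coefficients of variation are computed on untransformed, non-imputed
concentrations: per species in the QC pool (technical CV), per participant
across visits (intra-participant CV, summarized as the median over eligible
participants) and across all biosamples (inter CV).  Filtering drops
biosamples with >25% missing values, species with <10% valid values, species
whose QC CV exceeds 20% or exceeds their biosample CV, the classes that the
platform cannot separate reliably (PA/LPA, PS/LPS, PG/LPG) and individually
excluded species.

Missing lipid values are left-censored (signal below the class detection
limit), so they are imputed from a truncated normal: the per-species
conditional expectation below the class detection limit, shifted by the
median offset of the k nearest neighbour samples and clipped at the limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import EXCLUDED_CLASSES, parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "CVReport",
    "FilterReport",
    "FilterThresholds",
    "ImputationModel",
    "EXCLUDED_SPECIES",
    "compute_cv",
    "apply_filters",
    "class_detection_limits",
    "impute_truncated_knn",
    "impute_adjacent_mean",
]

#: Species excluded individually (incorrect transition masses on the platform).
EXCLUDED_SPECIES = ("PI(16:0/18:3)",)


def _cv(values: np.ndarray) -> float:
    """100 * sample sd / mean; NaN if <2 values or zero mean."""
    values = values[np.isfinite(values)]
    if values.size < 2:
        return np.nan
    m = values.mean()
    if m == 0:
        return np.nan
    return 100.0 * values.std(ddof=1) / m


@dataclass
class CVReport:
    """Per-species CVs (%) on untransformed, non-imputed concentrations."""

    cv_qc: pd.Series
    cv_intra: pd.Series  # median over eligible participants
    cv_inter: pd.Series  # pooled over biosamples
    n_participants_used: pd.Series


def compute_cv(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    min_timepoints: int = 3,
    min_quantifications: int = 3,
) -> CVReport:
    """Compute QC, intra-participant and inter (biosample) CVs per species.

    ``metadata`` is indexed by sample id with columns ``participant``,
    ``is_qc`` and ``collection_date``.  Same-day duplicate samples of a
    participant are excluded from the intra CV; participants need at least
    ``min_timepoints`` sampling timepoints and a species at least
    ``min_quantifications`` observed values within a participant to
    contribute.
    """
    meta = metadata.loc[matrix.index]
    qc_mask = meta["is_qc"].astype(bool)
    qc = matrix.loc[qc_mask]
    bio = matrix.loc[~qc_mask]

    cv_qc = qc.apply(lambda s: _cv(s.to_numpy()), axis=0)
    cv_inter = bio.apply(lambda s: _cv(s.to_numpy()), axis=0)

    intra_rows = {}
    n_used = {}
    bio_meta = meta.loc[~qc_mask]
    for pid, grp in bio_meta.groupby("participant"):
        # same-day duplicates excluded: keep the first sample per date
        dedup = grp.drop_duplicates(subset="collection_date", keep="first")
        if len(dedup) < min_timepoints:
            continue
        sub = matrix.loc[dedup.index]
        enough = sub.notna().sum(axis=0) >= min_quantifications
        cvs = sub.apply(lambda s: _cv(s.to_numpy()), axis=0)
        intra_rows[pid] = cvs.where(enough)
    if intra_rows:
        intra_table = pd.DataFrame(intra_rows).T
        cv_intra = intra_table.median(axis=0)
        n_used = intra_table.notna().sum(axis=0)
    else:
        cv_intra = pd.Series(np.nan, index=matrix.columns)
        n_used = pd.Series(0, index=matrix.columns)
    return CVReport(cv_qc=cv_qc, cv_intra=cv_intra, cv_inter=cv_inter,
                    n_participants_used=pd.Series(n_used))


@dataclass(frozen=True)
class FilterThresholds:
    max_sample_missing: float = 0.25
    min_valid_fraction: float = 0.10
    max_qc_cv: float = 20.0  # percent

    def __post_init__(self) -> None:
        if not 0 < self.max_sample_missing < 1:
            raise ValueError("max_sample_missing must be in (0,1)")
        if not 0 < self.min_valid_fraction < 1:
            raise ValueError("min_valid_fraction must be in (0,1)")
        if not 0 < self.max_qc_cv < 100:
            raise ValueError("max_qc_cv must be in (0,100)")


@dataclass
class FilterReport:
    """Dropped samples/species with reasons, and the retained robust set."""

    dropped_samples: pd.DataFrame  # sample_id, reason
    dropped_species: pd.DataFrame  # species, reason
    robust_species: list[str]
    order: tuple[str, ...] = (
        "sample_missingness", "species_validity", "robust_cv",
        "excluded_class", "excluded_species",
    )

    def to_frame(self) -> pd.DataFrame:
        a = self.dropped_samples.assign(kind="sample").rename(
            columns={"sample_id": "item"})
        b = self.dropped_species.assign(kind="species").rename(
            columns={"species": "item"})
        return pd.concat([a, b], ignore_index=True)[["kind", "item", "reason"]]


def apply_filters(
    matrix: pd.DataFrame,
    cv_report: CVReport,
    thresholds: FilterThresholds = FilterThresholds(),
    qc_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the sample/species filters in a fixed order.

    Order: (1) biosamples with more than 25% missing values; (2) species with
    fewer than 10% valid values; (3) the robust-CV rule (QC CV <= 20% and
    QC CV < biosample CV) defines the retained robust set; (4) excluded
    classes (PA/LPA, PS/LPS, PG/LPG) and excluded species.  Steps 1, 2 and 4
    remove rows/columns; step 3 marks species outside the robust set as
    dropped with reason but they are removed as well, so the returned matrix
    is the robust analysis set.
    """
    qc_set = set(qc_samples or [])
    dropped_samples = []
    dropped_species = []

    bio_rows = [s for s in matrix.index if s not in qc_set]
    miss = matrix.loc[bio_rows].isna().mean(axis=1)
    bad_samples = miss[miss > thresholds.max_sample_missing].index
    for s in bad_samples:
        dropped_samples.append((s, "high_missingness"))
    out = matrix.drop(index=bad_samples)

    valid = out.notna().mean(axis=0)
    low_valid = valid[valid < thresholds.min_valid_fraction].index
    for sp in low_valid:
        dropped_species.append((sp, "low_validity"))
    out = out.drop(columns=low_valid)

    for sp in out.columns:
        cv_qc = cv_report.cv_qc.get(sp, np.nan)
        cv_bio = cv_report.cv_inter.get(sp, np.nan)
        if np.isfinite(cv_qc) and cv_qc > thresholds.max_qc_cv:
            dropped_species.append((sp, "high_qc_cv"))
        elif np.isfinite(cv_qc) and np.isfinite(cv_bio) and cv_qc >= cv_bio:
            dropped_species.append((sp, "qc_cv_exceeds_bio_cv"))
    cv_dropped = [sp for sp, r in dropped_species
                  if r in ("high_qc_cv", "qc_cv_exceeds_bio_cv")]
    out = out.drop(columns=cv_dropped)

    for sp in list(out.columns):
        if parse_lipid_name(sp).subclass in EXCLUDED_CLASSES:
            dropped_species.append((sp, "excluded_class"))
            out = out.drop(columns=sp)
        elif sp in EXCLUDED_SPECIES:
            dropped_species.append((sp, "excluded_species"))
            out = out.drop(columns=sp)

    report = FilterReport(
        dropped_samples=pd.DataFrame(dropped_samples,
                                     columns=["sample_id", "reason"]),
        dropped_species=pd.DataFrame(dropped_species,
                                     columns=["species", "reason"]),
        robust_species=list(out.columns),
    )
    logger.info("filtering dropped %d samples, %d species; %d species retained",
                len(dropped_samples), len(dropped_species), out.shape[1])
    return out, report


def class_detection_limits(matrix: pd.DataFrame) -> dict[str, float]:
    """Per-class detection limit: minimum observed untransformed concentration."""
    limits: dict[str, float] = {}
    for sp in matrix.columns:
        cls = parse_lipid_name(sp).subclass
        observed = matrix[sp].dropna()
        observed = observed[observed > 0]
        if observed.empty:
            continue
        m = float(observed.min())
        limits[cls] = min(limits.get(cls, np.inf), m)
    return limits


@dataclass
class ImputationModel:
    """Truncated-KNN imputation parameters."""

    k: int = 10
    seed: int = 0
    detection_limits: dict[str, float] = field(default_factory=dict)


def _truncated_mean_sd(mu: float, sigma: float, upper: float
                       ) -> tuple[float, float]:
    """Mean and sd of X | X <= upper for X ~ N(mu, sigma^2)."""
    if sigma <= 0:
        return min(mu, upper), 0.0
    alpha = (upper - mu) / sigma
    phi = stats.norm.pdf(alpha)
    big_phi = stats.norm.cdf(alpha)
    if big_phi <= 1e-300:
        return upper, 0.0
    lam = phi / big_phi
    mean = mu - sigma * lam
    var = max(1.0 - alpha * lam - lam ** 2, 0.0)
    return mean, sigma * np.sqrt(var)


def impute_truncated_knn(
    matrix: pd.DataFrame,
    model: ImputationModel | None = None,
) -> pd.DataFrame:
    """Impute left-censored values from a truncated normal plus KNN offsets.

    For each missing cell the base imputation is the conditional expectation
    of the species' fitted log-normal below the class detection limit D_c.
    The k nearest neighbour samples (Euclidean distance on z-scaled, shared
    observed log concentrations) that observe the species shift the base by
    the median of their standardized residuals scaled to the sd of the
    censored tail, after which the value is clipped at log D_c and
    exponentiated.  Species with fewer than three
    observations fall back to a seeded uniform draw in [0.5 D_c, D_c].

    Deterministic given ``model.seed``.
    """
    model = model or ImputationModel()
    if model.k < 1:
        raise ValueError("k must be >= 1")
    limits = model.detection_limits or class_detection_limits(matrix)
    for cls, d in limits.items():
        if d <= 0:
            raise ValueError(f"detection limit for {cls} must be > 0")
    rng = np.random.default_rng(model.seed)

    with np.errstate(divide="ignore"):
        log = np.log(matrix.where(matrix > 0))
    mu = log.mean(axis=0)
    sigma = log.std(axis=0, ddof=1).fillna(0.0)
    z = (log - mu) / sigma.replace(0, 1.0)
    zv = z.to_numpy()
    out = matrix.copy()
    cls_of = {sp: parse_lipid_name(sp).subclass for sp in matrix.columns}
    col_idx = {sp: i for i, sp in enumerate(matrix.columns)}
    n_obs = log.notna().sum(axis=0)

    missing_cells = np.argwhere(matrix.isna().to_numpy())
    if missing_cells.size == 0:
        return out

    # pairwise sample distances on shared observed z-scores
    obs = np.isfinite(zv)
    n = zv.shape[0]
    dist = np.full((n, n), np.inf)
    for i in range(n):
        shared = obs[i] & obs
        diff = np.where(shared, zv[i] - np.nan_to_num(zv), np.nan)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = np.nansum(diff ** 2, axis=1) / cnt
        dist[i] = np.sqrt(d2)
        dist[i, i] = np.inf
        dist[i, cnt == 0] = np.inf

    for i, j in missing_cells:
        sp = matrix.columns[j]
        d_c = limits.get(cls_of[sp])
        if d_c is None:
            continue  # species never observed anywhere in its class
        log_d = np.log(d_c)
        if n_obs.iloc[j] < 3:
            out.iat[i, j] = float(rng.uniform(0.5 * d_c, d_c))
            logger.debug("%s: <3 observations, drew near detection limit", sp)
            continue
        base, tail_sd = _truncated_mean_sd(mu.iloc[j], sigma.iloc[j], log_d)
        order = np.argsort(dist[i], kind="stable")
        offsets = []
        for nb in order:
            if not np.isfinite(dist[i, nb]):
                break
            if np.isfinite(zv[nb, j]):
                offsets.append(zv[nb, j])
            if len(offsets) >= model.k:
                break
        if offsets:
            # neighbours rank the sample within the censored tail; the shift
            # is scaled by the tail sd so it cannot re-subtract the distance
            # to the detection bound already captured by the truncated mean
            base = base + float(np.median(offsets)) * tail_sd
        out.iat[i, j] = float(np.exp(min(base, log_d)))
    return out


def impute_adjacent_mean(series: pd.Series) -> pd.Series:
    """Fill gaps in a time-ordered series with the mean of adjacent values.

    Interior gaps take the mean of the nearest earlier and later observed
    values; leading/trailing gaps take the nearest observed value.  An
    all-missing series is returned unchanged with a warning.
    """
    if series.notna().sum() == 0:
        logger.warning("series all-missing; nothing to impute")
        return series.copy()
    fwd = series.ffill()
    bwd = series.bfill()
    return series.fillna((fwd + bwd) / 2).fillna(fwd).fillna(bwd)
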