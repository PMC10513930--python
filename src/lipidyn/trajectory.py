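"""Infection/vaccination event phases and lipid trajectory clustering.

Event samples are labelled by days since symptom onset: early phase days
1-6, late phase days 7-14, recovery phase days 15-35 (weeks 3-5); day 0 and
days beyond 35 are treated as healthy baseline on either side of the event.
Per-species trajectories (log2-transformed, z-scaled, phase-ordered) are
clustered with k-means; the cluster number is chosen by the elbow of the
minimum-centroid-distance curve, and cluster median profiles are correlated
with clinical measures under BH correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES",
    "assign_phase",
    "TrajectoryCluster",
    "cluster_trajectories",
    "cluster_clinical_correlation",
]

PHASES = ("pre_baseline", "early", "late", "recovery", "post_baseline")


def assign_phase(days_since_onset: int) -> str:
    """Event phase for a sample collected ``days_since_onset`` after onset."""
    if days_since_onset < 0:
        raise ValueError("days since onset must be >= 0")
    if days_since_onset == 0:
        return "pre_baseline"
    if days_since_onset <= 6:
        return "early"
    if days_since_onset <= 14:
        return "late"
    if days_since_onset <= 35:
        return "recovery"
    return "post_baseline"


@dataclass
class TrajectoryCluster:
    """One k-means trajectory cluster of significant species."""

    cluster_id: int
    members: list[str]
    median_profile: np.ndarray = field(default=None, repr=False)


def _min_centroid_distance(centroids: np.ndarray) -> float:
    d = pairwise_distances(centroids)
    iu = np.triu_indices_from(d, k=1)
    return float(d[iu].min())


def choose_elbow(ks: list[int], curve: list[float]) -> int:
    """Elbow of a decreasing minimum-centroid-distance curve.

    The curve collapses once k exceeds the number of underlying templates
    (two centroids then split one template), so the point of maximal
    convexity (largest second difference) sits one past the true k; the
    elbow is the k preceding it.
    """
    if len(ks) < 3:
        return ks[int(np.argmax(curve))] if curve else ks[0]
    c = np.asarray(curve)
    second = c[:-2] - 2 * c[1:-1] + c[2:]  # indexed by interior ks[1:-1]
    kink = ks[1 + int(np.argmax(second))]
    return max(kink - 1, ks[0])


def cluster_trajectories(
    z_profiles: pd.DataFrame,
    k_range: range = range(2, 9),
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[list[TrajectoryCluster], int, dict[int, float]]:
    """Cluster species trajectory profiles with elbow-selected k-means.

    ``z_profiles`` has one row per species (log2-transformed, z-scaled,
    phase-ordered values).  Per candidate k a seeded k-means with
    ``n_restarts`` restarts is fitted and the minimum pairwise centroid
    distance recorded; the final k is the elbow of that curve.  Degenerate
    all-identical profiles return a single cluster.
    """
    x = z_profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if np.allclose(x, x[0]):
        logger.warning("all profiles identical; single trajectory cluster")
        members = sorted(z_profiles.index)
        return ([TrajectoryCluster(1, members, np.median(x, axis=0))], 1, {})
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if list(k_range) != ks:
        logger.warning("k range truncated to %s for %d profiles", ks, n)
    curve: dict[int, float] = {}
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(x)
        curve[k] = _min_centroid_distance(km.cluster_centers_)
        fits[k] = km
    k_opt = choose_elbow(ks, [curve[k] for k in ks])
    labels = fits[k_opt].labels_
    clusters = []
    for cid in range(k_opt):
        members = sorted(z_profiles.index[labels == cid])
        profile = np.median(x[labels == cid], axis=0)
        clusters.append(TrajectoryCluster(cid + 1, members, profile))
    return clusters, k_opt, curve


def cluster_clinical_correlation(
    clusters: list[TrajectoryCluster],
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of cluster median profiles with clinical measures.

    ``clinical`` rows must align with the profile timepoints.  BH correction
    spans all cluster x measure pairs; constant measures are skipped.
    """
    rows = []
    for cl in clusters:
        prof = np.asarray(cl.median_profile, dtype=float)
        for meas in clinical.columns:
            y = clinical[meas].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(prof)
            if ok.sum() < 3 or np.ptp(y[ok]) == 0:
                logger.info("measure %s constant/sparse; skipped", meas)
                continue
            r, p = stats.pearsonr(prof[ok], y[ok])
            rows.append({"cluster": cl.cluster_id, "measure": meas,
                         "r": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
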