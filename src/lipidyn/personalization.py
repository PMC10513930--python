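"""Participant-specificity of lipid profiles.

How much of each lipid's variance is attributable to interparticipant
differences is estimated by a one-way random-intercept variance decomposition
(method-of-moments ANOVA estimator with the unbalanced-design correction) on
log-transformed healthy samples.  The most personalized lipids feed a t-SNE
embedding; intra-participant sample-pair distances are compared against
inter-participant centroid distances by a Welch t test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceDecomposition",
    "EmbeddingDistanceTest",
    "participant_variance",
    "select_personalized",
    "embedding_distance_test",
    "tsne_embedding",
]


@dataclass
class VarianceDecomposition:
    """Per-species participant/residual variance split."""

    var_participant: pd.Series
    var_residual: pd.Series
    fraction_explained: pd.Series
    flags: pd.Series  # "" | "constant"


def _icc_one_species(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float, str]:
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    uniq, inv = np.unique(groups, return_inverse=True)
    counts = np.bincount(inv)
    keep = counts[inv] >= 2
    values, inv = values[keep], inv[keep]
    uniq2, inv = np.unique(inv, return_inverse=True)
    counts = np.bincount(inv)
    a = counts.size
    n_total = values.size
    if a < 2 or n_total < 3:
        return np.nan, np.nan, np.nan, "insufficient"
    if np.ptp(values) == 0:
        return 0.0, 0.0, 0.0, "constant"
    grand = values.mean()
    means = np.bincount(inv, weights=values) / counts
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((values - means[inv]) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n_total - a)
    # unbalanced-design correction for the expected group size
    n0 = (n_total - (counts ** 2).sum() / n_total) / (a - 1)
    var_b = max((ms_between - ms_within) / n0, 0.0)
    var_e = ms_within
    denom = var_b + var_e
    frac = var_b / denom if denom > 0 else 0.0
    return var_b, var_e, frac, ""


def participant_variance(
    matrix_healthy: pd.DataFrame,
    participants: pd.Series,
) -> VarianceDecomposition:
    """Variance decomposition per species over healthy samples.

    ``matrix_healthy`` holds log-transformed concentrations; ``participants``
    maps each sample (row) to its participant.  Participants contributing
    fewer than two samples are ignored.
    """
    groups = participants.loc[matrix_healthy.index].to_numpy()
    var_b, var_e, frac, flags = {}, {}, {}, {}
    for sp in matrix_healthy.columns:
        b, e, f, flag = _icc_one_species(matrix_healthy[sp].to_numpy(), groups)
        var_b[sp], var_e[sp], frac[sp], flags[sp] = b, e, f, flag
    return VarianceDecomposition(
        var_participant=pd.Series(var_b),
        var_residual=pd.Series(var_e),
        fraction_explained=pd.Series(frac),
        flags=pd.Series(flags),
    )


def select_personalized(decomp: VarianceDecomposition, n: int = 100) -> list[str]:
    """Top-n species by participant-explained variance fraction.

    Ties are broken lexicographically by species name; asking for more
    species than available returns all with a warning.
    """
    frac = decomp.fraction_explained.dropna()
    if n > len(frac):
        logger.warning("requested %d species, only %d available", n, len(frac))
        n = len(frac)
    order = sorted(frac.index, key=lambda sp: (-frac[sp], sp))
    return order[:n]


@dataclass
class EmbeddingDistanceTest:
    """Intra sample-pair vs inter centroid-pair distances in an embedding."""

    intra: np.ndarray
    inter: np.ndarray
    t_statistic: float
    p_value: float


def embedding_distance_test(
    coords: np.ndarray,
    participant_labels: np.ndarray,
) -> EmbeddingDistanceTest:
    """Welch two-sided t test of intra- vs inter-participant distances.

    Intra distances are Euclidean distances over all same-participant sample
    pairs; inter distances are distances between participant centroids, one
    per participant pair.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(participant_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 participants")
    intra = []
    centroids = []
    for pid in uniq:
        pts = coords[labels == pid]
        centroids.append(pts.mean(axis=0))
        for i, j in itertools.combinations(range(len(pts)), 2):
            intra.append(np.linalg.norm(pts[i] - pts[j]))
    inter = [np.linalg.norm(a - b)
             for a, b in itertools.combinations(centroids, 2)]
    t, p = stats.ttest_ind(intra, inter, equal_var=False)
    return EmbeddingDistanceTest(np.asarray(intra), np.asarray(inter),
                                 float(t), float(p))


def tsne_embedding(
    matrix: pd.DataFrame,
    perplexity: float = 5.0,
    theta: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """2-D t-SNE of log2-transformed, z-scaled profiles (delegated to sklearn).

    ``theta`` is the Barnes–Hut trade-off parameter (``angle``).
    """
    from sklearn.manifold import TSNE

    x = np.log2(matrix.to_numpy())
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
    return TSNE(n_components=2, perplexity=perplexity, angle=theta,
                random_state=seed, init="pca").fit_transform(x)
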