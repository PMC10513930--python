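"""Spike-in based quantification of summarized MRM intensities.

Deuterated internal standards of known concentration (nmol/ml) anchor the
conversion of intensities to estimated concentrations: the analyte-to-spike
area ratio is multiplied by the spike's actual concentration.  Complex lipids
with two identical fatty acyls produce fragment-ion signal at twice the
intensity, so their analyte signal is halved before ratioing.

Standards that are themselves poorly detected (missingness > 5%) are
substituted by a same-class alternate.  Lipid classes acquired without a
class-matched standard (the additional method-3 classes) are normalized
against a surrogate standard chosen by a three-rule correlation hierarchy on
QC samples, and their absolute scale is estimated by regressing known
log-concentrations on log normalized intensities over the spike-quantified
lipids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeStandard",
    "SpikeAssignment",
    "SURROGATE_CANDIDATE_CLASSES",
    "MISSINGNESS_THRESHOLD",
    "estimate_concentration",
    "reassign_spikes",
    "select_surrogate_standard",
    "select_surrogate_standards",
    "regress_method3_concentration",
    "quantify",
]

#: Only standards of these classes may serve as surrogates for the
#: additional method-3 classes (they are acquired with DMS enabled).
SURROGATE_CANDIDATE_CLASSES = frozenset({"PC", "PE", "LPC", "LPE"})
#: Standards missing in strictly more than this fraction of samples are
#: substituted.
MISSINGNESS_THRESHOLD = 0.05
#: Minimum shared observations for a defined pairwise Pearson correlation.
MIN_SHARED_OBS = 3


@dataclass
class SpikeStandard:
    """One deuterated spike-in standard."""

    name: str
    subclass: str
    actual_concentration: float  # nmol/ml
    area_by_sample: pd.Series  # NaN where not quantified
    substitute_name: str | None = None

    def __post_init__(self) -> None:
        if self.actual_concentration <= 0:
            raise ValueError("actual concentration must be > 0")

    @property
    def missingness_rate(self) -> float:
        areas = self.area_by_sample
        return float(((areas.isna()) | (areas == 0)).mean())


@dataclass(frozen=True)
class SpikeAssignment:
    """Standard assigned to one species and the rule that produced it."""

    species: str
    standard: str
    rule_used: str  # class_default | reassigned | corr_rule_1 | corr_rule_2 | corr_rule_3
    correlation: float | None = None


def estimate_concentration(
    analyte_intensity: float,
    spike_intensity: float,
    spike_conc: float,
    identical_fa: bool = False,
) -> float:
    """Estimate a concentration (nmol/ml) from the analyte/spike area ratio.

    With ``identical_fa`` the analyte signal is halved first: fragment ions
    from the two identical acyls double the measured intensity.
    """
    if spike_conc <= 0:
        raise ValueError("spike concentration must be > 0")
    if not np.isfinite(spike_intensity) or spike_intensity <= 0:
        raise ValueError("spike intensity must be positive and finite")
    adjusted = analyte_intensity / 2.0 if identical_fa else analyte_intensity
    return (adjusted / spike_intensity) * spike_conc


def reassign_spikes(
    standards: list[SpikeStandard],
    substitution_table: dict[str, str] | None = None,
) -> dict[str, str]:
    """Map each standard to the standard actually used for quantification.

    Standards whose missingness rate strictly exceeds 5% are replaced by
    their same-class substitute; a rate of exactly 5% keeps the standard.

    Raises
    ------
    ValueError
        If a standard above threshold has no substitute, or the substitute
        belongs to a different class.
    """
    by_name = {s.name: s for s in standards}
    mapping: dict[str, str] = {}
    for std in standards:
        sub_name = std.substitute_name
        if substitution_table and std.name in substitution_table:
            sub_name = substitution_table[std.name]
        if std.missingness_rate > MISSINGNESS_THRESHOLD:
            if not sub_name:
                raise ValueError(
                    f"standard {std.name} missing in "
                    f"{std.missingness_rate:.0%} of samples but has no "
                    f"substitute"
                )
            sub = by_name.get(sub_name)
            if sub is not None and sub.subclass != std.subclass:
                raise ValueError(
                    f"substitute {sub_name} for {std.name} is not same-class")
            mapping[std.name] = sub_name
            logger.info("standard %s (missingness %.0f%%) substituted with %s",
                        std.name, 100 * std.missingness_rate, sub_name)
        else:
            mapping[std.name] = std.name
    return mapping


def _pairwise_r(x: pd.Series, y: pd.Series) -> float:
    """Pearson r over samples where both series are observed; NaN if <3."""
    both = x.notna() & y.notna()
    if both.sum() < MIN_SHARED_OBS:
        return np.nan
    xv, yv = x[both].to_numpy(), y[both].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def _rank_candidates(
    series: pd.Series,
    qc_log10: pd.DataFrame,
    candidates: list[str],
    completeness: pd.Series,
) -> tuple[str, float] | None:
    """Best-correlating eligible candidate; ties by completeness then name."""
    scored = []
    for cand in candidates:
        r = _pairwise_r(series, qc_log10[cand])
        if np.isnan(r):
            continue
        scored.append((r, completeness[cand], cand))
    if not scored:
        return None
    # highest r, then highest completeness, then lexicographically first name
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    r, _, cand = scored[0]
    return cand, r


def select_surrogate_standards(
    qc_log10: pd.DataFrame,
    species: list[str],
    species_class: dict[str, str],
    candidate_standards: list[str],
    standard_class: dict[str, str] | None = None,
) -> dict[str, SpikeAssignment]:
    """Assign surrogate standards to method-3 species via the rule hierarchy.

    ``qc_log10`` holds log10 intensities over QC samples, with one column per
    species and per candidate standard.  Rules, applied in order per species:

    1. among candidates with >= 50% complete QC observations, the one with the
       highest Pearson correlation to the species;
    2. else the standard selected (via rule 1) for the same-class species
       with which it correlates best;
    3. else the standard correlating best with any species across all the
       additional classes.

    Raises
    ------
    ValueError
        If no candidate standards are given.
    """
    if standard_class is not None:
        bad = [c for c in candidate_standards
               if standard_class[c] not in SURROGATE_CANDIDATE_CLASSES]
        if bad:
            raise ValueError(f"non PC/PE/LPC/LPE surrogate candidates: {bad}")
    if not candidate_standards:
        raise ValueError("no candidate surrogate standards")
    completeness = qc_log10[candidate_standards].notna().mean()
    eligible = [c for c in candidate_standards if completeness[c] >= 0.5]

    assignments: dict[str, SpikeAssignment] = {}
    rule1_detail: dict[str, tuple[str, float]] = {}
    for sp in species:
        best = _rank_candidates(qc_log10[sp], qc_log10, eligible, completeness)
        if best is not None:
            rule1_detail[sp] = best
            assignments[sp] = SpikeAssignment(sp, best[0], "corr_rule_1", best[1])

    for sp in species:
        if sp in assignments:
            continue
        classmates = [(rule1_detail[o][1], o) for o in species
                      if o != sp and species_class[o] == species_class[sp]
                      and o in rule1_detail]
        if classmates:
            classmates.sort(key=lambda t: (-t[0], t[1]))
            r, mate = classmates[0]
            assignments[sp] = SpikeAssignment(
                sp, rule1_detail[mate][0], "corr_rule_2", r)

    global_best = None
    for sp in species:
        if sp in assignments:
            continue
        if global_best is None:
            scored = [(r, o) for o, (_, r) in rule1_detail.items()]
            if scored:
                scored.sort(key=lambda t: (-t[0], t[1]))
                global_best = rule1_detail[scored[0][1]]
            else:
                # no species correlates at all: fall back over all candidates
                # paired against every species, most complete standard wins
                order = sorted(candidate_standards,
                               key=lambda c: (-completeness[c], c))
                global_best = (order[0], np.nan)
        assignments[sp] = SpikeAssignment(
            sp, global_best[0], "corr_rule_3", global_best[1])
    return assignments


def select_surrogate_standard(
    species: str,
    qc_log10: pd.DataFrame,
    species_class: dict[str, str],
    candidate_standards: list[str],
    all_species: list[str] | None = None,
) -> SpikeAssignment:
    """Single-species convenience wrapper around the hierarchy."""
    pool = all_species if all_species is not None else [species]
    if species not in pool:
        pool = [species] + list(pool)
    return select_surrogate_standards(
        qc_log10, pool, species_class, candidate_standards)[species]


def regress_method3_concentration(
    norm_intensities: pd.DataFrame,
    known_intensity: np.ndarray,
    known_conc: np.ndarray,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Predict nmol/ml for method-3 species from normalized intensities.

    Fits ``log10(conc) = a + b * log10(normalized intensity)`` by least
    squares over the spike-quantified (intensity, concentration) pairs pooled
    across samples, then applies the line to the method-3 normalized
    intensities.  The transform is monotone, so the relative ordering of a
    species across samples is preserved.

    Returns the predicted concentration matrix and the (intercept, slope)
    of the fitted line.
    """
    x = np.log10(np.asarray(known_intensity, dtype=float))
    y = np.log10(np.asarray(known_conc, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError(f"need >= 10 known pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant known intensities")
    fit = stats.linregress(x, y)
    with np.errstate(divide="ignore"):
        logx = np.log10(norm_intensities)
    pred = 10.0 ** (fit.intercept + fit.slope * logx)
    pred = pred.where(norm_intensities.notna() & (norm_intensities > 0))
    return pred, (float(fit.intercept), float(fit.slope))


def quantify(
    intensity: pd.DataFrame,
    standards: list[SpikeStandard],
    class_standard: dict[str, str],
    qc_samples: list[str] | None = None,
    substitution_table: dict[str, str] | None = None,
    estimate_method3_abundance: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full intensity-to-concentration conversion.

    Parameters
    ----------
    intensity
        Samples × species summarized intensities (NaN = not available).
    standards
        Spike-in standards with per-sample areas.
    class_standard
        Subclass -> standard-name mapping for the classes with a matched
        spike.  Subclasses absent from this mapping take the surrogate /
        regression route.
    qc_samples
        Sample ids of the QC pool used for surrogate selection; defaults to
        all samples.

    Returns
    -------
    (concentrations, provenance)
        Concentrations in nmol/ml and a per-species provenance tag in
        ``{direct_spike, surrogate_normalized, regression_estimated}``.
    """
    by_name = {s.name: s for s in standards}
    used = reassign_spikes(standards, substitution_table)
    qc_samples = list(qc_samples) if qc_samples is not None else list(intensity.index)

    parsed = {sp: parse_lipid_name(sp) for sp in intensity.columns}
    direct = [sp for sp in intensity.columns
              if parsed[sp].subclass in class_standard]
    method3 = [sp for sp in intensity.columns
               if parsed[sp].subclass not in class_standard]

    conc = pd.DataFrame(np.nan, index=intensity.index, columns=intensity.columns)
    provenance = pd.Series(index=intensity.columns, dtype=object)

    for sp in direct:
        std_name = used[class_standard[parsed[sp].subclass]]
        std = by_name[std_name]
        areas = std.area_by_sample.reindex(intensity.index)
        adj = intensity[sp] / 2.0 if parsed[sp].has_identical_fas else intensity[sp]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (adj / areas) * std.actual_concentration
        vals = vals.where(areas.notna() & (areas > 0))
        n_lost = int((adj.notna() & ~(areas.notna() & (areas > 0))).sum())
        if n_lost:
            logger.info("%s: %d values lost to missing spike areas", sp, n_lost)
        conc[sp] = vals
        provenance[sp] = "direct_spike"

    if method3:
        candidates = sorted(
            used[s.name] for s in standards
            if s.subclass in SURROGATE_CANDIDATE_CLASSES)
        candidates = sorted(set(candidates))
        qc_log10 = pd.DataFrame(index=qc_samples)
        with np.errstate(divide="ignore"):
            for sp in method3:
                qc_log10[sp] = np.log10(intensity[sp].reindex(qc_samples))
            for cand in candidates:
                areas = by_name[cand].area_by_sample.reindex(qc_samples)
                qc_log10[cand] = np.log10(areas.where(areas > 0))
        assignments = select_surrogate_standards(
            qc_log10, method3, {sp: parsed[sp].subclass for sp in method3},
            candidates)
        norm = pd.DataFrame(index=intensity.index, columns=method3, dtype=float)
        for sp in method3:
            areas = by_name[assignments[sp].standard].area_by_sample.reindex(
                intensity.index)
            norm[sp] = (intensity[sp] / areas).where(areas > 0)
        if estimate_method3_abundance:
            xs, ys = [], []
            for sp in direct:
                std = by_name[used[class_standard[parsed[sp].subclass]]]
                areas = std.area_by_sample.reindex(intensity.index)
                n = (intensity[sp] / areas).where(areas > 0)
                ok = n.notna() & conc[sp].notna() & (n > 0) & (conc[sp] > 0)
                xs.append(n[ok].to_numpy())
                ys.append(conc[sp][ok].to_numpy())
            pred, _ = regress_method3_concentration(
                norm, np.concatenate(xs), np.concatenate(ys))
            conc[method3] = pred
            provenance[method3] = "regression_estimated"
        else:
            conc[method3] = norm
            provenance[method3] = "surrogate_normalized"

    return conc, provenance
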