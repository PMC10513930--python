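"""End-to-end orchestration: transitions -> concentrations -> analysis set.

Ties the extraction, quantification, QC-filter and imputation layers together
for a synthetic study (or any inputs in the same tabular dialects) and hands
back the completed concentration matrix plus the intermediate reports that
the association layers consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import extraction, qc, quantify
from .simulate import SimData

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Products of the extraction-to-imputation pipeline."""

    intensity: pd.DataFrame
    concentrations: pd.DataFrame  # unfiltered, with missingness
    provenance: pd.Series
    cv_report: qc.CVReport
    filter_report: qc.FilterReport
    filtered: pd.DataFrame
    imputed: pd.DataFrame
    detection_limits: dict[str, float]


def run_pipeline(data: SimData, knn_k: int = 10, seed: int = 0,
                 thresholds: qc.FilterThresholds | None = None
                 ) -> PipelineResult:
    """Run extraction, quantification, filtering and imputation."""
    records = [
        extraction.TransitionRecord(
            sample_id=row.sample_id, method=int(row.method),
            polarity=row.polarity, q1_mz=float(row.q1_mz),
            q3_mz=float(row.q3_mz), scan_index=int(row.scan_index),
            intensities=tuple(row[i] for i in range(6, 26)))
        for row in data.transitions.itertuples(index=False)
    ]
    intensity, match = extraction.extract_intensity_matrix(
        records, data.transition_catalog)
    logger.info("intensity matrix %s; %d excluded-class transitions",
                intensity.shape, len(match.excluded_class))

    qc_ids = [s for s in intensity.index if data.samples.loc[s, "is_qc"]]
    conc, provenance = quantify.quantify(
        intensity, data.spike_standards, data.class_standard,
        qc_samples=qc_ids)

    cv_report = qc.compute_cv(conc, data.samples)
    filtered, filter_report = qc.apply_filters(
        conc, cv_report, thresholds or qc.FilterThresholds(),
        qc_samples=qc_ids)
    bio = filtered.drop(index=[s for s in filtered.index if s in qc_ids])
    limits = qc.class_detection_limits(bio)
    imputed = qc.impute_truncated_knn(
        bio, qc.ImputationModel(k=knn_k, seed=seed, detection_limits=limits))
    return PipelineResult(
        intensity=intensity, concentrations=conc, provenance=provenance,
        cv_report=cv_report, filter_report=filter_report, filtered=filtered,
        imputed=imputed, detection_limits=limits)
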