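"""Summarization and species matching of scheduled-MRM transition intensities.

Each scheduled transition is acquired 20 times per sample.  A transition with
more than two zero-intensity recordings among the 20 repeats is considered not
available; otherwise its summary intensity is the mean over the nonzero
recordings.  Transitions are matched to lipid species on
(method, polarity, Q1, Q3, scan index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import EXCLUDED_CLASSES, parse_lipid_name

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionRecord",
    "TransitionSummary",
    "MatchResult",
    "N_REPLICATES",
    "MAX_ZERO_RECORDINGS",
    "summarize_transition",
    "match_transitions",
    "build_intensity_matrix",
    "read_transition_table",
    "extract_intensity_matrix",
]

N_REPLICATES = 20
#: A transition with more than this many zero recordings is excluded.
MAX_ZERO_RECORDINGS = 2


@dataclass(frozen=True)
class TransitionRecord:
    """One scheduled MRM transition in one sample, with its 20 repeats."""

    sample_id: str
    method: int
    polarity: str
    q1_mz: float
    q3_mz: float
    scan_index: int
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.intensities) != N_REPLICATES:
            raise ValueError(
                f"expected {N_REPLICATES} replicate intensities, "
                f"got {len(self.intensities)}"
            )
        if self.q1_mz <= 0 or self.q3_mz <= 0:
            raise ValueError("Q1/Q3 m/z must be positive")
        if any(i < 0 for i in self.intensities):
            raise ValueError("intensities must be non-negative")

    @property
    def key(self) -> tuple:
        return (self.method, self.polarity, round(self.q1_mz, 4),
                round(self.q3_mz, 4), self.scan_index)


@dataclass(frozen=True)
class TransitionSummary:
    """Mean nonzero intensity of one transition, or missing if >2 zeros."""

    sample_id: str
    species: str | None
    mean_intensity: float | None
    n_nonzero: int


def summarize_transition(rec: TransitionRecord, species: str | None = None
                         ) -> TransitionSummary:
    """Summarize the 20 repeats: missing if >2 zeros, else mean of nonzeros."""
    vals = np.asarray(rec.intensities, dtype=float)
    nonzero = vals[vals != 0.0]
    n_zero = N_REPLICATES - nonzero.size
    if n_zero > MAX_ZERO_RECORDINGS:
        return TransitionSummary(rec.sample_id, species, None, nonzero.size)
    return TransitionSummary(rec.sample_id, species, float(nonzero.mean()),
                             nonzero.size)


@dataclass
class MatchResult:
    """Outcome of matching records against a transition catalog."""

    matched: list[tuple[TransitionRecord, str]] = field(default_factory=list)
    unmatched: list[TransitionRecord] = field(default_factory=list)
    excluded_class: list[tuple[TransitionRecord, str]] = field(default_factory=list)


def match_transitions(
    records: list[TransitionRecord],
    catalog: dict[tuple, str],
    q_tolerance: float = 0.0,
) -> MatchResult:
    """Match records to species on (method, polarity, Q1, Q3, scan_index).

    Matching is exact on the catalog key by default; ``q_tolerance`` (Da)
    relaxes the Q1/Q3 comparison for real instrument exports.  Species of the
    classes excluded from analysis (PG/PS/PA and their lyso forms) are matched
    but reported separately; unmatched records are reported, never dropped
    silently.

    Raises
    ------
    ValueError
        On duplicate catalog keys or two records claiming the same key within
        one sample.
    """
    keys = list(catalog)
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate keys in transition catalog")
    seen: set[tuple] = set()
    result = MatchResult()
    for rec in records:
        species = catalog.get(rec.key)
        if species is None and q_tolerance > 0:
            for (m, pol, q1, q3, si), sp in catalog.items():
                if (m == rec.method and pol == rec.polarity
                        and si == rec.scan_index
                        and abs(q1 - rec.q1_mz) <= q_tolerance
                        and abs(q3 - rec.q3_mz) <= q_tolerance):
                    species = sp
                    break
        if species is None:
            result.unmatched.append(rec)
            continue
        sample_key = (rec.sample_id,) + rec.key
        if sample_key in seen:
            raise ValueError(
                f"two records claim transition {rec.key} in sample "
                f"{rec.sample_id}"
            )
        seen.add(sample_key)
        if parse_lipid_name(species).subclass in EXCLUDED_CLASSES:
            result.excluded_class.append((rec, species))
        else:
            result.matched.append((rec, species))
    if result.unmatched:
        logger.warning("%d transition records unmatched", len(result.unmatched))
    return result


def build_intensity_matrix(summaries: list[TransitionSummary]) -> pd.DataFrame:
    """Assemble summaries into a samples × species table (NaN = missing)."""
    if not summaries:
        logger.warning("no transition summaries; returning empty matrix")
        return pd.DataFrame()
    rows = [(s.sample_id, s.species,
             np.nan if s.mean_intensity is None else s.mean_intensity)
            for s in summaries]
    long = pd.DataFrame(rows, columns=["sample_id", "species", "intensity"])
    mat = long.pivot(index="sample_id", columns="species", values="intensity")
    mat.columns.name = None
    mat.index.name = "sample_id"
    for sid, n in mat.notna().sum(axis=1).items():
        logger.debug("sample %s: %d species observed", sid, n)
    return mat


def read_transition_table(path) -> list[TransitionRecord]:
    """Read the tabular transition dialect.

    Expected columns: ``sample_id, method, polarity, q1_mz, q3_mz,
    scan_index, rep_01..rep_20``.
    """
    table = pd.read_csv(path)
    rep_cols = [f"rep_{i:02d}" for i in range(1, N_REPLICATES + 1)]
    missing = [c for c in rep_cols if c not in table.columns]
    if missing:
        raise ValueError(f"transition table lacks replicate columns {missing}")
    records = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        records.append(TransitionRecord(
            sample_id=str(d["sample_id"]), method=int(d["method"]),
            polarity=str(d["polarity"]), q1_mz=float(d["q1_mz"]),
            q3_mz=float(d["q3_mz"]), scan_index=int(d["scan_index"]),
            intensities=tuple(float(d[c]) for c in rep_cols)))
    return records


def extract_intensity_matrix(
    records: list[TransitionRecord],
    catalog: dict[tuple, str],
    q_tolerance: float = 0.0,
) -> tuple[pd.DataFrame, MatchResult]:
    """Match, summarize and tabulate records in one pass."""
    match = match_transitions(records, catalog, q_tolerance=q_tolerance)
    summaries = [summarize_transition(rec, species)
                 for rec, species in match.matched]
    return build_intensity_matrix(summaries), match
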