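"""Synthetic longitudinal lipidomics study generator.

Generates a complete synthetic cohort — participants, visit schedule with
infection episodes, a class-structured lipid catalog, true concentrations
with planted effects, replicate-level MRM transitions with deuterated
spike-ins, QC samples, clinical and cytokine panels — so that every pipeline
stage is testable without any external download.  Every planted parameter is
recorded in a ground-truth ledger.

The default configuration emulates the statistical structure of a deeply
sampled human plasma cohort: class median abundances spanning four orders of
magnitude, participant-specific random effects (class-specific ICC, high for
TAG/SM/CE, low for FFA), low technical CV in QC replicates, left-censored
missingness near a per-class detection bound, per-class ageing slopes, SSPG
effects on a subset of species, infection-phase trajectory templates and
cytokine-lipid loadings.  The default catalog is a scaled-down (~170
species) version of the platform's TAG-heavy class proportions; a
paper-scale catalog can be configured by raising the per-class species
counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import build_annotation_catalog, parse_lipid_name
from .models import classify_ir
from .quantify import SpikeStandard

logger = logging.getLogger(__name__)

__all__ = [
    "ClassSpec",
    "PlantedEffects",
    "SimulationConfig",
    "SimData",
    "build_species_catalog",
    "simulate_cohort",
    "simulate_concentrations",
    "simulate_transitions",
    "simulate_cytokines_clinical",
    "simulate_study",
    "write_fixture_bundle",
    "load_transitions_bundle",
]

#: Classes quantified against a class-matched spike-in standard.
SPIKED_CLASSES = ("PC", "PE", "PE-O", "PE-P", "LPC", "LPE", "FFA", "TAG",
                  "CE", "DAG", "CER", "DCER", "HCER", "LCER", "SM")

_METHOD_OF_CLASS = {
    "PC": (1, "negative"), "PE": (1, "negative"), "PE-O": (1, "negative"),
    "PE-P": (1, "negative"), "LPC": (1, "negative"), "LPE": (1, "negative"),
    "FFA": (2, "negative"), "TAG": (2, "positive"), "CE": (2, "positive"),
    "DAG": (2, "positive"), "CER": (2, "positive"), "DCER": (2, "positive"),
    "HCER": (2, "positive"), "LCER": (2, "positive"),
    "SM": (3, "positive"), "PI": (3, "negative"), "PG": (3, "negative"),
    "PS": (3, "negative"), "PA": (3, "negative"), "LPG": (3, "negative"),
}

_FA_POOL = [(14, 0), (15, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1),
            (18, 2), (18, 3), (20, 4), (20, 5), (22, 4), (22, 5), (22, 6),
            (24, 1)]


@dataclass
class ClassSpec:
    """Per-subclass generative parameters.

    ``median_log10`` is the class median concentration (log10 nmol/ml);
    ``species_sd`` the between-species spread (log10); ``bio_sd`` the total
    biological standard deviation on the natural-log scale, split between
    participant and residual variance by ``icc``; ``tech_cv`` / ``qc_tech_cv``
    the per-transition technical coefficient of variation in biosamples / QC
    samples (on top of the shared per-sample extraction factor);
    ``censor_quantile`` the fraction of the class intensity distribution
    sitting below the detection bound; ``ageing_slope`` the planted per-year
    change of the natural-log concentration.
    """

    n_species: int
    median_log10: float
    species_sd: float = 0.6
    icc: float = 0.35
    bio_sd: float = 0.5
    tech_cv: float = 0.025
    qc_tech_cv: float = 0.025
    censor_quantile: float = 0.02
    ageing_slope: float = 0.0
    response_log10: float = 3.0
    spike_conc: float = 5.0


def default_class_spec() -> dict[str, ClassSpec]:
    """The default scaled-down, TAG-heavy catalog (~170 species)."""
    return {
        "TAG": ClassSpec(40, 0.8, 0.8, icc=0.55, ageing_slope=0.02),
        "PC": ClassSpec(16, 1.9, 0.5, icc=0.40),
        "PE": ClassSpec(10, 0.8, 0.5, icc=0.40),
        "PE-O": ClassSpec(5, 0.0, 0.4, icc=0.40),
        "PE-P": ClassSpec(6, 0.3, 0.4, icc=0.40, ageing_slope=-0.01),
        "LPC": ClassSpec(7, 1.2, 0.8, icc=0.35),
        "LPE": ClassSpec(5, 0.2, 0.5, icc=0.35),
        "CE": ClassSpec(10, 1.8, 0.8, icc=0.50, ageing_slope=0.01),
        "CER": ClassSpec(5, -0.3, 0.4, icc=0.35),
        "DCER": ClassSpec(4, -0.8, 0.4, icc=0.35),
        "HCER": ClassSpec(5, -0.5, 0.4, icc=0.55),
        "LCER": ClassSpec(5, -1.2, 0.3, icc=0.35),
        "DAG": ClassSpec(8, 0.3, 0.6, icc=0.35),
        "FFA": ClassSpec(10, 2.5, 0.3, icc=0.10),
        "SM": ClassSpec(8, 2.3, 0.3, icc=0.60, ageing_slope=0.005),
        "PI": ClassSpec(8, 0.5, 0.5, icc=0.35),
        # classes generated to exercise the exclusion paths
        "PG": ClassSpec(3, -1.0, 0.4, icc=0.35, censor_quantile=0.15),
        "PS": ClassSpec(3, -1.0, 0.4, icc=0.35, censor_quantile=0.15),
        "PA": ClassSpec(2, -1.2, 0.4, icc=0.35, censor_quantile=0.15),
        "LPG": ClassSpec(2, -1.5, 0.4, icc=0.35, censor_quantile=0.15),
    }


#: Infection trajectory templates: additive effect on the natural-log
#: concentration in (early, late, recovery) phase, units of the species'
#: biological standard deviation.
DEFAULT_TEMPLATES = {
    "early_up": (0.8, 0.3, 0.1),
    "early_down": (-0.8, -0.3, -0.1),
    "late_up": (0.0, 0.8, 0.4),
    "late_down": (0.0, -0.8, -0.4),
}


@dataclass
class PlantedEffects:
    """Effect sizes planted into the synthetic cohort."""

    sspg_fraction: float = 0.3
    sspg_beta: float = 0.5  # per SD of SSPG, in units of the species' bio SD
    infection_fraction: float = 0.3
    templates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    n_cytokines: int = 8
    n_loaded_cytokines: int = 2
    loaded_species_per_cytokine: int = 15
    cytokine_loading: float = 0.3
    cytokine_noise_sd: float = 0.5
    cytokine_participant_sd: float = 0.3


@dataclass
class SimulationConfig:
    """Complete description of the synthetic study."""

    seed: int = 0
    n_participants: int = 20
    fraction_ir: float = 0.5
    n_healthy_visits: int = 8
    visit_interval_years: float = 0.25
    n_episodes: int = 1
    episode_days: tuple[int, ...] = (2, 5, 9, 13, 20, 28)
    n_qc: int = 40
    sample_factor_sd: float = 0.065  # shared extraction/injection noise (ln)
    replicate_sd: float = 0.03  # within-transition lognormal noise (ln)
    dropout_width: float = 0.1  # sharpness of the censor transition (ln)
    class_spec: dict[str, ClassSpec] = field(default_factory=default_class_spec)
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    # planted QC violations (counts)
    n_high_missing_samples: int = 1
    n_low_valid_species: int = 1
    n_noisy_qc_species: int = 1
    n_flat_species: int = 1

    def validate(self) -> None:
        for frac in (self.fraction_ir,):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_healthy_visits < 1:
            raise ValueError("infeasible schedule: need >= 1 healthy visit")


@dataclass
class SimData:
    """In-memory synthetic study with its ground-truth ledger."""

    config: SimulationConfig
    participants: pd.DataFrame
    samples: pd.DataFrame  # metadata indexed by sample_id
    catalog: pd.DataFrame  # species catalog incl. transition keys
    true_conc: pd.DataFrame
    transitions: pd.DataFrame  # tabular transition dialect
    spike_standards: list[SpikeStandard]
    class_standard: dict[str, str]
    cytokines: pd.DataFrame
    clinical: pd.DataFrame
    ledger: dict

    @property
    def transition_catalog(self) -> dict[tuple, str]:
        return {
            (int(r.method), r.polarity, round(float(r.q1_mz), 4),
             round(float(r.q3_mz), 4), int(r.scan_index)): r.species
            for r in self.catalog.itertuples()
        }


def _species_names(cls: str, n: int) -> list[str]:
    """Deterministic species names for one class."""
    pool = _FA_POOL
    names: list[str] = []
    if cls == "TAG":
        totals = [(c, d) for c in range(44, 58) for d in (0, 1, 2, 3)]
        i = 0
        while len(names) < n:
            tc, td = totals[i % len(totals)]
            fa = pool[(i * 5) % len(pool)]
            if fa[0] <= tc:
                name = f"TAG{tc}:{td}-FA{fa[0]}:{fa[1]}"
                if name not in names:
                    names.append(name)
            i += 1
    elif cls in ("PE-O", "PE-P"):
        kind = "O" if cls == "PE-O" else "P"
        i = 0
        while len(names) < n:
            fa1 = pool[(i * 2) % len(pool)]
            fa2 = pool[(i * 3 + 5) % len(pool)]
            name = f"PE({kind}-{fa1[0]}:{fa1[1]}/{fa2[0]}:{fa2[1]})"
            if name not in names:
                names.append(name)
            i += 1
    elif cls in ("PC", "PE", "PI", "DAG", "PA", "PG", "PS"):
        pairs = [(a, b) for a in range(len(pool)) for b in range(a, len(pool))]
        # one identical-FA species per dual class, to exercise the 2x rule
        fa = pool[2]
        names.append(f"{cls}({fa[0]}:{fa[1]}/{fa[0]}:{fa[1]})")
        i = 0
        while len(names) < n:
            a, b = pairs[(i * 7 + 1) % len(pairs)]
            fa1, fa2 = pool[a], pool[b]
            name = f"{cls}({fa1[0]}:{fa1[1]}/{fa2[0]}:{fa2[1]})"
            if name not in names:
                names.append(name)
            i += 1
        if cls == "PI" and n >= 2 and "PI(16:0/18:3)" not in names:
            names[-1] = "PI(16:0/18:3)"  # platform-excluded species
    else:
        if n > len(pool):
            raise ValueError(
                f"{cls}: at most {len(pool)} distinct single-acyl species "
                f"can be named from the FA pool, requested {n}")
        i = 0
        while len(names) < n:
            fa = pool[(i * 4 + (0 if cls != "CE" else 1)) % len(pool)]
            name = f"{cls}({fa[0]}:{fa[1]})"
            if name not in names:
                names.append(name)
            i += 1
    return names


def build_species_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Species catalog with transition keys, deterministic given the config."""
    rows = []
    scan_counters: dict[tuple[int, str], int] = {}
    q_counter = 0
    for cls in config.class_spec:
        method, polarity = _METHOD_OF_CLASS[cls]
        for name in _species_names(cls, config.class_spec[cls].n_species):
            key = (method, polarity)
            scan = scan_counters.get(key, 0)
            scan_counters[key] = scan + 1
            sp = parse_lipid_name(name)
            rows.append({
                "species": name, "subclass": cls, "method": method,
                "polarity": polarity,
                "q1_mz": round(400.0 + 2.0 * q_counter, 4),
                "q3_mz": round(100.0 + 1.5 * q_counter, 4),
                "scan_index": scan,
                "identical_fa": sp.has_identical_fas,
            })
            q_counter += 1
    return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participants and visit schedule (healthy visits + infection episodes).

    SSPG above 150 mg/dl marks insulin resistance.  Returns (participants,
    samples); ``samples`` is indexed by sample id and includes QC rows.
    """
    config.validate()
    n = config.n_participants
    n_ir = int(round(config.fraction_ir * n))
    pids = [f"P{i + 1:03d}" for i in range(n)]
    is_ir = np.array([True] * n_ir + [False] * (n - n_ir))
    sspg = np.where(is_ir, rng.uniform(155, 260, n), rng.uniform(60, 145, n))
    participants = pd.DataFrame({
        "participant": pids,
        "sex": rng.choice(["M", "F"], n),
        "age": rng.uniform(30, 70, n).round(1),
        "bmi": rng.uniform(20, 36, n).round(1),
        "ethnicity": rng.choice(["A", "B", "C"], n, p=[0.5, 0.3, 0.2]),
        "sspg": sspg.round(1),
        "ir_status": [classify_ir(v) for v in sspg.round(1)],
    }).set_index("participant", drop=False)

    rows = []
    for pid in pids:
        p = participants.loc[pid]
        enroll_offset = float(rng.uniform(0, 2))
        for v in range(config.n_healthy_visits):
            years = v * config.visit_interval_years
            rows.append({
                "sample_id": f"{pid}_H{v + 1:02d}", "participant": pid,
                "is_qc": False, "health": "healthy", "event_id": "",
                "days_since_onset": np.nan, "phase": "baseline",
                "years_since_baseline": years,
                "collection_date": round(enroll_offset + years, 4),
                "storage_length": round(10.0 - enroll_offset - years, 3),
                "sex": p["sex"], "age": p["age"] + years, "bmi": p["bmi"],
                "ethnicity": p["ethnicity"], "sspg": p["sspg"],
                "ir_status": p["ir_status"],
            })
        for ep in range(config.n_episodes):
            onset_years = (ep + 1) * config.n_healthy_visits \
                * config.visit_interval_years / (config.n_episodes + 1)
            for day in config.episode_days:
                years = onset_years + day / 365.25
                rows.append({
                    "sample_id": f"{pid}_E{ep + 1}D{day:02d}",
                    "participant": pid, "is_qc": False, "health": "infection",
                    "event_id": f"{pid}_RVI{ep + 1}",
                    "days_since_onset": day, "phase": "",
                    "years_since_baseline": years,
                    "collection_date": round(enroll_offset + years, 4),
                    "storage_length": round(10.0 - enroll_offset - years, 3),
                    "sex": p["sex"], "age": p["age"] + years, "bmi": p["bmi"],
                    "ethnicity": p["ethnicity"], "sspg": p["sspg"],
                    "ir_status": p["ir_status"],
                })
    for q in range(config.n_qc):
        rows.append({
            "sample_id": f"QC_{q + 1:03d}", "participant": "QC",
            "is_qc": True, "health": "qc", "event_id": "",
            "days_since_onset": np.nan, "phase": "",
            "years_since_baseline": np.nan, "collection_date": np.nan,
            "storage_length": np.nan, "sex": "", "age": np.nan,
            "bmi": np.nan, "ethnicity": "", "sspg": np.nan, "ir_status": "",
        })
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)
    from .trajectory import assign_phase
    ev = samples["days_since_onset"].notna()
    samples.loc[ev, "phase"] = samples.loc[ev, "days_since_onset"].map(
        lambda d: assign_phase(int(d)))
    return participants, samples


def simulate_concentrations(
    config: SimulationConfig,
    participants: pd.DataFrame,
    samples: pd.DataFrame,
    catalog: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """True concentrations (nmol/ml) for biosamples, plus the effect ledger.

    ln C = class median + species offset + participant effect + ageing
    slope x years + SSPG effect + infection-template effect + residual.
    """
    bio = samples[~samples["is_qc"]]
    species = catalog["species"].tolist()
    cls_of = dict(zip(catalog["species"], catalog["subclass"]))
    n_s, n_j = len(bio), len(species)

    sspg_z = (participants["sspg"] - participants["sspg"].mean()) \
        / participants["sspg"].std()

    ln10 = np.log(10.0)
    offsets, sd_b, sd_e, slopes, bio_sds = {}, {}, {}, {}, {}
    for cls, spec in config.class_spec.items():
        members = [sp for sp in species if cls_of[sp] == cls]
        offs = rng.normal(0.0, spec.species_sd * ln10, len(members))
        for sp, off in zip(members, offs):
            offsets[sp] = spec.median_log10 * ln10 + off
            sd_b[sp] = spec.bio_sd * np.sqrt(spec.icc)
            sd_e[sp] = spec.bio_sd * np.sqrt(1.0 - spec.icc)
            slopes[sp] = spec.ageing_slope
            bio_sds[sp] = spec.bio_sd

    eff = config.effects
    n_sspg = int(round(eff.sspg_fraction * n_j))
    sspg_species = list(rng.choice(species, n_sspg, replace=False))
    n_inf = int(round(eff.infection_fraction * n_j))
    inf_species = list(rng.choice(species, n_inf, replace=False))
    template_names = list(eff.templates)
    template_of = {sp: template_names[i % len(template_names)]
                   for i, sp in enumerate(inf_species)}

    u = {pid: rng.normal(0.0, 1.0, n_j) for pid in participants.index}
    ln_c = np.empty((n_s, n_j))
    sdb_vec = np.array([sd_b[sp] for sp in species])
    sde_vec = np.array([sd_e[sp] for sp in species])
    off_vec = np.array([offsets[sp] for sp in species])
    slope_vec = np.array([slopes[sp] for sp in species])
    biosd_vec = np.array([bio_sds[sp] for sp in species])
    sspg_mask = np.isin(species, sspg_species).astype(float)
    phase_idx = {"early": 0, "late": 1, "recovery": 2}
    tmpl_mat = np.zeros((3, n_j))
    for j, sp in enumerate(species):
        if sp in template_of:
            tmpl_mat[:, j] = eff.templates[template_of[sp]]

    for i, (sid, row) in enumerate(bio.iterrows()):
        pid = row["participant"]
        mean = (off_vec + sdb_vec * u[pid]
                + slope_vec * row["years_since_baseline"]
                + eff.sspg_beta * sspg_z[pid] * biosd_vec * sspg_mask)
        if row["phase"] in phase_idx:
            mean = mean + tmpl_mat[phase_idx[row["phase"]]] * biosd_vec
        ln_c[i] = mean + rng.normal(0.0, 1.0, n_j) * sde_vec

    true_conc = pd.DataFrame(np.exp(ln_c), index=bio.index, columns=species)
    ledger = {
        "icc": {sp: config.class_spec[cls_of[sp]].icc for sp in species},
        "sspg_species": sorted(sspg_species),
        "sspg_beta": eff.sspg_beta,
        "infection_templates": {sp: template_of[sp] for sp in inf_species},
        "ageing_slope_per_class": {cls: spec.ageing_slope
                                   for cls, spec in config.class_spec.items()},
        "species_offsets_ln": {sp: float(offsets[sp]) for sp in species},
    }
    return true_conc, ledger


def simulate_transitions(
    config: SimulationConfig,
    samples: pd.DataFrame,
    catalog: pd.DataFrame,
    true_conc: pd.DataFrame,
    rng: np.random.Generator,
    ledger: dict,
) -> tuple[pd.DataFrame, list[SpikeStandard], dict[str, str]]:
    """Replicate-level transition intensities plus spike-in areas.

    Intensity = concentration x class response factor x technical noise
    (doubled for identical-FA species); each of the 20 repeats adds lognormal
    replicate noise and may drop to zero with probability rising as the
    signal approaches the class censor bound.  QC samples derive from one
    fixed stock with technical noise only.  Planted QC violations (a
    high-missingness sample, a low-validity species, a QC-noisy species and
    a species with near-zero biological variance but unstable QC signal) are
    recorded in the ledger.
    """
    species = catalog["species"].tolist()
    cls_of = dict(zip(catalog["species"], catalog["subclass"]))
    identical = dict(zip(catalog["species"], catalog["identical_fa"]))
    bio_ids = list(true_conc.index)
    qc_ids = [s for s in samples.index if samples.loc[s, "is_qc"]]
    all_ids = bio_ids + qc_ids
    n_s, n_j = len(all_ids), len(species)

    # planted violations: deterministic choices via rng
    analysis_pool = [sp for sp in species
                     if cls_of[sp] in ("CER", "DAG", "LPE", "PE")]
    low_valid = list(rng.choice(analysis_pool, config.n_low_valid_species,
                                replace=False))
    rest = [sp for sp in analysis_pool if sp not in low_valid]
    noisy_qc = list(rng.choice(rest, config.n_noisy_qc_species, replace=False))
    rest = [sp for sp in rest if sp not in noisy_qc]
    flat = list(rng.choice(rest, config.n_flat_species, replace=False))
    bad_samples = list(rng.choice(bio_ids, config.n_high_missing_samples,
                                  replace=False))
    ledger["planted_violations"] = {
        "high_missing_samples": sorted(bad_samples),
        "low_valid_species": sorted(low_valid),
        "noisy_qc_species": sorted(noisy_qc),
        "flat_species": sorted(flat),
    }

    qc_stock = np.array([np.exp(ledger["species_offsets_ln"][sp])
                         for sp in species])
    # flat species: almost no biological variance -> rebuild its biosample
    # concentrations around the stock with tiny spread (written back so the
    # ground truth stays consistent)
    j_of = {sp: j for j, sp in enumerate(species)}
    for sp in flat:
        true_conc[sp] = qc_stock[j_of[sp]] * np.exp(
            rng.normal(0, 0.02, len(bio_ids)))
    tc = true_conc.to_numpy()

    resp = np.array([10.0 ** config.class_spec[cls_of[sp]].response_log10
                     for sp in species])
    double = np.where([identical[sp] for sp in species], 2.0, 1.0)
    tech_bio = np.array([config.class_spec[cls_of[sp]].tech_cv
                         for sp in species])
    tech_qc = np.array([config.class_spec[cls_of[sp]].qc_tech_cv
                        for sp in species])
    for sp in noisy_qc:
        tech_bio[j_of[sp]] = 0.35
        tech_qc[j_of[sp]] = 0.35
    for sp in flat:
        tech_bio[j_of[sp]] = 0.04
        tech_qc[j_of[sp]] = 0.12

    conc_all = np.vstack([tc, np.tile(qc_stock, (len(qc_ids), 1))])
    tech_sd = np.vstack([np.tile(tech_bio, (len(bio_ids), 1)),
                         np.tile(tech_qc, (len(qc_ids), 1))])
    # shared extraction/injection factor per sample (cancelled by the
    # internal standards) plus independent per-transition noise
    sample_factor = np.exp(rng.normal(0, config.sample_factor_sd, n_s))
    base = (conc_all * resp * double * sample_factor[:, None]
            * np.exp(rng.normal(0, 1, (n_s, n_j)) * tech_sd))

    # per-class censor bound from the biosample intensity distribution
    bounds = np.empty(n_j)
    for cls, spec in config.class_spec.items():
        idx = [j for j, sp in enumerate(species) if cls_of[sp] == cls]
        vals = base[:len(bio_ids), idx].ravel()
        bounds[idx] = np.quantile(vals, spec.censor_quantile)
    ledger["censor_bounds_intensity"] = {sp: float(bounds[j])
                                         for sp, j in j_of.items()}

    with np.errstate(over="ignore"):
        p_zero = 1.0 / (1.0 + np.exp((np.log(base) - np.log(bounds))
                                     / config.dropout_width))
    reps = base[:, :, None] * np.exp(
        rng.normal(0, config.replicate_sd, (n_s, n_j, 20)))
    zero_mask = rng.random((n_s, n_j, 20)) < p_zero[:, :, None]
    # forced violations (low-validity species censored in QC stock as well:
    # a species at the edge of detection is low everywhere)
    for sp in low_valid:
        force = rng.random(n_s) < 0.95
        zero_mask[:, j_of[sp], :] |= force[:, None]
    for sid in bad_samples:
        i = all_ids.index(sid)
        kill = rng.choice(n_j, int(0.35 * n_j), replace=False)
        zero_mask[i, kill, :] = True
    reps = np.where(zero_mask, 0.0, reps)

    # realized filter expectations: which samples/species the QC filters
    # should drop, given the zeros actually generated
    excl = {"PA", "LPA", "PG", "LPG", "PS", "LPS"}
    analysis_j = [j for j, sp in enumerate(species) if cls_of[sp] not in excl]
    missing = (zero_mask.sum(axis=2) > 2)[:, analysis_j]
    bio_missing_frac = missing[:len(bio_ids)].mean(axis=1)
    exp_bad = [bio_ids[i] for i in np.flatnonzero(bio_missing_frac > 0.25)]
    keep_rows = np.array([sid not in exp_bad for sid in all_ids])
    valid_frac = 1.0 - missing[keep_rows].mean(axis=0)
    exp_low_valid = [species[analysis_j[k]]
                     for k in np.flatnonzero(valid_frac < 0.10)]
    ledger["expected_filter"] = {
        "dropped_samples": sorted(exp_bad),
        "low_validity": sorted(exp_low_valid),
        "high_qc_cv": sorted(noisy_qc),
        "qc_cv_exceeds_bio_cv": sorted(flat),
        "excluded_species": sorted(sp for sp in species
                                   if sp == "PI(16:0/18:3)"),
    }

    cat_cols = catalog.set_index("species")
    frame = {
        "sample_id": np.repeat(all_ids, n_j),
        "method": np.tile(cat_cols["method"].to_numpy(), n_s),
        "polarity": np.tile(cat_cols["polarity"].to_numpy(), n_s),
        "q1_mz": np.tile(cat_cols["q1_mz"].to_numpy(), n_s),
        "q3_mz": np.tile(cat_cols["q3_mz"].to_numpy(), n_s),
        "scan_index": np.tile(cat_cols["scan_index"].to_numpy(), n_s),
    }
    flat_reps = reps.reshape(n_s * n_j, 20)
    for r in range(20):
        frame[f"rep_{r + 1:02d}"] = flat_reps[:, r]
    transitions = pd.DataFrame(frame)

    # spike-in standards: one per spiked class, plus a DAG substitute with
    # planted missingness above the 5% reassignment threshold
    standards: list[SpikeStandard] = []
    class_standard: dict[str, str] = {}
    spiked = [c for c in SPIKED_CLASSES if c in config.class_spec]
    for cls in spiked:
        spec = config.class_spec[cls]
        resp_c = 10.0 ** spec.response_log10
        area = spec.spike_conc * resp_c * sample_factor * np.exp(
            rng.normal(0, spec.tech_cv, n_s))
        name = f"d{cls}(16:0/18:1)" if cls not in (
            "FFA", "CE", "LPC", "LPE", "SM", "CER", "DCER", "HCER", "LCER") \
            else f"d{cls}(16:0)"
        if cls == "TAG":
            name = "dTAG50:1-FA16:0"
        series = pd.Series(area, index=all_ids)
        sub_name = None
        if cls == "DAG":
            name = "dDAG(16:0/18:3)"
            sub_name = "dDAG(16:0/18:2)"
            missing = rng.choice(n_s, int(0.21 * n_s), replace=False)
            series.iloc[missing] = np.nan
            sub_area = spec.spike_conc * resp_c * sample_factor * np.exp(
                rng.normal(0, spec.tech_cv, n_s))
            standards.append(SpikeStandard(sub_name, cls, spec.spike_conc,
                                           pd.Series(sub_area, index=all_ids)))
        standards.append(SpikeStandard(name, cls, spec.spike_conc, series,
                                       substitute_name=sub_name))
        class_standard[cls] = name
    ledger["spike_substitution"] = {"dDAG(16:0/18:3)": "dDAG(16:0/18:2)"}
    ledger["identical_fa_species"] = sorted(
        sp for sp in species if identical[sp])
    return transitions, standards, class_standard


def simulate_cytokines_clinical(
    config: SimulationConfig,
    participants: pd.DataFrame,
    samples: pd.DataFrame,
    true_conc: pd.DataFrame,
    rng: np.random.Generator,
    ledger: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cytokine panel with planted lipid loadings, and a clinical panel.

    Cytokines are linear combinations of scaled log lipid abundances plus a
    BMI term, a participant random effect and Gaussian noise.  The clinical
    panel contains glucose (tracking SSPG), triglycerides (tracking total
    TAG), cholesterol (tracking total CE) and unrelated noise measures.
    """
    eff = config.effects
    bio = samples.loc[true_conc.index]
    z = np.log(true_conc.to_numpy())
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    species = list(true_conc.columns)
    n_s = len(bio)
    bmi_z = ((bio["bmi"] - bio["bmi"].mean()) / bio["bmi"].std()).to_numpy()
    pid_codes = bio["participant"].astype("category").cat.codes.to_numpy()

    loadings: dict[str, dict[str, float]] = {}
    cyt = {}
    for k in range(eff.n_cytokines):
        name = f"CYT{k + 1:02d}"
        signal = np.zeros(n_s)
        loadings[name] = {}
        if k < eff.n_loaded_cytokines:
            start = k * eff.loaded_species_per_cytokine
            chosen = species[start:start + eff.loaded_species_per_cytokine]
            for sp in chosen:
                signal += eff.cytokine_loading * z[:, species.index(sp)]
                loadings[name][sp] = eff.cytokine_loading
        u = rng.normal(0, eff.cytokine_participant_sd,
                       pid_codes.max() + 1)[pid_codes]
        cyt[name] = (signal + 0.2 * bmi_z + u
                     + rng.normal(0, eff.cytokine_noise_sd, n_s))
    cytokines = pd.DataFrame(cyt, index=bio.index)
    ledger["cytokine_loadings"] = loadings

    cls_of = {sp: parse_lipid_name(sp).subclass for sp in species}

    def _class_log_total(cls):
        cols = [s for s in species if cls_of[s] == cls]
        if not cols:
            return pd.Series(0.0, index=bio.index)
        return np.log(true_conc[cols].sum(axis=1))

    tag_total = _class_log_total("TAG")
    ce_total = _class_log_total("CE")
    sspg_z = ((bio["sspg"] - bio["sspg"].mean())
              / bio["sspg"].std()).to_numpy()

    def _z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    clinical = pd.DataFrame(index=bio.index)
    clinical["GLU"] = 0.8 * sspg_z + rng.normal(0, 0.6, n_s)
    clinical["TGL"] = 0.7 * _z(tag_total) + rng.normal(0, 0.5, n_s)
    clinical["CHOL"] = 0.7 * _z(ce_total) + rng.normal(0, 0.5, n_s)
    for name in ("HSCRP", "ALT", "WBC", "INSF", "HDL", "CR", "ALB"):
        clinical[name] = rng.normal(0, 1, n_s)
    ledger["clinical_drivers"] = {"GLU": "sspg", "TGL": "TAG", "CHOL": "CE"}
    return cytokines, clinical


def simulate_study(config: SimulationConfig | None = None) -> SimData:
    """Generate the full synthetic study from one master seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    participants, samples = simulate_cohort(config, rng)
    catalog = build_species_catalog(config)
    true_conc, ledger = simulate_concentrations(
        config, participants, samples, catalog, rng)
    transitions, standards, class_standard = simulate_transitions(
        config, samples, catalog, true_conc, rng, ledger)
    cytokines, clinical = simulate_cytokines_clinical(
        config, participants, samples, true_conc, rng, ledger)
    return SimData(config=config, participants=participants, samples=samples,
                   catalog=catalog, true_conc=true_conc,
                   transitions=transitions, spike_standards=standards,
                   class_standard=class_standard, cytokines=cytokines,
                   clinical=clinical, ledger=ledger)


def _config_to_json(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["episode_days"] = list(d["episode_days"])
    for cls, spec in d["class_spec"].items():
        d["class_spec"][cls] = dict(spec)
    d["effects"]["templates"] = {k: list(v) for k, v
                                 in d["effects"]["templates"].items()}
    return d


def write_fixture_bundle(outdir: str | Path, config: SimulationConfig | None = None
                         ) -> SimData:
    """Write every pipeline input file plus the ground-truth ledger.

    Re-running with the same config (seed) reproduces byte-identical CSVs.
    """
    data = simulate_study(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        data.transitions.to_csv(out / "transitions.csv", index=False,
                                float_format="%.6g")
        data.catalog.to_csv(out / "catalog.csv", index=False)
        data.samples.to_csv(out / "metadata.csv", index=False)
        data.participants.to_csv(out / "participants.csv", index=False)
        spikes = pd.DataFrame(
            [{"standard": s.name, "subclass": s.subclass,
              "actual_concentration_nmol_ml": s.actual_concentration,
              "substitute_name": s.substitute_name or ""}
             for s in data.spike_standards])
        spikes.to_csv(out / "spike_catalog.csv", index=False)
        areas = pd.DataFrame({s.name: s.area_by_sample
                              for s in data.spike_standards})
        areas.to_csv(out / "spike_areas.csv", float_format="%.6g")
        data.cytokines.to_csv(out / "cytokines.csv", float_format="%.6g")
        data.clinical.to_csv(out / "clinical.csv", float_format="%.6g")
        events = data.samples[data.samples["event_id"] != ""]
        events[["sample_id", "event_id", "days_since_onset"]].assign(
            event_type="infection").to_csv(out / "events.csv", index=False)
        build_annotation_catalog(data.catalog["species"]).to_csv(
            out / "annotation_catalog.csv", index=False)
        data.true_conc.to_csv(out / "ground_truth_concentrations.csv",
                              float_format="%.8g")
        with open(out / "ground_truth_ledger.json", "w") as fh:
            json.dump(data.ledger, fh, indent=1, sort_keys=True)
        with open(out / "config.json", "w") as fh:
            json.dump(_config_to_json(data.config), fh, indent=1,
                      sort_keys=True)
    except Exception:
        for f in out.glob("*"):
            f.unlink()
        raise
    return data


def load_transitions_bundle(outdir: str | Path):
    """Load the transition records and catalog back from a fixture bundle."""
    from .extraction import read_transition_table

    out = Path(outdir)
    records = read_transition_table(out / "transitions.csv")
    catalog = pd.read_csv(out / "catalog.csv")
    cat = {(int(r.method), r.polarity, round(float(r.q1_mz), 4),
            round(float(r.q3_mz), 4), int(r.scan_index)): r.species
           for r in catalog.itertuples()}
    return records, cat
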