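"""Synthetic patients, nurse behavior, and the randomized crossover usability trial.

The defaults are calibrated to the study's printed summary statistics —
prevalence 0.26, completion successes 203/216 vs 212/216, completion-time
medians 4.4 vs 2.3 minutes, usability-total means 3.40 vs 4.35 — because
the source reports summaries, not generative parameters.  Everything is
driven by one :class:`numpy.random.Generator` seeded once.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .engine import NORMAL, POSITIVE, AssessmentSession, classify, run_scripted
from .item_bank import AUTO_ITEM, FEATURES, Feature, ItemBank, default_item_bank, feature_evidence_map

__all__ = [
    "DOMAINS",
    "PatientState",
    "SimConfig",
    "TrialDataset",
    "TrialDesign",
    "UsabilityResponse",
    "sample_patient",
    "simulate_assessment",
    "simulate_trial",
    "simulate_usability",
]

MODALITIES = ("paper", "dst")

DOMAINS = (
    "perceived_usefulness",
    "ease_of_use",
    "learnability",
    "trustworthiness",
    "intention_to_use",
    "satisfaction",
)

# Per-domain location anchors for the latent usability model; the weighted
# (per-item) mean is shifted to hit the configured total target exactly.
_LIKERT_ANCHORS = {
    "paper": (3.86, 2.83, 3.33, 3.33, 3.67, 3.60),
    "dst": (4.57, 4.33, 4.33, 4.33, 4.40, 4.33),
}
_LIKERT_ITEM_COUNTS = {
    "paper": (4, 6, 3, 4, 5, 4),  # 26 items
    "dst": (6, 10, 6, 6, 7, 8),  # 43 items (adds interface items)
}


@dataclass(frozen=True)
class PatientState:
    delirium: bool
    true_features: tuple[bool, bool, bool, bool]
    item_truth: dict[int, str]  # latent values for display items 1..21


@dataclass
class SimConfig:
    prevalence: float = 0.26
    p_feature_given_nondelirium: dict[Feature, float] = field(
        default_factory=lambda: {
            Feature.F1: 0.15,
            Feature.F2: 0.10,
            Feature.F3: 0.12,
            Feature.F4: 0.08,
        }
    )
    #: probability each item of a present feature is latently positive
    p_item_positive_given_feature: float = 0.6
    #: per-item probability a nurse records the wrong value (15 vs 5 total
    #: errors over 216 assessments of 21 items)
    nurse_error_rate: dict[str, float] = field(
        default_factory=lambda: {"paper": 15 / (216 * 21), "dst": 5 / (216 * 21)}
    )
    #: per-assessment probability of failed completion (13/216 vs 4/216)
    completion_failure_rate: dict[str, float] = field(
        default_factory=lambda: {"paper": 13 / 216, "dst": 4 / 216}
    )
    #: lognormal completion-time model: median (min) and log-scale sigma
    #: (sigma matched to the printed IQRs 2.5-5.4 and 1.25-3.55)
    time_median: dict[str, float] = field(
        default_factory=lambda: {"paper": 4.4, "dst": 2.3}
    )
    time_sigma: dict[str, float] = field(
        default_factory=lambda: {
            "paper": math.log(5.4 / 2.5) / (2 * norm.ppf(0.75)),
            "dst": math.log(3.55 / 1.25) / (2 * norm.ppf(0.75)),
        }
    )
    likert_total_target: dict[str, float] = field(
        default_factory=lambda: {"paper": 3.40, "dst": 4.35}
    )
    likert_domain_anchors: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_LIKERT_ANCHORS)
    )
    likert_item_counts: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_LIKERT_ITEM_COUNTS)
    )
    likert_latent_sd: dict[str, float] = field(
        default_factory=lambda: {"paper": 0.60, "dst": 0.45}
    )

    def validate(self) -> "SimConfig":
        probs = [self.prevalence, self.p_item_positive_given_feature]
        probs += list(self.p_feature_given_nondelirium.values())
        probs += list(self.nurse_error_rate.values())
        probs += list(self.completion_failure_rate.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.time_median.values()):
            raise ValueError("time medians must be positive")
        return self

    def likert_domain_targets(self, modality: str) -> tuple[float, ...]:
        """Anchors shifted so the item-weighted mean equals the total target."""
        anchors = np.asarray(self.likert_domain_anchors[modality], dtype=float)
        counts = np.asarray(self.likert_item_counts[modality], dtype=float)
        weighted = float(np.dot(anchors, counts) / counts.sum())
        return tuple(anchors + (self.likert_total_target[modality] - weighted))


@dataclass(frozen=True)
class TrialDesign:
    n_nurses: int = 72
    patients_per_nurse_per_modality: int = 3
    n_patients: int = 148  # size of the patient pool sampled with replacement
    washout_hours: float = 24.0

    def validate(self) -> "TrialDesign":
        if self.n_nurses <= 0 or self.n_nurses % 2:
            raise ValueError("n_nurses must be a positive even number (balanced groups)")
        if self.patients_per_nurse_per_modality <= 0:
            raise ValueError("patients_per_nurse_per_modality must be positive")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        return self

    @property
    def n_assessments(self) -> int:
        return self.n_nurses * self.patients_per_nurse_per_modality * 2


@dataclass(frozen=True)
class UsabilityResponse:
    nurse_id: str
    modality: str
    items: dict[str, np.ndarray]  # domain -> 1..5 integer ratings
    domain_scores: dict[str, float]
    total: float

    @property
    def n_items(self) -> int:
        return int(sum(len(v) for v in self.items.values()))


@dataclass
class TrialDataset:
    assessments: pd.DataFrame
    usability: pd.DataFrame
    likert_items: pd.DataFrame
    design: TrialDesign
    seed: int


# -- patients ------------------------------------------------------------


def sample_patient(config: SimConfig, rng: np.random.Generator) -> PatientState:
    """Draw a latent patient: diagnosis, feature pattern, and item truths."""
    p = config.p_feature_given_nondelirium
    delirium = bool(rng.random() < config.prevalence)
    if delirium:
        while True:
            f3 = bool(rng.random() < p[Feature.F3])
            f4 = bool(rng.random() < p[Feature.F4])
            if f3 or f4:
                break
        flags = (True, True, f3, f4)
    else:
        while True:
            flags = tuple(bool(rng.random() < p[f]) for f in FEATURES)
            if not classify(flags).delirium:
                break

    bank = _shared_bank()
    feat_items = feature_evidence_map(bank)
    item_truth: dict[int, str] = {}
    for f, present in zip(FEATURES, flags):
        display = [i for i in feat_items[f] if i != AUTO_ITEM]
        if present:
            vals = [
                POSITIVE if rng.random() < config.p_item_positive_given_feature else NORMAL
                for _ in display
            ]
            if POSITIVE not in vals:
                vals[int(rng.integers(len(vals)))] = POSITIVE
            item_truth.update(zip(display, vals))
        else:
            item_truth.update({i: NORMAL for i in display})
    return PatientState(delirium=delirium, true_features=flags, item_truth=item_truth)


@lru_cache(maxsize=1)
def _shared_bank() -> ItemBank:
    return default_item_bank()


# -- single assessment ---------------------------------------------------


def simulate_assessment(
    patient: PatientState,
    modality: str,
    config: SimConfig,
    rng: np.random.Generator,
    bank: Optional[ItemBank] = None,
    nurse_id: str = "N000",
    patient_id: str = "P000",
) -> dict:
    """One nurse-administered assessment: recording noise, engine outcome, timing."""
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    bank = bank or _shared_bank()
    err = config.nurse_error_rate[modality]
    observed: dict[int, str] = {}
    human_errors = 0
    for i, truth in patient.item_truth.items():
        if rng.random() < err:
            observed[i] = NORMAL if truth == POSITIVE else POSITIVE
            human_errors += 1
        else:
            observed[i] = truth

    mode = "fast" if modality == "dst" else "full"
    session = AssessmentSession(bank, patient_id, nurse_id, modality=modality, mode=mode)
    run_scripted(session, observed)
    metrics = session.metrics()

    success = bool(rng.random() >= config.completion_failure_rate[modality])
    duration = float(
        config.time_median[modality]
        * math.exp(config.time_sigma[modality] * rng.standard_normal())
    )
    return {
        "nurse_id": nurse_id,
        "patient_id": patient_id,
        "modality": modality,
        "truth_delirium": patient.delirium,
        "outcome_delirium": session.outcome.delirium,
        "outcome_label": session.outcome.label,
        "success": success,
        "human_errors": human_errors,
        "duration_min": duration,
        "items_administered": metrics["items_administered"],
        "items_skipped": metrics["items_skipped"],
    }


# -- usability questionnaire ---------------------------------------------


@lru_cache(maxsize=256)
def _latent_mean_for_target(target: float, sd: float) -> float:
    """Latent-normal location whose equal-width 5-level discretization has
    expectation ``target``.  Ratings are round(latent) clipped to 1..5."""
    if target >= 5.0:
        return 5.0 + 8.0 * sd
    if target <= 1.0:
        return 1.0 - 8.0 * sd

    def expected(mu: float) -> float:
        ks = np.arange(1, 5)
        return float(1.0 + norm.sf((ks + 0.5 - mu) / sd).sum())

    return float(brentq(lambda m: expected(m) - target, -20.0, 30.0, xtol=1e-10))


def simulate_usability(
    nurse_id: str, modality: str, config: SimConfig, rng: np.random.Generator
) -> UsabilityResponse:
    """Draw one nurse's Likert questionnaire for one modality."""
    counts = config.likert_item_counts[modality]
    targets = config.likert_domain_targets(modality)
    sd = config.likert_latent_sd[modality]
    items: dict[str, np.ndarray] = {}
    for domain, count, target in zip(DOMAINS, counts, targets):
        mu = _latent_mean_for_target(round(target, 9), sd)
        latent = mu + sd * rng.standard_normal(count)
        items[domain] = np.clip(np.rint(latent), 1, 5).astype(int)
    domain_scores = {d: float(v.mean()) for d, v in items.items()}
    total = float(np.concatenate(list(items.values())).mean())
    return UsabilityResponse(
        nurse_id=nurse_id,
        modality=modality,
        items=items,
        domain_scores=domain_scores,
        total=total,
    )


# -- the full crossover trial --------------------------------------------


def simulate_trial(
    design: Optional[TrialDesign] = None,
    config: Optional[SimConfig] = None,
    seed: int = 0,
    bank: Optional[ItemBank] = None,
) -> TrialDataset:
    """Simulate the randomized crossover usability trial.

    Group A administers paper first, group B the app first; each nurse
    assesses ``patients_per_nurse_per_modality`` patients per modality,
    with patients drawn with replacement from a fixed pool.
    """
    design = (design or TrialDesign()).validate()
    config = (config or SimConfig()).validate()
    bank = bank or _shared_bank()
    rng = np.random.default_rng(seed)

    n = design.n_nurses
    half = n // 2
    perm = rng.permutation(n)
    group_of = {}
    nurse_ids = [f"N{i + 1:03d}" for i in range(n)]
    for pos, idx in enumerate(perm):
        group_of[nurse_ids[idx]] = "A" if pos < half else "B"

    pool = [f"P{i + 1:03d}" for i in range(design.n_patients)]
    states: dict[str, PatientState] = {}

    rows: list[dict] = []
    usability_rows: list[dict] = []
    likert_rows: list[dict] = []
    for nid in nurse_ids:
        group = group_of[nid]
        sequence = MODALITIES if group == "A" else tuple(reversed(MODALITIES))
        for order, modality in enumerate(sequence, start=1):
            for slot in range(1, design.patients_per_nurse_per_modality + 1):
                pid = pool[int(rng.integers(len(pool)))]
                if pid not in states:
                    states[pid] = sample_patient(config, rng)
                row = simulate_assessment(
                    states[pid], modality, config, rng, bank=bank,
                    nurse_id=nid, patient_id=pid,
                )
                row.update({"group": group, "order": order, "slot": slot})
                rows.append(row)
            resp = simulate_usability(nid, modality, config, rng)
            urow = {
                "nurse_id": nid,
                "group": group,
                "modality": modality,
                "order": order,
                "n_items": resp.n_items,
                "total": resp.total,
            }
            urow.update(resp.domain_scores)
            usability_rows.append(urow)
            for domain, vals in resp.items.items():
                for j, v in enumerate(vals, start=1):
                    likert_rows.append(
                        {
                            "nurse_id": nid,
                            "modality": modality,
                            "domain": domain,
                            "item_index": j,
                            "response": int(v),
                        }
                    )

    columns = [
        "nurse_id", "group", "modality", "order", "slot", "patient_id",
        "truth_delirium", "outcome_delirium", "outcome_label", "success",
        "human_errors", "duration_min", "items_administered", "items_skipped",
    ]
    assessments = pd.DataFrame(rows)[columns]
    usability = pd.DataFrame(usability_rows)[
        ["nurse_id", "group", "modality", "order", "n_items", "total", *DOMAINS]
    ]
    likert_items = pd.DataFrame(likert_rows)
    return TrialDataset(
        assessments=assessments,
        usability=usability,
        likert_items=likert_items,
        design=design,
        seed=seed,
    )
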