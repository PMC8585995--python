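"""Synthetic residential-SUD cohort generator.

Emulates the statistical structure of a residential substance-use-treatment
cohort so the full pipeline (instrument scoring -> triage -> concordance
statistics) is testable without real patient data: per-disorder true status
is Bernoulli with the validation cohort's reference prevalences, an
imperfect index screen is overlaid with configurable sensitivity and
specificity, and demographics follow the published sample's margins
(94.8% male, mean age 31.1, alcohol and cocaine the leading impact
substances).

Disorders are simulated independently by default (no comorbidity
correlation); an optional common-factor parameter induces exchangeable
positive correlation across disorders.  Random streams are counter-based
per (patient, disorder), so realizations are reproducible and the first k
patients' draws do not depend on the cohort size.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    DISORDERS,
    Disorder,
    DisorderFlag,
    Education,
    FlagSource,
    IncomeSource,
    MaritalStatus,
    PatientRecord,
    Route,
    Sex,
    Substance,
    SubstanceUseEntry,
    SuicideScreen,
)

__all__ = [
    "CohortSpec",
    "SimulatedCohort",
    "generate_cohort",
    "simulate_index_test",
    "cohort_to_frame",
    "answers_for_flags",
    "DEFAULT_PREVALENCE",
    "DEFAULT_SENSITIVITY",
    "DEFAULT_SPECIFICITY",
]

# Reference prevalences (TP+FN)/n from the n=213 validation cohort; the three
# disorders without published cells get round values consistent with the
# anxiety-spectrum rows.
DEFAULT_PREVALENCE: dict[Disorder, float] = {
    Disorder.depression: 80 / 213,
    Disorder.gad: 51 / 213,
    Disorder.ptsd: 80 / 213,
    Disorder.social_phobia: 43 / 213,
    Disorder.adhd: 58 / 213,
    Disorder.dysthymia: 30 / 213,
    Disorder.psychosis: 55 / 213,
    Disorder.mania: 21 / 213,
    Disorder.panic: 0.12,
    Disorder.agoraphobia: 0.10,
    Disorder.specific_phobia: 0.12,
}

# Published operating characteristics of the index screen per disorder; the
# three unpublished disorders default to the screen's claimed >80%/>82%.
DEFAULT_SENSITIVITY: dict[Disorder, float] = {
    Disorder.depression: 0.84,
    Disorder.gad: 0.88,
    Disorder.ptsd: 0.81,
    Disorder.social_phobia: 0.88,
    Disorder.adhd: 0.86,
    Disorder.dysthymia: 0.87,
    Disorder.psychosis: 0.81,
    Disorder.mania: 0.88,
    Disorder.panic: 0.85,
    Disorder.agoraphobia: 0.85,
    Disorder.specific_phobia: 0.85,
}
DEFAULT_SPECIFICITY: dict[Disorder, float] = {
    Disorder.depression: 0.77,
    Disorder.gad: 0.85,
    Disorder.ptsd: 0.75,
    Disorder.social_phobia: 0.85,
    Disorder.adhd: 0.89,
    Disorder.dysthymia: 0.92,
    Disorder.psychosis: 0.86,
    Disorder.mania: 0.93,
    Disorder.panic: 0.85,
    Disorder.agoraphobia: 0.85,
    Disorder.specific_phobia: 0.85,
}

# Sample margins of the n=213 validation cohort.
DEFAULT_SEX = {Sex.male: 202 / 213, Sex.female: 11 / 213}
DEFAULT_EDUCATION = {
    Education.none: 3 / 213,
    Education.elementary: 22 / 213,
    Education.high_school: 165 / 213,
    Education.college: 23 / 213,
}
DEFAULT_MARITAL = {
    MaritalStatus.single: 101 / 212,
    MaritalStatus.married_cohabiting: 57 / 212,
    MaritalStatus.widowed_divorced_separated: 54 / 212,
}
DEFAULT_INCOME = {
    IncomeSource.employment: 100 / 213,
    IncomeSource.self_employment: 8 / 213,
    IncomeSource.family_support: 77 / 213,
    IncomeSource.other: 24 / 213,
    IncomeSource.none: 4 / 213,
}
DEFAULT_SUBSTANCES = {
    Substance.alcohol: 75 / 213,
    Substance.cocaine: 70 / 213,
    Substance.marijuana: 28 / 213,
    Substance.inhalants: 33 / 213,
    Substance.other: 7 / 213,
}

AGE_MEAN, AGE_SD, AGE_MIN = 31.09, 11.12, 18

# stream tags for the counter-based RNG
_TAG_TRUTH, _TAG_INDEX, _TAG_DEMO, _TAG_SUICIDE = 0, 1, 2, 3


def _check_distribution(dist: dict, name: str, tol: float = 1e-6) -> None:
    values = list(dist.values())
    if any(v < 0 for v in values):
        raise ValueError(f"{name}: probabilities must be non-negative")
    if abs(sum(values) - 1.0) > tol:
        raise ValueError(f"{name}: probabilities sum to {sum(values):.6f}, not 1")


class CohortSpec(BaseModel):
    """Simulation parameters; defaults reproduce the validation cohort's margins."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    n: int = 213
    disorder_prevalence: dict[Disorder, float] = Field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    index_se: dict[Disorder, float] = Field(
        default_factory=lambda: dict(DEFAULT_SENSITIVITY)
    )
    index_sp: dict[Disorder, float] = Field(
        default_factory=lambda: dict(DEFAULT_SPECIFICITY)
    )
    emergency_recent_fraction: float = 0.5
    suicide_active_rate: float = 0.05
    suicide_lifetime_rate: float = 0.10
    comorbidity_factor: float = 0.0
    sex_distribution: dict[Sex, float] = Field(default_factory=lambda: dict(DEFAULT_SEX))
    education_distribution: dict[Education, float] = Field(
        default_factory=lambda: dict(DEFAULT_EDUCATION)
    )
    marital_distribution: dict[MaritalStatus, float] = Field(
        default_factory=lambda: dict(DEFAULT_MARITAL)
    )
    income_distribution: dict[IncomeSource, float] = Field(
        default_factory=lambda: dict(DEFAULT_INCOME)
    )
    substance_mix: dict[Substance, float] = Field(
        default_factory=lambda: dict(DEFAULT_SUBSTANCES)
    )
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortSpec":
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("emergency_recent_fraction", "suicide_active_rate",
                     "suicide_lifetime_rate", "comorbidity_factor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for mapping, label in (
            (self.disorder_prevalence, "disorder_prevalence"),
            (self.index_se, "index_se"),
            (self.index_sp, "index_sp"),
        ):
            for d, v in mapping.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{label}[{d.value}] = {v} outside [0, 1]")
        for dist, label in (
            (self.sex_distribution, "sex_distribution"),
            (self.education_distribution, "education_distribution"),
            (self.marital_distribution, "marital_distribution"),
            (self.income_distribution, "income_distribution"),
            (self.substance_mix, "substance_mix"),
        ):
            _check_distribution(dist, label)
        return self


class SimulatedCohort(BaseModel):
    model_config = ConfigDict(extra="forbid")

    records: list[PatientRecord]
    truth: dict[str, list[DisorderFlag]]
    index: dict[str, list[DisorderFlag]]
    spec: CohortSpec


def _rng(seed: int, *tags: int) -> np.random.Generator:
    """Counter-based stream: an independent generator per (seed, *tags)."""
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def _draw_categorical(rng: np.random.Generator, dist: dict):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _draw_recency(rng: np.random.Generator, recent_fraction: float, window: int = 30) -> int:
    if rng.random() < recent_fraction:
        return int(rng.integers(0, window + 1))
    return int(rng.integers(window + 1, 731))


def _record_id(i: int) -> str:
    return f"SIM-{i:06d}"


def generate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a cohort: truth flags, index-screen flags, and patient records.

    Per patient, each disorder's true status is Bernoulli(prevalence); with a
    positive ``comorbidity_factor`` q a patient-level severity coin shifts
    every disorder's probability toward 0/1 jointly, inducing exchangeable
    positive correlation while preserving the marginal prevalences.  The
    index flag is then drawn from the truth with the configured Se/Sp (see
    :func:`simulate_index_test`).  Deterministic given ``spec.seed``; an
    ``n=0`` spec yields an empty cohort.
    """
    records: list[PatientRecord] = []
    truth: dict[str, list[DisorderFlag]] = {}
    index: dict[str, list[DisorderFlag]] = {}
    disorders = [d for d in DISORDERS if d in spec.disorder_prevalence]

    for i in range(spec.n):
        rid = _record_id(i)
        truth_flags: list[DisorderFlag] = []
        index_flags: list[DisorderFlag] = []
        # severity coin for the optional common-factor comorbidity structure
        severe = _rng(spec.seed, _TAG_TRUTH, i, len(DISORDERS)).random() < 0.5
        for disorder in disorders:
            j = DISORDERS.index(disorder)
            rng = _rng(spec.seed, _TAG_TRUTH, i, j)
            pi = spec.disorder_prevalence[disorder]
            q = spec.comorbidity_factor
            # mixture keeps the marginal at pi: 0.5*(pi+q*min(pi,1-pi)) + 0.5*(pi-q*...)
            shift = q * min(pi, 1 - pi)
            p = pi + shift if severe else pi - shift
            positive = rng.random() < p
            recency = _draw_recency(rng, spec.emergency_recent_fraction) if positive else None
            truth_flags.append(
                DisorderFlag(
                    disorder=disorder,
                    probable=positive,
                    days_since_last_episode=recency,
                    source=FlagSource.reference_mini,
                )
            )
            irng = _rng(spec.seed, _TAG_INDEX, i, j)
            if positive:
                ipos = irng.random() < spec.index_se[disorder]
            else:
                ipos = irng.random() < 1 - spec.index_sp[disorder]
            index_flags.append(
                DisorderFlag(
                    disorder=disorder,
                    probable=ipos,
                    days_since_last_episode=(
                        (recency if recency is not None else _draw_recency(
                            irng, spec.emergency_recent_fraction))
                        if ipos else None
                    ),
                    source=FlagSource.ddsi,
                )
            )
        truth[rid] = truth_flags
        index[rid] = index_flags

        drng = _rng(spec.seed, _TAG_DEMO, i)
        age = max(AGE_MIN, int(round(drng.normal(AGE_MEAN, AGE_SD))))
        impact = _draw_categorical(drng, spec.substance_mix)
        srng = _rng(spec.seed, _TAG_SUICIDE, i)
        u = srng.random()
        if u < spec.suicide_active_rate:
            suicide = SuicideScreen(
                ideation=True,
                intentionality=int(srng.integers(5, 11)),
                days_since_last_indicator=int(srng.integers(0, 31)),
            )
        elif u < spec.suicide_active_rate + spec.suicide_lifetime_rate:
            suicide = SuicideScreen(
                lifetime_attempt=True,
                days_since_last_indicator=int(srng.integers(31, 1096)),
            )
        else:
            suicide = SuicideScreen()
        records.append(
            PatientRecord(
                record_id=rid,
                age=age,
                sex=_draw_categorical(drng, spec.sex_distribution),
                education=_draw_categorical(drng, spec.education_distribution),
                marital_status=_draw_categorical(drng, spec.marital_distribution),
                income_source=_draw_categorical(drng, spec.income_distribution),
                substance_use=[
                    SubstanceUseEntry(
                        substance=impact,
                        age_of_onset=max(10, age - int(drng.integers(1, 16))),
                        lifetime_use=True,
                        days_used_past_30=int(drng.integers(0, 31)),
                        longest_abstinence=int(drng.integers(0, 366)),
                        route=Route.oral if impact is Substance.alcohol else Route.other,
                        is_impact_substance=True,
                    )
                ],
                days_in_residence=int(drng.integers(7, 181)),
                suicide=suicide,
            )
        )

    return SimulatedCohort(records=records, truth=truth, index=index, spec=spec)


def simulate_index_test(
    truth: dict[str, list[DisorderFlag]],
    se: float | dict[Disorder, float],
    sp: float | dict[Disorder, float],
    seed: int,
    recent_fraction: float = 0.5,
) -> dict[str, list[DisorderFlag]]:
    """Overlay an imperfect index screen on reference-standard flags.

    Each flag is re-drawn independently: positive with probability ``se``
    where the truth is positive, with probability ``1 - sp`` where negative.
    ``se``/``sp`` may be scalars or per-disorder maps.  Deterministic given
    ``seed``; streams are per (patient position, disorder), so a patient's
    draws do not depend on cohort size.
    """

    def rate(table: float | dict[Disorder, float], d: Disorder) -> float:
        v = table[d] if isinstance(table, dict) else float(table)
        if not 0 <= v <= 1:
            raise ValueError(f"rate {v} for {d.value} outside [0, 1]")
        return v

    index: dict[str, list[DisorderFlag]] = {}
    for i, rid in enumerate(truth):
        out: list[DisorderFlag] = []
        for flag in truth[rid]:
            j = DISORDERS.index(flag.disorder)
            rng = _rng(seed, _TAG_INDEX, i, j)
            if flag.probable:
                positive = rng.random() < rate(se, flag.disorder)
            else:
                positive = rng.random() < 1 - rate(sp, flag.disorder)
            recency = None
            if positive:
                recency = (
                    flag.days_since_last_episode
                    if flag.days_since_last_episode is not None
                    else _draw_recency(rng, recent_fraction)
                )
            out.append(
                DisorderFlag(
                    disorder=flag.disorder,
                    probable=positive,
                    days_since_last_episode=recency,
                    source=FlagSource.ddsi,
                )
            )
        index[rid] = out
    return index


def cohort_to_frame(cohort: SimulatedCohort):
    """Paired-cohort layout (``<disorder>_index`` / ``<disorder>_reference``)."""
    from .psychometrics import flags_to_frame

    return flags_to_frame(cohort.index, cohort.truth)


def answers_for_flags(definition, flags: list[DisorderFlag]) -> list[Optional[int]]:
    """Construct interview responses that reproduce the given disorder flags.

    For each probable disorder, endorses just enough of its module rule's
    items (all of them for an ``all_of`` rule, ``at_least`` of them for an
    ``any_of`` rule); every other item is answered negative.  Screening the
    returned responses with the same definition yields exactly ``flags``.
    """
    if definition.modules is None:
        raise ValueError("definition is not module-rule scored")
    responses: dict[str, int] = {it.item_id: 0 for it in definition.items}
    for flag in flags:
        rule = definition.modules.get(flag.disorder)
        if rule is None:
            raise ValueError(f"definition has no module for {flag.disorder.value}")
        if flag.probable:
            targets = (
                rule.all_of if rule.all_of is not None else rule.any_of[: rule.at_least]
            )
            for item_id in targets:
                responses[item_id] = 1
    return [responses[it.item_id] for it in definition.items]
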