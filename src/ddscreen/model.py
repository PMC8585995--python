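"""Domain types for dual-disorder screening sessions.

A screening session in a residential substance-use treatment facility is
represented by a :class:`PatientRecord`: sociodemographics, the substance-use
pattern, raw instrument responses, and an optional suicide screen.  Screening
outputs are :class:`DisorderFlag` objects — one probable/not-probable verdict
per psychiatric disorder — tagged with their source (the brief screening
interview, or the structured diagnostic interview used as reference standard).

Structural parsing (types, enum membership, unknown keys) is handled by
pydantic; *eligibility and range invariants* are checked separately by
:func:`validate_record`, which reports every violated rule rather than
stopping at the first.
"""

from __future__ import annotations

import enum
import warnings
from typing import Any, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "Disorder",
    "DISORDERS",
    "EMERGENCY_DISORDERS",
    "Sex",
    "Education",
    "MaritalStatus",
    "IncomeSource",
    "Substance",
    "Route",
    "FlagSource",
    "SubstanceUseEntry",
    "SuicideScreen",
    "PatientRecord",
    "DisorderFlag",
    "RecordValidationError",
    "validate_record",
    "load_patient_record",
]

MIN_AGE_YEARS = 18
MIN_DAYS_IN_RESIDENCE = 7


class Disorder(str, enum.Enum):
    """The eleven psychiatric disorders covered by the screening interview."""

    depression = "depression"
    dysthymia = "dysthymia"
    mania = "mania"
    psychosis = "psychosis"
    panic = "panic"
    agoraphobia = "agoraphobia"
    specific_phobia = "specific_phobia"
    social_phobia = "social_phobia"
    gad = "gad"
    ptsd = "ptsd"
    adhd = "adhd"


#: Canonical ordering of the screened disorders.
DISORDERS: tuple[Disorder, ...] = tuple(Disorder)

#: Disorders treated as psychiatric emergencies when recently symptomatic
#: (psychotic and manic episodes; suicidality is handled by its own screen).
EMERGENCY_DISORDERS: frozenset[Disorder] = frozenset({Disorder.psychosis, Disorder.mania})


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    # accepted on input; excluded from sex-stratified statistics
    unspecified = "unspecified"


class Education(str, enum.Enum):
    none = "none"
    elementary = "elementary"
    high_school = "high_school"
    college = "college"
    other_unknown = "other_unknown"


class MaritalStatus(str, enum.Enum):
    single = "single"
    married_cohabiting = "married_cohabiting"
    widowed_divorced_separated = "widowed_divorced_separated"
    other_unknown = "other_unknown"


class IncomeSource(str, enum.Enum):
    employment = "employment"
    self_employment = "self_employment"
    family_support = "family_support"
    other = "other"
    none = "none"
    unknown = "unknown"


class Substance(str, enum.Enum):
    alcohol = "alcohol"
    cocaine = "cocaine"
    marijuana = "marijuana"
    inhalants = "inhalants"
    other = "other"


class Route(str, enum.Enum):
    oral = "oral"
    nasal = "nasal"
    smoked = "smoked"
    injected = "injected"
    other = "other"


class FlagSource(str, enum.Enum):
    """Provenance of a disorder verdict: index screen or reference standard."""

    ddsi = "ddsi"
    reference_mini = "reference_mini"


class SubstanceUseEntry(BaseModel):
    """One substance's use pattern: onset, recency, route, impact status."""

    model_config = ConfigDict(extra="forbid")

    substance: Substance
    age_of_onset: Optional[int] = None
    lifetime_use: bool = True
    days_used_past_30: int = 0
    longest_abstinence: Optional[int] = None
    route: Route = Route.other
    is_impact_substance: bool = False


class SuicideScreen(BaseModel):
    """Four acute suicidality indicators plus lifetime-attempt history.

    ``days_since_last_indicator`` dates the most recent indicator and is what
    the triage algorithm compares with its acuity window.
    """

    model_config = ConfigDict(extra="forbid")

    ideation: bool = False
    planning: bool = False
    attempt: bool = False
    intentionality: int = 0
    days_since_last_indicator: Optional[int] = None
    lifetime_attempt: bool = False


class PatientRecord(BaseModel):
    """One screened individual, as entered at intake."""

    model_config = ConfigDict(extra="forbid")

    record_id: str
    age: int
    sex: Sex
    education: Education = Education.other_unknown
    marital_status: MaritalStatus = MaritalStatus.other_unknown
    income_source: IncomeSource = IncomeSource.unknown
    substance_use: list[SubstanceUseEntry] = Field(default_factory=list)
    days_in_residence: int = MIN_DAYS_IN_RESIDENCE
    item_responses: dict[str, list[Optional[int]]] = Field(default_factory=dict)
    suicide: Optional[SuicideScreen] = None


class DisorderFlag(BaseModel):
    """Per-disorder probable/not-probable verdict with symptom recency."""

    model_config = ConfigDict(extra="forbid")

    disorder: Disorder
    probable: bool
    days_since_last_episode: Optional[int] = None
    source: FlagSource = FlagSource.ddsi

    def model_post_init(self, __context: Any) -> None:
        if not self.probable and self.days_since_last_episode is not None:
            raise ValueError(
                f"{self.disorder.value}: days_since_last_episode is only "
                "meaningful when probable=True"
            )


class RecordValidationError(ValueError):
    """Raised when a record violates eligibility or range rules.

    ``errors`` lists *every* violated rule, not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def record_violations(record: PatientRecord, intentionality_max: int = 10) -> list[str]:
    """Return the exhaustive list of invariant violations for ``record``.

    An empty list means the record is valid.  Checked rules:

    * eligibility: age >= 18 years, at least 7 days in residential treatment
      (to wash out residual intoxication effects);
    * each substance entry: 0 <= days_used_past_30 <= 30;
    * at most one substance marked as the impact substance;
    * suicide screen: intentionality within [0, intentionality_max]; the
      recency field present only when some indicator or lifetime attempt is.
    """
    errors: list[str] = []
    if record.age < MIN_AGE_YEARS:
        errors.append(
            f"eligibility: age {record.age} below the minimum of {MIN_AGE_YEARS} years"
        )
    if record.days_in_residence < MIN_DAYS_IN_RESIDENCE:
        errors.append(
            f"eligibility: {record.days_in_residence} days in residence, "
            f"minimum is {MIN_DAYS_IN_RESIDENCE}"
        )
    n_impact = 0
    for entry in record.substance_use:
        if not 0 <= entry.days_used_past_30 <= 30:
            errors.append(
                f"range: {entry.substance.value} days_used_past_30="
                f"{entry.days_used_past_30} outside [0, 30]"
            )
        if entry.is_impact_substance:
            n_impact += 1
    if n_impact > 1:
        errors.append(f"substance_use: {n_impact} impact substances marked, at most 1 allowed")
    s = record.suicide
    if s is not None:
        if not 0 <= s.intentionality <= intentionality_max:
            errors.append(
                f"range: suicide intentionality {s.intentionality} outside "
                f"[0, {intentionality_max}]"
            )
        no_indicator = not (
            s.ideation or s.planning or s.attempt or s.lifetime_attempt
            or s.intentionality > 0
        )
        if no_indicator and s.days_since_last_indicator is not None:
            errors.append(
                "suicide: days_since_last_indicator present but no indicator "
                "or lifetime attempt reported"
            )
    return errors


def validate_record(record: PatientRecord, intentionality_max: int = 10) -> PatientRecord:
    """Validate a record against the eligibility and range invariants.

    Returns the record unchanged when all invariants hold (so validation is
    idempotent); otherwise raises :class:`RecordValidationError` carrying the
    full list of violations.
    """
    errors = record_violations(record, intentionality_max=intentionality_max)
    if errors:
        raise RecordValidationError(errors)
    return record


def load_patient_record(document: Mapping[str, Any], strict: bool = True) -> PatientRecord:
    """Build a :class:`PatientRecord` from a parsed answer-file document.

    Keys must match the field names of :class:`PatientRecord`.  Unknown keys
    are rejected in strict mode and dropped with a warning in lenient mode,
    so degraded field data can still be screened.
    """
    if not strict:
        known = set(PatientRecord.model_fields)
        unknown = set(document) - known
        if unknown:
            warnings.warn(
                f"ignoring unknown answer-file keys: {sorted(unknown)}",
                stacklevel=2,
            )
            document = {k: v for k, v in document.items() if k in known}
    return PatientRecord.model_validate(document)
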