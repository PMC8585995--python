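"""Definition-driven scoring engine for the screening battery.

Instruments are described by small YAML/JSON documents (items, response
scales, reverse-keyed items, skip rules, a scoring rule and a positivity
threshold) and scored generically, so the battery — the alcohol-dependence
questionnaire (SADD, summed 0–3 items, cut-off 7), the drug-abuse screen
(DAST-10, yes/no items with one reverse-keyed item, cut-off 3), the suicide
screen, and the eleven-module dual-diagnosis screening interview — is
configuration, not code.

The dual-diagnosis interview's item content is unpublished, so the shipped
definition is a structurally faithful shell: eleven disorder modules whose
positivity rules are configurable predicates over item ids.  All tests drive
it through generated answer sets.

Missing responses are hard errors; a screening tool must never impute
symptom data.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import TYPE_CHECKING, Any, Mapping, Optional, Sequence, Union

import yaml
from importlib import resources
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .model import DISORDERS, Disorder, DisorderFlag, FlagSource, SuicideScreen

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a module cycle
    from .triage import TriageConfig

__all__ = [
    "ResponseScale",
    "Item",
    "InstrumentDefinition",
    "InstrumentScore",
    "SuicideTier",
    "DefinitionError",
    "ScoringError",
    "load_instrument_definition",
    "load_default_instrument",
    "DEFAULT_INSTRUMENTS",
    "score_fixed_sum_instrument",
    "screen_ddsi_modules",
    "screen_suicide",
    "reverse_key",
]

#: Instrument ids shipped with the package.
DEFAULT_INSTRUMENTS = ("sadd", "dast10", "suicide_screen", "ddsi")


class DefinitionError(ValueError):
    """An instrument definition document violates its schema."""


class ScoringError(ValueError):
    """Responses cannot be scored against the definition (off-scale or missing)."""


class ResponseScale(str, enum.Enum):
    binary_yes_no = "binary_yes_no"
    ordinal_0_3 = "ordinal_0_3"
    ordinal_0_10 = "ordinal_0_10"

    @property
    def max_value(self) -> int:
        return {"binary_yes_no": 1, "ordinal_0_3": 3, "ordinal_0_10": 10}[self.value]

    def contains(self, value: int) -> bool:
        return 0 <= value <= self.max_value


class SkipRule(BaseModel):
    """Skip this item when an earlier item's response equals ``equals``."""

    model_config = ConfigDict(extra="forbid")

    item: str
    equals: int


class Item(BaseModel):
    model_config = ConfigDict(extra="forbid")

    item_id: str
    prompt: str = ""
    response_scale: ResponseScale = ResponseScale.binary_yes_no
    skip_if: Optional[SkipRule] = None


class ScoreBand(BaseModel):
    """Severity band reported in the interpretation; never drives triage."""

    model_config = ConfigDict(extra="forbid")

    min: float
    max: float
    label: str


class ModuleRule(BaseModel):
    """Positivity predicate of one disorder module over item ids.

    Exactly one of ``any_of`` / ``all_of`` must be given, optionally with
    ``at_least`` to require that many positive responses among ``any_of``.
    """

    model_config = ConfigDict(extra="forbid")

    any_of: Optional[list[str]] = None
    all_of: Optional[list[str]] = None
    at_least: int = 1

    @model_validator(mode="after")
    def _one_kind(self) -> "ModuleRule":
        if (self.any_of is None) == (self.all_of is None):
            raise ValueError("module rule needs exactly one of any_of/all_of")
        if self.at_least < 1:
            raise ValueError("at_least must be >= 1")
        return self

    @property
    def referenced_items(self) -> list[str]:
        return list(self.any_of or self.all_of or [])


class Scoring(str, enum.Enum):
    sum = "sum"
    module_rule = "module_rule"


class InstrumentDefinition(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    instrument_id: str
    title: str = ""
    scoring: Scoring = Scoring.sum
    items: list[Item]
    reverse_keyed: set[str] = Field(default_factory=set)
    positivity_threshold: float = 1
    modules: Optional[dict[Disorder, ModuleRule]] = None
    bands: list[ScoreBand] = Field(default_factory=list)

    @field_validator("items")
    @classmethod
    def _unique_ids(cls, items: list[Item]) -> list[Item]:
        seen: set[str] = set()
        for it in items:
            if it.item_id in seen:
                raise ValueError(f"duplicate item id {it.item_id!r}")
            seen.add(it.item_id)
        return items

    @model_validator(mode="after")
    def _check(self) -> "InstrumentDefinition":
        ids = [it.item_id for it in self.items]
        idset = set(ids)
        unknown = self.reverse_keyed - idset
        if unknown:
            raise ValueError(f"reverse_keyed references unknown items: {sorted(unknown)}")
        for pos, it in enumerate(self.items):
            if it.skip_if is not None:
                if it.skip_if.item not in idset:
                    raise ValueError(
                        f"item {it.item_id!r}: skip rule references unknown "
                        f"item {it.skip_if.item!r}"
                    )
                if ids.index(it.skip_if.item) >= pos:
                    raise ValueError(
                        f"item {it.item_id!r}: skip rule may only reference "
                        "items earlier in order"
                    )
        if self.scoring is Scoring.sum:
            if not 0 <= self.positivity_threshold <= self.max_total:
                raise ValueError(
                    f"positivity_threshold {self.positivity_threshold} outside "
                    f"achievable range [0, {self.max_total}]"
                )
        else:
            if not self.modules:
                raise ValueError("module_rule scoring requires a modules map")
            for disorder, rule in self.modules.items():
                missing = set(rule.referenced_items) - idset
                if missing:
                    raise ValueError(
                        f"module {disorder.value}: rule references unknown "
                        f"items {sorted(missing)}"
                    )
        return self

    @property
    def max_total(self) -> int:
        """Largest achievable sum score (all items answered at scale maximum)."""
        return sum(it.response_scale.max_value for it in self.items)

    def item_index(self) -> dict[str, int]:
        return {it.item_id: i for i, it in enumerate(self.items)}


class InstrumentScore(BaseModel):
    model_config = ConfigDict(extra="forbid")

    instrument_id: str
    total: float
    positive: bool
    interpretation: str = ""
    answered: int = 0
    skipped: int = 0


def reverse_key(value: int, scale: ResponseScale) -> int:
    """Invert a response on its scale (an involution: applying twice restores it)."""
    return scale.max_value - value


def load_instrument_definition(
    document: Union[str, Path, Mapping[str, Any]],
) -> InstrumentDefinition:
    """Parse and validate an instrument definition.

    ``document`` may be a mapping (already parsed), a path to a YAML/JSON
    file, or YAML/JSON text.  Schema violations — duplicate item ids, an
    unreachable positivity threshold, a skip rule referencing a later item —
    raise :class:`DefinitionError`.
    """
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and document.endswith((".yaml", ".yml", ".json"))
    ):
        text = Path(document).read_text(encoding="utf-8")
    elif isinstance(document, str):
        text = document
    else:
        try:
            return InstrumentDefinition.model_validate(dict(document))
        except ValueError as exc:
            raise DefinitionError(str(exc)) from exc
    try:
        parsed = yaml.safe_load(text) if not text.lstrip().startswith("{") else json.loads(text)
    except Exception as exc:
        raise DefinitionError(f"cannot parse definition document: {exc}") from exc
    if not isinstance(parsed, Mapping):
        raise DefinitionError("definition document must be a mapping")
    try:
        return InstrumentDefinition.model_validate(dict(parsed))
    except ValueError as exc:
        raise DefinitionError(str(exc)) from exc


def load_default_instrument(instrument_id: str) -> InstrumentDefinition:
    """Load one of the shipped instrument definitions (see DEFAULT_INSTRUMENTS)."""
    if instrument_id not in DEFAULT_INSTRUMENTS:
        raise DefinitionError(
            f"no shipped instrument {instrument_id!r}; available: {DEFAULT_INSTRUMENTS}"
        )
    text = (resources.files("ddscreen.data") / f"{instrument_id}.yaml").read_text("utf-8")
    return load_instrument_definition(text)


def _resolve_responses(
    definition: InstrumentDefinition, responses: Sequence[Optional[int]]
) -> tuple[dict[str, Optional[int]], int]:
    """Map item id -> response, honouring skip rules; returns (values, n_skipped).

    A skipped item's value is recorded as None.  Raises ScoringError for an
    off-scale value or a missing response on a non-skipped item.
    """
    if len(responses) != len(definition.items):
        raise ScoringError(
            f"{definition.instrument_id}: got {len(responses)} responses for "
            f"{len(definition.items)} items"
        )
    values: dict[str, Optional[int]] = {}
    skipped = 0
    for item, resp in zip(definition.items, responses):
        rule = item.skip_if
        if rule is not None and values.get(rule.item) == rule.equals:
            values[item.item_id] = None
            skipped += 1
            continue
        if resp is None:
            raise ScoringError(
                f"{definition.instrument_id}: missing response for non-skipped "
                f"item {item.item_id!r}"
            )
        if not item.response_scale.contains(resp):
            raise ScoringError(
                f"{definition.instrument_id}: response {resp} for item "
                f"{item.item_id!r} is off the {item.response_scale.value} scale"
            )
        values[item.item_id] = resp
    return values, skipped


def score_fixed_sum_instrument(
    definition: InstrumentDefinition, responses: Sequence[Optional[int]]
) -> InstrumentScore:
    """Score a sum-type instrument.

    ``responses`` is ordered like ``definition.items``; positions whose skip
    rule fired may hold ``None``.  Reverse-keyed items are inverted on their
    own scale before summing.  ``positive`` is ``total >= positivity_threshold``.
    """
    if definition.scoring is not Scoring.sum:
        raise ScoringError(f"{definition.instrument_id} is not a sum-scored instrument")
    values, skipped = _resolve_responses(definition, responses)
    total = 0
    for item in definition.items:
        v = values[item.item_id]
        if v is None:
            continue
        if item.item_id in definition.reverse_keyed:
            v = reverse_key(v, item.response_scale)
        total += v
    positive = total >= definition.positivity_threshold
    label = next(
        (b.label for b in definition.bands if b.min <= total <= b.max), None
    )
    interp = f"total {total}/{definition.max_total}, " + (
        "positive" if positive else "negative"
    ) + f" at cut-off {definition.positivity_threshold:g}"
    if label:
        interp += f" ({label})"
    return InstrumentScore(
        instrument_id=definition.instrument_id,
        total=total,
        positive=positive,
        interpretation=interp,
        answered=len(definition.items) - skipped,
        skipped=skipped,
    )


def screen_ddsi_modules(
    definition: InstrumentDefinition,
    responses: Sequence[Optional[int]],
    recency_answers: Optional[Mapping[Disorder, int]] = None,
) -> list[DisorderFlag]:
    """Evaluate every disorder module of the screening interview.

    Returns one :class:`DisorderFlag` per configured module, in the canonical
    disorder order.  A module is probable when its rule evaluates true over
    the (skip-resolved) responses; recency in days is copied from
    ``recency_answers`` for probable disorders.  Flags carry source ``ddsi``.
    """
    if definition.scoring is not Scoring.module_rule or definition.modules is None:
        raise ScoringError(f"{definition.instrument_id} is not module-rule scored")
    values, _ = _resolve_responses(definition, responses)
    recency_answers = recency_answers or {}
    flags: list[DisorderFlag] = []
    for disorder in DISORDERS:
        rule = definition.modules.get(disorder)
        if rule is None:
            continue
        hits = 0
        for item_id in rule.referenced_items:
            v = values[item_id]
            if v is None:
                # skipped item counts as a negative response to the rule
                continue
            if v >= 1:
                hits += 1
        if rule.all_of is not None:
            probable = hits == len(rule.all_of)
        else:
            probable = hits >= rule.at_least
        flags.append(
            DisorderFlag(
                disorder=disorder,
                probable=probable,
                days_since_last_episode=recency_answers.get(disorder) if probable else None,
                source=FlagSource.ddsi,
            )
        )
    return flags


class SuicideTier(str, enum.Enum):
    """Suicidality triage tier from the acute-indicator screen."""

    active_emergency = "active_emergency"
    non_acute_risk = "non_acute_risk"
    none = "none"


def screen_suicide(screen: SuicideScreen, config: "TriageConfig") -> SuicideTier:
    """Tier a suicide screen into active emergency / non-acute risk / none.

    An acute signal is ideation, planning, an attempt, or intentionality at
    or above ``config.intentionality_threshold``.  A signal within the acuity
    window (``config.acuity_window_days``, default 30) is an active
    emergency; beyond the window it is non-acute risk, as is a lifetime
    attempt with no current signal.  An acute signal with no recency recorded
    cannot be tiered and raises :class:`ScoringError`.
    """
    acute_signal = (
        screen.ideation
        or screen.planning
        or screen.attempt
        or screen.intentionality >= config.intentionality_threshold
    )
    if acute_signal:
        if screen.days_since_last_indicator is None:
            raise ScoringError(
                "suicide screen: acute indicator present but "
                "days_since_last_indicator missing; acuity cannot be assessed"
            )
        if screen.days_since_last_indicator <= config.acuity_window_days:
            return SuicideTier.active_emergency
        return SuicideTier.non_acute_risk
    if screen.lifetime_attempt:
        return SuicideTier.non_acute_risk
    return SuicideTier.none
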