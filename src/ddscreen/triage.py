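"""Traffic-light triage of screening outputs.

The screen assumes it is administered at a community residential treatment
facility with no on-site mental-health specialist, so its job is to
prioritise: distinguish a genuine psychiatric emergency — an active
psychotic or manic episode, or acute suicidality — from probable but
non-acute co-occurring disorders, and from the absence of any probable
disorder.

The rule, evaluated red first, then yellow, then green:

* **red** — suicide screen tiers as an active emergency, or an emergency
  disorder (psychosis or mania by default) is probable with its last
  symptomatic episode inside the acuity window (30 days by default).
  Priority referral to a specialized institution.
* **yellow** — not red, and there is non-acute suicide risk, or an emergency
  disorder is probable with a remote last episode, or any non-emergency
  disorder is probable.  Referral to a mental-health specialist.
* **green** — none of the above.  Continue standard treatment.

Alcohol- and drug-screen positivity (SADD >= 7, DAST-10 >= 3) is carried on
the result for the report but never alters the light: every resident of such
a facility is in substance-use treatment already, and gating the light on
the substance scores would leave sub-threshold patients with no light at
all.  A strict fidelity mode that does gate green on both substance screens
is available via ``strict_green=True``; when no rule fires there, the result
carries ``light=None`` and ``no_rule_fired=True``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .instruments import InstrumentScore, ScoringError, SuicideTier
from .model import EMERGENCY_DISORDERS, Disorder, DisorderFlag

__all__ = [
    "Light",
    "TriageConfig",
    "TriageResult",
    "TriageDataError",
    "assign_light",
    "recommendation_text",
    "load_language_resource",
]


class Light(str, enum.Enum):
    red = "red"
    yellow = "yellow"
    green = "green"


class TriageConfig(BaseModel):
    """Tunable thresholds of the triage rule.

    Defaults are the published algorithm's: a 30-day acuity window,
    suicidal-intentionality cut-off 5 on the 0-10 scale, alcohol screen
    cut-off 7 (SADD) and drug screen cut-off 3 (DAST-10), and psychosis and
    mania as the emergency disorders.
    """

    model_config = ConfigDict(extra="forbid")

    acuity_window_days: int = 30
    intentionality_threshold: int = 5
    aud_threshold: float = 7
    sud_threshold: float = 3
    emergency_disorders: frozenset[Disorder] = Field(
        default_factory=lambda: frozenset(EMERGENCY_DISORDERS)
    )

    @field_validator("acuity_window_days")
    @classmethod
    def _positive_window(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("acuity_window_days must be positive")
        return v


class TriageResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    light: Optional[Light]
    triggers: list[str] = Field(default_factory=list)
    recommendation: str = ""
    aud_positive: bool = False
    sud_positive: bool = False
    no_rule_fired: bool = False


class TriageDataError(ValueError):
    """Triage cannot be decided from the data given (e.g. missing recency)."""


def _classify_flags(
    flags: Iterable[DisorderFlag], config: TriageConfig
) -> tuple[list[str], list[str], list[str]]:
    """Split probable flags into (emergency-recent, emergency-remote, other)."""
    emergency_recent: list[str] = []
    emergency_remote: list[str] = []
    non_emergency: list[str] = []
    for flag in flags:
        if not flag.probable:
            continue
        if flag.disorder in config.emergency_disorders:
            if flag.days_since_last_episode is None:
                raise TriageDataError(
                    f"probable emergency disorder {flag.disorder.value} has no "
                    "days_since_last_episode; acuity cannot be decided"
                )
            if flag.days_since_last_episode <= config.acuity_window_days:
                emergency_recent.append(flag.disorder.value)
            else:
                emergency_remote.append(flag.disorder.value)
        else:
            non_emergency.append(flag.disorder.value)
    return emergency_recent, emergency_remote, non_emergency


def assign_light(
    flags: Iterable[DisorderFlag],
    suicide_tier: SuicideTier,
    aud: Optional[InstrumentScore] = None,
    sud: Optional[InstrumentScore] = None,
    config: Optional[TriageConfig] = None,
    language_resource: Optional[Mapping[str, str]] = None,
    strict_green: bool = False,
) -> TriageResult:
    """Assign exactly one traffic light to a screening session.

    ``flags`` are the index-screen disorder verdicts, ``suicide_tier`` the
    output of the suicide screen, ``aud``/``sud`` the alcohol and drug
    instrument scores (optional; reported, never light-altering unless
    ``strict_green``).  Precedence is red > yellow > green and the triggers
    list names every condition that fired for the assigned light.
    """
    config = config or TriageConfig()
    emergency_recent, emergency_remote, non_emergency = _classify_flags(flags, config)

    aud_positive = bool(aud.positive) if aud is not None else False
    sud_positive = bool(sud.positive) if sud is not None else False

    triggers: list[str] = []
    if suicide_tier is SuicideTier.active_emergency:
        triggers.append("suicide:active_emergency")
    triggers.extend(f"{d}:episode_within_window" for d in emergency_recent)
    if triggers:
        light: Optional[Light] = Light.red
    else:
        if suicide_tier is SuicideTier.non_acute_risk:
            triggers.append("suicide:non_acute_risk")
        triggers.extend(f"{d}:episode_beyond_window" for d in emergency_remote)
        triggers.extend(f"{d}:probable" for d in non_emergency)
        if triggers:
            light = Light.yellow
        elif strict_green and not (aud_positive and sud_positive):
            # literal published green condition also requires AUD>=7 and SUD>=3
            return TriageResult(
                light=None,
                triggers=[],
                recommendation="",
                aud_positive=aud_positive,
                sud_positive=sud_positive,
                no_rule_fired=True,
            )
        else:
            light = Light.green

    return TriageResult(
        light=light,
        triggers=triggers,
        recommendation=recommendation_text(light, language_resource),
        aud_positive=aud_positive,
        sud_positive=sud_positive,
    )


def load_language_resource(path: Union[str, Path, None] = None) -> dict[str, str]:
    """Load recommendation texts; the shipped English resource by default."""
    if path is None:
        text = (resources.files("ddscreen.data") / "recommendations_en.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError("language resource must be a mapping of light -> text")
    return {str(k): str(v) for k, v in loaded.items()}


def recommendation_text(
    light: Light, language_resource: Optional[Mapping[str, str]] = None
) -> str:
    """The recommendation paragraph for a light, from the language resource."""
    if not isinstance(light, Light):
        raise ValueError(f"unknown light {light!r}")
    texts = language_resource if language_resource is not None else load_language_resource()
    try:
        return texts[light.value]
    except KeyError as exc:
        raise ValueError(f"language resource has no text for {light.value!r}") from exc
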