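# ddscreen

A toolkit for **dual-disorder screening** in residential substance-use
treatment settings: a configuration-driven scoring engine for a brief
screening battery, the **traffic-light triage algorithm** that sorts
patients into red / yellow / green referral tiers, and the
diagnostic-accuracy statistics used to validate a screening interview
against a structured diagnostic interview as reference standard — plus a
synthetic-cohort simulator so the whole pipeline is testable without real
patient data.

## Who this is for

Community residential facilities for substance-use disorders often have no
on-site mental-health specialist, yet a majority of their residents have a
co-occurring psychiatric disorder ("dual disorder"). A standardized
screening step at intake lets non-specialist staff identify probable
disorders, distinguish genuine psychiatric emergencies from non-acute risk,
and refer accordingly. `ddscreen` implements the computational core of such
a screening service, and the statistical machinery a methodologist needs to
validate the screen.

## The pieces

**Screening battery.** Instruments are small YAML documents (items, response
scales, reverse-keyed items, skip rules, scoring rule, positivity cut-off)
scored by a generic engine. Shipped defaults:

- `sadd` — 15-item alcohol-dependence questionnaire, items scored 0–3,
  positive at **AUD ≥ 7**;
- `dast10` — 10-item yes/no drug-abuse screen, one reverse-keyed item,
  positive at **SUD ≥ 3**;
- `ddsi` — an 11-module dual-diagnosis interview shell covering depression,
  dysthymia, mania, psychosis, panic, agoraphobia, specific phobia, social
  phobia, generalized anxiety, PTSD and ADHD (the validated interview's item
  text is unpublished, so module rules are configuration);
- `suicide_screen` — ideation, planning, attempt, intentionality (0–10),
  lifetime attempt.

**Triage.** With acuity window `w = 30` days and intentionality cut-off 5:

```
red    ⇔  suicide screen active (ideation ∨ planning ∨ attempt ∨ intent ≥ 5, ≤ w days)
          ∨ probable psychosis/mania with last episode ≤ w days
yellow ⇔  ¬red ∧ (non-acute suicide risk ∨ remote psychosis/mania
          ∨ any other probable disorder)
green  ⇔  otherwise
```

Red means priority referral to a specialized institution; yellow, referral
to a mental-health specialist; green, continue standard treatment.
Substance-screen positivity is reported but never changes the light.

**Validation statistics.** For each disorder, the index screen versus the
reference standard gives a 2×2 table, from which

Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),

with Wald (default) or Wilson confidence intervals, screen-positive
prevalence (TP+FP)/n, Pearson χ² for group comparisons and two-sample t
tests from summary statistics.

**Simulator.** Per-disorder true status is Bernoulli with the validation
cohort's reference prevalences; an imperfect index screen is overlaid with
configurable Se/Sp; demographics follow the published sample margins.
Counter-based random streams make cohorts reproducible patient-by-patient.

## Worked example

```bash
ddscreen triage patient.yaml
```

with `patient.yaml` describing a 28-year-old man, 14 days in residence,
cocaine as impact substance, SADD total 7, DAST-10 total 5, a probable
depression module (last symptomatic period 120 days ago) and a negative
suicide screen, prints:

```json
{
  "record_id": "P-0042",
  "light": "yellow",
  "no_rule_fired": false,
  "suicide_tier": "none",
  "triggers": [
    "depression:probable"
  ],
  "aud_positive": true,
  "sud_positive": true,
  "recommendation": "The patient has probable psychiatric disorders co-occurring with substance use. This condition represents a low to medium risk. The recommendation is to refer the patient to a mental health specialist for assessment and treatment."
}
```

Depression is probable but is not an emergency disorder, and there is no
acute suicidality, so the session is yellow: both substance screens are
positive (`aud_positive`, `sud_positive`) yet they do not escalate the
light. Other subcommands: `ddscreen score` (instrument totals),
`ddscreen report` (full Markdown report with the unconditional disclaimer),
`ddscreen simulate --n 500 --seed 7 --out cohort.csv`, and
`ddscreen evaluate cohort.csv` (per-disorder Se/Sp/PPV/NPV table).

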