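# Suicide screen: the four acute indicators used by the triage algorithm
# (ideation, planning, attempt, intentionality 0-10) plus lifetime attempt.
# Scored as presence/absence; the triage tier is computed by screen_suicide,
# not by the sum.
schema_version: 1
instrument_id: suicide_screen
title: Suicide risk screen
scoring: sum
positivity_threshold: 1
reverse_keyed: []
items:
  - {item_id: sui_ideation, prompt: "Current suicidal ideation", response_scale: binary_yes_no}
  - {item_id: sui_planning, prompt: "Current suicide planning", response_scale: binary_yes_no}
  - {item_id: sui_attempt, prompt: "Recent suicide attempt", response_scale: binary_yes_no}
  - {item_id: sui_intent, prompt: "Intentionality of the wish to die (0-10)", response_scale: ordinal_0_10}
  - {item_id: sui_lifetime, prompt: "Any lifetime suicide attempt", response_scale: binary_yes_no}
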