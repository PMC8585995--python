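# Short Alcohol Dependence Data questionnaire: 15 frequency items scored
# 0 (never) .. 3 (nearly always). Severity bands are reported in the
# interpretation only; the triage algorithm uses the cut-off of 7.
schema_version: 1
instrument_id: sadd
title: Short Alcohol Dependence Data questionnaire
scoring: sum
positivity_threshold: 7
reverse_keyed: []
bands:
  - {min: 0, max: 0, label: no reported dependence symptoms}
  - {min: 1, max: 9, label: low dependence}
  - {min: 10, max: 19, label: medium dependence}
  - {min: 20, max: 45, label: high dependence}
items:
  - {item_id: sadd_01, prompt: "Difficulty getting the thought of drink out of your mind", response_scale: ordinal_0_3}
  - {item_id: sadd_02, prompt: "Getting drunk being more important than the next meal", response_scale: ordinal_0_3}
  - {item_id: sadd_03, prompt: "Planning the day around when and where to drink", response_scale: ordinal_0_3}
  - {item_id: sadd_04, prompt: "Drinking in the morning, afternoon and evening", response_scale: ordinal_0_3}
  - {item_id: sadd_05, prompt: "Drinking for the effect, regardless of the kind of drink", response_scale: ordinal_0_3}
  - {item_id: sadd_06, prompt: "Drinking as much as wanted regardless of what comes next day", response_scale: ordinal_0_3}
  - {item_id: sadd_07, prompt: "Knowing that many problems are caused by drink but drinking anyway", response_scale: ordinal_0_3}
  - {item_id: sadd_08, prompt: "Shakes on waking after a heavy drinking session", response_scale: ordinal_0_3}
  - {item_id: sadd_09, prompt: "Morning drinking to stop the shakes", response_scale: ordinal_0_3}
  - {item_id: sadd_10, prompt: "Craving a drink badly on waking", response_scale: ordinal_0_3}
  - {item_id: sadd_11, prompt: "Retching or vomiting after a heavy drinking session", response_scale: ordinal_0_3}
  - {item_id: sadd_12, prompt: "Going out of the way to stay drunk after heavy drinking", response_scale: ordinal_0_3}
  - {item_id: sadd_13, prompt: "Drinking to forget frightening things from the previous night", response_scale: ordinal_0_3}
  - {item_id: sadd_14, prompt: "Seeing frightening things after a heavy drinking session", response_scale: ordinal_0_3}
  - {item_id: sadd_15, prompt: "Going drinking again after waking with shakes", response_scale: ordinal_0_3}
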