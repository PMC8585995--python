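# Drug Abuse Screening Test, 10-item form: yes/no items scored 0/1. Item 3
# asks about the ability to stop and is reverse-keyed ("yes" scores 0).
# Cut-off 3 for a positive drug-use-disorder screen.
schema_version: 1
instrument_id: dast10
title: Drug Abuse Screening Test (DAST-10)
scoring: sum
positivity_threshold: 3
reverse_keyed: [dast_03]
bands:
  - {min: 0, max: 0, label: no reported problems}
  - {min: 1, max: 2, label: low level}
  - {min: 3, max: 5, label: moderate level}
  - {min: 6, max: 8, label: substantial level}
  - {min: 9, max: 10, label: severe level}
items:
  - {item_id: dast_01, prompt: "Used drugs other than those required for medical reasons", response_scale: binary_yes_no}
  - {item_id: dast_02, prompt: "Used more than one drug at a time", response_scale: binary_yes_no}
  - {item_id: dast_03, prompt: "Always able to stop using drugs when wanting to", response_scale: binary_yes_no}
  - {item_id: dast_04, prompt: "Blackouts or flashbacks as a result of drug use", response_scale: binary_yes_no}
  - {item_id: dast_05, prompt: "Feeling bad or guilty about drug use", response_scale: binary_yes_no}
  - {item_id: dast_06, prompt: "Spouse or parents complaining about involvement with drugs", response_scale: binary_yes_no}
  - {item_id: dast_07, prompt: "Neglected family because of drug use", response_scale: binary_yes_no}
  - {item_id: dast_08, prompt: "Engaged in illegal activities to obtain drugs", response_scale: binary_yes_no}
  - {item_id: dast_09, prompt: "Withdrawal symptoms when stopping drug use", response_scale: binary_yes_no}
  - {item_id: dast_10, prompt: "Medical problems as a result of drug use", response_scale: binary_yes_no}
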