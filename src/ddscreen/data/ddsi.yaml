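# Dual-diagnosis screening interview shell: eleven disorder modules, each a
# pair of gate items; a module is probable when either gate is endorsed.
# The original interview's item wording is unpublished, so prompts here are
# generic symptom gates and every per-module rule is configuration — replace
# this document to field a clinically validated item set.
schema_version: 1
instrument_id: ddsi
title: Dual-diagnosis screening interview (11 disorder modules)
scoring: module_rule
positivity_threshold: 1
reverse_keyed: []
items:
  - {item_id: dep_1, prompt: "Period of two weeks or more of depressed mood most of the day", response_scale: binary_yes_no}
  - {item_id: dep_2, prompt: "Period of two weeks or more of loss of interest or pleasure", response_scale: binary_yes_no}
  - {item_id: dys_1, prompt: "Depressed mood most days for two years or more", response_scale: binary_yes_no}
  - {item_id: dys_2, prompt: "Long-standing low mood with poor energy or self-esteem", response_scale: binary_yes_no}
  - {item_id: man_1, prompt: "Period of abnormally elevated or irritable mood with increased energy", response_scale: binary_yes_no}
  - {item_id: man_2, prompt: "Period of markedly reduced need for sleep with racing thoughts", response_scale: binary_yes_no}
  - {item_id: psy_1, prompt: "Heard or saw things others could not, outside intoxication", response_scale: binary_yes_no}
  - {item_id: psy_2, prompt: "Held beliefs others found impossible (being followed, controlled)", response_scale: binary_yes_no}
  - {item_id: pan_1, prompt: "Sudden attacks of intense fear peaking within minutes", response_scale: binary_yes_no}
  - {item_id: pan_2, prompt: "Persistent worry about further attacks or their consequences", response_scale: binary_yes_no}
  - {item_id: ago_1, prompt: "Fear or avoidance of places where escape might be difficult", response_scale: binary_yes_no}
  - {item_id: ago_2, prompt: "Avoiding leaving home alone, crowds, or public transport", response_scale: binary_yes_no}
  - {item_id: sph_1, prompt: "Marked fear of a specific object or situation (heights, animals, blood)", response_scale: binary_yes_no}
  - {item_id: sph_2, prompt: "Avoidance of that object or situation interfering with life", response_scale: binary_yes_no}
  - {item_id: soc_1, prompt: "Marked fear of social situations involving possible scrutiny", response_scale: binary_yes_no}
  - {item_id: soc_2, prompt: "Avoidance of speaking, eating or performing in front of others", response_scale: binary_yes_no}
  - {item_id: gad_1, prompt: "Excessive worry about several areas most days for six months", response_scale: binary_yes_no}
  - {item_id: gad_2, prompt: "Worry hard to control, with tension, restlessness or poor sleep", response_scale: binary_yes_no}
  - {item_id: pts_1, prompt: "Exposure to a traumatic event with intrusive memories or nightmares", response_scale: binary_yes_no}
  - {item_id: pts_2, prompt: "Avoidance of reminders with hypervigilance since the event", response_scale: binary_yes_no}
  - {item_id: adh_1, prompt: "Since childhood, persistent inattention affecting work or study", response_scale: binary_yes_no}
  - {item_id: adh_2, prompt: "Since childhood, persistent restlessness or impulsivity", response_scale: binary_yes_no}
modules:
  depression: {any_of: [dep_1, dep_2]}
  dysthymia: {any_of: [dys_1, dys_2]}
  mania: {any_of: [man_1, man_2]}
  psychosis: {any_of: [psy_1, psy_2]}
  panic: {any_of: [pan_1, pan_2]}
  agoraphobia: {any_of: [ago_1, ago_2]}
  specific_phobia: {any_of: [sph_1, sph_2]}
  social_phobia: {any_of: [soc_1, soc_2]}
  gad: {any_of: [gad_1, gad_2]}
  ptsd: {any_of: [pts_1, pts_2]}
  adhd: {any_of: [adh_1, adh_2]}
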