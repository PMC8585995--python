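# Recommendation texts of the traffic-light triage system, one paragraph per
# light, plus the unconditional report disclaimer. Editable language
# resource; the original application's texts are Spanish.
red: >-
  The patient has probable psychiatric disorders co-occurring with substance
  use. This condition poses a medium to high risk. The recommendation is to
  refer the patient as a priority to a specialized institution for assessment
  and treatment.
yellow: >-
  The patient has probable psychiatric disorders co-occurring with substance
  use. This condition represents a low to medium risk. The recommendation is
  to refer the patient to a mental health specialist for assessment and
  treatment.
green: >-
  The patient does not have probable mental disorders co-occurring with
  substance use. This condition does not represent an apparent risk. The
  recommendation is to continue with standard treatment.
disclaimer: >-
  This screening report is not intended to replace professional psychiatric
  or psychological assessment, or the recommendations clinicians usually
  provide for patients. Sensible, responsible use is recommended, and
  communication with the treating psychiatrist should always be maintained.
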