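merges:
  No Fine Motor Concerns: Fine Motor Concerns
  No Gross Motor Concerns: Gross Motor Concerns
  No Home Treatments: Current Home Treatments
overrides:
- Elbow Tone
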