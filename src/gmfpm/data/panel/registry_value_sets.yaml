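# Value sets of the synthetic panel-exercise registry.
domains:
- Neurologic Function
- Mobility Performance
- Activity Performance
- Motor Performance
- Device Use
value_sets:
- name: yes_no
  kind: binary
  values:
  - 'Yes'
  - 'No'
  aliases:
    Y: 'Yes'
    N: 'No'
- name: mas
  kind: ordinal
  values:
  - '0'
  - '1'
  - '1.5'
  - '2'
  - '3'
  - '4'
  aliases:
    1+: '1.5'
    '+1': '1.5'
- name: sitting_balance
  kind: ordinal
  values:
  - Intact
  - Impaired
- name: neck_strength
  kind: ordinal
  values:
  - WFL
  - Limited
- name: stair_railings
  kind: nominal
  values:
  - Bilateral
  - Rail on left going up
  - Rail on right going up
  - None
- name: ambulation_level
  kind: ordinal
  values:
  - Independent
  - Stand-by assistance
  - Minimal assistance
  - Moderate assistance
  - Maximum assistance
  - Dependent
- name: stairs_assistance
  kind: ordinal
  values:
  - Complete independence
  - Standby assistance
  - Contact guard assistance
  - Minimal assistance
  - Moderate assistance
  - Maximal assistance
  - Dependent
- name: primary_mobility
  kind: nominal
  values:
  - Independent wheelchair - manual
  - Independent wheelchair - power
  - Ambulation with device
  - Ambulation without device
  - Dependent wheelchair mobility
  - Other
- name: concern_summary
  kind: ordinal
  values:
  - No concerns
  - Any one concern
  - More than one concern
- name: treatments_summary
  kind: ordinal
  values:
  - No treatments
  - Any one treatment
- name: fine_motor_summary
  kind: ordinal
  values:
  - No fine motor concerns
  - Concerns with any one fine motor activity
  - More than one fine motor concern
- name: assistive_summary
  kind: ordinal
  values:
  - No assistive device
  - Any assistive device used
- name: mobility_summary
  kind: nominal
  values:
  - No wheelchair use
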