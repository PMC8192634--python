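# T-descriptor decision table, AJCC/UICC TNM 8th edition (lung).
# Size classes are inclusive on their upper bound ("> x but <= y cm").
# Structure names must match involvement_target concept_ids in the lexicon.
version: AJCC8
size_breakpoints_mm:
  - [T1a, 10]
  - [T1b, 20]
  - [T1c, 30]
  - [T2a, 40]
  - [T2b, 50]
  - [T3, 70]
size_above_last: T4
involvement_tiers:
  T2: [main_bronchus, visceral_pleura]
  T3: [chest_wall, parietal_pericardium, phrenic_nerve]
  T4: [mediastinum, diaphragm, heart, great_vessels, trachea, carina, esophagus, recurrent_laryngeal_nerve, vertebral_body]
presence_map:
  post_obstructive_atelectasis: T2
  main_bronchus: T2
  satellite_same_lobe: T3
  nodule_ipsilateral_other_lobe: T4
# minimum size for a different-lobe ipsilateral nodule to raise T4 (> 1 cm)
nodule_min_size_mm: 10
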