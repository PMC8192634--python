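# Default section policy.
#
# `patterns` are case-insensitive regexes matched against a whole heading
# line (an optional parenthetical like "Findings (PET-CT)" is tolerated).
# `in_scope: false` removes a section from tumor/size candidate extraction:
# whole-body PET-CT reports describe masses and cysts with sizes in organs
# that can never hold the primary lung tumor.
default_in_scope: true
categories:
  history:
    patterns: ["history", "clinical history", "indication", "clinical information"]
    in_scope: false
  comparison:
    patterns: ["comparison", "comparisons", "prior studies"]
    in_scope: false
  technique:
    patterns: ["technique", "procedure", "protocol"]
    in_scope: false
  findings:
    patterns: ["findings", "ct findings", "pet-ct findings", "pet findings", "impression", "report"]
    in_scope: true
  head:
    patterns: ["head", "brain", "head and neck"]
    in_scope: false
  neck:
    patterns: ["neck"]
    in_scope: false
  chest:
    patterns: ["chest", "thorax", "lungs", "lung", "chest ct"]
    in_scope: true
  mediastinum:
    patterns: ["mediastinum", "mediastinum and hila"]
    in_scope: true
  abdomen:
    patterns: ["abdomen", "abdomen and pelvis", "abdomen/pelvis"]
    in_scope: false
  pelvis:
    patterns: ["pelvis"]
    in_scope: false
  bones:
    patterns: ["bones", "osseous structures", "skeleton"]
    in_scope: false
  musculoskeletal:
    patterns: ["musculoskeletal", "soft tissues", "extremities"]
    in_scope: false
  other:
    patterns: []
    in_scope: true
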