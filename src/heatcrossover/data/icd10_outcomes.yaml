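# ICD-10 outcome taxonomy for pediatric emergency healthcare use.
#
# Each outcome lists its code ranges (3-character categories; a bare code
# covers all of its subcodes) and a field rule: primary_only matches the
# primary diagnosis field; primary_or_secondary additionally matches any
# secondary field (external-cause codes such as drownings and falls are
# recorded in secondary diagnosis fields).
#
# all_cause has no ranges: it matches every record.
outcomes:
  all_cause:
    ranges: []
    field_rule: primary_only
  respiratory:
    ranges: ["J00-J99"]
    field_rule: primary_only
  asthma:
    ranges: ["J45"]
    field_rule: primary_only
  injury:
    ranges: ["S00-T66", "T68-88"]
    field_rule: primary_only
  drowning:
    ranges: ["V90", "V92", "W67-W70", "W73", "W74"]
    field_rule: primary_or_secondary
  falls:
    ranges: ["W00-W19"]
    field_rule: primary_or_secondary
  transportation:
    ranges: ["V01-V99"]
    field_rule: primary_or_secondary
  heat:
    ranges: ["T67", "E86", "E87"]
    field_rule: primary_only
  heatstroke:
    ranges: ["T67"]
    field_rule: primary_only
  dehydration:
    ranges: ["E86-87"]
    field_rule: primary_only
  renal:
    # printed as N00-N399; read as the N00-N39 urinary-system block
    ranges: ["N00-N39"]
    field_rule: primary_only
  infectious_parasitic:
    ranges: ["A00-B99"]
    field_rule: primary_only
  otitis:
    ranges: ["H60", "H65-67"]
    field_rule: primary_only
  enteritis:
    ranges: ["A00-A09"]
    field_rule: primary_only
  lower_respiratory:
    ranges: ["J12-J18", "J20-J22"]
    field_rule: primary_only
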