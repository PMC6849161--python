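# Declarative report-level label rules (schema version 1).
#
# Each rule fires on a non-negated observation entity found in the
# findings body or the conclusion.  For stroke and microbleed labels the
# observation's location/time values are resolved from explicit mod-loc /
# mod-time relations or from a co-extensive nested modifier; negated
# modifiers are ignored.
#
# Fields:
#   label        one of the 24 inventory labels
#   observation  observation entity type the rule keys on
#   location     "deep" | "cortical" (cortical prints as "lobar" for
#                haemorrhagic stroke and microbleed labels)
#   time         "old" | "recent"
#   default_when_no_time   with a matching location but no time value,
#                fire anyway (the deep ischaemic default: assumed old)
#   presence     fire on bare presence of the observation type
#   underspecified  fallback when no specific rule for this observation
#                type fires
#   context_cue / context_cue_absent   lemma prefix that must (or must
#                not) occur in the observation's sentence
schema: 1
rules:
  - label: "Ischaemic stroke, deep, recent"
    observation: ischaemic_stroke
    location: deep
    time: recent
  - label: "Ischaemic stroke, deep, old"
    observation: ischaemic_stroke
    location: deep
    time: old
    default_when_no_time: true
  - label: "Ischaemic stroke, cortical, recent"
    observation: ischaemic_stroke
    location: cortical
    time: recent
  - label: "Ischaemic stroke, cortical, old"
    observation: ischaemic_stroke
    location: cortical
    time: old
  - label: "Ischaemic stroke, underspecified"
    observation: ischaemic_stroke
    underspecified: true
  - label: "Haemorrhagic stroke, deep, recent"
    observation: haemorrhagic_stroke
    location: deep
    time: recent
  - label: "Haemorrhagic stroke, deep, old"
    observation: haemorrhagic_stroke
    location: deep
    time: old
  - label: "Haemorrhagic stroke, lobar, recent"
    observation: haemorrhagic_stroke
    location: cortical
    time: recent
  - label: "Haemorrhagic stroke, lobar, old"
    observation: haemorrhagic_stroke
    location: cortical
    time: old
  - label: "Haemorrhagic stroke, underspecified"
    observation: haemorrhagic_stroke
    underspecified: true
  - label: "Stroke, underspecified"
    observation: stroke_unknown
    presence: true
  - label: "Tumour, meningioma"
    observation: tumour_meningioma
    presence: true
  - label: "Tumour, metastasis"
    observation: tumour_metastasis
    presence: true
  - label: "Tumour, glioma"
    observation: tumour_glioma
    presence: true
  - label: "Tumour, other"
    observation: tumour
    presence: true
  - label: "Small vessel disease"
    observation: small_vessel_disease
    presence: true
  - label: "Atrophy"
    observation: atrophy
    presence: true
  - label: "Subdural haematoma"
    observation: subdural_haematoma
    presence: true
  - label: "Subarachnoid haemorrhage, aneurysmal"
    observation: subarachnoid_haemorrhage
    context_cue: aneurysm
  - label: "Subarachnoid haemorrhage, other"
    observation: subarachnoid_haemorrhage
    context_cue_absent: aneurysm
  - label: "Microbleed, deep"
    observation: microbleed
    location: deep
  - label: "Microbleed, lobar"
    observation: microbleed
    location: cortical
  - label: "Microbleed, underspecified"
    observation: microbleed
    underspecified: true
  - label: "Haemorrhagic transformation"
    observation: haemorrhagic_transformation
    presence: true
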