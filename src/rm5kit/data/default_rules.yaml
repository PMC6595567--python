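# Default normalization rules, tuned to the phrasing conventions of
# mental-health trial reviews.  Rules are matched first-match-wins by
# ascending priority against the plain-text projection of the named
# characteristics field; patterns are case-insensitive.  Replace this file
# to adapt the engine to another review group's conventions.
name: default
fallback: unclassified

# Optional numeric codes for labels (text labels are the canonical form;
# codes are for exports that want numeric factors).
label_codes:
  double: 2
  single: 1
  open: 0

rules:
  # --- blinding (methods) --------------------------------------------------
  - field: methods
    variable: blinding
    pattern: 'doubl[ey][\s-]*(blind|mask)'
    label: double
    priority: 10
  - field: methods
    variable: blinding
    pattern: 'triple[\s-]*(blind|mask)'
    label: double
    priority: 15
  - field: methods
    variable: blinding
    pattern: '(single|singly)[\s-]*blind|(rater|assessor|outcome assessor)[\s-]*blind'
    label: single
    priority: 20
  - field: methods
    variable: blinding
    pattern: 'open[\s-]*label|un[\s-]?blind|no blinding|not blinded|non[\s-]?blind'
    label: open
    priority: 30

  # --- allocation (methods) ------------------------------------------------
  # quasi before randomised: "quasi-randomised" contains "randomised"
  - field: methods
    variable: allocation
    pattern: 'quasi[\s-]*random|alternat(e|ion|ing)[\s-]*allocation|by odd[\s-]*even|date of birth'
    label: quasi
    priority: 110
  - field: methods
    variable: allocation
    pattern: 'allocation[:\s]*(unclear|not stated|not described)'
    label: unclear
    priority: 115
  - field: methods
    variable: allocation
    pattern: 'randomi[sz](ed|ation)|random(ly)?[\s-]*(allocat|assign)|random allocation'
    label: randomised
    priority: 120

  # --- care setting (participants), exported under extras ------------------
  - field: participants
    variable: setting
    pattern: 'in[\s-]?patients?|hospitali[sz]ed'
    label: inpatient
    priority: 210
  - field: participants
    variable: setting
    pattern: 'out[\s-]?patients?|community'
    label: outpatient
    priority: 220
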