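# Blinding surface forms with their true canonical label.  The synthetic
# corpus generator embeds these phrases in methods free text; the manifest
# records which phrase (by index) and label each study received, making this
# bank the ground truth for normalization tests.
blinding:
  - {phrase: "double blind", label: double}
  - {phrase: "double-blind", label: double}
  - {phrase: "doubly blinded", label: double}
  - {phrase: "double blinded", label: double}
  - {phrase: "double masked", label: double}
  - {phrase: "triple blind", label: double}
  - {phrase: "single blind", label: single}
  - {phrase: "single-blind", label: single}
  - {phrase: "singly blinded", label: single}
  - {phrase: "rater-blinded", label: single}
  - {phrase: "assessor blinded", label: single}
  - {phrase: "open label", label: open}
  - {phrase: "open-label", label: open}
  - {phrase: "unblinded", label: open}
  - {phrase: "no blinding", label: open}
  - {phrase: "blinding not described", label: unclassified}
allocation:
  - {phrase: "randomised", label: randomised}
  - {phrase: "randomized", label: randomised}
  - {phrase: "randomly allocated", label: randomised}
  - {phrase: "random allocation", label: randomised}
  - {phrase: "randomly assigned", label: randomised}
  - {phrase: "quasi-randomised", label: quasi}
  - {phrase: "alternate allocation", label: quasi}
  - {phrase: "allocation unclear", label: unclear}
  - {phrase: "allocation not stated", label: unclear}
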