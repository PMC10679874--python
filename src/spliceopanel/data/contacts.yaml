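# Structure-defined splicing-modulator contact residues (reference = human).
# Positions are 1-based on the ungapped reference protein sequence.
# The SF3B1 set is user-extensible: only one of its eight PB contacts is
# encoded here; add the others as they become available.
- modulator: PB
  protein: SF3B1
  contacts:
    - {position: 1078, residue: V}
- modulator: PB
  protein: PHF5A
  contacts:
    - {position: 36, residue: C}
- modulator: OTS964
  protein: CDK11
  contacts:
    - {position: 572, residue: H}
    - {position: 579, residue: G}
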