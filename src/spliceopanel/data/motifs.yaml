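# Example snRNA motif configuration (IUPAC patterns, optional match-start
# windows, 0-based half-open).  These consensi are configuration, not
# asserted species truth; adjust per organism.
- name: Sm site
  pattern: RATTTTTGR
- name: LSm site
  pattern: TTTTNN
- name: branch-point interaction
  pattern: GTAGTA
- name: 5'SS interaction
  pattern: ACAGAGA
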