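# Stress-related cis-regulatory element catalog for promoter scanning.
# Consensus strings are PlantCARE-convention defaults, editable; they are the
# package's working definitions, not values printed by any single source.
# All elements are scanned on both strands.
elements:
  - name: ARE            # anaerobic induction
    consensus: AAACCA
    both_strands: true
  - name: WRE3           # wound-responsive element 3
    consensus: CCACCT
    both_strands: true
  - name: WUN            # wound-responsive motif
    consensus: AAATTTCCT
    both_strands: true
  - name: STRE           # general stress response element
    consensus: AGGGG
    both_strands: true
  - name: LTR            # low-temperature responsiveness
    consensus: CCGAAA
    both_strands: true
  - name: MBS            # MYB binding site, drought-inducible
    consensus: CAACTG
    both_strands: true
  - name: DRE            # dehydration-responsive element core
    consensus: GCCGAC
    both_strands: true
  - name: AT-rich        # elicitor-mediated activation
    consensus: ATAGAAATCAA
    both_strands: true
  - name: TC-rich        # defense and stress responsiveness
    consensus: ATTTTCTTCA
    both_strands: true
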