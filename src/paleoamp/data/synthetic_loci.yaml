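# Bundled locus registry for the MLS-style amplicon experiment.
#
# Reference sequences are SYNTHETIC (seeded random backbones carrying the
# published primer sequences and published amplicon lengths / diagnostic
# coordinates).  The HVR-I diagnostic motif positions are likewise synthetic
# illustrations, not published motif positions.
loci:
  - name: mtDNA-HVRI
    molecule: mitochondrial
    coord_offset: 16050
    reference_fasta: synthetic_refs.fasta
    reference_id: mtDNA-HVRI
    amplicons:
      - pcr_id: hvr1a
        span: [16069, 16191]        # 123 bp
        primer_f: [16069, 16090]
        primer_r: [16172, 16191]
      - pcr_id: hvr1b
        span: [16201, 16301]        # 101 bp
        primer_f: [16201, 16219]
        primer_r: [16282, 16301]
    diagnostic_sites:
      - {position: 16126, role: haplogroup_diagnostic, endogenous: T, contaminant: C}
      - {position: 16152, role: haplogroup_diagnostic, endogenous: A, contaminant: G}
      - {position: 16234, role: haplogroup_diagnostic, endogenous: T, contaminant: C}
      - {position: 16258, role: haplogroup_diagnostic, endogenous: A, contaminant: G}
  - name: mtDNA-COI
    molecule: mitochondrial
    coord_offset: 6240
    reference_fasta: synthetic_refs.fasta
    reference_id: mtDNA-COI
    amplicons:
      - pcr_id: coi
        span: [6240, 6304]          # 65 bp
        primer_f: [6240, 6257]
        primer_r: [6287, 6304]
    diagnostic_sites:
      - {position: 6261, role: haplogroup_diagnostic, endogenous: A, contaminant: C}
      - {position: 6267, role: haplogroup_diagnostic, endogenous: C, contaminant: A}
  - name: LCT
    molecule: nuclear
    coord_offset: -13945
    reference_fasta: synthetic_refs.fasta
    reference_id: LCT
    amplicons:
      - pcr_id: lct
        span: [-13945, -13874]      # 72 bp
        primer_f: [-13945, -13926]
        primer_r: [-13894, -13874]
    diagnostic_sites:
      - {position: -13910, role: target_variant,
         endogenous: C, contaminant: T, ancestral: C, derived: T}
  - name: MCPH1
    molecule: nuclear
    coord_offset: 37961
    reference_fasta: synthetic_refs.fasta
    reference_id: MCPH1
    amplicons:
      - pcr_id: mcph1
        span: [37961, 38036]        # 76 bp
        primer_f: [37961, 37981]
        primer_r: [38015, 38036]
    diagnostic_sites:
      - {position: 37995, role: target_variant,
         endogenous: G, contaminant: C, ancestral: G, derived: C}
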