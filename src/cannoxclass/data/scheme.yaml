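# Cannabinoid oxidocyclase classification scheme.
#
# Coordinates are 1-based nucleotide positions on the 1638-nt THCAS ORF
# reference frame; amino-acid positions are ceil(nt/3).  Sites listed
# explicitly are the positions printed in the clade descriptions (e.g.
# "706 C (Gln)").  Diagnostic substitutions that are only counted, not
# printed, are carried as counts (aa_subs / syn_subs / nonsense_subs) and
# realized as deterministic, non-colliding placeholder positions when the
# scheme is instantiated.
reference_length: 1638

nodes:
  # ---- clade A: THCAS + CBCAS and relatives -------------------------------
  - {name: A, kind: clade, parent: root, aa_subs: 3}

  - {name: A1_THCAS, kind: subclade, parent: A, aa_subs: 3, orf_length: 1638}
  - {name: "1", kind: group, parent: A1_THCAS}
  - {name: "1/1", kind: type, parent: "1", alias: B_T}
  - {name: "1/2", kind: type, parent: "1", syn_subs: 1}
  - {name: "1/3", kind: type, parent: "1", alias: B_T0, defective: true,
     sites: [{pos: 706, nt: C, aa: Q}]}
  - {name: "1/4", kind: type, parent: "1", sites: [{pos: 749, nt: A, aa: D}]}
  - {name: "1/5", kind: type, parent: "1", sites: [{pos: 998, nt: G, aa: R}]}
  - {name: "1/6", kind: type, parent: "1", aa_subs: 1}
  - {name: "2", kind: group, parent: A1_THCAS,
     sites: [{pos: 373, nt: C, aa: L}]}
  - {name: "2/1", kind: type, parent: "2", aa_subs: 2}
  - {name: "2/2", kind: type, parent: "2", aa_subs: 1}
  - {name: "2/3", kind: type, parent: "2", inherit_sites: "2/1", syn_subs: 2}
  - {name: "2/4", kind: type, parent: "2", aa_subs: 3}
  - {name: "2/5", kind: type, parent: "2", aa_subs: 5}
  - {name: "2/6", kind: type, parent: "2", aa_subs: 10}
  - {name: "3", kind: type, parent: A1_THCAS,
     sites: [{pos: 187, nt: C, aa: L}]}
  - {name: "4", kind: type, parent: A1_THCAS,
     sites: [{pos: 794, nt: G, aa: G}, {pos: 1229, nt: A, aa: E}]}
  - {name: "5", kind: type, parent: A1_THCAS,
     sites: [{pos: 851, nt: T, aa: V}, {pos: 883, nt: C, aa: P}]}
  - {name: "6", kind: type, parent: A1_THCAS,
     sites: [{pos: 998, nt: G, aa: R}, {pos: 1064, nt: A, aa: N}]}
  - {name: "7", kind: type, parent: A1_THCAS,
     sites: [{pos: 749, nt: A, aa: D}, {pos: 1018, nt: G, aa: A}]}
  - {name: "8", kind: type, parent: A1_THCAS, aa_subs: 6}

  - {name: A2_CBCAS, kind: subclade, parent: A, aa_subs: 12, orf_length: 1638}

  - {name: A3, kind: subclade, parent: A, aa_subs: 13, orf_length: 1641,
     indels: [{pos: 9, length: 3, motif: dup_codon3}]}

  - {name: A4, kind: subclade, parent: A, aa_subs: 14, nonsense_subs: 4}
  - {name: A4-1, kind: type, parent: A4, aa_subs: 2}
  - {name: A4-2, kind: type, parent: A4, aa_subs: 2}

  # ---- clade B: CBDAS and its pseudogene relatives ------------------------
  - {name: B, kind: clade, parent: root, aa_subs: 16}

  - {name: B1_CBDAS, kind: subclade, parent: B, aa_subs: 14, orf_length: 1635,
     indels: [{pos: 755, length: -3}]}
  - {name: B1-1, kind: type, parent: B1_CBDAS, alias: CBDAS1,
     sites: [{pos: 1423, nt: A, aa: K}]}
  - {name: B1-2, kind: type, parent: B1_CBDAS, aa_subs: 3, forced_aa: S,
     alias: "B_D,B_DW,B_D01,B_D02"}

  - {name: B2, kind: subclade, parent: B, aa_subs: 2,
     indels: [{pos: 153, length: -4, alt_lengths: [-4, -6]}]}
  - {name: B2-1, kind: type, parent: B2, aa_subs: 8, nonsense_subs: 4,
     secondary: true}
  - {name: B2-2, kind: type, parent: B2, aa_subs: 2, secondary: true}
  - {name: B2-3, kind: type, parent: B2, aa_subs: 9, secondary: true}

  # ---- clade C: uncharacterized full-length and pseudogene copies ---------
  - {name: C, kind: clade, parent: root, aa_subs: 19, orf_length: 1638}
  - {name: C-1, kind: type, parent: C, aa_subs: 2}
  - {name: C-2, kind: type, parent: C, aa_subs: 2}
  - {name: C-3, kind: type, parent: C, aa_subs: 2}
  - {name: C-4, kind: type, parent: C, aa_subs: 2}
  - {name: C-5, kind: type, parent: C, aa_subs: 2}
  - {name: C-6, kind: type, parent: C, aa_subs: 2}
  - {name: C-7, kind: type, parent: C, aa_subs: 2}

# Per-cultivar locus counts: full-length coding (cd) and nonfunctional (nf)
# copies per (sub)clade, as recovered from the five high-quality assemblies.
profiles:
  Finola:
    chemotype: III
    b1_type: B1-2
    counts:
      A1_THCAS: [0, 0]
      A2_CBCAS: [2, 4]
      A3: [1, 0]
      A4: [0, 1]
      B1_CBDAS: [1, 0]
      B2: [0, 0]
      C: [0, 5]
  Purple Kush:
    chemotype: I
    a1_type: "1/5"
    counts:
      A1_THCAS: [1, 0]
      A2_CBCAS: [2, 3]
      A3: [0, 1]
      A4: [0, 1]
      B1_CBDAS: [0, 0]
      B2: [0, 3]
      C: [0, 4]
  CBDRx:
    chemotype: III
    b1_type: B1-1
    counts:
      A1_THCAS: [0, 0]
      A2_CBCAS: [1, 5]
      A3: [0, 0]
      A4: [0, 1]
      B1_CBDAS: [1, 0]
      B2: [0, 0]
      C: [1, 4]
  Jamaican Lion (Mother):
    chemotype: II
    a1_type: "1/1"
    b1_type: B1-1
    a3_nf_in_block2: true
    c_split: [[2, 2], [5, 1]]
    counts:
      A1_THCAS: [1, 0]
      A2_CBCAS: [6, 2]
      A3: [0, 1]
      A4: [0, 2]
      B1_CBDAS: [1, 0]
      B2: [0, 3]
      C: [7, 3]
  Jamaican Lion (Father):
    chemotype: III
    b1_type: B1-1
    counts:
      A1_THCAS: [0, 0]
      A2_CBCAS: [3, 1]
      A3: [0, 0]
      A4: [0, 1]
      B1_CBDAS: [1, 0]
      B2: [0, 0]
      C: [4, 1]
  Jilong:
    chemotype: unknown
    a1_type: "8"
    counts:
      A1_THCAS: [1, 0]
      A2_CBCAS: [0, 0]
      A3: [0, 2]
      A4: [0, 0]
      B1_CBDAS: [0, 0]
      B2: [0, 5]
      C: [0, 0]
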