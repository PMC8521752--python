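# cannoxclass

Classification, pseudogene annotation, and microsynteny analysis of
**cannabinoid oxidocyclase genes** — the THCAS/CBDAS/CBCAS family of
secreted, FAD-linked berberine-bridge-enzyme-like (BBE-like, group 10)
oxidocyclases that cyclize the prenyl moiety of CBGA into THCA, CBDA, and
CBCA in *Cannabis sativa*.

## The problem

*Cannabis* genome assemblies and amplicon studies have produced a confusing
zoo of names for these genes ("fiber-type THCAS", "inactive THCAS",
"mutated CBDAS", ...). The family is in fact organized into **three clades
(A–C) and seven subclades** — A1_THCAS, A2_CBCAS, A3, A4, B1_CBDAS, B2, and
C — each identifiable without a full phylogenetic analysis from
**clade-diagnostic characters**: substitutions (and a few indels) that are
constant within a clade and absent outside it, with all site numbers
projected onto the 1638-nt THCAS ORF reference frame. Examples packaged
here verbatim: `706 C (Gln)` defines the nearly defective B_T0 THCAS type;
a 3-bp deletion at position 755 plus 14 unique amino-acid substitutions
define B1_CBDAS; a 4-bp frameshift deletion at position 153 defines the B2
pseudogene subclade; a duplication of codon 3 (TAC; Tyr) plus 13
substitutions define A3.

`cannoxclass` implements that classification system as a reusable pipeline:

* **refcoord** — FASTA I/O, affine-gap global alignment (match +2,
  mismatch −3, gap open −8, extend −1; gap runs right-normalized for
  deterministic placement), and projection of query coordinates onto THCAS
  reference numbering.
* **annotate** — intronless-ORF annotation and lesion calling in the
  homologous-codon frame: frameshift / nonsense / missense / in-frame
  indel, with `nonfunctional` = at least one frameshift or premature stop.
  Missense-only defective alleles (B_T0, B_D01, B_D02, B_DW) stay `coding`.
* **classify** — diagnostic-site discovery (constant-within,
  unique-outside, at nucleotide or amino-acid level) and top-down
  clade → subclade → group → type assignment with a match-fraction
  threshold (default 0.8) and strict runner-up rule; nearest-type reporting
  and mixed-profile flags for putative chimeras.
* **phylo** — p-distances, neighbor joining with deterministic
  tie-breaking, outgroup-rooted monophyly tests, bootstrap clade support,
  and nearest-clade placement as the phylogenetic cross-check.
* **synteny** — gene-order tandem-array detection and family-anchored
  collinear blocks reproducing the two syntenic clusters that carry all
  oxidocyclase loci, with their conserved flanking markers (group 5.2
  BBE-like, RLP, Patellin, TWINKLE, ClpP; ZnF, RLK / Ankyrin, NPF).
* **synthetic_data** — a seeded simulator of the family's
  duplication/divergence history that plants the published diagnostic
  positions and counts, pseudogene lesions, tandem arrays, and the exact
  per-cultivar copy-number profiles of six high-quality assemblies
  (Finola, Purple Kush, CBDRx, Jamaican Lion mother/father, Jilong), so
  the whole pipeline is testable end-to-end without downloads.

## Worked example

Simulate the chemotype-II "Jamaican Lion (Mother)" genome (26 oxidocyclase
loci on two block-1 haplotype contigs and one block-2 CBCAS-array contig)
and classify the loci back:

```bash
$ cannoxclass simulate --profile "Jamaican Lion (Mother)" --seed 1 --outdir sim
[cannoxclass] simulated Jamaican Lion (Mother): 26 oxidocyclase loci on 3 contigs (manifest 97c03bea1c08)

$ cannoxclass classify sim/loci.fasta --seed 1 --outdir cls
[cannoxclass] seq=Jamaican_Lion_Mother_locus01_A1_THCAS clade=A subclade=A1_THCAS type=1/1 status=coding concordance=agree
[cannoxclass] seq=Jamaican_Lion_Mother_locus02_B2 clade=B subclade=B2 type=B2-1 status=nonfunctional concordance=agree
...

$ cat cls/copy_number.tsv
        cd  nf  total
A1_THCAS  1   0   1
A2_CBCAS  6   2   8
A3        0   1   1
A4        0   2   2
B1_CBDAS  1   0   1
B2        0   3   3
C         7   3  10
Sums     15  11  26
```

Each locus is assigned by its diagnostic profile (e.g. locus01 matches all
A1_THCAS diagnostics and the type-1/1 reference profile, so it is the
functional THCAS allele B_T), its coding status comes from the lesion
caller (the B2 loci are nonfunctional through their shared 4-bp frameshift
at position 153), the `concordance` column confirms the independent
nearest-clade phylogenetic placement agrees, and the copy-number table
reproduces the cultivar's published cd/nf counts (15 coding + 11
nonfunctional = 26). `sim/` also contains the genome FASTA, a GFF3 with
`family=`/`status=` attributes for the synteny tools, and a truth table.

The same operations are available as a library:

```python
import cannoxclass as cx

cfg = cx.default_scheme_config()
panel, labels, real = cx.default_panel(cfg, seed=1)
scheme = cx.build_scheme(panel, labels, cfg)
result = cx.classify_sequence(my_sequence, scheme)   # NucSequence in, labels out
```

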