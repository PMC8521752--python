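# Methods

## The classification model

Cannabinoid oxidocyclase genes (THCAS, CBDAS, CBCAS and their relatives)
form a recent, *Cannabis*-specific expansion inside group 10 of the
BBE-like family. The package classifies sequences into the four-level
hierarchy clade (A, B, C) → subclade (A1_THCAS, A2_CBCAS, A3, A4,
B1_CBDAS, B2, C) → group (within A1) → numbered type, using
**diagnostic characters**: states at reference-projected positions that
are constant within a taxon and, under current sampling, absent outside
it. Three kinds of character are used, mirroring how the subclades are
described in the literature:

* amino-acid replacements at homologous codons (the dominant kind; e.g.
  the 12 unique substitutions of A2_CBCAS, the 16 of clade B, the 19 of
  clade C);
* nucleotide-level synonymous substitutions where a type is defined by
  them (e.g. A1 type 1/2, which is functionally equivalent to type 1/1);
* shared indels: the 3-bp deletion at position 755 (B1_CBDAS), the 4-bp
  (alternatively 6-bp) frameshift deletion at position 153 (B2), and the
  duplication of codon 3 (TAC) in A3.

All positions are 1-based nucleotide coordinates on the ungapped 1638-nt
THCAS ORF; amino-acid positions are `ceil(nt/3)`. This convention lets the
printed positions (706, 749, 998, 373, 755, 153, ...) be used directly.

### Assignment rule

A query is projected onto the reference frame once and then assigned
top-down. At the clade and subclade levels the score is the **match
fraction**: matched diagnostic states over informative ones, where
positions at which the query is deleted or ambiguous are dropped from the
denominator, and indel diagnostics match on (position, length) with the
configured alternative lengths accepted (the B2 deletion matches at 4 or
6 bp). A level is assigned only if the best child scores at least the
threshold (default 0.8, config-exposed) *and* strictly beats the
runner-up; otherwise the sequence is "novel" at that level. When two
siblings both clear the threshold the result carries a mixed-profile
note — motivated by reported putative chimeras — but the best match is
still assigned when strictly ahead.

Types inside a subclade are not disjoint character sets (some types share
printed substitutions, and one type may differ from another only by
synonymous changes), so type assignment uses **nearest-type profiles**:
the union of all sibling type/group sites, with each type's expected state
being its own definition where it has one and the subclade consensus
elsewhere. The best-scoring profile wins under the same threshold and
strict-runner-up rule; an imperfect winner is reported as nearest type
with a note. The consensus at a position is the majority state among
subclade members whose type does not define a site there, which keeps it
well-defined even in two-type subclades.

The threshold and the strict-runner-up rule are this package's decisions
(the original assignments were made by expert inspection); 0.8 tolerates
isolated missing data at clade level while still rejecting profiles that
match only by chance (a random ORF matches ≈5% of any clade's sites).

### Lesion calling

Pseudogene annotation keeps the coding frame homologous to a functional
reference: indels are read off the alignment (frameshift iff length is not
a multiple of 3), and every reference codon strictly before the reference
stop is translated from the query nucleotides aligned to it — a stop is a
nonsense lesion, any other difference a missense lesion. Lesions
downstream of the first frameshift are flagged `secondary`; they are
retained in reports because the subclade B2 types are distinguished by
exactly such secondary mutations. A sequence is `nonfunctional` iff it has
at least one frameshift or nonsense lesion; missense-only defective
alleles (B_T0, B_DW, B_D01, B_D02) are `coding` with a type-level
known-defective annotation, which is what makes the copy-number table's
cd/nf split come out right. We deliberately call nonsense in the
homologous-codon frame rather than in the frameshifted reading: it matches
how the pseudogenes were annotated ("CDS remained homologous"), and it
keeps lesion calls consistent with amino-acid-level diagnostic discovery,
which also reads homologous codons. Queries covering less than 10% of the
reference raise a fragment error instead of receiving a status; the 10%
floor is a package decision, as no minimum fragment length is published.

## Coordinate projection and alignment

Queries are aligned to the reference with an affine-gap global aligner
(biopython's PairwiseAligner under the hood) scored match +2, mismatch −3,
gap open −8, gap extend −1 — a gap of length L costs 8 + L. The heavy gap
opening makes the named multi-base indels align as single events.
Co-optimal placements are resolved deterministically by right-normalizing
every gap run (sliding it 3' while the flanking bases permit), which pins
the B1 deletion at 755–757, the B2 deletion at 153–156, and anchors the
A3 codon duplication as insertions after reference position 9 (the 3'
copy of the tandem pair). A reverse-complement pre-pass flips the query
when the reverse orientation scores at least 20% higher. IUPAC ambiguity
codes align as mismatches, are returned verbatim by state queries, and
count as "no information" during classification.

## Phylogenetic route

As a cross-check on the character-based route, the package builds
neighbor-joining trees from p-distances computed over reference-projected
positions where neither sequence is deleted or ambiguous. NJ is
implemented directly (deterministic tie-breaking by smallest descendant
label; negative branch estimates clamped to zero) and recovers the
generating topology on additive matrices by construction, which the test
suite verifies on random additive trees. Clade support is reported as
bootstrap proportions over resampled columns (default 100 replicates,
seeded). Queries are placed by minimal mean p-distance to labelled clade
members, with the runner-up margin reported; on simulated panels this
placement agrees with the diagnostic route in ≥95% of cases. Bayesian
inference and substitution-model selection are out of scope.

## The simulator

The synthetic module realizes the family's evolutionary model as a
generative process: a random ancestral 1638-nt ORF (ATG start, single
terminal stop) "neofunctionalizes" and diversifies along the branching
order ancestor → clades A/B/C → subclades → types, each node applying its
planted mutations; a Humulus-like group-10 outgroup diverges at ~10% of
codons outside all diagnostic positions.

**Printed vs placeholder sites.** Positions printed in the clade
descriptions are planted verbatim; for that to be possible the ancestor is
constrained at those codons (e.g. codon 236 is AAA/Lys so that 706→C
yields CAA/Gln). Diagnostic substitutions that are only *counted* in the
source (the per-subclade totals) are realized at placeholder codons drawn
once from a fixed internal stream — independent of the simulation seed, so
the packaged scheme's positions are stable — without collisions between
nodes, and excluding the indel neighbourhoods and codons 1–4. Placeholder
mutant codons are chosen deterministically (smallest single-nucleotide
change to a different, non-stop amino acid; synonymous and premature-stop
placeholders sit on ancestor codons constrained to make a single-base
change sufficient; B1 type 2's three sites are forced to serine). The
concrete mutant *states* therefore depend on the seed-specific ancestor:
a scheme realized from seed *s* classifies sequences generated at seed
*s*. This is parameter recovery by design, not cross-seed generalization.

**Genomes.** A cultivar profile fixes the cd/nf copy counts per subclade
(six profiles are packaged, one per published high-quality assembly) and
the simulator lays the loci out in the two syntenic blocks: block 1 holds
the divergent 5' region (THCAS plus the B2 tandem array plus an A4
pseudogene on THCA haplotypes; CBDAS plus A3 on CBDA haplotypes), a group
5.2 BBE-like gene, the clade-C tandem array, and the conserved 3' flank
(RLP, Patellin, TWINKLE, ClpP); block 2, present only when the profile has
CBCAS copies, holds the A2 array between ZnF/RLK and Ankyrin/NPF. The
chemotype-II profile emits both block-1 haplotypes and carries its single
A3 pseudogene inside the CBCAS array (the "recent insertion" motif);
profiles whose published A3 count is zero get no A3 locus even though the
insertion is described for one such assembly — the copy-number table is
taken as the source of truth because exact count conservation is the
simulator's contract. Nonfunctional copies of otherwise-coding subclades
receive one random pseudogenizing lesion (premature stop or 1–2-nt
deletion) placed clear of all diagnostic positions. Intergenic spacers are
2–10 kb of random sequence; flanking marker genes are random 0.6–1.5-kb
sequences identified by their GFF3 `family=` attribute, since the
synteny analysis is gene-order-based. Background substitutions are
uniform single-nucleotide changes at a configurable per-site rate
(0–5%), with all diagnostic positions maskable; indels occur only where
configured. Randomness is seeded with one independent stream per contig,
so adding a contig does not perturb the others.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: LTR-retrotransposon expansions and repeat
landscapes around the loci, within-type allelic variation and
recombination, sequencing/assembly artifacts (the background model is
substitution-only), codon-usage and selection structure in the ORFs
(random codons), and real intergenic sequence. Diagnostic counts for real
assemblies additionally depend on sampling depth, which the fixed
34-leaf panel idealizes.

## Synteny analysis

Tandem arrays are maximal runs of ≥2 same-family genes with at most
`max_interveners` (default 2) other genes between consecutive members —
the default tolerates the A3 pseudogene inserted inside a CBCAS array.
Collinear blocks are longest chains of family-matched gene pairs, strictly
monotone on both contigs (both orientations searched), allowing up to
`max_gap` (default 2) unmatched genes between anchors, with at least
`min_anchors` (default 3) anchors. These thresholds are package decisions;
no numeric criteria for protein-level microsynteny are published.
Nucleotide-level alignment of whole regions (LASTZ-style) is out of scope:
gene-order logic suffices to reproduce the block structure, including the
conserved 3' flank shared between otherwise alignment-free divergent
regions.

## Homolog mining

The `mine` subcommand scans an assembly with a 21-mer prefilter built from
all prototype ORFs (both strands), merges seeded windows (≥20 shared
k-mers), and verifies candidates by global alignment to the reference —
keeping hits with ≥80% identity over ≥50% of the reference length,
reported on the coding strand. The thresholds are package decisions; no
mining cutoffs are published.

## Numerical and degenerate-input choices

* Ties in alignment: right-normalized gaps (see above); ties in NJ:
  smallest (Q, label-pair); ties in classification: no strict winner ⇒
  "novel".
* Empty diagnostic-site sets score 0 (they can never clear the
  threshold); a panel label with zero members is a domain error.
* Zero comparable sites in a p-distance pair is a domain error naming the
  pair.
* Sequences shorter than 10% of the reference: fragment error from the
  lesion caller; classification still reports the levels whose sites fall
  in the covered region, flagged partial.
* The simulator validates that planted indels realize at their exact
  printed positions; ancestor codons around them are resampled until gap
  placement is unambiguous.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
panels of 35 sequences (34 scheme leaves plus the outgroup), six cultivar
genomes totalling ~100 loci on ~0.1–0.3-Mb contigs, round-trip batteries
of ~200 classifications across four seeds, and property batteries of
50–100 random instances per oracle (alignment DP ≤12 nt, NJ ≤10 taxa,
tandem-array contigs of 15 genes). Bootstrap support uses 20 replicates in
tests (100 by default in the API).
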