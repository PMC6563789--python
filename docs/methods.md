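# Methods

## The model

The unit of analysis is the second exon of a mosaic immune gene: an ordered
series of conserved blocks (*elements*) drawn from a shared library, each
present or absent in a given family member. The presence/absence vector is
the gene's *element pattern*; patterns carry catalog names (A3, E2, 01, …)
and are the primary classification axis. Three biological levels of sequence
variation are distinguished:

1. **Pattern-level divergence** — patterns are ancient relative to
   genotypes, so two genes of different patterns differ substantially even
   within their shared elements.
2. **Genotype (germline) divergence** — animals carry their own sequence
   variants of each pattern; exact gene sequences are effectively never
   shared between animals.
3. **Somatic variation** — within an animal, single somatic immune cells
   differ from the germline (read out from sperm) by whole-gene deletions,
   whole-gene duplications and point substitutions that preserve reading
   frames.

Every analysis stage is the computational counterpart of one experimental
read-out: element typing and anchored alignment (sequence categorisation),
entropy diversity and SNP statistics (alignment variation), in-silico PCR
band profiles (gel electrophoresis), repertoire set comparison (clone
sequencing), ΔΔCt ratios (qPCR copy number), and JC+NJ+bootstrap trees with
a pattern-monophyly report (phylogenetics).

## Element decomposition and anchored alignment

`decompose` places each element consensus on the query by semi-global
alignment (edlib, infix mode; ties resolved leftmost). An element is a
candidate when its identity — exact matches over consensus length — is at
least `min_identity` (default 0.70) covering at least `min_coverage`
(default 0.80) of the consensus. Candidates are filtered to an ordered
chain by a weighted-interval dynamic program that maximises summed identity,
because elements occur as ordered genomic blocks. Placement ends can wobble
by a few bases when adjacent elements are both present, so the chain step
tolerates overlaps of up to 6 bp and trims them after selection; reported
intervals always partition cleanly. The thresholds are set so that 5%
per-site divergence never drops an element while a whole-element deletion
always does; a query with more than half its length unassigned (or no
placements at all) is flagged low-confidence rather than rejected.

Classification is an exact presence-vector lookup against the catalog —
never a nearest-neighbour guess; anything else is `NOVEL`.

`element_align` replaces a general-purpose progressive aligner with a
deterministic element-anchored construction: per element, each present
sequence's segment is aligned to the element consensus by Needleman–Wunsch
(match +1, mismatch −1, gap open −4, gap extend −1; fixed so results are
bit-reproducible), insertions relative to the consensus are merged
left-justified, absent elements become all-gap blocks, and unassigned
stretches stack left-justified between element blocks. Ungapping any row
reproduces its input exactly (asserted at construction).

## Diversity statistics

Column diversity is Shannon entropy in natural-log units,
H = −Σ_s f(s) ln f(s), over non-gap symbols, with 0·ln 0 ≡ 0. Group
diversity is the arithmetic mean of per-column entropies. Groups must
contain sequences of one element pattern and one length; the enforced
precondition is identical ungapped length, under which gapped and ungapped
column sets are equivalent (shared gaps are all-gap columns and carry no
frequencies), so entropies are computed position-wise on the ungapped
sequences. The amino-acid profile translates each sequence in the common
frame (frame 0 by default; a trailing stop is dropped) and the reported
ratio is mean aa diversity over mean nt diversity. (Published summaries of
this statistic sometimes label the same quantity "nt/aa" while tabulating
aa/nt values; this package computes and labels aa/nt.) Under unconstrained
substitution the ratio's expectation is roughly 3 × (fraction of
non-synonymous changes) ≈ 2.2, because one amino-acid column spans three
nucleotide columns.

SNPs are polymorphic columns: at least two distinct non-gap symbols among
covering rows. Variation frequency is 1 − (majority-symbol frequency) with
a non-gap denominator, and the filter keeps calls strictly above the
threshold (default 0.25). A count of polymorphic columns, not
column×allele variants, is reported — the alternative reading is possible
but not used. ORF screening translates the amplicon in its designated frame
and reports BROKEN iff a stop codon occurs before the final complete codon.

## Repertoire and copy number

In-silico PCR matches IUPAC degenerate primers with a mismatch budget
(default 2). The forward site is the best (fewest-mismatch) placement, ties
5′-most; the reverse-complement site is searched downstream, ties 5′-most
on the minus strand. Amplicon length is the inclusive span. Lengths merge
into bands when neighbours lie within the gel-resolution parameter (default
30 bp, chain merging; band length is the rounded cluster mean) — so any
band-level claim is resolution-parameterised, never hard-coded.

ΔΔCt: dCt(x) = Cq(target, x) − Cq(reference gene, x), ΔΔCt = dCt(focal) −
dCt(reference sample), ratio = E^(−ΔΔCt) with amplification efficiency E
fixed at 2.0 (configurable). An absent target Cq in the focal cell yields
an ABSENT result rendered "X"; an absent reference-gene Cq is an integrity
error, since normalisation is impossible.

Repertoire comparison partitions members by exact sequence identity and
additionally reports pattern-level absences (patterns present in one
repertoire and missing from the other), the stronger signal of whole-gene
loss. Cross-animal comparison requires an explicit flag because genotypes
share no exact sequences.

## Phylogenetics

Jukes–Cantor distance d = −(3/4) ln(1 − 4p/3) with p the mismatch fraction
over pairwise-deleted (both-resident) columns. Pairwise deletion rather
than complete deletion is used because mosaic gaps would otherwise remove
most columns; this is an explicit, documented choice. p ≥ 0.75 has no
finite distance and raises; inside bootstrap
replicates, where resampling can transiently saturate a pair, a fixed large
distance (5.0 substitutions/site) is substituted instead.

Neighbor joining is the canonical Saitou–Nei agglomeration on the Q
criterion, with ties broken by the lexicographically smallest
(representative-taxon, representative-taxon) pair, making output
deterministic; negative branch lengths are clamped to zero with a warning.
Bootstrap resamples columns with replacement; support for each original
internal bipartition is the percentage of replicate trees containing it,
retained in full in the data and suppressed at or below 50 only in rendered
newick (mirroring common display practice). Clade purity asks, for each
element pattern (or a declared group of near-identical patterns such as
01/02), whether its leaves form one side of some edge of the unrooted tree;
purity is the fraction of monophyletic patterns, and each failure lists the
foreign leaves inside the smallest clan spanning the pattern. NJ is used
instead of likelihood or parsimony search deliberately: for data of this
structure the methods agree on clade composition, and a deterministic
in-repo method is exactly reproducible.

## The simulator

`simulate_germline` draws an element library (default 15 elements, 51–120
bp, lengths multiples of three, codon-wise stop-free), a catalog of 12
patterns (random presence subsets with at least three elements; the
terminal element — the family's name-defining block — is present in every
pattern), pattern-level realisations of each present element at
`pattern_divergence` (0.10 subs/site), and per-genotype genes at
`germline_divergence` (0.03) above the pattern realisation. Genes are
flanked by concrete stop-free realisations of a degenerate primer pair, so
the full amplicon translates from its first base. The default of three
genotypes with seven genes each is a realistic scale for this gene family,
whose sperm amplicon profiles show six or seven bands per animal.

The two-level divergence is the package's own design choice: with only
genotype-level divergence, within-pattern and between-pattern distances
would coincide and pattern clades could not form; making patterns old
relative to genotypes is the biological cause of the observed clade purity.

`simulate_cell` deletes each gene with `p_del` (0.2), duplicates survivors
with `p_dup` (0.1, copy number 2), and substitutes per site at `mu` (0.002).
Sperm cells force all rates to zero, so sperm within a genotype are
identical by construction. ORF preservation is rejection sampling: a
substitution whose codon would become a stop is resampled among the
remaining bases (or skipped) — the simplest mechanism consistent with the
observed absence of pseudogenes, without asserting the unknown biological
mechanism. Deletion and duplication act on whole genes only, matching the
whole-gene repertoire changes observed; element-level somatic shuffling is
out of scope. `mu` was set so that the expected number of exactly-shared
sequences between a coelomocyte and sperm of one animal lands in the
observed one-to-few range at this gene-family size.

Clone libraries sample genes with replacement proportionally to copy number
(default 60 clones/cell, giving ~0.9 redundancy at seven genes). The qPCR
forward model is Cq = base − log2(copies) + Normal(0, σ) with base 20
cycles and σ = 0.15 (0 copies → ABSENT; the reference gene is fixed at one
copy). Noiseless, the ΔΔCt pipeline inverts this model exactly (powers of
two).

Randomness uses one seed split hierarchically by (stage, genotype, cell,
gene) via numpy `SeedSequence` spawn keys, so adding cells or genes does not
perturb earlier draws and equal seeds give byte-identical outputs.

### What the simulator does and does not emulate

It emulates: mosaic gene structure and pattern catalogs, genotype
non-sharing, sperm/soma contrast, whole-gene dosage events, frame-preserving
substitution, clone redundancy, and qPCR noise. It does not model
whole-genome-amplification or PCR representation bias (an optional per-gene
amplification-failure probability exists, default 0), selection on specific
sites, hypermutation hotspots, element-level recombination, or
immune-challenge dynamics. Passing tests therefore demonstrate the
*analytical machinery* is correct under the stated generative model; they do
not validate biological conclusions about real single-cell data, where
amplification artefacts are a genuine confounder.

## Problem sizes and numerical choices

The test suite and acceptance script use: 200 genes for pattern-recovery
accuracy, 500+ genes for ORF preservation, 100 coelomocytes per genotype ×3
seeds for deletion-rate recovery, all 123 unrooted binary trees on 4–6 taxa
for NJ correctness, and 20 germline seeds for clade purity — sizes at which
every binomial check is well-powered while a full run stays in tens of
seconds. Alignment scoring, NJ tie-breaks and the bootstrap RNG are fixed
as above so all results are exactly reproducible given a seed. Degenerate
inputs: empty libraries, asymmetric matrices, unlabeled leaves, absent
reference genes and mixed-length diversity groups raise typed errors rather
than returning silently wrong numbers.

## Known limitations

- The packaged element library and pattern catalog are synthetic schematics
  (the real element definitions live in prior literature, not in any data
  shipped here); real-data runs must supply a library built from reference
  alignments, and the shipped degenerate primers are placeholders for
  synthetic mode.
- Element discovery de novo is out of scope; decomposition requires a
  library.
- The clade-count question ("how many clades") is not answered — clade
  delimitation on an unrooted tree is not well-defined; monophyly per
  pattern is reported instead.
- dN/dS and episodic-selection tests are out of scope (the diversity ratio
  is the implemented proxy).
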