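# sptrf

Single-cell analysis of somatic diversification in the *SpTrf* (*Sp185/333*)
immune gene family of the purple sea urchin, *Strongylocentrotus purpuratus* —
plus a fully ground-truthed forward simulator so every analysis stage can be
verified without external data.

## The problem

*SpTrf* genes encode a family of immune effector proteins whose second exon is
a mosaic of conserved sequence blocks ("elements") that are present or absent
in a fixed genomic order; the presence/absence vector is the gene's *element
pattern* (named A3, E2, D1, 01, …). Sperm cells of one animal all carry the
same germline gene repertoire, while single somatic immune cells
(coelomocytes) show missing genes, extra gene copies and point substitutions —
evidence of somatic immune gene diversification in an invertebrate. This
package implements the computational side of that comparison for anyone
working with mosaic gene families in non-model systems:

- **Element-pattern typing** (`sptrf.elements`): semi-global placement of each
  element consensus on a query, ordered non-overlapping placement selection,
  exact catalog classification, and a deterministic element-anchored multiple
  alignment in which all-gap blocks mark missing elements.
- **Diversity statistics** (`sptrf.diversity`): per-column Shannon entropy
  H = −Σ f ln f over non-gap residues, the mean amino-acid/nucleotide
  diversity ratio for same-length, same-pattern groups (a ratio above 1
  indicates an excess of non-synonymous change), SNP calling with the
  variation-frequency filter (vf = 1 − majority frequency, kept when
  vf > 0.25), and ORF integrity screening.
- **Repertoire comparison** (`sptrf.repertoire`): in-silico degenerate-primer
  PCR amplicon profiles with gel-resolution band merging, shared/unique
  sequence-set comparison between cell classes, and ΔΔCt relative copy
  numbers, ratio = 2^(−ΔΔCt), normalised to a single-copy reference gene
  (*SpGAPDH*), with absent genes rendered "X".
- **Phylogenetics** (`sptrf.phylogeny`): Jukes–Cantor distances with pairwise
  deletion, d = −(3/4) ln(1 − 4p/3), deterministic Saitou–Nei neighbor
  joining, column bootstrap supports, and a clade-purity report testing
  whether each element pattern is monophyletic.
- **Simulator** (`sptrf.simulate`): germline families built from a shared
  element library, per-cell whole-gene deletion/duplication and
  ORF-preserving substitution, clone libraries sampled with redundancy, and
  a qPCR forward model Cq = base − log2(copies) + noise — all with an
  explicit truth record.

## Worked example

Simulate a three-animal study and analyse one animal's single coelomocyte
against its sperm:

```bash
sptrf simulate --seed 7 --out demo
sptrf qpcr demo/cq.csv --focal C1c1 --reference S1c1
```

```
target  ratio
A1.01   1.147
A1.02   0.882
A1.A3   0.835
A1.B3   1.173
A1.D1   1.193
A1.D5   0.792
A1.E2   2.041
```

Each row is one germline gene's copy number in the coelomocyte relative to
sperm (ΔΔCt, *SpGAPDH*-normalised). A ratio near 1 means the gene is intact,
near 2 a duplication (here A1.E2), and a deleted gene would print `X`.

```bash
sptrf pcr demo/germline_animal1.fasta
```

```
lengths 918,879,813,711,834,663,768
bands   663x1,711x1,768x1,824x2,879x1,918x1
```

Seven germline genes produce six gel bands at the default 30-bp resolution:
two genes co-migrate in the 824-bp band, which is why band counts
underestimate gene counts. Typing a clone library
(`sptrf type demo/clones_C1c1.fasta --library demo/library.json`) assigns
each clone an element pattern and variant number, and per-pattern diversity
across the study's cells gives amino-acid/nucleotide entropy ratios of about
2 under the simulator's unconstrained substitution model, e.g.

```
A3  n=6  nt=0.0636  aa=0.1264  ratio=1.99
E2  n=4  nt=0.0693  aa=0.1444  ratio=2.08
```

The same operations accept real data: FASTA amplicon sequences named
`<S|C|M><animal>-<pattern>-<variant>` (e.g. `C3-E2-14`), a user-supplied
element library JSON built from reference alignments, and Cq tables as CSV.

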