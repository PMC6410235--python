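# orfdecay

Gene-loss inference from genome assemblies: map a reference gene model
onto target genomes, call ORF-disrupting mutations, confirm them with raw
sequencing reads, place shared mutations on a species tree, and check
locus presence by flanking-gene synteny.

## The problem

When a gene becomes dispensable, its open reading frame (ORF) decays:
premature stop codons, frameshifting indels, broken GT/AG splice sites,
lost start codons, and eventually whole-exon or whole-locus erosion.
Comparative genomicists diagnose such losses by projecting an intact
reference gene (say, the cow orthologue) onto the genome assemblies of
related species and cataloguing the lesions — a procedure usually done by
hand in an alignment viewer. `orfdecay` implements that procedure as a
tested, deterministic pipeline, with a synthetic-data generator that
evolves genomes down a phylogeny with mutations planted on branches, so
every stage can be verified against a known truth table.

The built-in scenarios replicate the decay of the melatonin pathway in
cetaceans: the synthesis genes *Aanat* and *Asmt* and the receptors
*Mtnr1a* and *Mtnr1b* across 12 toothed and baleen whales, with the
hippopotamus and the Florida manatee as outgroups.

## Method

For each reference exon, candidate loci in the target are found by exact
*k*-mer seeding (word size 10, blastn-like) and aligned with a
three-state affine-gap (Gotoh) semi-global alignment — global in the
exon, free end-gaps in the target window — under match/mismatch/gap
scores +2/−3/−5(open)/−2(extend). `N` scores 0 against anything, so
assembly gaps can neither create nor hide mutations. From the aligned
exons the caller emits, per species:

- **indels** (one maximal gap run = one event), classified frameshifting
  iff length mod 3 ≠ 0, left-normalized VCF-style against the reference
  CDS so the same ancestral event gets identical coordinates in every
  descendant;
- **premature stops** (in-frame TAA/TAG/TGA upstream of the reference
  stop; stops read in a frameshifted context are flagged as consequences,
  not independent events);
- **start-codon loss**, **non-canonical splice dinucleotides** (donor ≠
  GT, acceptor ≠ AG), and **exon deletion vs. gap-obscured absence**.

Identical calls across species are grouped by exact key and placed on
the branch above the most recent common ancestor of the carriers (Dollo
parsimony: single origin, no reversal), with non-carrier descendants
reported as conflicts. Mutations are validated by aligning simulated (or
real) reads against reference/mutant haplotype pairs: reads under 95%
identity are discarded, and a call is *confirmed* when ≥ 2 independent
sequencing projects each contribute a spanning mutant read. Where no
exon maps at all, the interval between the two nearest protein-coding
neighbour genes is scanned for N-runs and residual exon seeds to decide
`absent_complete` / `absent_gapped` / `remnant`. Everything is folded
into a per-species × gene verdict: `intact`, `pseudogene`,
`likely_pseudogene`, `lost`, or `inconclusive`.

## Worked example

```sh
orfdecay all --gene Aanat --seed 1 --no-validate --out-dir report/
```

prints the status matrix (excerpt):

```
species  gene   status      validated  evidence
Oorc     Aanat  pseudogene  False      start_loss:exon1@1;premature_stop:exon1@46;frameshift_deletion:exon3@291;...
Pcat     Aanat  pseudogene  False      frameshift_deletion:exon3@291;frameshift_deletion:exon3@330
Bacu     Aanat  pseudogene  False      premature_stop:exon1@46;splice_acceptor_noncanonical:exon3@271
Hamp     Aanat  intact      False      .
Tman     Aanat  pseudogene  False      start_loss:exon1@1;splice_donor_noncanonical:exon3@421
```

Every cetacean carries the shared exon-1 premature stop (called in 11 of
12 species; the sperm whale's exon 1 sits in an assembly gap and is
reported indeterminate, not absent), all eight toothed whales share the
exon-3 frameshift deletions, the four baleen whales share the intron-2
acceptor mutation, and the hippo keeps a clean ORF. The shared-group
table places the stop on the cetacean root branch:

```
gene   type            exon  cds_pos  n_carriers  indeterminate  branch
Aanat  premature_stop  1     46       11          Pcat           Cetacea
```

`report/` also contains the per-exon mapping table, the full mutation
TSV, the synteny report and a JSON status matrix. `orfdecay simulate`
writes a scenario to disk as plain FASTA/GFF3/FASTQ/newick/TSV files,
and `orfdecay synteny | validate | classify` re-run individual stages
from such a directory.

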