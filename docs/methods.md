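# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open; every human-readable
report (TSV, rendered maps) is 1-based, closed. Minus-strand gene models
are normalized at load time into transcription order with plus-strand
sequence, so frame arithmetic has one code path. CDS coordinates count
bases along the concatenated coding exons.

## Exon mapping

Each reference exon is located independently, mirroring how curators map
exons one at a time rather than using spliced alignment.

**Seeding.** Exact shared *k*-mers (default word size 10, the blastn
default used for diverged nucleotide searches) are clustered by
alignment diagonal within a 50-nt band, which tolerates indels up to the
band width inside one cluster; larger rearrangements simply produce two
clusters whose expanded windows merge. Each cluster's footprint is
expanded by one exon length per side. Candidates are ranked by hit count,
ties broken leftmost.

**Alignment.** The exon is aligned to each candidate window with the
three-state affine-gap recurrence (match +2, mismatch −3, gap open −5,
gap extend −2; a gap of length *g* costs `open + extend·(g−1)`), global
in the exon with free end-gaps in the window. The DP is vectorized
row-wise in numpy; the horizontal gap state uses a running-maximum scan,
exact because `gap_open ≤ gap_extend` makes re-opening inside a gap
never optimal. Traceback is deterministic with precedence diagonal >
up > left, and ties at the semi-global end column resolve leftmost, so
identical inputs give byte-identical alignments. `N` scores 0 against
any base and never counts as an identity match: an assembly gap can
neither fabricate nor mask a mutation.

**Acceptance of a placement.** An exon is `mapped` when (a) identity
over aligned columns ≥ 0.60 and (b) score ≥ 0.25 of the perfect score
(match reward × exon length). The identity cut alone is insufficient:
under semi-global alignment a short surviving fragment of an exon can
meander through flanking sequence, collect chance matches, and reach
≈ 0.65 "identity" while its score density stays low (measured ≈ 0.19 of
perfect for a one-third fragment, vs ≥ 0.33 for a genuinely mapped exon
carrying even a 282-nt deletion). The score-fraction criterion separates
the two regimes; placements failing it fall back to the missing/remnant
logic. A consequence worth knowing: an exon with more than roughly 40%
of its length deleted will be treated as a remnant rather than mapped.

**Missing exons.** An unmapped exon's expected interval is projected
from the nearest mapped exons using reference spacing. If ≥ 30% of that
interval is N it is `missing_in_gap` (no conclusion possible); otherwise
`missing_no_gap`. Sub-threshold placements count as remnant evidence
only when backed by at least 5 clustered word hits (≈ a 14-nt exact
stretch): isolated chance 10–12-mer repeats between unrelated sequences
occur at observable rates in multi-kilobase loci and must not produce
spurious "remnant" states.

## Mutation calling

One maximal gap run is one indel event; adjacent runs separated by ≥ 1
aligned column stay separate (a 12-nt and a 6-nt deletion are two
events, not one of 18). Indels are classified by `length mod 3` and
left-normalized against the reference CDS — shifting through equal
flanking bases to the leftmost equivalent placement — so that the same
ancestral event matches exactly across species regardless of where each
alignment happened to put the gap. The cumulative frame shift is tracked
along the CDS; a +1 shift later compensated by a +2 shift marks
subsequent sequence `restored`.

Premature stops are read on the reference codon grid projected through
the alignment, only for codons fully contained in one exon (codons
spanning splice junctions are not evaluated; none of the built-in
scenarios plant one). Where the running frame shift is non-zero, codons
are read in the shifted target frame and flagged `frameshift_context`:
they are consequences of the upstream frameshift and are excluded from
cross-species grouping. Start loss is any non-ATG (or gapped) triple
aligned to the reference start. Splice checks inspect the two intronic
bases on each side of every intron between consecutively mapped exons;
GT/AG is canonical, GC donors are reported non-canonical but annotated
"GC-AG minor". N at a splice position yields no call.

Whole-exon absence: `exon_deletion` requires mapped flanks on both sides
and an N-free intervening interval; terminal exons without a distal
anchor are always `exon_missing_gap`, because assembly truncation cannot
be excluded. `exon_missing_gap` is an absence-of-data marker, not an
event: it feeds the indeterminate sets used in grouping and is excluded
from truth comparisons.

An optional list of critical codons (e.g. an active-site residue) causes
deletions covering them to be annotated "active-site loss", which the
status classifier treats as qualifying damage.

## Shared mutations and branch placement

Calls are grouped by the exact key (gene, type, exon, left-normalized
CDS position, length, alt allele). Species whose exon is in an assembly
gap at the event position join the group as *indeterminate*; species
whose exon is cleanly absent do not, and surface as conflicts instead —
under Dollo logic the exon loss may postdate the indel, and the pipeline
reports rather than resolves this. Placement is Dollo parsimony: the
branch above the MRCA of the carriers, verified in tests against
exhaustive enumeration of all clades. Indeterminate species never move
the MRCA. An optional ±1-codon tolerance exists for matching stop codons
(default off; left normalization makes exact matching correct for
indels).

## Read validation

Each read is screened by sampled *k*-mer overlap (which also picks the
orientation), then aligned to the reference and mutant haplotype windows
(event ± 80 nt). Reads whose best identity — gaps counted against —
falls below 0.95 are discarded. A surviving read supports the allele of
its higher-scoring haplotype, equal scores are ambiguous and dropped,
and only reads spanning the event plus ≥ 10 nt on both sides count
(edge-anchored reads cannot distinguish alleles reliably). A mutation is
`confirmed` with ≥ 1 spanning mutant read in each of ≥ 2 samples
("independent sequencing projects"); one available sample can at best
leave it `unconfirmed (single sample)`. Verdicts never alter the gene
status — mutations present in an assembly stand on their own — they only
set the `validated` flag.

Because reads are aligned end-to-end against a bounded window, reads
overhanging the window are effectively discarded by the identity filter;
the 80-nt flank with 100-nt reads at 20× leaves an expected ≈ 12
fully-contained spanning reads per sample, so the probability of a
planted mutation going unconfirmed by chance is negligible (< 10⁻⁵ per
sample).

## Synteny

The *n* = 5 nearest protein-coding neighbours on each side (non-coding
genes skipped) define the locus. When no exon maps, the query interval
between the two direct neighbours is scanned: any N-run ≥ 10 nt (single
ambiguous bases are not assembly gaps) → `absent_gapped`; an N-free
interval with no remnant-strength exon signal → `absent_complete`;
remnant-strength signal (sub-threshold placement or ≥ 5 clustered word
hits inside the interval) → `remnant`. Neighbour orthology is by
case-insensitive symbol match; symbol aliasing is out of scope.

## Status classification

Decision order: (1) no mapped exon — `lost` only with `absent_complete`
synteny, otherwise `inconclusive`; (2) any hard disrupting call
(premature stop, frameshift, non-canonical splice, start loss, exon
deletion) — `pseudogene`; (3) only in-frame indels, deleting ≥ 4 codons
in total or a critical residue — `likely_pseudogene` (small in-frame
indels alone never condemn a gene); (4) clean complete mapping —
`intact`; (5) otherwise `inconclusive`.

## Synthetic scenarios

The generator builds a reference chromosome (random sense codons, ATG
start, single terminal stop, GT…AG introns, five single-exon coding
neighbours per side plus one non-coding gene), then copies it down a
rooted tree. Per branch, Poisson(rate × length) random substitutions are
applied, then that branch's planted mutations, all expressed in root
coordinates; length-changing edits are applied right-to-left so planted
coordinates stay interpretable, and an edit nested inside a later, larger
removal on the same lineage is superseded by it. Random substitutions
avoid planted substitution sites and a 10-nt guard band around planted
indels: a substitution adjacent to an indel changes the indel's optimal
alignment representation and would make the truth table ill-defined.
For the same reason, a planted stop codon that happens to be a one-base
rotation of the reference codon (e.g. ATG→TGA, which aligns as an indel
pair rather than three substitutions) is swapped for a different stop
codon. These guards model the fact that the planted events *are* the
conditions being tested; background divergence is a separate knob.

The four melatonin scenarios plant, on the appropriate branches, the
events observed in cetaceans: the shared *Aanat* exon-1 stop (cetacean
root) with toothed-whale start loss and exon-3 frameshifts, baleen-whale
acceptor mutation, and the sperm whale's 12-nt and 6-nt in-frame
deletions with its exon 1 N-masked; the shared *Asmt* 1-nt exon-1
insertion, exon-5 erosion in five toothed whales with gap-masked exon 5
elsewhere, the toothed-whale exon-8 acceptor change, and exon 9 removed
in all cetaceans; whole-locus *Mtnr1a* loss in the seven delphinoid
toothed whales (clean in three, N-filled in four), the sperm whale's
19-nt frameshift deletion, and baleen-whale exon-1 relic indels; and the
trans-species *Mtnr1b* exon-2 1-nt deletion (cetacean root), the grey
whale's 282-nt in-frame deletion, paired exon-1 stops and insertions,
four start losses, and gap-masked exon 2 in orca and bottlenose dolphin.
Exact CDS positions of most events are fixture choices (recorded in
`simulate.py`); published sources print event lengths and sharing
patterns, not base-level coordinates, so tests assert types, lengths and
carrier sets. Two sequencing samples per species are simulated (100-nt
reads, 20×, 0.5% substitution error), except one sample for the Yangtze
river dolphin and none for the bowhead whale, matching the availability
pattern of the real archives.

The default per-branch substitution rate in the replication scenarios is
0: they reproduce observed mutation maps, and the recovery guarantee
(truth multiset = called multiset) is exact there. With background noise
(tested at 0.005/site/branch) all planted events are still recovered and
extra calls are substitution-derived only. What passing these tests does
*not* show: robustness to real assembly artefacts (chimeric scaffolds,
collapsed repeats, paralogous gene copies), heterogeneous divergence,
intron-length evolution, or annotation errors in neighbour genes — on
real data the paralog problem in particular (two *Aanat*-like genes
exist in cow and hippo) is only mitigated by best-score locus selection
with runner-up reporting, not solved.

## Problem sizes and runtime

Scenarios use exon/intron geometries of a few hundred nt to ~850 nt per
exon on ~10–15 kb chromosomes, 14 species, and 20× read sets over the
gene region — small enough that the full test suite and the acceptance
script each run in minutes on one CPU while exercising every code path
at realistic mutation scales (events from 1 to 282 nt).

## Known limitations

- Codons spanning exon junctions are not checked for stops.
- Exon remnant detection requires a ≥ 14-nt conserved core; shorter or
  fully diverged relics are reported as clean absence.
- One reference isoform per run; isoform selection is the caller's job.
- Neighbour genes are matched by symbol, not sequence orthology.
- The score-fraction mapping criterion deliberately reclassifies exons
  with > ~40% of their length deleted as remnants.
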