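"""Confirmation of assembly-derived mutations against raw sequencing reads.

A candidate mutation is validated by aligning every read (both
orientations) against two local haplotypes — the reference allele and the
mutant allele embedded in identical flanking sequence. Reads whose best
identity falls below 95% are discarded, mirroring standard read-level
quality filtering. A surviving read supports the allele of its
higher-scoring haplotype, but only if its alignment spans the event plus
a flank on both sides; edge-anchored reads are ambiguous and do not
count. A mutation is *confirmed* when at least ``min_samples`` (default
2) independent sequencing projects or individuals each contribute at
least ``min_reads`` spanning mutant reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .align import ScoringScheme, align_exon
from .mutations import MutationCall

__all__ = [
    "ReadSet",
    "ReadSupport",
    "ValidationParams",
    "validate_mutation",
    "load_reads",
    "build_haplotype_pair",
]


@dataclass
class ReadSet:
    """Reads from one sequencing project or individual."""

    sample_id: str
    reads: list[tuple[str, str]]  # (read_id, sequence)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass
class ReadSupport:
    """Per-mutation read-level evidence across samples."""

    mutation_key: tuple
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    supporting_samples: set[str] = field(default_factory=set)
    verdict: str = "insufficient_data"  # confirmed | unconfirmed | insufficient_data
    note: str = ""


@dataclass(frozen=True)
class ValidationParams:
    min_identity: float = 0.95
    min_samples: int = 2
    min_reads: int = 1
    span_flank: int = 10
    word_size: int = 8


def load_reads(path: str | Path, sample_id: str | None = None) -> ReadSet:
    """Load a FASTQ or FASTA read file as one sample."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]
    return ReadSet(sample_id=sample_id or path.stem, reads=reads)


def build_haplotype_pair(
    mut: MutationCall, target_seq: str, flank: int = 60
) -> tuple[str, str, tuple[int, int]]:
    """Local (reference, mutant) haplotype windows around a called event.

    The mutant haplotype is the target sequence as assembled; the
    reference haplotype reverts the event (re-inserting deleted bases,
    removing inserted ones, or restoring the reference allele of a
    substitution). Requires ``mut.target_pos``. Returns the two windows
    plus the event interval within the *mutant* window.
    """
    if mut.target_pos is None:
        raise ValueError("mutation has no target coordinate")
    pos = mut.target_pos
    if "deletion" in mut.type:
        ev_len_mut = 0
        lo = max(0, pos - flank)
        hi = min(len(target_seq), pos + flank)
        mutant = target_seq[lo:hi]
        reference = target_seq[lo:pos] + mut.ref_allele + target_seq[pos:hi]
        event = (pos - lo, pos - lo)
    elif "insertion" in mut.type:
        lo = max(0, pos - flank)
        hi = min(len(target_seq), pos + mut.length + flank)
        mutant = target_seq[lo:hi]
        reference = target_seq[lo:pos] + target_seq[pos + mut.length : hi]
        event = (pos - lo, pos - lo + mut.length)
    else:  # substitution-like (stop, splice, start)
        lo = max(0, pos - flank)
        hi = min(len(target_seq), pos + mut.length + flank)
        mutant = target_seq[lo:hi]
        reference = (
            target_seq[lo:pos] + mut.ref_allele + target_seq[pos + mut.length : hi]
        )
        event = (pos - lo, pos - lo + mut.length)
    return reference, mutant, event


def _window_kmers(windows: list[str], k: int) -> set[str]:
    return {w[i : i + k] for w in windows for i in range(len(w) - k + 1)}


def _orientations(read: str, kmers: set[str], k: int) -> list[str]:
    """Orientations of the read worth aligning, by sampled k-mer hits.

    Returns an empty list when neither orientation shares a k-mer with
    the haplotypes (read does not overlap the locus), otherwise the
    orientation(s) with the most hits (both on a tie).
    """
    rc = str(Seq(read).reverse_complement())
    counts = []
    for s in (read, rc):
        n = 0
        for i in range(0, len(s) - k + 1, max(1, k // 2)):
            if s[i : i + k] in kmers:
                n += 1
        counts.append(n)
    if counts[0] == counts[1] == 0:
        return []
    if counts[0] > counts[1]:
        return [read]
    if counts[1] > counts[0]:
        return [rc]
    return [read, rc]


def _best_alignment(seqs: list[str], hap: str, scheme: ScoringScheme):
    """Best over the given read orientations; (score, identity, span)."""
    best = None
    for seq in seqs:
        aln = align_exon(seq, hap, scheme, min_identity=0.0)
        if best is None or aln.score > best[0]:
            tpos = [t for _, t in aln.aligned_columns if t is not None]
            span = (tpos[0], tpos[-1] + 1) if tpos else (0, 0)
            best = (aln.score, aln.identity, span)
    return best


def validate_mutation(
    mut: MutationCall,
    haplotypes: tuple[str, str],
    readsets: list[ReadSet],
    params: ValidationParams | None = None,
    event_interval: tuple[int, int] | None = None,
) -> ReadSupport:
    """Classify a mutation as confirmed / unconfirmed / insufficient_data.

    ``haplotypes`` is ``(reference_window, mutant_window)``;
    ``event_interval`` the event's half-open interval within the mutant
    window (defaults to the window centre for backwards compatibility).
    """
    params = params or ValidationParams()
    support = ReadSupport(mutation_key=mut.key)
    if not readsets or all(not rs.reads for rs in readsets):
        support.verdict = "insufficient_data"
        support.note = "no readsets"
        return support
    ref_hap, mut_hap = haplotypes
    if event_interval is None:
        mid = len(mut_hap) // 2
        event_interval = (mid, mid)
    # event interval on the reference haplotype: same left edge, ref length
    ref_event_len = len(mut.ref_allele.replace("-", ""))
    ref_event = (event_interval[0], event_interval[0] + ref_event_len)
    scheme = ScoringScheme(word_size=max(4, params.word_size))
    kmers = _window_kmers([ref_hap, mut_hap], params.word_size)
    for rs in readsets:
        counts = {"spanning_mutant": 0, "spanning_reference": 0, "filtered_out": 0}
        for _rid, read in rs.reads:
            seqs = _orientations(read, kmers, params.word_size)
            if not seqs:
                continue
            ref_best = _best_alignment(seqs, ref_hap, scheme)
            mut_best = _best_alignment(seqs, mut_hap, scheme)
            best_identity = max(ref_best[1], mut_best[1])
            if best_identity < params.min_identity:
                counts["filtered_out"] += 1
                continue
            if mut_best[0] > ref_best[0]:
                allele, span, event = "mutant", mut_best[2], event_interval
            elif ref_best[0] > mut_best[0]:
                allele, span, event = "reference", ref_best[2], ref_event
            else:
                continue  # ambiguous: equal scores
            if (
                span[0] <= event[0] - params.span_flank
                and span[1] >= event[1] + params.span_flank
            ):
                counts[f"spanning_{allele}"] += 1
        support.per_sample[rs.sample_id] = counts
        if counts["spanning_mutant"] >= params.min_reads:
            support.supporting_samples.add(rs.sample_id)
    n = len(support.supporting_samples)
    if n >= params.min_samples:
        support.verdict = "confirmed"
    elif len(readsets) < params.min_samples:
        support.verdict = "unconfirmed"
        support.note = "single sample" if len(readsets) == 1 else "too few samples"
    else:
        support.verdict = "unconfirmed"
    return support


def support_rows(supports: list[ReadSupport]) -> list[dict]:
    rows = []
    for s in supports:
        gene, mtype, exon, cds_pos, length, alt = s.mutation_key
        for sample, counts in s.per_sample.items() or {"-": {}}.items():
            rows.append(
                {
                    "gene": gene,
                    "type": mtype,
                    "exon": exon + 1,
                    "cds_pos": cds_pos + 1,
                    "sample": sample,
                    **counts,
                    "verdict": s.verdict,
                }
            )
        if not s.per_sample:
            rows.append(
                {
                    "gene": gene,
                    "type": mtype,
                    "exon": exon + 1,
                    "cds_pos": cds_pos + 1,
                    "sample": ".",
                    "verdict": s.verdict,
                }
            )
    return rows
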