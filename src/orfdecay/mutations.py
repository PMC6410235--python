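"""ORF-disrupting mutation calling from exon alignments.

The caller turns a :class:`~orfdecay.align.GeneMapping` into a list of
:class:`MutationCall` records covering the event classes that abolish an
open reading frame: frameshifting and in-frame indels, premature stop
codons, start-codon loss, non-canonical splice sites, and whole-exon
deletion or gap-obscured absence.

Indels are left-normalized (VCF convention) against the reference CDS so
that the same ancestral event lands on identical coordinates in every
descendant species; without this, alignment-dependent gap placement would
break cross-species matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import REMNANT_MIN_SEED_SUPPORT, ExonAlignment, GeneMapping
from .gene_models import GeneModel, Genome, extract_cds, intron_interval

__all__ = [
    "MutationCall",
    "left_normalize",
    "call_indels",
    "call_premature_stops",
    "check_start_codon",
    "check_splice_sites",
    "call_exon_loss",
    "call_all",
    "HARD_DISRUPTING_TYPES",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

HARD_DISRUPTING_TYPES = frozenset(
    {
        "premature_stop",
        "frameshift_deletion",
        "frameshift_insertion",
        "start_loss",
        "splice_donor_noncanonical",
        "splice_acceptor_noncanonical",
        "exon_deletion",
    }
)


@dataclass(frozen=True)
class MutationCall:
    """One ORF-relevant event in one species.

    ``cds_pos`` is the 0-based reference-CDS coordinate of the
    left-normalized event; ``frame_consequence`` tracks the cumulative
    reading-frame shift downstream of the event ('none', 'shift+1',
    'shift+2' or 'restored'). ``frameshift_context`` marks stop codons
    read in a shifted frame: these are consequences of an upstream
    frameshift, not independent events.
    """

    type: str
    exon_index: int
    cds_pos: int
    length: int
    ref_allele: str
    alt_allele: str
    frame_consequence: str = "none"
    species_id: str = ""
    gene_id: str = ""
    target_pos: int | None = None
    frameshift_context: bool = False
    note: str = ""

    @property
    def key(self) -> tuple:
        """Cross-species matching key (species-independent)."""
        return (
            self.gene_id,
            self.type,
            self.exon_index,
            self.cds_pos,
            self.length,
            self.alt_allele,
        )


class CallError(ValueError):
    pass


def left_normalize(
    ref_cds: str, cds_pos: int, deleted: str, inserted: str
) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent placement.

    ``deleted`` is the reference sequence removed at ``cds_pos`` (empty
    for a pure insertion); ``inserted`` the sequence added there (empty
    for a pure deletion). Returns ``(cds_pos, deleted, inserted)`` after
    shifting: an indel may move left one base at a time whenever the base
    preceding it equals the last base of the indel sequence (rotation).
    """
    if deleted and inserted:
        return cds_pos, deleted, inserted  # complex event: leave in place
    pos = cds_pos
    if deleted:
        n = len(deleted)
        while pos > 0 and ref_cds[pos - 1] == ref_cds[pos + n - 1]:
            pos -= 1
        return pos, ref_cds[pos : pos + n], ""
    s = inserted
    while pos > 0 and s and ref_cds[pos - 1] == s[-1]:
        s = s[-1] + s[:-1]
        pos -= 1
    return pos, "", s


def _exon_gap_runs(
    aln: ExonAlignment,
) -> list[tuple[int, str, int, int | None]]:
    """Maximal gap runs as (ref_offset, side, length, target_pos).

    side 'target' = bases present in reference but absent from target
    (deletion); side 'ref' = extra target bases (insertion). ref_offset
    is the exon-local reference position where the event is anchored.
    """
    runs = []
    cols = aln.aligned_columns
    i = 0
    while i < len(cols):
        r, t = cols[i]
        if t is None:  # deletion in target
            j = i
            while j < len(cols) and cols[j][1] is None:
                j += 1
            runs.append((cols[i][0], "target", j - i, None))
            i = j
        elif r is None:  # insertion in target
            j = i
            while j < len(cols) and cols[j][0] is None:
                j += 1
            nxt = next((c[0] for c in cols[j:] if c[0] is not None), None)
            anchor = nxt if nxt is not None else (
                max((c[0] for c in cols[:i] if c[0] is not None), default=0) + 1
            )
            runs.append((anchor, "ref", j - i, cols[i][1]))
            i = j
        else:
            i += 1
    return runs


def call_indels(
    aln: ExonAlignment,
    model: GeneModel,
    ref_cds: str,
    target_seq: str | None = None,
    species_id: str = "",
    running_shift: int = 0,
) -> tuple[list[MutationCall], int]:
    """Indel calls for one mapped exon.

    Each maximal gap run is one event, classified frameshifting or
    in-frame by ``length mod 3`` and left-normalized against the
    reference CDS. ``running_shift`` is the cumulative frame shift
    carried in from upstream exons; the updated value is returned so a
    +1 shift later compensated by a +2 shift is marked 'restored'.
    """
    if not aln.mapped:
        raise CallError("cannot call on unmapped exon")
    calls: list[MutationCall] = []
    offset = model.exon_cds_offset(aln.exon_index)
    shift = running_shift
    for ref_off, side, length, target_pos in _exon_gap_runs(aln):
        cds_pos = offset + (ref_off if ref_off is not None else 0)
        if side == "target":
            deleted = ref_cds[cds_pos : cds_pos + length]
            pos, deleted, _ = left_normalize(ref_cds, cds_pos, deleted, "")
            ref_allele, alt_allele = deleted, "-" * length
            kind = "deletion"
            delta = -length
        else:
            if target_seq is not None and target_pos is not None:
                inserted = target_seq[target_pos : target_pos + length]
            else:
                inserted = "N" * length
            pos, _, inserted = left_normalize(ref_cds, cds_pos, "", inserted)
            ref_allele, alt_allele = "-" * length, inserted
            kind = "insertion"
            delta = length
        if length % 3 == 0:
            mtype = f"inframe_{kind}"
            fc = "none"
        else:
            mtype = f"frameshift_{kind}"
            shift = (shift + delta) % 3
            fc = "restored" if shift == 0 else f"shift+{shift}"
        calls.append(
            MutationCall(
                type=mtype,
                exon_index=aln.exon_index,
                cds_pos=pos,
                length=length,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                frame_consequence=fc,
                species_id=species_id,
                gene_id=model.gene_id,
                target_pos=target_pos,
            )
        )
    return calls, shift


def _target_base_at(aln: ExonAlignment, ref_off: int, target: str) -> str | None:
    """Target base aligned to exon-local reference position, or None if gapped."""
    for r, t in aln.aligned_columns:
        if r == ref_off:
            return None if t is None else target[t]
    return None


def call_premature_stops(
    mapping: GeneMapping,
    model: GeneModel,
    ref_cds: str,
    target_seq: str,
) -> list[MutationCall]:
    """Stop codons in the target strictly upstream of the reference stop.

    Codons are read on the reference codon grid projected through each
    exon alignment. Where the cumulative frame shift from upstream indels
    is non-zero, codons are read in the shifted frame and flagged
    ``frameshift_context`` — consequences of the frameshift, not
    independent events.
    """
    calls: list[MutationCall] = []
    shift = 0
    stop_pos = model.stop_cds_pos
    for aln in mapping.exon_alignments:
        if not aln.mapped:
            continue
        offset = model.exon_cds_offset(aln.exon_index)
        indels, new_shift = call_indels(
            aln, model, ref_cds, target_seq, mapping.species_id, shift
        )
        # map exon-local ref position -> target pos for fast lookup
        pos_map: dict[int, int | None] = {}
        for r, t in aln.aligned_columns:
            if r is not None:
                pos_map[r] = t
        exon_len = model.exon_lengths[aln.exon_index]
        # frame shift active at each exon-local position
        boundaries = sorted(
            (c.cds_pos - offset, (c.length if "insertion" in c.type else -c.length))
            for c in indels
            if "frameshift" in c.type
        )
        first_codon = -(-(offset) // 3) * 3 - offset  # first full codon start
        for local in range(max(first_codon, 0), exon_len - 2, 3):
            cds_codon_start = offset + local
            if cds_codon_start >= stop_pos:
                break
            local_shift = (
                shift + sum(d for b, d in boundaries if b <= local)
            ) % 3
            ts = [pos_map.get(local + k) for k in range(3)]
            if any(t is None for t in ts):
                continue
            if local_shift == 0:
                codon = "".join(target_seq[t] for t in ts)  # type: ignore[index]
                in_context = False
            else:
                # read in the shifted target frame anchored at this codon
                t0 = ts[0]
                if t0 is None or t0 + 3 > len(target_seq):
                    continue
                codon = target_seq[t0 : t0 + 3]
                in_context = True
            if codon in STOP_CODONS:
                ref_codon = ref_cds[cds_codon_start : cds_codon_start + 3]
                if ref_codon in STOP_CODONS:
                    continue
                calls.append(
                    MutationCall(
                        type="premature_stop",
                        exon_index=aln.exon_index,
                        cds_pos=cds_codon_start,
                        length=3,
                        ref_allele=ref_codon,
                        alt_allele=codon,
                        frame_consequence="none",
                        species_id=mapping.species_id,
                        gene_id=model.gene_id,
                        target_pos=ts[0],
                        frameshift_context=in_context,
                    )
                )
        shift = new_shift
    return calls


def check_start_codon(
    mapping: GeneMapping, model: GeneModel, target_seq: str
) -> MutationCall | None:
    """start_loss when the bases aligned to the reference ATG are not ATG.

    Returns None (with no claim) when the start exon is unmapped.
    """
    start_pos = model.start_codon_cds_pos
    exon_idx = model.exon_of_cds_pos(start_pos)
    aln = mapping.exon_alignments[exon_idx]
    if not aln.mapped:
        return None
    offset = model.exon_cds_offset(exon_idx)
    bases = []
    for k in range(3):
        b = _target_base_at(aln, start_pos - offset + k, target_seq)
        bases.append("-" if b is None else b)
    observed = "".join(bases)
    if observed == "ATG":
        return None
    return MutationCall(
        type="start_loss",
        exon_index=exon_idx,
        cds_pos=start_pos,
        length=3,
        ref_allele="ATG",
        alt_allele=observed,
        species_id=mapping.species_id,
        gene_id=model.gene_id,
    )


def check_splice_sites(
    mapping: GeneMapping,
    model: GeneModel,
    target_seq: str,
) -> list[MutationCall]:
    """Non-canonical donor (GT) / acceptor (AG) dinucleotides.

    For each intron inferred between consecutive mapped exons, the first
    two and last two intronic target bases are inspected. N at either
    position yields no call (indeterminate). The GC-AG minor donor class
    is still reported non-canonical, annotated as such.
    """
    calls: list[MutationCall] = []
    alns = mapping.exon_alignments
    for i in range(len(alns) - 1):
        left, right = alns[i], alns[i + 1]
        if not (left.mapped and right.mapped):
            continue
        ivl, ivr = left.target_interval, right.target_interval
        if ivl is None or ivr is None or ivr[0] - ivl[1] < 4:
            continue
        donor = target_seq[ivl[1] : ivl[1] + 2]
        acceptor = target_seq[ivr[0] - 2 : ivr[0]]
        cds_boundary = model.exon_cds_offset(i + 1)
        if "N" not in donor and donor != "GT":
            calls.append(
                MutationCall(
                    type="splice_donor_noncanonical",
                    exon_index=i,
                    cds_pos=cds_boundary,
                    length=2,
                    ref_allele="GT",
                    alt_allele=donor,
                    species_id=mapping.species_id,
                    gene_id=model.gene_id,
                    target_pos=ivl[1],
                    note="GC-AG minor" if donor == "GC" else "",
                )
            )
        if "N" not in acceptor and acceptor != "AG":
            calls.append(
                MutationCall(
                    type="splice_acceptor_noncanonical",
                    exon_index=i + 1,
                    cds_pos=cds_boundary,
                    length=2,
                    ref_allele="AG",
                    alt_allele=acceptor,
                    species_id=mapping.species_id,
                    gene_id=model.gene_id,
                    target_pos=ivr[0] - 2,
                )
            )
    return calls


def call_exon_loss(
    mapping: GeneMapping,
    model: GeneModel,
    target_seq: str,
    min_gap_run: int = 10,
) -> list[MutationCall]:
    """Whole-exon absence calls.

    exon_deletion requires mapped flanking exons on both sides and an
    N-free intervening interval (true sequence, no exon remnant);
    exon_missing_gap covers N-obscured intervals and terminal exons with
    no anchor on one side, where assembly truncation cannot be excluded.
    """
    calls: list[MutationCall] = []
    placed = {
        a.exon_index: a.target_interval
        for a in mapping.exon_alignments
        if a.mapped
    }
    for aln in mapping.exon_alignments:
        if aln.mapped:
            continue
        idx = aln.exon_index
        left = max((i for i in placed if i < idx), default=None)
        right = min((i for i in placed if i > idx), default=None)
        offset = model.exon_cds_offset(idx)
        length = model.exon_lengths[idx]
        local_lo = placed[left][1] if left is not None else 0
        local_hi = placed[right][0] if right is not None else len(target_seq)
        if (
            aln.status == "low_identity"
            and aln.seed_support >= REMNANT_MIN_SEED_SUPPORT
            and aln.target_interval is not None
            and aln.target_interval[0] < local_hi
            and aln.target_interval[1] > local_lo
        ):
            # a sub-threshold hit at the expected locus: a decayed remnant
            calls.append(
                MutationCall(
                    type="exon_missing_gap",
                    exon_index=idx,
                    cds_pos=offset,
                    length=length,
                    ref_allele="",
                    alt_allele="",
                    species_id=mapping.species_id,
                    gene_id=model.gene_id,
                    note="remnant (sub-threshold hit)",
                )
            )
            continue
        if left is not None and right is not None:
            lo = placed[left][1]
            hi = placed[right][0]
            region = target_seq[lo:hi] if hi > lo else ""
            has_gap = _longest_n_run(region) >= min_gap_run
            mtype = "exon_missing_gap" if has_gap else "exon_deletion"
        else:
            mtype = "exon_missing_gap"  # terminal: truncation not excluded
        calls.append(
            MutationCall(
                type=mtype,
                exon_index=idx,
                cds_pos=offset,
                length=length,
                ref_allele="",
                alt_allele="",
                species_id=mapping.species_id,
                gene_id=model.gene_id,
                note="" if mtype == "exon_deletion" else (
                    "terminal exon, no distal anchor"
                    if left is None or right is None
                    else "assembly gap in projected interval"
                ),
            )
        )
    return calls


def _longest_n_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == "N" else 0
        best = max(best, cur)
    return best


def call_all(
    mapping: GeneMapping,
    model: GeneModel,
    ref_genome: Genome,
    target_seq: str,
    critical_codons: tuple[int, ...] = (),
) -> list[MutationCall]:
    """Full mutation scan for one species x gene: indels, stops, start,
    splice sites and exon loss, in CDS order.

    ``critical_codons`` are reference codon indices whose deletion is
    annotated 'active-site loss'.
    """
    ref_cds = extract_cds(model, ref_genome)
    calls: list[MutationCall] = []
    shift = 0
    for aln in mapping.exon_alignments:
        if aln.mapped:
            indels, shift = call_indels(
                aln, model, ref_cds, target_seq, mapping.species_id, shift
            )
            calls.extend(indels)
    calls.extend(call_premature_stops(mapping, model, ref_cds, target_seq))
    start = check_start_codon(mapping, model, target_seq)
    if start is not None:
        calls.append(start)
    calls.extend(check_splice_sites(mapping, model, target_seq))
    calls.extend(call_exon_loss(mapping, model, target_seq))
    if critical_codons:
        annotated = []
        for c in calls:
            if "deletion" in c.type and any(
                c.cds_pos <= 3 * k < c.cds_pos + c.length for k in critical_codons
            ):
                annotated.append(replace(c, note=(c.note + " active-site loss").strip()))
            else:
                annotated.append(c)
        calls = annotated
    return sorted(calls, key=lambda c: (c.cds_pos, c.type))
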