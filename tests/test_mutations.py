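"""Mutation calling: indels, frame arithmetic, stops, splice sites,
start codon, exon loss, left normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orfdecay.align import map_gene
from orfdecay.gene_models import Genome, extract_cds
from orfdecay.mutations import (
    CallError,
    call_all,
    call_exon_loss,
    call_indels,
    call_premature_stops,
    check_splice_sites,
    check_start_codon,
    left_normalize,
)
from orfdecay.simulate import generate_reference_gene


def _apply_deletion(seq: str, pos: int, length: int) -> str:
    return seq[:pos] + seq[pos + length :]


def _apply_insertion(seq: str, pos: int, ins: str) -> str:
    return seq[:pos] + ins + seq[pos:]


@pytest.fixture(scope="module")
def locus():
    """A 3-exon gene plus its genomic context, reused across tests."""
    model, genome, _ = generate_reference_gene(
        3, [120, 150, 84], [300, 350], seed=21, gene_id="g", chrom="c"
    )
    return model, genome


def _call_on_target(model, ref_genome, target_seq):
    target = Genome(sequences={model.chrom: target_seq})
    mapping = map_gene(model, ref_genome, target, model.chrom, species_id="sp")
    return call_all(mapping, model, ref_genome, target_seq), mapping


@pytest.mark.parametrize("length", range(1, 31))
def test_deletion_frame_classification_exhaustive(locus, length):
    """frameshift <=> deleted length not divisible by 3, lengths 1..30."""
    model, genome = locus
    seq = genome.sequences["c"]
    g = model.exons[1][0] + 40  # inside exon 2
    target = _apply_deletion(seq, g, length)
    calls, _ = _call_on_target(model, genome, target)
    dels = [c for c in calls if c.type.endswith("_deletion")]
    assert len(dels) == 1
    assert dels[0].length == length
    expected = "inframe_deletion" if length % 3 == 0 else "frameshift_deletion"
    assert dels[0].type == expected
    assert dels[0].exon_index == 1


@pytest.mark.parametrize("length", [1, 2, 3, 7, 12])
def test_insertion_frame_classification(locus, length, rng):
    model, genome = locus
    seq = genome.sequences["c"]
    g = model.exons[1][0] + 60
    ins = "".join(rng.choice(list("ACGT"), size=length))
    target = _apply_insertion(seq, g, ins)
    calls, _ = _call_on_target(model, genome, target)
    inss = [c for c in calls if c.type.endswith("_insertion")]
    assert len(inss) == 1
    assert inss[0].length == length
    expected = "inframe_insertion" if length % 3 == 0 else "frameshift_insertion"
    assert inss[0].type == expected


def test_gap_free_alignment_gives_no_indels(locus):
    model, genome = locus
    calls, mapping = _call_on_target(model, genome, genome.sequences["c"])
    assert calls == []
    ref_cds = extract_cds(model, genome)
    got, shift = call_indels(
        mapping.exon_alignments[0], model, ref_cds, genome.sequences["c"]
    )
    assert got == [] and shift == 0


def test_call_indels_rejects_unmapped_exon(locus):
    model, genome = locus
    seq = genome.sequences["c"]
    s, e = model.exons[1]
    target = Genome(sequences={"c": seq[:s] + "N" * (e - s) + seq[e:]})
    mapping = map_gene(model, genome, target, "c")
    ref_cds = extract_cds(model, genome)
    with pytest.raises(CallError, match="unmapped"):
        call_indels(mapping.exon_alignments[1], model, ref_cds)


# --- left normalization ---------------------------------------------------


def brute_force_leftmost_deletion(ref: str, pos: int, length: int) -> int:
    """Smallest pos' whose deletion yields the same derived sequence."""
    derived = ref[:pos] + ref[pos + length :]
    for p in range(pos + 1):
        if ref[:p] + ref[p + length :] == derived:
            return p
    raise AssertionError


def brute_force_leftmost_insertion(ref: str, pos: int, ins: str):
    derived = ref[:pos] + ins + ref[pos:]
    for p in range(pos + 1):
        for rot in range(len(ins)):
            cand = ins[rot:] + ins[:rot]
            if ref[:p] + cand + ref[p:] == derived:
                return p, cand
    raise AssertionError


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.data())
def test_left_normalize_deletion_matches_brute_force(data):
    ref = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=50))
    length = data.draw(st.integers(1, min(6, len(ref) - 1)))
    pos = data.draw(st.integers(0, len(ref) - length))
    got_pos, got_del, _ = left_normalize(ref, pos, ref[pos : pos + length], "")
    assert got_pos == brute_force_leftmost_deletion(ref, pos, length)
    assert got_del == ref[got_pos : got_pos + length]
    again = left_normalize(ref, got_pos, got_del, "")
    assert again == (got_pos, got_del, "")  # idempotent


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.data())
def test_left_normalize_insertion_matches_brute_force(data):
    ref = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=50))
    ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=5))
    pos = data.draw(st.integers(0, len(ref)))
    got_pos, _, got_ins = left_normalize(ref, pos, "", ins)
    bf_pos, _bf_ins = brute_force_leftmost_insertion(ref, pos, ins)
    assert got_pos == bf_pos
    # derived sequences must be identical
    assert ref[:got_pos] + got_ins + ref[got_pos:] == ref[:pos] + ins + ref[pos:]


# --- premature stops ------------------------------------------------------


def test_substituted_stop_codon_called_at_codon_start(locus):
    model, genome = locus
    seq = list(genome.sequences["c"])
    cds_pos = 72  # codon 25
    g = model.exons[0][0] + cds_pos
    ref_cds = extract_cds(model, genome)
    assert ref_cds[cds_pos : cds_pos + 3] not in ("TAA", "TAG", "TGA")
    seq[g : g + 3] = "TGA"
    calls, _ = _call_on_target(model, genome, "".join(seq))
    stops = [c for c in calls if c.type == "premature_stop"]
    assert len(stops) == 1
    assert stops[0].cds_pos == 72
    assert stops[0].alt_allele == "TGA"
    assert not stops[0].frameshift_context


def test_identical_target_has_no_stop_calls(locus):
    model, genome = locus
    calls, _ = _call_on_target(model, genome, genome.sequences["c"])
    assert [c for c in calls if c.type == "premature_stop"] == []


def test_stops_downstream_of_frameshift_are_flagged_not_independent(locus):
    """After an uncompensated frameshift, downstream stop codons are
    consequences of the shift and must not surface as separate events."""
    model, genome = locus
    seq = genome.sequences["c"]
    g = model.exons[0][0] + 30
    target = _apply_deletion(seq, g, 1)  # shift +1 from cds 30 onwards
    calls, _ = _call_on_target(model, genome, target)
    for c in calls:
        if c.type == "premature_stop":
            assert c.frameshift_context


# --- start codon ----------------------------------------------------------


def test_start_loss_on_substituted_atg(locus):
    model, genome = locus
    seq = list(genome.sequences["c"])
    g = model.exons[0][0]
    assert "".join(seq[g : g + 3]) == "ATG"
    seq[g] = "G"  # ATG -> GTG
    calls, _ = _call_on_target(model, genome, "".join(seq))
    starts = [c for c in calls if c.type == "start_loss"]
    assert len(starts) == 1 and starts[0].alt_allele == "GTG"


def test_intact_start_gives_no_call(locus):
    model, genome = locus
    target = Genome(sequences={"c": genome.sequences["c"]})
    mapping = map_gene(model, genome, target, "c")
    assert check_start_codon(mapping, model, genome.sequences["c"]) is None


def test_start_inside_deletion_is_still_a_loss(locus):
    """Deleting the region around the ATG yields start_loss whether the
    aligner renders the lost codon as gaps or as mismatched bases."""
    model, genome = locus
    seq = genome.sequences["c"]
    g = model.exons[0][0]
    target = _apply_deletion(seq, g - 2, 8)  # removes the ATG entirely
    target_genome = Genome(sequences={"c": target})
    mapping = map_gene(model, genome, target_genome, "c")
    call = check_start_codon(mapping, model, target)
    assert call is not None and call.type == "start_loss"
    assert call.alt_allele != "ATG"


# --- splice sites ---------------------------------------------------------


def test_canonical_splice_sites_silent(locus):
    model, genome = locus
    target = Genome(sequences={"c": genome.sequences["c"]})
    mapping = map_gene(model, genome, target, "c")
    assert check_splice_sites(mapping, model, genome.sequences["c"]) == []


@pytest.mark.parametrize(
    "which,alt,expected_type",
    [
        ("acceptor", "AA", "splice_acceptor_noncanonical"),
        ("donor", "GC", "splice_donor_noncanonical"),
    ],
)
def test_noncanonical_splice_called(locus, which, alt, expected_type):
    from orfdecay.gene_models import intron_interval

    model, genome = locus
    seq = list(genome.sequences["c"])
    s, e = intron_interval(model, 1)  # intron between exons 2 and 3
    if which == "acceptor":
        seq[e - 2 : e] = alt
    else:
        seq[s : s + 2] = alt
    calls, _ = _call_on_target(model, genome, "".join(seq))
    hits = [c for c in calls if c.type == expected_type]
    assert len(hits) == 1
    assert hits[0].alt_allele == alt
    if alt == "GC":
        assert "GC-AG minor" in hits[0].note


# --- exon loss ------------------------------------------------------------


def test_internal_exon_deletion_with_clean_flanks(locus):
    model, genome = locus
    seq = genome.sequences["c"]
    s, e = model.exons[1]
    calls, _ = _call_on_target(model, genome, seq[:s] + seq[e:])
    loss = [c for c in calls if c.type == "exon_deletion"]
    assert len(loss) == 1 and loss[0].exon_index == 1


def test_exon_replaced_by_ns_is_gap_not_deletion(locus):
    model, genome = locus
    seq = genome.sequences["c"]
    s, e = model.exons[1]
    calls, _ = _call_on_target(model, genome, seq[:s] + "N" * 500 + seq[e:])
    loss = [c for c in calls if c.type.startswith("exon_")]
    assert len(loss) == 1 and loss[0].type == "exon_missing_gap"


def test_terminal_exon_absence_is_conservative(locus):
    """A missing last exon with sequence ending right after cannot be
    distinguished from assembly truncation."""
    model, genome = locus
    seq = genome.sequences["c"]
    s, _ = model.exons[2]
    calls, _ = _call_on_target(model, genome, seq[:s])
    loss = [c for c in calls if c.exon_index == 2 and c.type.startswith("exon_")]
    assert len(loss) == 1 and loss[0].type == "exon_missing_gap"


def test_critical_residue_annotation(locus):
    model, genome = locus
    seq = genome.sequences["c"]
    g = model.exons[1][0] + 30  # codon 50 = cds 150..153
    target = _apply_deletion(seq, g, 6)
    target_genome = Genome(sequences={"c": target})
    mapping = map_gene(model, genome, target_genome, "c", species_id="sp")
    calls = call_all(mapping, model, genome, target, critical_codons=(50,))
    dels = [c for c in calls if c.type == "inframe_deletion"]
    assert len(dels) == 1
    assert "active-site loss" in dels[0].note
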