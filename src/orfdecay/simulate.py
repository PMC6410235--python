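"""Synthetic genomes with branch-planted gene-disrupting mutations.

The generator produces everything the analysis consumes — a reference
gene model embedded in a chromosome with flanking neighbour genes, target
genomes evolved down a rooted species tree, per-species annotation
tables, and simulated read sets — together with a *truth table* of the
mutation calls each leaf is expected to yield.

Descent with modification is explicit: a mutation planted on a branch is
inherited by every descendant leaf, which is what makes shared-mutation
grouping and Dollo branch placement testable. All edit coordinates are
expressed in root (reference) coordinates; per-branch random
substitutions are applied first and length-changing edits afterwards,
sorted right-to-left, so planted coordinates stay interpretable.

Four ready-made scenarios (:func:`melatonin_scenario`) reproduce the
published mutation maps of the melatonin synthesis (*Aanat*, *Asmt*) and
signalling (*Mtnr1a*, *Mtnr1b*) genes across 12 cetaceans with the
hippopotamus and the Florida manatee as successive outgroups: shared
exon-1 stops and 1-nt indels at the cetacean root, sperm-whale in-frame
and frameshifting deletions, whole-locus loss of *Mtnr1a* in the
delphinoid toothed whales, exon erosions, non-canonical splice sites and
assembly-gap blind spots.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gene_models import GeneModel, Genome, extract_cds, intron_interval
from .mutations import MutationCall, left_normalize
from .read_validation import ReadSet
from .synteny import AnnotationTable
from .trees import SpeciesTree, parse_newick

__all__ = [
    "MutationSpec",
    "ScenarioConfig",
    "ScenarioResult",
    "generate_reference_gene",
    "evolve_on_tree",
    "melatonin_scenario",
    "simulate_reads",
    "CETACEAN_TREE",
    "MELATONIN_GENES",
]

SENSE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - {"TAA", "TAG", "TGA"}
)

#: 12 cetaceans (8 toothed, 4 baleen) with hippo and manatee outgroups.
CETACEAN_TREE = (
    "(((((((Oorc,(Ttru,(Lobl,Schi)))Delphinidae,Dleu),(Lvex,Nasi))Delphinoidea,"
    "Pcat)Odontoceti,((Bacu,Bbon),(Erob,Bmys))Mysticeti)Cetacea,Hamp)"
    "Whippomorpha,Tman)Root;"
)

ODONTOCETI = ("Oorc", "Ttru", "Lobl", "Schi", "Dleu", "Lvex", "Nasi", "Pcat")
MYSTICETI = ("Bacu", "Bbon", "Erob", "Bmys")
CETACEANS = ODONTOCETI + MYSTICETI
ALL_SPECIES = CETACEANS + ("Hamp", "Tman")

MELATONIN_GENES = ("Aanat", "Asmt", "Mtnr1a", "Mtnr1b")

#: comparison-relevant call types (exon_missing_gap marks absent data,
#: not an event, and is excluded from truth/recovery comparisons)
EVENT_TYPES = frozenset(
    {
        "premature_stop",
        "frameshift_deletion",
        "frameshift_insertion",
        "inframe_deletion",
        "inframe_insertion",
        "start_loss",
        "splice_donor_noncanonical",
        "splice_acceptor_noncanonical",
        "exon_deletion",
    }
)


@dataclass(frozen=True)
class MutationSpec:
    """A mutation planted on one tree branch, in root coordinates.

    ``branch`` names a leaf or internal node; the event is applied on the
    branch above it and inherited by all its descendants. ``type`` covers
    the caller's taxonomy plus two generator-only kinds: ``exon_gap``
    (mask an exon with N, an assembly blind spot) and ``locus_deletion``
    (remove the whole gene between its neighbours, optionally leaving an
    N-run of ``fill_n`` bases).
    """

    branch: str
    gene: str
    type: str
    exon_index: int = -1
    cds_pos: int = -1
    length: int = 0
    alt_allele: str = ""
    intron_index: int = -1
    fill_n: int = 0
    pad: int = 30

    def __post_init__(self) -> None:
        if self.type in ("frameshift_deletion", "frameshift_insertion"):
            if self.length % 3 == 0:
                raise ValueError("frameshift indel length must not be multiple of 3")
        if self.type in ("inframe_deletion", "inframe_insertion"):
            if self.length % 3 != 0:
                raise ValueError("in-frame indel length must be a multiple of 3")
        if "insertion" in self.type and len(self.alt_allele) != self.length:
            raise ValueError("insertion requires alt_allele of given length")


@dataclass
class ScenarioConfig:
    """Everything needed to evolve one gene scenario deterministically."""

    seed: int
    tree_newick: str = CETACEAN_TREE
    substitution_rate: float = 0.0  # substitutions/site per branch
    gene: str = "gene"
    exon_lengths: tuple[int, ...] = (99, 120, 84)
    intron_lengths: tuple[int, ...] = (300, 350)
    specs: tuple[MutationSpec, ...] = ()
    upstream_symbols: tuple[str, ...] = ("GU5", "GU4", "GU3", "GU2", "GU1")
    downstream_symbols: tuple[str, ...] = ("GD1", "GD2", "GD3", "GD4", "GD5")
    samples_per_species: dict[str, int] = field(default_factory=dict)
    default_samples: int = 2
    depth: float = 20.0
    read_length: int = 100
    error_rate: float = 0.005


def _rng(seed: int, *names: str | int) -> np.random.Generator:
    """Named deterministic substream of the scenario seed."""
    tags = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tags]))


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_reference_gene(
    n_exons: int,
    exon_lengths: list[int] | tuple[int, ...],
    intron_lengths: list[int] | tuple[int, ...],
    seed: int,
    gene_id: str = "gene",
    chrom: str = "chr1",
    upstream_symbols: tuple[str, ...] = ("GU5", "GU4", "GU3", "GU2", "GU1"),
    downstream_symbols: tuple[str, ...] = ("GD1", "GD2", "GD3", "GD4", "GD5"),
) -> tuple[GeneModel, Genome, AnnotationTable]:
    """Build a reference chromosome holding one multi-exon gene.

    The CDS is random sense codons (ATG first, TAA last, no internal
    stop); introns begin GT and end AG. Flanking single-exon
    protein-coding neighbour genes (plus one non-coding RNA gene next to
    the direct upstream neighbour) are laid out for synteny analysis.
    """
    if len(exon_lengths) != n_exons or len(intron_lengths) != n_exons - 1:
        raise ValueError("need n_exons exon lengths and n_exons-1 intron lengths")
    if sum(exon_lengths) % 3 != 0:
        raise ValueError("total CDS length must be a multiple of 3")
    if any(l < 3 for l in exon_lengths) or any(l < 20 for l in intron_lengths):
        raise ValueError("exon lengths must be >= 3, intron lengths >= 20")
    rng = _rng(seed, "reference", gene_id)
    cds = _random_orf(sum(exon_lengths) // 3, rng)
    parts: list[str] = []
    rows: list[dict] = []
    pos = 0

    def add_gene(symbol: str, biotype: str, length: int) -> None:
        nonlocal pos
        spacer = _random_seq(int(rng.integers(150, 300)), rng)
        parts.append(spacer)
        pos += len(spacer)
        seq = (
            _random_orf(length // 3, rng)
            if biotype == "protein_coding"
            else _random_seq(length, rng)
        )
        rows.append(
            {
                "gene_symbol": symbol,
                "chrom": chrom,
                "start": pos,
                "end": pos + len(seq),
                "strand": "+",
                "biotype": biotype,
            }
        )
        parts.append(seq)
        pos += len(seq)

    for sym in upstream_symbols:
        add_gene(sym, "protein_coding", 300)
    add_gene(f"RNU-{gene_id}", "lncRNA", 120)  # non-coding: skipped by synteny

    spacer = _random_seq(int(rng.integers(150, 300)), rng)
    parts.append(spacer)
    pos += len(spacer)
    exons: list[tuple[int, int]] = []
    cds_off = 0
    for i, exon_len in enumerate(exon_lengths):
        exons.append((pos, pos + exon_len))
        parts.append(cds[cds_off : cds_off + exon_len])
        cds_off += exon_len
        pos += exon_len
        if i < n_exons - 1:
            ilen = intron_lengths[i]
            intron = "GT" + _random_seq(ilen - 4, rng) + "AG"
            parts.append(intron)
            pos += ilen
    rows.append(
        {
            "gene_symbol": gene_id,
            "chrom": chrom,
            "start": exons[0][0],
            "end": exons[-1][1],
            "strand": "+",
            "biotype": "protein_coding",
        }
    )
    for sym in downstream_symbols:
        add_gene(sym, "protein_coding", 300)
    parts.append(_random_seq(200, rng))

    genome = Genome(sequences={chrom: "".join(parts)}, source="synthetic")
    phases = []
    phase = 0
    for s, e in exons:
        phases.append(phase)
        phase = (phase + (e - s)) % 3
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=tuple(exons),
        cds_phases=tuple(phases),
    )
    table = AnnotationTable(species_id="reference", table=pd.DataFrame(rows))
    return model, genome, table


# ---------------------------------------------------------------------------
# evolution on the tree


def _cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    e = model.exon_of_cds_pos(cds_pos)
    return model.exons[e][0] + (cds_pos - model.exon_cds_offset(e))


def _spec_edits(
    spec: MutationSpec, model: GeneModel
) -> tuple[list[tuple[int, int, str]], list[tuple[int, int, str]], list[tuple[int, int, int]]]:
    """(substitution edits, structural edits, mask edits) in root coords.

    Mask edits carry (start, end, pad); they are applied last, through
    the coordinate shifts of the structural edits.
    """
    subs: list[tuple[int, int, str]] = []
    structural: list[tuple[int, int, str]] = []
    masks: list[tuple[int, int, int]] = []
    t = spec.type
    if t in ("premature_stop", "start_loss"):
        g = _cds_to_genomic(model, spec.cds_pos)
        alt = spec.alt_allele
        if len(alt) != 3:
            raise ValueError(f"{t} spec needs a 3-nt alt codon")
        subs.append((g, g + 3, alt))
    elif t == "splice_donor_noncanonical":
        s, _ = intron_interval(model, spec.intron_index)
        subs.append((s, s + 2, spec.alt_allele))
    elif t == "splice_acceptor_noncanonical":
        _, e = intron_interval(model, spec.intron_index)
        subs.append((e - 2, e, spec.alt_allele))
    elif t in ("frameshift_deletion", "inframe_deletion"):
        g = _cds_to_genomic(model, spec.cds_pos)
        structural.append((g, g + spec.length, ""))
    elif t in ("frameshift_insertion", "inframe_insertion"):
        g = _cds_to_genomic(model, spec.cds_pos)
        structural.append((g, g, spec.alt_allele))
    elif t == "exon_deletion":
        s, e = model.exons[spec.exon_index]
        structural.append((s, e, ""))
    elif t == "exon_gap":
        s, e = model.exons[spec.exon_index]
        masks.append((s, e, spec.pad))
    elif t == "locus_deletion":
        s = model.exons[0][0] - 100
        e = model.exons[-1][1] + 100
        structural.append((s, e, "N" * spec.fill_n))
    else:
        raise ValueError(f"unknown spec type {t!r}")
    return subs, structural, masks


def _shift_confusable(ref_codon: str, alt: str) -> bool:
    """True when alt reads as a 1-base shift of the reference codon."""
    return alt[0:2] == ref_codon[1:3] or alt[1:3] == ref_codon[0:2]


def _safe_stop_alt(ref_cds: str, cds_pos: int, desired: str) -> str:
    ref_codon = ref_cds[cds_pos : cds_pos + 3]
    for alt in (desired, "TGA", "TAA", "TAG"):
        if alt in ("TGA", "TAA", "TAG") and not _shift_confusable(ref_codon, alt):
            return alt
    return desired


def _lineage_nodes(tree: SpeciesTree, leaf_label: str) -> list[str]:
    """Branch names from root to leaf (internal labels + leaf label)."""
    node = tree.tree.find_node_with_taxon_label(leaf_label)
    names = []
    while node is not None:
        if node.taxon is not None:
            names.append(node.taxon.label)
        elif node.label:
            names.append(node.label)
        node = node.parent_node
    return names[::-1]


class ConflictingSpecsError(ValueError):
    pass


@dataclass
class ScenarioResult:
    """Evolved scenario: genomes, truth, annotations, tree."""

    config: ScenarioConfig
    model: GeneModel
    ref_genome: Genome
    ref_annotation: AnnotationTable
    tree: SpeciesTree
    genomes: dict[str, Genome]
    truth: dict[str, list[MutationCall]]
    indeterminate: dict[str, set[tuple[str, int]]]
    annotations: dict[str, AnnotationTable]
    locus_state: dict[str, str]
    edit_maps: dict[str, list[tuple[int, int, int]]]

    @property
    def chrom(self) -> str:
        return self.model.chrom

    def map_position(self, species: str, root_pos: int) -> int:
        return _map_pos(self.edit_maps[species], root_pos)

    def gene_region(self, species: str, margin: int = 300) -> tuple[int, int]:
        """Leaf-coordinate interval around the gene locus."""
        lo = self.map_position(species, self.model.exons[0][0] - margin)
        hi = self.map_position(species, self.model.exons[-1][1] + margin)
        n = len(self.genomes[species].sequences[self.chrom])
        return max(0, lo), min(n, hi)

    def readsets(self, species: str) -> list[ReadSet]:
        cfg = self.config
        n_samples = cfg.samples_per_species.get(species, cfg.default_samples)
        if n_samples <= 0:
            return []
        lo, hi = self.gene_region(species)
        region = self.genomes[species].sequences[self.chrom][lo:hi]
        return simulate_reads(
            region,
            n_samples=n_samples,
            depth=cfg.depth,
            read_length=cfg.read_length,
            error_rate=cfg.error_rate,
            seed=cfg.seed,
            tag=f"{cfg.gene}:{species}",
        )


def _map_pos(edits: list[tuple[int, int, int]], pos: int) -> int:
    """Map a root coordinate through (start, end, new_len) edits."""
    shift = 0
    for start, end, new_len in edits:
        if end <= pos:
            shift += new_len - (end - start)
        elif start < pos:
            return start + shift + min(pos - start, new_len)
    return pos + shift


def evolve_on_tree(
    model: GeneModel,
    ref_genome: Genome,
    ref_annotation: AnnotationTable,
    config: ScenarioConfig,
) -> ScenarioResult:
    """Copy the root sequence down the tree, applying substitutions and
    planted mutations per branch; emit leaf genomes plus the truth table.

    Random substitutions (Poisson(rate x chromosome length) per branch)
    avoid the footprints of planted events so that the truth table stays
    exact; everything else in the chromosome is fair game.
    """
    tree = parse_newick(config.tree_newick)
    chrom = model.chrom
    root_seq = ref_genome.sequences[chrom]
    ref_cds = extract_cds(model, ref_genome)

    # a planted stop that is a 1-base rotation of the reference codon
    # (e.g. ATG -> TGA) aligns optimally as an indel pair, not as three
    # substitutions; swap in a stop codon that cannot be shift-represented
    config = replace(
        config,
        specs=tuple(
            replace(s, alt_allele=_safe_stop_alt(ref_cds, s.cds_pos, s.alt_allele))
            if s.type == "premature_stop"
            else s
            for s in config.specs
        ),
    )

    # pre-compute each spec's edits and validate branches exist
    known_branches: set[str] = set()
    for node in tree.tree.preorder_node_iter():
        if node.taxon is not None:
            known_branches.add(node.taxon.label)
        elif node.label:
            known_branches.add(node.label)
    spec_edits = {}
    protected: set[int] = set()
    for spec in config.specs:
        if spec.branch not in known_branches:
            raise ValueError(f"spec references unknown branch {spec.branch!r}")
        spec_edits[spec] = _spec_edits(spec, model)
        subs_g, structural_g, _masks_g = spec_edits[spec]
        for s, e, _ in subs_g:
            protected.update(range(s, e))
        # guard band around structural events: a substitution right next
        # to an indel changes its optimal alignment representation and
        # would make the planted truth ambiguous
        for s, e, _ in structural_g:
            protected.update(range(s - 10, e + 10))

    # per-branch random substitutions, shared by all descendants
    branch_subs: dict[str, dict[int, str]] = {}
    for name in sorted(known_branches):
        rng = _rng(config.seed, "branch", name)
        n = rng.poisson(config.substitution_rate * len(root_seq))
        subs: dict[int, str] = {}
        for _ in range(int(n)):
            p = int(rng.integers(0, len(root_seq)))
            if p in protected:
                continue
            old = root_seq[p]
            choices = [b for b in "ACGT" if b != old]
            subs[p] = choices[int(rng.integers(0, 3))]
        branch_subs[name] = subs

    genomes: dict[str, Genome] = {}
    truth: dict[str, list[MutationCall]] = {}
    indeterminate: dict[str, set[tuple[str, int]]] = {}
    annotations: dict[str, AnnotationTable] = {}
    locus_state: dict[str, str] = {}
    edit_maps: dict[str, list[tuple[int, int, int]]] = {}

    for leaf in tree.leaf_labels:
        lineage = _lineage_nodes(tree, leaf)
        lineage_set = set(lineage)
        specs = [s for s in config.specs if s.branch in lineage_set]
        # order: root-to-leaf, then config order within a branch
        specs.sort(key=lambda s: (lineage.index(s.branch), config.specs.index(s)))

        seq = list(root_seq)
        for name in lineage:
            for p, base in branch_subs[name].items():
                seq[p] = base
        for spec in specs:
            for s, e, repl in spec_edits[spec][0]:
                seq[s:e] = list(repl)

        structural: list[tuple[int, int, str]] = []
        masks: list[tuple[int, int, int]] = []
        for spec in specs:
            structural.extend(spec_edits[spec][1])
            masks.extend(spec_edits[spec][2])
        structural.sort(key=lambda t: (t[0], -t[1]))
        # an edit nested inside a larger removal (e.g. an inherited indel
        # swallowed by a later exon/locus deletion) is superseded by it
        kept: list[tuple[int, int, str]] = []
        for s, e, repl in structural:
            if kept and s >= kept[-1][0] and e <= kept[-1][1]:
                continue
            kept.append((s, e, repl))
        structural = kept
        for (s1, e1, _), (s2, e2, _) in zip(structural, structural[1:]):
            if e1 > s2:
                raise ConflictingSpecsError(
                    f"conflicting specs on lineage of {leaf}: "
                    f"[{s1},{e1}) overlaps [{s2},{e2})"
                )
        for s, e, repl in sorted(structural, reverse=True):
            seq[s:e] = list(repl)
        edits = [(s, e, len(repl)) for s, e, repl in structural]
        for s, e, pad in masks:
            ms = max(0, _map_pos(edits, s - pad))
            me = min(len(seq), _map_pos(edits, e + pad))
            seq[ms:me] = ["N"] * (me - ms)
        genomes[leaf] = Genome(sequences={chrom: "".join(seq)}, source="synthetic")
        edit_maps[leaf] = edits

        truth[leaf], indeterminate[leaf], locus_state[leaf] = _leaf_truth(
            leaf, specs, model, ref_cds
        )
        annotations[leaf] = _shift_annotation(leaf, ref_annotation, edits)

    return ScenarioResult(
        config=config,
        model=model,
        ref_genome=ref_genome,
        ref_annotation=ref_annotation,
        tree=tree,
        genomes=genomes,
        truth=truth,
        indeterminate=indeterminate,
        annotations=annotations,
        locus_state=locus_state,
        edit_maps=edit_maps,
    )


def _leaf_truth(
    leaf: str,
    specs: list[MutationSpec],
    model: GeneModel,
    ref_cds: str,
) -> tuple[list[MutationCall], set[tuple[str, int]], str]:
    """Expected calls for one leaf, with shadowing by gaps and deletions."""
    gene = model.gene_id
    locus = "present"
    masked: set[int] = set()
    deleted: set[int] = set()
    for s in specs:
        if s.type == "locus_deletion":
            locus = "absent_gapped" if s.fill_n else "absent_complete"
        elif s.type == "exon_gap":
            masked.add(s.exon_index)
        elif s.type == "exon_deletion":
            deleted.add(s.exon_index)
    indet = {(gene, e) for e in masked} if locus == "present" else set()
    if locus != "present":
        return [], indet, locus

    def visible(exon: int) -> bool:
        return exon not in masked and exon not in deleted

    calls: list[MutationCall] = []
    indels: list[tuple[int, int, MutationSpec]] = []  # (cds_pos, signed delta)
    for s in specs:
        if s.type in (
            "frameshift_deletion",
            "inframe_deletion",
            "frameshift_insertion",
            "inframe_insertion",
        ):
            if not visible(s.exon_index):
                continue
            delta = s.length if "insertion" in s.type else -s.length
            indels.append((s.cds_pos, delta, s))
    indels.sort(key=lambda t: t[0])
    shift = 0
    for cds_pos, delta, s in indels:
        if "deletion" in s.type:
            pos, deleted_seq, _ = left_normalize(
                ref_cds, cds_pos, ref_cds[cds_pos : cds_pos + s.length], ""
            )
            ref_a, alt_a = deleted_seq, "-" * s.length
        else:
            pos, _, ins = left_normalize(ref_cds, cds_pos, "", s.alt_allele)
            ref_a, alt_a = "-" * s.length, ins
        if s.length % 3 == 0:
            fc = "none"
        else:
            shift = (shift + delta) % 3
            fc = "restored" if shift == 0 else f"shift+{shift}"
        calls.append(
            MutationCall(
                type=s.type,
                exon_index=s.exon_index,
                cds_pos=pos,
                length=s.length,
                ref_allele=ref_a,
                alt_allele=alt_a,
                frame_consequence=fc,
                species_id=leaf,
                gene_id=gene,
            )
        )

    def shift_at(cds_pos: int) -> int:
        return sum(
            d for p, d, s in indels if s.length % 3 != 0 and p <= cds_pos
        ) % 3

    for s in specs:
        if s.type == "premature_stop":
            if not visible(s.exon_index) or shift_at(s.cds_pos) != 0:
                continue
            calls.append(
                MutationCall(
                    type="premature_stop",
                    exon_index=s.exon_index,
                    cds_pos=s.cds_pos,
                    length=3,
                    ref_allele=ref_cds[s.cds_pos : s.cds_pos + 3],
                    alt_allele=s.alt_allele,
                    species_id=leaf,
                    gene_id=gene,
                )
            )
        elif s.type == "start_loss":
            if not visible(s.exon_index):
                continue
            calls.append(
                MutationCall(
                    type="start_loss",
                    exon_index=s.exon_index,
                    cds_pos=s.cds_pos,
                    length=3,
                    ref_allele="ATG",
                    alt_allele=s.alt_allele,
                    species_id=leaf,
                    gene_id=gene,
                )
            )
        elif s.type in ("splice_donor_noncanonical", "splice_acceptor_noncanonical"):
            i = s.intron_index
            if not (visible(i) and visible(i + 1)):
                continue
            donor = s.type == "splice_donor_noncanonical"
            calls.append(
                MutationCall(
                    type=s.type,
                    exon_index=i if donor else i + 1,
                    cds_pos=model.exon_cds_offset(i + 1),
                    length=2,
                    ref_allele="GT" if donor else "AG",
                    alt_allele=s.alt_allele,
                    species_id=leaf,
                    gene_id=gene,
                )
            )
        elif s.type == "exon_deletion":
            idx = s.exon_index
            left_ok = idx > 0 and visible(idx - 1)
            right_ok = idx < model.n_exons - 1 and visible(idx + 1)
            if left_ok and right_ok:
                calls.append(
                    MutationCall(
                        type="exon_deletion",
                        exon_index=idx,
                        cds_pos=model.exon_cds_offset(idx),
                        length=model.exon_lengths[idx],
                        ref_allele="",
                        alt_allele="",
                        species_id=leaf,
                        gene_id=gene,
                    )
                )
            # terminal or gap-flanked: reported as exon_missing_gap, which
            # is an absence-of-data marker, not a truth event
    calls.sort(key=lambda c: (c.cds_pos, c.type))
    return calls, indet, locus


def _shift_annotation(
    leaf: str, ref_annotation: AnnotationTable, edits: list[tuple[int, int, int]]
) -> AnnotationTable:
    rows = []
    for _, row in ref_annotation.table.iterrows():
        start = _map_pos(edits, int(row.start))
        end = _map_pos(edits, int(row.end))
        if end - start < 20:  # gene effectively removed
            continue
        new = dict(row)
        new["start"], new["end"] = start, end
        rows.append(new)
    return AnnotationTable(species_id=leaf, table=pd.DataFrame(rows))


def simulate_reads(
    haplotype: str,
    n_samples: int = 2,
    depth: float = 20.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
    tag: str = "",
) -> list[ReadSet]:
    """Uniform shotgun reads with substitution errors, both orientations.

    Each sample (a stand-in for one sequencing project or individual)
    gets its own seeded substream, so samples differ but reruns are
    bit-identical.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_length > len(haplotype):
        raise ValueError("read length exceeds haplotype length")
    comp = str.maketrans("ACGTN", "TGCAN")
    readsets = []
    for s in range(n_samples):
        rng = _rng(seed, "reads", tag, s)
        n_reads = int(round(depth * len(haplotype) / read_length))
        reads = []
        for r in range(n_reads):
            start = int(rng.integers(0, len(haplotype) - read_length + 1))
            read = list(haplotype[start : start + read_length])
            n_err = rng.binomial(read_length, error_rate)
            for p in rng.integers(0, read_length, size=int(n_err)):
                old = read[p]
                choices = [b for b in "ACGT" if b != old]
                read[p] = choices[int(rng.integers(0, 3))]
            seq = "".join(read)
            if rng.random() < 0.5:
                seq = seq.translate(comp)[::-1]
            reads.append((f"{tag}.s{s}.r{r}", seq))
        readsets.append(ReadSet(sample_id=f"{tag}.sample{s + 1}", reads=reads))
    return readsets


# ---------------------------------------------------------------------------
# scenario directories: flat-file round trip


def write_scenario(scenario: ScenarioResult, out_dir) -> None:
    """Write a scenario as standard flat files (FASTA/GFF3/FASTQ/newick/TSV)."""
    from pathlib import Path

    from .gene_models import write_gff3

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chrom = scenario.chrom
    with open(out / "reference.fasta", "w") as fh:
        fh.write(f">{chrom}\n{scenario.ref_genome.sequences[chrom]}\n")
    write_gff3(out / "reference.gff3", [scenario.model])
    scenario.ref_annotation.table.to_csv(
        out / "reference.genes.tsv", sep="\t", index=False
    )
    with open(out / "tree.nwk", "w") as fh:
        fh.write(scenario.config.tree_newick + "\n")
    for species, genome in scenario.genomes.items():
        with open(out / f"{species}.fasta", "w") as fh:
            fh.write(f">{chrom}\n{genome.sequences[chrom]}\n")
        scenario.annotations[species].table.to_csv(
            out / f"{species}.genes.tsv", sep="\t", index=False
        )
        for rs in scenario.readsets(species):
            name = rs.sample_id.split(".")[-1]
            with open(out / f"{species}.{name}.fastq", "w") as fh:
                for rid, seq in rs.reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    truth_rows = [
        {
            "species": species,
            "gene": c.gene_id,
            "type": c.type,
            "exon": c.exon_index + 1,
            "cds_pos": c.cds_pos + 1,
            "length": c.length,
            "alt": c.alt_allele or ".",
        }
        for species, calls in scenario.truth.items()
        for c in calls
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth_mutations.tsv", sep="\t", index=False)


@dataclass
class DirectoryScenario:
    """Pipeline inputs reloaded from a scenario directory.

    Presents the same surface :func:`~orfdecay.status.run_pipeline`
    expects from a freshly evolved :class:`ScenarioResult`, so the
    pipeline runs identically on flat files.
    """

    model: GeneModel
    ref_genome: Genome
    ref_annotation: "AnnotationTable"
    tree: SpeciesTree
    genomes: dict[str, Genome]
    annotations: dict[str, "AnnotationTable"]
    directory: "object" = None

    @property
    def chrom(self) -> str:
        return self.model.chrom

    def readsets(self, species: str) -> list[ReadSet]:
        from pathlib import Path

        from .read_validation import load_reads

        if self.directory is None:
            return []
        files = sorted(Path(self.directory).glob(f"{species}.sample*.fastq"))
        return [load_reads(p) for p in files]


def load_scenario_dir(path, gene: str) -> DirectoryScenario:
    """Reload a scenario directory written by :func:`write_scenario`."""
    from pathlib import Path

    from .gene_models import load_gene_model, load_genome
    from .synteny import load_annotation_table

    path = Path(path)
    model, ref_genome = load_gene_model(
        path / "reference.gff3", path / "reference.fasta", gene
    )
    ref_annotation = load_annotation_table(
        path / "reference.genes.tsv", species_id="reference"
    )
    tree = parse_newick((path / "tree.nwk").read_text().strip())
    genomes = {}
    annotations = {}
    for sp in tree.leaf_labels:
        genomes[sp] = load_genome(path / f"{sp}.fasta")
        annotations[sp] = load_annotation_table(
            path / f"{sp}.genes.tsv", species_id=sp
        )
    return DirectoryScenario(
        model=model,
        ref_genome=ref_genome,
        ref_annotation=ref_annotation,
        tree=tree,
        genomes=genomes,
        annotations=annotations,
        directory=path,
    )


# ---------------------------------------------------------------------------
# the four melatonin-gene replication scenarios


def _aanat_specs() -> tuple[MutationSpec, ...]:
    g = "Aanat"
    return (
        # shared exon-1 premature stop at the cetacean root (codon 15)
        MutationSpec("Cetacea", g, "premature_stop", exon_index=0, cds_pos=45,
                     length=3, alt_allele="TGA"),
        # toothed whales: start loss + exon-3 frameshift deletions
        MutationSpec("Odontoceti", g, "start_loss", exon_index=0, cds_pos=0,
                     length=3, alt_allele="GTG"),
        MutationSpec("Odontoceti", g, "frameshift_deletion", exon_index=2,
                     cds_pos=290, length=1),
        MutationSpec("Odontoceti", g, "frameshift_deletion", exon_index=2,
                     cds_pos=330, length=2),
        # baleen whales: disrupted intron 2 / exon 3 acceptor
        MutationSpec("Mysticeti", g, "splice_acceptor_noncanonical",
                     intron_index=1, alt_allele="AA"),
        # sperm whale: 12-nt (exon 2) and 6-nt (exon 3) in-frame deletions,
        # exon 1 hidden behind an assembly gap
        MutationSpec("Pcat", g, "inframe_deletion", exon_index=1, cds_pos=180,
                     length=12),
        MutationSpec("Pcat", g, "inframe_deletion", exon_index=2, cds_pos=300,
                     length=6),
        MutationSpec("Pcat", g, "exon_gap", exon_index=0),
        # manatee: convergent start loss + exon-3/intron-3 donor mutation
        MutationSpec("Tman", g, "start_loss", exon_index=0, cds_pos=0,
                     length=3, alt_allele="ATA"),
        MutationSpec("Tman", g, "splice_donor_noncanonical", intron_index=2,
                     alt_allele="GA"),
    )


def _asmt_specs() -> tuple[MutationSpec, ...]:
    g = "Asmt"
    specs = [
        # shared 1-nt insertion in exon 1 at the cetacean root
        MutationSpec("Cetacea", g, "frameshift_insertion", exon_index=0,
                     cds_pos=30, length=1, alt_allele="A"),
        # exon 9 not found in any cetacean assembly
        MutationSpec("Cetacea", g, "exon_deletion", exon_index=8),
        # toothed whales: non-canonical intron-7/exon-8 acceptor
        MutationSpec("Odontoceti", g, "splice_acceptor_noncanonical",
                     intron_index=6, alt_allele="GG"),
        # sperm whale: 1-nt insertion in exon 4
        MutationSpec("Pcat", g, "frameshift_insertion", exon_index=3,
                     cds_pos=340, length=1, alt_allele="T"),
        # Pacific white-sided dolphin: 1-nt deletion in exon 3
        MutationSpec("Lobl", g, "frameshift_deletion", exon_index=2,
                     cds_pos=230, length=1),
        # manatee: premature stop in exon 5
        MutationSpec("Tman", g, "premature_stop", exon_index=4, cds_pos=432,
                     length=3, alt_allele="TAA"),
    ]
    # complete erosion of exon 5 in five toothed whales
    for sp in ("Oorc", "Lobl", "Schi", "Nasi", "Dleu"):
        specs.append(MutationSpec(sp, g, "exon_deletion", exon_index=4))
    # exon 5 behind assembly gaps elsewhere in Cetacea (except Pcat, Erob)
    for sp in ("Ttru", "Lvex", "Bacu", "Bbon", "Bmys"):
        specs.append(MutationSpec(sp, g, "exon_gap", exon_index=4))
    # exon 1 not retrievable in four species
    for sp in ("Lobl", "Schi", "Pcat", "Bmys"):
        specs.append(MutationSpec(sp, g, "exon_gap", exon_index=0))
    return tuple(specs)


def _mtnr1a_specs() -> tuple[MutationSpec, ...]:
    g = "Mtnr1a"
    specs = [
        # sperm whale: 19-nt frameshifting deletion in exon 1; exon 2 gapped
        MutationSpec("Pcat", g, "frameshift_deletion", exon_index=0,
                     cds_pos=100, length=19),
        MutationSpec("Pcat", g, "exon_gap", exon_index=1),
        # baleen whales: exon-1 relics with disruptive indels; exon 2 gapped
        MutationSpec("Mysticeti", g, "frameshift_deletion", exon_index=0,
                     cds_pos=60, length=4),
        MutationSpec("Mysticeti", g, "frameshift_insertion", exon_index=0,
                     cds_pos=200, length=2, alt_allele="CT"),
        MutationSpec("Mysticeti", g, "exon_gap", exon_index=1),
        # manatee: 1-nt deletion in exon 2
        MutationSpec("Tman", g, "frameshift_deletion", exon_index=1,
                     cds_pos=500, length=1),
    ]
    # delphinoid toothed whales: whole-locus loss between Fat1 and F11;
    # clean interval in three species, N-gapped interval in four
    for sp in ("Lobl", "Dleu", "Nasi"):
        specs.append(MutationSpec(sp, g, "locus_deletion", fill_n=0))
    for sp in ("Oorc", "Ttru", "Schi", "Lvex"):
        specs.append(MutationSpec(sp, g, "locus_deletion", fill_n=500))
    return tuple(specs)


def _mtnr1b_specs() -> tuple[MutationSpec, ...]:
    g = "Mtnr1b"
    specs = [
        # trans-species 1-nt deletion in exon 2 at the cetacean root
        MutationSpec("Cetacea", g, "frameshift_deletion", exon_index=1,
                     cds_pos=600, length=1),
        # grey whale: large in-frame 282-nt deletion in exon 2
        MutationSpec("Erob", g, "inframe_deletion", exon_index=1,
                     cds_pos=700, length=282),
        # manatee: exon-2 frameshifts and premature stop
        MutationSpec("Tman", g, "premature_stop", exon_index=1, cds_pos=561,
                     length=3, alt_allele="TAA"),
        MutationSpec("Tman", g, "frameshift_deletion", exon_index=1,
                     cds_pos=650, length=2),
        MutationSpec("Tman", g, "frameshift_insertion", exon_index=1,
                     cds_pos=900, length=1, alt_allele="G"),
    ]
    # exon-1 stop shared by orca and humpbacked dolphin
    for sp in ("Oorc", "Schi"):
        specs.append(MutationSpec(sp, g, "premature_stop", exon_index=0,
                                  cds_pos=150, length=3, alt_allele="TGA"))
    # exon-1 1-nt insertion in two baleen whales
    for sp in ("Bacu", "Erob"):
        specs.append(MutationSpec(sp, g, "frameshift_insertion", exon_index=0,
                                  cds_pos=250, length=1, alt_allele="T"))
    # start-codon loss in four toothed whales
    for sp in ("Oorc", "Ttru", "Lobl", "Schi"):
        specs.append(MutationSpec(sp, g, "start_loss", exon_index=0, cds_pos=0,
                                  length=3, alt_allele="GTG"))
    # exon 2 behind assembly gaps in orca and bottlenose dolphin
    for sp in ("Oorc", "Ttru"):
        specs.append(MutationSpec(sp, g, "exon_gap", exon_index=1))
    # Pacific white-sided dolphin: exon 2 cleanly absent
    specs.append(MutationSpec("Lobl", g, "exon_deletion", exon_index=1))
    return tuple(specs)


#: per-gene reference geometry: exon lengths, intron lengths, direct
#: neighbour symbols (the remaining flankers are generic)
_GENE_GEOMETRY: dict[str, dict] = {
    "Aanat": {
        "exons": (120, 150, 150, 84),
        "introns": (300, 350, 320),
        "up": ("AU5", "AU4", "AU3", "AU2", "UBE2O"),
        "down": ("RHBDF", "AD2", "AD3", "AD4", "AD5"),
        "specs": _aanat_specs,
    },
    "Asmt": {
        "exons": (105, 90, 96, 99, 120, 90, 84, 93, 60),
        "introns": (250, 300, 280, 260, 310, 270, 290, 240),
        "up": ("SU5", "SU4", "SU3", "SU2", "SU1"),
        "down": ("SD1", "SD2", "SD3", "SD4", "SD5"),
        "specs": _asmt_specs,
    },
    "Mtnr1a": {
        "exons": (423, 315),
        "introns": (800,),
        "up": ("MU5", "MU4", "MU3", "MU2", "FAT1"),
        "down": ("F11", "MD2", "MD3", "MD4", "MD5"),
        "specs": _mtnr1a_specs,
    },
    "Mtnr1b": {
        "exons": (525, 846),
        "introns": (700,),
        "up": ("NU5", "NU4", "NU3", "NU2", "NU1"),
        "down": ("SLC36A4", "ND2", "ND3", "ND4", "ND5"),
        "specs": _mtnr1b_specs,
    },
}

#: sequencing-project availability: two independent samples per species,
#: except the Yangtze river dolphin (a single genome project) and the
#: bowhead whale (no usable read sets)
SRA_SAMPLES = {"Lvex": 1, "Bmys": 0}


def melatonin_config(
    gene: str, seed: int = 1, substitution_rate: float = 0.0
) -> ScenarioConfig:
    """Scenario configuration replicating one melatonin gene's mutation map."""
    if gene not in _GENE_GEOMETRY:
        raise ValueError(f"unknown gene {gene!r}; choose from {MELATONIN_GENES}")
    geo = _GENE_GEOMETRY[gene]
    return ScenarioConfig(
        seed=seed,
        tree_newick=CETACEAN_TREE,
        substitution_rate=substitution_rate,
        gene=gene,
        exon_lengths=geo["exons"],
        intron_lengths=geo["introns"],
        specs=geo["specs"](),
        upstream_symbols=geo["up"],
        downstream_symbols=geo["down"],
        samples_per_species=dict(SRA_SAMPLES),
    )


def melatonin_scenario(
    gene: str, seed: int = 1, substitution_rate: float = 0.0
) -> ScenarioResult:
    """Generate and evolve the replication scenario for one gene."""
    config = melatonin_config(gene, seed=seed, substitution_rate=substitution_rate)
    model, genome, table = generate_reference_gene(
        n_exons=len(config.exon_lengths),
        exon_lengths=config.exon_lengths,
        intron_lengths=config.intron_lengths,
        seed=config.seed,
        gene_id=config.gene,
        chrom=f"{config.gene}_locus",
        upstream_symbols=config.upstream_symbols,
        downstream_symbols=config.downstream_symbols,
    )
    return evolve_on_tree(model, genome, table, config)
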