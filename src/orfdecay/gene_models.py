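"""Reference gene models and genomic sequences.

A :class:`GeneModel` is the exon/intron skeleton of one protein-coding
transcript: ordered coding exons (genomic intervals, 0-based half-open),
per-exon CDS phases and the CDS coordinates of the start and stop codons.
Minus-strand genes are normalized at load time so that every downstream
module sees exons in transcription order and plus-strand sequence — frame
arithmetic then has a single code path.

A :class:`Genome` is a plain in-memory map from sequence id to an
upper-case nucleotide string over {A, C, G, T, N}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "Genome",
    "load_genome",
    "load_gene_model",
    "extract_cds",
    "translate",
    "write_gff3",
]

_VALID_BASES = set("ACGTN")


class GeneModelError(ValueError):
    """Malformed or missing gene model."""


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene: ordered coding exons on a chromosome.

    ``exons`` are genomic intervals (0-based, half-open) listed in
    transcription order; on the minus strand this means descending genomic
    coordinates. ``cds_phases[i]`` is the reading-frame phase at the start
    of exon ``i`` (number of bases belonging to the codon begun in the
    previous exon).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_phases: tuple[int, ...]
    start_codon_cds_pos: int = 0
    stop_codon_cds_pos: int = -1  # -1: infer as cds_length - 3

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"bad strand {self.strand!r}")
        if len(self.exons) != len(self.cds_phases):
            raise GeneModelError("one phase per exon required")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise GeneModelError("exons overlap")
        # transcription order check
        order = self.exons if self.strand == "+" else self.exons[::-1]
        if list(order) != genomic:
            raise GeneModelError("exons not in transcription order")
        phase = 0
        for i, (start, end) in enumerate(self.exons):
            if end <= start:
                raise GeneModelError("empty exon interval")
            if self.cds_phases[i] != phase:
                raise GeneModelError(
                    f"exon {i} phase {self.cds_phases[i]} != expected {phase}"
                )
            phase = (phase + (end - start)) % 3

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def stop_cds_pos(self) -> int:
        if self.stop_codon_cds_pos >= 0:
            return self.stop_codon_cds_pos
        return self.cds_length - 3

    def exon_cds_offset(self, exon_index: int) -> int:
        """CDS coordinate of the first base of exon ``exon_index``."""
        return sum(self.exon_lengths[:exon_index])

    def exon_of_cds_pos(self, cds_pos: int) -> int:
        off = 0
        for i, ln in enumerate(self.exon_lengths):
            if off <= cds_pos < off + ln:
                return i
            off += ln
        raise IndexError(f"CDS position {cds_pos} outside gene")


@dataclass
class Genome:
    """In-memory nucleotide sequences, alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"sequence {name}: invalid characters {sorted(bad)}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"coordinate overflow: {chrom}:{start}-{end} (len {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def load_genome(fasta_path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`."""
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    return Genome(sequences=seqs, source=str(fasta_path))


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_gene_model(
    gff3_path: str | Path, fasta_path: str | Path, gene_id: str
) -> tuple[GeneModel, Genome]:
    """Load one gene's CDS structure from a GFF3 file plus its genome.

    CDS features are matched by ``ID`` or ``Parent`` attribute equal to
    ``gene_id`` (or ``gene_id.cds``-style children). Raises
    :class:`GeneModelError` if the gene is absent or the total CDS length
    is not a multiple of 3.
    """
    genome = load_genome(fasta_path)
    rows: list[tuple[str, int, int, str, int]] = []
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            attrs = _parse_gff3_attributes(cols[8])
            owner = attrs.get("Parent", attrs.get("ID", ""))
            if owner.split(".")[0] != gene_id and owner != gene_id:
                continue
            chrom, start, end = cols[0], int(cols[3]) - 1, int(cols[4])
            strand = cols[6]
            phase = int(cols[7]) if cols[7] in "012" else 0
            rows.append((chrom, start, end, strand, phase))
    if not rows:
        raise GeneModelError(f"gene not found: {gene_id!r} has no CDS features")
    chrom = rows[0][0]
    strand = rows[0][3]
    rows.sort(key=lambda r: r[1], reverse=(strand == "-"))
    exons = tuple((r[1], r[2]) for r in rows)
    if sum(e - s for s, e in exons) % 3 != 0:
        raise GeneModelError(
            f"malformed reference model: CDS length of {gene_id} not a multiple of 3"
        )
    phases = []
    phase = 0
    for s, e in exons:
        phases.append(phase)
        phase = (phase + (e - s)) % 3
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_phases=tuple(phases),
    )
    return model, genome


def extract_exon(model: GeneModel, genome: Genome, exon_index: int) -> str:
    """Exon sequence in transcription orientation (reverse-complemented on -)."""
    start, end = model.exons[exon_index]
    raw = genome.fetch(model.chrom, start, end)
    if model.strand == "-":
        return str(Seq(raw).reverse_complement())
    return raw


def extract_cds(model: GeneModel, genome: Genome) -> str:
    """Concatenated exon sequences in transcription order."""
    return "".join(extract_exon(model, genome, i) for i in range(model.n_exons))


def translate(cds: str) -> str:
    """Standard-code translation; internal stops as '*', N-codons as 'X'.

    A trailing partial codon is ignored with a warning.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    extra = len(cds) % 3
    if extra:
        warnings.warn(
            f"trailing partial codon of {extra} nt ignored", stacklevel=2
        )
        cds = cds[: len(cds) - extra]
    return str(Seq(cds).translate())


def intron_interval(model: GeneModel, intron_index: int) -> tuple[int, int]:
    """Genomic interval of the intron between exons i and i+1 (plus strand)."""
    if model.strand == "+":
        return model.exons[intron_index][1], model.exons[intron_index + 1][0]
    return model.exons[intron_index + 1][1], model.exons[intron_index][0]


def write_gff3(
    path: str | Path, models: Iterable[GeneModel], source: str = "orfdecay"
) -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            g_start = min(s for s, _ in model.exons)
            g_end = max(e for _, e in model.exons)
            fh.write(
                f"{model.chrom}\t{source}\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{model.strand}\t.\tID={model.gene_id}\n"
            )
            for i, (s, e) in enumerate(model.exons):
                fh.write(
                    f"{model.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{model.strand}\t{model.cds_phases[i]}\t"
                    f"ID={model.gene_id}.cds{i + 1};Parent={model.gene_id}\n"
                )


def serialize(model: GeneModel) -> dict:
    return {
        "gene_id": model.gene_id,
        "chrom": model.chrom,
        "strand": model.strand,
        "exons": [list(iv) for iv in model.exons],
        "cds_phases": list(model.cds_phases),
        "start_codon_cds_pos": model.start_codon_cds_pos,
        "stop_codon_cds_pos": model.stop_cds_pos,
    }


def deserialize(data: dict) -> GeneModel:
    return GeneModel(
        gene_id=data["gene_id"],
        chrom=data["chrom"],
        strand=data["strand"],
        exons=tuple(tuple(iv) for iv in data["exons"]),
        cds_phases=tuple(data["cds_phases"]),
        start_codon_cds_pos=data.get("start_codon_cds_pos", 0),
        stop_codon_cds_pos=data.get("stop_codon_cds_pos", -1),
    )
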