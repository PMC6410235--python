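"""Flanking-gene (synteny) analysis of target-locus presence.

When a gene cannot be found in an assembly, the question becomes whether
the *locus* is intact-but-empty (true loss), interrupted by assembly gaps
(unknowable), or holds a decayed remnant. The procedure: collect the
nearest protein-coding neighbours of the target gene in a reference
annotation, locate the two direct neighbours in the query annotation, and
scan the intervening query sequence for N-runs and for residual exon
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import (
    REMNANT_MIN_SEED_SUPPORT,
    GeneMapping,
    ScoringScheme,
    seed_clusters,
)
from .gene_models import GeneModel, Genome, extract_exon

__all__ = [
    "AnnotationTable",
    "SyntenyBlock",
    "load_annotation_table",
    "flanking_context",
    "compare_synteny",
    "scan_gaps",
]

_COLUMNS = ["gene_symbol", "chrom", "start", "end", "strand", "biotype"]


@dataclass
class AnnotationTable:
    """Gene-order annotation for one species (BED-like, 0-based)."""

    species_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.table = self.table.sort_values(["chrom", "start"]).reset_index(drop=True)

    def find(self, symbol: str) -> pd.Series | None:
        hit = self.table[self.table.gene_symbol.str.lower() == symbol.lower()]
        return None if hit.empty else hit.iloc[0]


def load_annotation_table(path: str | Path, species_id: str = "") -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    return AnnotationTable(species_id=species_id or Path(path).stem, table=df)


@dataclass
class SyntenyBlock:
    """Target gene plus up to n protein-coding flankers on each side."""

    species_id: str
    target_gene: str
    upstream: list[str] = field(default_factory=list)
    downstream: list[str] = field(default_factory=list)
    target_state: str | None = None  # present|absent_complete|absent_gapped|remnant
    interval_n_runs: list[tuple[int, int]] = field(default_factory=list)
    upstream_truncated: bool = False
    downstream_truncated: bool = False
    note: str = ""


class SyntenyError(ValueError):
    pass


def flanking_context(
    table: AnnotationTable, species: str, gene: str, n: int = 5
) -> SyntenyBlock:
    """The n nearest protein-coding genes on each side of ``gene``.

    Non-coding entries are skipped and do not count towards n. Lists are
    in genomic order; shorter-than-n lists are flagged truncated (contig
    edge).
    """
    row = table.find(gene)
    if row is None:
        raise SyntenyError(f"reference gene missing: {gene!r} not in table")
    chrom_genes = table.table[table.table.chrom == row.chrom].reset_index(drop=True)
    idx = chrom_genes.index[chrom_genes.gene_symbol == row.gene_symbol][0]
    coding = chrom_genes.biotype.str.lower() == "protein_coding"
    ups = chrom_genes[(chrom_genes.index < idx) & coding].tail(n)
    downs = chrom_genes[(chrom_genes.index > idx) & coding].head(n)
    return SyntenyBlock(
        species_id=species,
        target_gene=gene,
        upstream=list(ups.gene_symbol),
        downstream=list(downs.gene_symbol),
        upstream_truncated=len(ups) < n,
        downstream_truncated=len(downs) < n,
    )


def scan_gaps(seq: str, min_run: int = 10) -> list[tuple[int, int]]:
    """Maximal N-runs of length >= min_run, as sorted half-open intervals."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and len(seq) - start >= min_run:
        runs.append((start, len(seq)))
    return runs


def compare_synteny(
    ref_block: SyntenyBlock,
    query_table: AnnotationTable,
    query_genome: Genome,
    query_chrom: str,
    mapping: GeneMapping | None,
    model: GeneModel | None = None,
    ref_genome: Genome | None = None,
    scheme: ScoringScheme | None = None,
    min_gap_run: int = 10,
) -> SyntenyBlock:
    """Classify the target locus in a query species.

    If the gene mapping has any mapped exon the locus is *present* (or
    *remnant* when only sub-threshold hits exist). Otherwise the interval
    between the direct neighbours is scanned: any N-run of at least
    ``min_gap_run`` makes the call *absent_gapped* (missing sequence, no
    conclusion possible); an N-free interval with no residual exon seeds
    is *absent_complete*; residual seeds in an N-free interval are
    *remnant*.
    """
    block = SyntenyBlock(
        species_id=query_table.species_id,
        target_gene=ref_block.target_gene,
        upstream=list(ref_block.upstream),
        downstream=list(ref_block.downstream),
    )
    if mapping is not None and mapping.mapped_exons:
        block.target_state = "present"
        return block
    if not ref_block.upstream or not ref_block.downstream:
        raise SyntenyError("synteny indeterminate: reference block lacks neighbours")
    left = query_table.find(ref_block.upstream[-1])
    right = query_table.find(ref_block.downstream[0])
    if left is None or right is None:
        raise SyntenyError(
            "synteny indeterminate: direct neighbour missing in query "
            f"({ref_block.upstream[-1]!r}/{ref_block.downstream[0]!r})"
        )
    lo, hi = sorted([int(left.end), int(right.start)])
    interval = query_genome.fetch(query_chrom, lo, hi)
    block.interval_n_runs = [
        (lo + s, lo + e) for s, e in scan_gaps(interval, min_gap_run)
    ]
    # residual exon signal inside the interval? a single isolated k-mer
    # match is expected by chance; a remnant needs >= 2 clustered hits
    # or a sub-threshold alignment landing in the interval
    has_seed = False
    if mapping is not None:
        for a in mapping.exon_alignments:
            if (
                a.status == "low_identity"
                and a.seed_support >= REMNANT_MIN_SEED_SUPPORT
                and a.target_interval is not None
                and a.target_interval[0] < hi
                and a.target_interval[1] > lo
            ):
                has_seed = True
    if not has_seed and model is not None and ref_genome is not None:
        scheme = scheme or ScoringScheme()
        for idx in range(model.n_exons):
            exon_seq = extract_exon(model, ref_genome, idx)
            if len(exon_seq) < scheme.word_size:
                continue
            clusters = seed_clusters(exon_seq, interval, scheme)
            if clusters and clusters[0][0] >= REMNANT_MIN_SEED_SUPPORT:
                has_seed = True
                break
    if has_seed:
        block.target_state = "remnant"
        block.note = "residual exon seeds between neighbours"
    elif block.interval_n_runs:
        block.target_state = "absent_gapped"
    else:
        block.target_state = "absent_complete"
    return block


def synteny_rows(blocks: list[SyntenyBlock]) -> list[dict]:
    return [
        {
            "species": b.species_id,
            "gene": b.target_gene,
            "upstream": ",".join(b.upstream) or ".",
            "downstream": ",".join(b.downstream) or ".",
            "state": b.target_state or ".",
            "n_runs": ";".join(f"{s + 1}-{e}" for s, e in b.interval_n_runs) or ".",
            "note": b.note or ".",
        }
        for b in blocks
    ]


def render_synteny_map(blocks: list[SyntenyBlock]) -> str:
    """Simple fixed-width text rendering of per-species flanking maps."""
    lines = []
    for b in blocks:
        mark = {
            "present": f"[{b.target_gene}]",
            "remnant": f"[{b.target_gene}~relic]",
            "absent_gapped": "[...NNN...]",
            "absent_complete": "[--lost--]",
        }.get(b.target_state or "", "[?]")
        lines.append(
            f"{b.species_id:<12} "
            + " - ".join(b.upstream)
            + f" - {mark} - "
            + " - ".join(b.downstream)
        )
    return "\n".join(lines)
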