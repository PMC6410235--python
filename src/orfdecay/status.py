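"""Per-species gene verdicts and the end-to-end pipeline driver.

The verdict vocabulary:

* ``intact`` — every exon mapped, no ORF-relevant call of any kind;
* ``pseudogene`` — at least one hard disrupting call (premature stop,
  frameshift, non-canonical splice site, start loss, exon deletion);
* ``likely_pseudogene`` — only in-frame indels, but together they remove
  at least four codons or a flagged critical residue;
* ``lost`` — no exon mapped and the flanking-gene interval is complete
  and N-free (the locus itself is gone);
* ``inconclusive`` — anything the data cannot settle (assembly gaps,
  partial mappings without calls).

Read validation never changes a verdict — mutations found in an assembly
stand on their own — it only sets the ``validated`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import GeneMapping, ScoringScheme, map_gene, mapping_summary_rows
from .gene_models import GeneModel, Genome, extract_cds
from .mutations import HARD_DISRUPTING_TYPES, MutationCall, call_all
from .read_validation import (
    ReadSupport,
    ValidationParams,
    build_haplotype_pair,
    validate_mutation,
)
from .synteny import SyntenyBlock, compare_synteny, flanking_context, synteny_rows
from .trees import (
    SharedMutationGroup,
    assign_to_branch,
    group_summary_rows,
    match_mutations,
)

__all__ = ["GeneStatus", "classify_gene_status", "run_pipeline", "PipelineResult"]


@dataclass
class GeneStatus:
    species_id: str
    gene_id: str
    status: str
    evidence: list = field(default_factory=list)
    validated: bool = False

    def evidence_summary(self) -> str:
        parts = []
        for ev in self.evidence:
            if isinstance(ev, MutationCall):
                parts.append(f"{ev.type}:exon{ev.exon_index + 1}@{ev.cds_pos + 1}")
            elif isinstance(ev, SyntenyBlock):
                parts.append(f"synteny:{ev.target_state}")
        return ";".join(parts) or "."


def classify_gene_status(
    mapping: GeneMapping,
    calls: list[MutationCall],
    synteny: SyntenyBlock | None = None,
    support: list[ReadSupport] | None = None,
    damage_codons: int = 4,
) -> GeneStatus:
    """Aggregate one species x gene into a single verdict.

    Decision order: locus absence (via synteny) beats everything; then
    hard disrupting calls; then the in-frame damage rule; a clean,
    complete mapping is intact; everything else is inconclusive.
    """
    if synteny is not None and synteny.species_id and mapping.species_id:
        if synteny.species_id != mapping.species_id:
            raise ValueError(
                f"species mismatch: mapping {mapping.species_id!r} "
                f"vs synteny {synteny.species_id!r}"
            )
    species, gene = mapping.species_id, mapping.gene_id
    confirmed_keys = {
        s.mutation_key for s in (support or []) if s.verdict == "confirmed"
    }
    real_calls = [c for c in calls if not c.frameshift_context]
    validated = any(c.key in confirmed_keys for c in real_calls)

    if not mapping.mapped_exons:
        state = synteny.target_state if synteny else None
        if state == "absent_complete":
            return GeneStatus(species, gene, "lost", [synteny])
        return GeneStatus(
            species, gene, "inconclusive", [synteny] if synteny else []
        )
    hard = [c for c in real_calls if c.type in HARD_DISRUPTING_TYPES]
    if hard:
        return GeneStatus(species, gene, "pseudogene", hard, validated=validated)
    inframe = [c for c in real_calls if c.type.startswith("inframe_")]
    deleted_codons = sum(c.length // 3 for c in inframe if "deletion" in c.type)
    critical = any("active-site loss" in c.note for c in inframe)
    if inframe and (deleted_codons >= damage_codons or critical):
        return GeneStatus(
            species, gene, "likely_pseudogene", inframe, validated=validated
        )
    all_mapped = all(a.mapped for a in mapping.exon_alignments)
    if all_mapped and not real_calls:
        return GeneStatus(species, gene, "intact", [])
    return GeneStatus(species, gene, "inconclusive", real_calls, validated=validated)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus TSV-ready tables."""

    mappings: dict[str, GeneMapping]
    calls: dict[str, list[MutationCall]]
    synteny: dict[str, SyntenyBlock]
    supports: dict[str, list[ReadSupport]]
    groups: list[SharedMutationGroup]
    statuses: dict[str, GeneStatus]

    def status_matrix(self) -> pd.DataFrame:
        rows = [
            {
                "species": st.species_id,
                "gene": st.gene_id,
                "status": st.status,
                "validated": st.validated,
                "evidence": st.evidence_summary(),
            }
            for st in self.statuses.values()
        ]
        return pd.DataFrame(rows)

    def mutation_table(self) -> pd.DataFrame:
        rows = []
        for species, calls in sorted(self.calls.items()):
            verdicts = {
                s.mutation_key: s.verdict for s in self.supports.get(species, [])
            }
            for c in calls:
                rows.append(
                    {
                        "species": species,
                        "gene": c.gene_id,
                        "exon": c.exon_index + 1,
                        "type": c.type,
                        "cds_pos": c.cds_pos + 1,
                        "length": c.length,
                        "ref": c.ref_allele or ".",
                        "alt": c.alt_allele or ".",
                        "frame": c.frame_consequence,
                        "frameshift_context": c.frameshift_context,
                        "validation": verdicts.get(c.key, "not_tested"),
                        "note": c.note or ".",
                    }
                )
        return pd.DataFrame(rows)

    def group_table(self) -> pd.DataFrame:
        return pd.DataFrame(group_summary_rows(self.groups))


def run_pipeline(
    scenario,
    validate: bool = True,
    scheme: ScoringScheme | None = None,
    validation_params: ValidationParams | None = None,
    critical_codons: tuple[int, ...] = (),
) -> PipelineResult:
    """Map, call, synteny-check, validate, group and classify one scenario.

    ``scenario`` is a :class:`~orfdecay.simulate.ScenarioResult` (or any
    object with the same surface). Mutation validation aligns simulated
    read sets against reference/mutant haplotype windows for every
    non-gap call with a target coordinate.
    """
    scheme = scheme or ScoringScheme()
    model: GeneModel = scenario.model
    ref_genome: Genome = scenario.ref_genome
    chrom = scenario.chrom
    ref_block = flanking_context(
        scenario.ref_annotation, "reference", model.gene_id, n=5
    )

    mappings: dict[str, GeneMapping] = {}
    calls: dict[str, list[MutationCall]] = {}
    synteny: dict[str, SyntenyBlock] = {}
    supports: dict[str, list[ReadSupport]] = {}
    indeterminate: dict[str, set] = {}

    for species in scenario.tree.leaf_labels:
        genome = scenario.genomes[species]
        target_seq = genome.sequences[chrom]
        mapping = map_gene(
            model, ref_genome, genome, chrom, species_id=species, scheme=scheme
        )
        mappings[species] = mapping
        calls[species] = (
            call_all(mapping, model, ref_genome, target_seq, critical_codons)
            if mapping.mapped_exons
            else []
        )
        indeterminate[species] = {
            (model.gene_id, a.exon_index)
            for a in mapping.exon_alignments
            if a.status == "missing_in_gap"
        }
        synteny[species] = compare_synteny(
            ref_block,
            scenario.annotations[species],
            genome,
            chrom,
            mapping,
            model=model,
            ref_genome=ref_genome,
            scheme=scheme,
        )
        if validate:
            supports[species] = _validate_species(
                scenario, species, calls[species], target_seq, validation_params
            )
        else:
            supports[species] = []

    groupable = {
        sp: [
            c
            for c in cl
            if c.type not in ("exon_missing_gap",) and not c.frameshift_context
        ]
        for sp, cl in calls.items()
    }
    groups = match_mutations(groupable, indeterminate)
    for g in groups:
        assign_to_branch(g, scenario.tree)

    statuses = {
        sp: classify_gene_status(
            mappings[sp], calls[sp], synteny[sp], supports[sp]
        )
        for sp in mappings
    }
    return PipelineResult(
        mappings=mappings,
        calls=calls,
        synteny=synteny,
        supports=supports,
        groups=groups,
        statuses=statuses,
    )


def _validate_species(
    scenario,
    species: str,
    species_calls: list[MutationCall],
    target_seq: str,
    params: ValidationParams | None,
) -> list[ReadSupport]:
    readsets = scenario.readsets(species)
    supports = []
    for call in species_calls:
        if call.target_pos is None or call.type in (
            "exon_deletion",
            "exon_missing_gap",
        ):
            continue
        ref_hap, mut_hap, event = build_haplotype_pair(call, target_seq, flank=80)
        support = validate_mutation(
            call, (ref_hap, mut_hap), readsets, params, event_interval=event
        )
        supports.append(support)
    return supports


def write_reports(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the TSV/JSON report bundle; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("mutations.tsv", result.mutation_table()),
        ("shared_groups.tsv", result.group_table()),
        ("status_matrix.tsv", result.status_matrix()),
    ):
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = out / "status_matrix.json"
    result.status_matrix().to_json(p, orient="records", indent=2)
    paths["status_matrix.json"] = p
    rows = []
    for mapping in result.mappings.values():
        rows.extend(mapping_summary_rows(mapping))
    p = out / "exon_mappings.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["exon_mappings.tsv"] = p
    p = out / "synteny.tsv"
    pd.DataFrame(synteny_rows(list(result.synteny.values()))).to_csv(
        p, sep="\t", index=False
    )
    paths["synteny.tsv"] = p
    return paths
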