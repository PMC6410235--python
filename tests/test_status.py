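"""Gene-status classification and the pipeline driver."""

import pytest

from orfdecay.align import ExonAlignment, GeneMapping
from orfdecay.mutations import MutationCall
from orfdecay.read_validation import ReadSupport
from orfdecay.simulate import melatonin_scenario
from orfdecay.status import classify_gene_status, run_pipeline, write_reports
from orfdecay.synteny import SyntenyBlock


def _mapping(species="sp", gene="g", statuses=("mapped",)):
    alns = [
        ExonAlignment(
            exon_index=i,
            target_interval=(100 * i, 100 * i + 50) if s == "mapped" else None,
            aligned_columns=[],
            identity=1.0 if s == "mapped" else 0.0,
            score=100 if s == "mapped" else 0,
            status=s,
        )
        for i, s in enumerate(statuses)
    ]
    return GeneMapping(species_id=species, gene_id=gene, target_id="c",
                       exon_alignments=alns)


def _call(mtype, length=1, note="", key_pos=10):
    return MutationCall(
        type=mtype, exon_index=0, cds_pos=key_pos, length=length,
        ref_allele="A" * length, alt_allele="-" * length if "deletion" in mtype else "T",
        species_id="sp", gene_id="g", note=note,
    )


def _synteny(state):
    return SyntenyBlock(species_id="sp", target_gene="g", target_state=state)


def test_lost_requires_absent_complete():
    m = _mapping(statuses=("missing_no_gap", "missing_no_gap"))
    assert classify_gene_status(m, [], _synteny("absent_complete")).status == "lost"
    assert (
        classify_gene_status(m, [], _synteny("absent_gapped")).status
        == "inconclusive"
    )


def test_hard_call_means_pseudogene():
    m = _mapping()
    for mtype in (
        "premature_stop",
        "frameshift_deletion",
        "splice_donor_noncanonical",
        "start_loss",
        "exon_deletion",
    ):
        st = classify_gene_status(m, [_call(mtype)], _synteny("present"))
        assert st.status == "pseudogene", mtype


def test_inframe_damage_rule():
    m = _mapping()
    # 12-nt (4 codons) in-frame deletion alone: likely_pseudogene
    st = classify_gene_status(
        m, [_call("inframe_deletion", length=12)], _synteny("present")
    )
    assert st.status == "likely_pseudogene"
    # a 3-nt in-frame deletion alone is not enough
    st = classify_gene_status(
        m, [_call("inframe_deletion", length=3)], _synteny("present")
    )
    assert st.status == "inconclusive"
    # unless it removes a flagged critical residue
    st = classify_gene_status(
        m,
        [_call("inframe_deletion", length=3, note="active-site loss")],
        _synteny("present"),
    )
    assert st.status == "likely_pseudogene"


def test_clean_complete_mapping_is_intact():
    m = _mapping(statuses=("mapped", "mapped", "mapped"))
    assert classify_gene_status(m, [], _synteny("present")).status == "intact"


def test_gap_without_calls_is_inconclusive():
    m = _mapping(statuses=("mapped", "missing_in_gap"))
    st = classify_gene_status(m, [], _synteny("present"))
    assert st.status == "inconclusive"


def test_validated_flag_from_confirmed_support():
    m = _mapping()
    call = _call("premature_stop")
    sup = ReadSupport(mutation_key=call.key, verdict="confirmed")
    st = classify_gene_status(m, [call], _synteny("present"), [sup])
    assert st.status == "pseudogene" and st.validated
    sup2 = ReadSupport(mutation_key=call.key, verdict="unconfirmed")
    st2 = classify_gene_status(m, [call], _synteny("present"), [sup2])
    assert st2.status == "pseudogene" and not st2.validated


def test_species_mismatch_rejected():
    m = _mapping(species="a")
    s = _synteny("present")
    s.species_id = "b"
    with pytest.raises(ValueError, match="species mismatch"):
        classify_gene_status(m, [], s)


def test_classification_is_pure():
    m = _mapping()
    calls = [_call("premature_stop")]
    s = _synteny("present")
    assert (
        classify_gene_status(m, calls, s).status
        == classify_gene_status(m, calls, s).status
    )


@pytest.fixture(scope="module")
def aanat_result():
    sc = melatonin_scenario("Aanat", seed=1)
    return sc, run_pipeline(sc, validate=False)


def test_pipeline_covers_full_species_grid(aanat_result):
    sc, res = aanat_result
    matrix = res.status_matrix()
    assert set(matrix.species) == set(sc.tree.leaf_labels)
    assert matrix.status.notna().all()


def test_no_confirmed_hard_call_reported_intact(aanat_result):
    _sc, res = aanat_result
    for sp, st in res.statuses.items():
        hard = [
            c for c in res.calls[sp]
            if not c.frameshift_context and c.type in (
                "premature_stop", "frameshift_deletion", "frameshift_insertion",
                "start_loss", "exon_deletion",
            )
        ]
        if hard:
            assert st.status != "intact", sp


def test_outgroup_intact_cetaceans_disrupted(aanat_result):
    """Hippo keeps a clean ORF while every cetacean shows disruption."""
    sc, res = aanat_result
    assert res.statuses["Hamp"].status == "intact"
    for sp in sc.tree.leaf_labels:
        if sp not in ("Hamp",):
            assert res.statuses[sp].status != "intact", sp


def test_pipeline_reruns_byte_identical(tmp_path, aanat_result):
    sc, res = aanat_result
    sc2 = melatonin_scenario("Aanat", seed=1)
    res2 = run_pipeline(sc2, validate=False)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_reports(res, d1)
    write_reports(res2, d2)
    for name in ("mutations.tsv", "shared_groups.tsv", "status_matrix.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_cli_simulate_and_run(tmp_path):
    from click.testing import CliRunner

    from orfdecay.cli import main

    runner = CliRunner()
    out = tmp_path / "scen"
    r = runner.invoke(main, ["simulate", "--gene", "Aanat", "--seed", "2",
                             "--out-dir", str(out)])
    assert r.exit_code == 0, r.output
    assert (out / "reference.gff3").exists()
    assert (out / "Pcat.fasta").exists()
    assert (out / "truth_mutations.tsv").exists()
    r2 = runner.invoke(main, ["all", "--gene", "Aanat", "--seed", "2",
                              "--no-validate", "--out-dir", str(tmp_path / "rep")])
    assert r2.exit_code == 0, r2.output
    assert (tmp_path / "rep" / "status_matrix.tsv").exists()
    assert "pseudogene" in r2.output


def test_pipeline_from_flat_files_matches_in_memory(tmp_path):
    """Writing a scenario to disk and reloading it yields identical calls."""
    from orfdecay.simulate import load_scenario_dir, write_scenario

    sc = melatonin_scenario("Aanat", seed=5)
    write_scenario(sc, tmp_path / "scen")
    reloaded = load_scenario_dir(tmp_path / "scen", "Aanat")
    res_mem = run_pipeline(sc, validate=False)
    res_disk = run_pipeline(reloaded, validate=False)
    for sp in sc.tree.leaf_labels:
        mem = [(c.type, c.exon_index, c.cds_pos, c.length) for c in res_mem.calls[sp]]
        disk = [(c.type, c.exon_index, c.cds_pos, c.length) for c in res_disk.calls[sp]]
        assert mem == disk, sp
        assert res_mem.statuses[sp].status == res_disk.statuses[sp].status


def test_cli_config_file(tmp_path):
    from click.testing import CliRunner

    from orfdecay.cli import main

    cfg = tmp_path / "cfg.yaml"
    cfg.write_text("gene: Aanat\nseed: 2\n")
    runner = CliRunner()
    r = runner.invoke(main, ["all", "--config", str(cfg), "--no-validate",
                             "--out-dir", str(tmp_path / "rep")])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "rep" / "run_info.json").exists()
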