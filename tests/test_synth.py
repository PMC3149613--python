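"""Generator tests: determinism, construction invariants, planting semantics,
and the truth-table diff."""

import dataclasses

import numpy as np
import pytest

from strainscan.seqio import STOP_CODONS, translate_cds
from strainscan.synth import (
    MutationSpec,
    NonsenseSite,
    TruthTable,
    flagship_spec,
    generate_genome,
    make_pair,
    plant_mutations,
    smoke_spec,
    truth_check,
    write_fixture,
)

SPEC = MutationSpec(
    n_genes=10,
    gene_length_range=(60, 120),
    n_missense=4,
    n_missense_genes=2,
    n_silent=2,
    n_nonsense=1,
    n_deletions=1,
    intergenic_length_range=(10, 50),
    seed=3,
    nonsense_sites=(NonsenseSite(gene_index=4, codon_index=35, ref_codon="CAG",
                                 stop_codon="TGA", gene_length=80),),
)


def test_spec_validation():
    with pytest.raises(ValueError):
        MutationSpec(n_genes=0)
    with pytest.raises(ValueError):
        MutationSpec(n_genes=2, n_deletions=2, n_nonsense=1)
    with pytest.raises(ValueError):
        MutationSpec(n_missense=5, n_missense_genes=6)
    with pytest.raises(ValueError):
        NonsenseSite(gene_index=0, codon_index=10, ref_codon="CAG", stop_codon="CCC")


def test_generation_deterministic_per_seed():
    a = generate_genome(SPEC)
    b = generate_genome(SPEC)
    assert a.sequence == b.sequence
    assert a.annotations == b.annotations
    different = generate_genome(dataclasses.replace(SPEC, seed=4))
    assert different.sequence != a.sequence


def test_planting_deterministic_per_seed():
    anc = generate_genome(SPEC)
    m1, t1 = plant_mutations(anc, SPEC)
    m2, t2 = plant_mutations(anc, SPEC)
    assert m1.sequence == m2.sequence
    assert t1.events == t2.events


def test_every_ancestor_cds_translates_cleanly():
    anc = generate_genome(SPEC)
    assert len(anc.annotations) == SPEC.n_genes
    for ann in anc.annotations:
        cds = anc.cds_sequence(ann)
        assert len(cds) % 3 == 0
        tr = translate_cds(cds)
        assert tr.stop_index == len(cds) // 3  # exactly one terminal stop
        assert cds[:3] == "ATG"


def test_genome_length_within_analytic_bounds():
    anc = generate_genome(SPEC)
    lo, hi = SPEC.gene_length_range
    ilo, ihi = SPEC.intergenic_length_range
    n = SPEC.n_genes
    # one gene is forced to 80 codons by the nonsense site
    min_len = (n - 1) * 3 * (lo + 1) + 3 * 81 + (n + 1) * ilo
    max_len = (n - 1) * 3 * (hi + 1) + 3 * 81 + (n + 1) * ihi
    assert min_len <= len(anc) <= max_len


def test_deletion_shortens_genome_by_cds_length():
    anc = generate_genome(SPEC)
    mut, truth = plant_mutations(anc, SPEC)
    deleted = [g for g in truth.genes if truth.expected_row(g).status == "missing"]
    assert len(deleted) == SPEC.n_deletions
    by_name = {a.gene_name: a for a in anc.annotations}
    removed = sum(by_name[g].length for g in deleted)
    assert len(anc) - len(mut) == removed
    assert all(a.gene_name not in deleted for a in mut.annotations)


def test_nonsense_event_truncates_translation():
    anc = generate_genome(SPEC)
    mut, truth = plant_mutations(anc, SPEC)
    by_name = {a.gene_name: a for a in mut.annotations}
    for gene, events in truth.events.items():
        for e in events:
            if e.etype != "nonsense":
                continue
            cds = mut.cds_sequence(by_name[gene])
            tr = translate_cds(cds)
            assert tr.stop_index == e.codon_index
            assert tr.stop_codon == e.alt_codon
            assert e.alt_codon in STOP_CODONS


def test_silent_events_leave_protein_unchanged():
    anc = generate_genome(SPEC)
    mut, truth = plant_mutations(anc, SPEC)
    anc_by = {a.gene_name: a for a in anc.annotations}
    mut_by = {a.gene_name: a for a in mut.annotations}
    checked = 0
    for gene, events in truth.events.items():
        if all(e.etype == "silent" for e in events):
            a = translate_cds(anc.cds_sequence(anc_by[gene])).aa_sequence
            b = translate_cds(mut.cds_sequence(mut_by[gene])).aa_sequence
            assert a == b
            assert anc.cds_sequence(anc_by[gene]) != mut.cds_sequence(mut_by[gene])
            checked += 1
    assert checked >= 1


def test_missense_consequences_match_genetic_code():
    anc = generate_genome(SPEC)
    mut, truth = plant_mutations(anc, SPEC)
    anc_by = {a.gene_name: a for a in anc.annotations}
    mut_by = {a.gene_name: a for a in mut.annotations}
    for gene, events in truth.events.items():
        missense = [e for e in events if e.etype == "missense"]
        if not missense:
            continue
        a = translate_cds(anc.cds_sequence(anc_by[gene])).aa_sequence
        b = translate_cds(mut.cds_sequence(mut_by[gene])).aa_sequence
        diffs = {i + 1: (x, y) for i, (x, y) in enumerate(zip(a, b)) if x != y}
        assert len(diffs) == len(missense)
        for e in missense:
            ref_aa, alt_aa = diffs[e.codon_index]
            assert e.consequence == f"{ref_aa}{e.codon_index}{alt_aa}"


def test_no_events_means_identical_genomes():
    spec = MutationSpec(n_genes=5, gene_length_range=(50, 90), seed=8)
    anc = generate_genome(spec)
    mut, truth = plant_mutations(anc, spec)
    assert mut.sequence == anc.sequence
    assert truth.events == {}
    assert all(truth.expected_row(g).status == "identical" for g in truth.genes)


def test_flagship_spec_shape():
    spec = flagship_spec(1)
    anc, mut, truth = make_pair(spec)
    assert len(anc.annotations) == 86
    statuses = [truth.expected_row(g).status for g in truth.genes]
    assert statuses.count("substituted") == 42
    assert statuses.count("missing") == 5
    assert statuses.count("truncated") == 1
    assert statuses.count("identical") == 38
    total = sum(len(truth.expected_row(g).exchanges) for g in truth.genes)
    assert total == 78
    trunc_gene = truth.genes[45]
    assert truth.expected_row(trunc_gene).truncation == (141, "amber")
    events = truth.events[trunc_gene]
    assert events[0].ref_codon == "CAG" and events[0].alt_codon == "TAG"


def test_truth_check_flags_corruption(smoke_pair, smoke_result):
    _, _, truth = smoke_pair
    assert truth_check(smoke_result.rows, truth) == []
    rows = [dataclasses.replace(r) for r in smoke_result.rows]
    victim = next(r for r in rows if r.status == "identical")
    victim.status = "substituted"
    diffs = truth_check(rows, truth)
    assert len(diffs) == 1
    assert diffs[0].gene == victim.gene_name and diffs[0].field == "status"


def test_truth_table_tsv_roundtrip(tmp_path, smoke_pair):
    _, _, truth = smoke_pair
    path = tmp_path / "truth.tsv"
    truth.to_tsv(path)
    back = TruthTable.from_tsv(path)
    assert back.genes == truth.genes
    assert back.gene_lengths == truth.gene_lengths
    assert back.events == truth.events


def test_write_fixture_files(tmp_path):
    paths = write_fixture(tmp_path, smoke_spec(5), "smoke")
    for p in paths.values():
        assert p.exists() and p.stat().st_size > 0
    genes = (tmp_path / "smoke_genes.txt").read_text().splitlines()
    assert len(genes) == 12
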