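"""Classifier tests: best-hit selection, exchange/indel enumeration,
truncation detection, and the classification precedence rules."""

import numpy as np
import pytest

from strainscan.align import ScoringScheme, align_global
from strainscan.classify import (
    Exchange,
    best_hit,
    classify_gene,
    detect_truncation,
    enumerate_exchanges,
    enumerate_indels,
    frame_aligned_region,
    summarize,
)
from strainscan.orfs import Orf, enumerate_orfs, orf_index
from strainscan.seqio import (
    GeneAnnotation,
    GenomeRecord,
    ProteinRecord,
    SENSE_CODONS,
    reverse_complement,
    translate_cds,
)
from strainscan import MutationSpec, ScanConfig, make_pair, run_scan, truth_check
from strainscan.report import render_report

SCHEME = ScoringScheme()


def _orf(aa, start=1, strand=1, cds=None):
    cds = cds or ("ATG" + "GCT" * (len(aa) - 1) + "TAA")
    return Orf(genome_id="t", start=start, end=start + len(cds) - 1, strand=strand,
               frame=0, aa_sequence=aa, cds=cds)


def _protein(aa, name="q"):
    """A ProteinRecord with a synthetic CDS consistent with its sequence."""
    back = {"M": "ATG", "K": "AAA", "P": "CCC", "G": "GGA", "A": "GCT", "C": "TGC",
            "D": "GAT", "E": "GAA", "F": "TTT", "H": "CAC", "I": "ATC", "L": "CTG",
            "N": "AAC", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTT",
            "W": "TGG", "Y": "TAC"}
    cds = "".join(back[c] for c in aa) + "TAA"
    return ProteinRecord(gene_name=name, aa_sequence=aa, source_cds=cds)


def test_exchange_token_notation():
    assert Exchange("R", 51, "L").token == "R51L"
    with pytest.raises(ValueError):
        Exchange("R", 51, "R")


def test_enumerate_exchanges_identical_is_empty():
    q = _protein("MKPGA")
    aln = align_global(q.aa_sequence, q.aa_sequence, SCHEME)
    assert enumerate_exchanges(aln, q, q.aa_sequence) == []


def test_enumerate_exchanges_positions_and_order():
    q = _protein("MKPGAKPGAW")
    target = "MRPGAKPGAY"  # K2R, W10Y
    aln = align_global(q.aa_sequence, target, SCHEME)
    assert [e.token for e in enumerate_exchanges(aln, q, target)] == ["K2R", "W10Y"]


def test_enumerate_indels_single_residue_deletion():
    q = _protein("MKPGAW")
    target = "MKGAW"  # P3 deleted
    aln = align_global(q.aa_sequence, target, SCHEME)
    assert enumerate_exchanges(aln, q, target) == []
    assert enumerate_indels(aln, q, target) == ["P3del"]


def test_enumerate_indels_insertion():
    q = _protein("MKPGAW")
    target = "MKPYGAW"  # Y inserted after P3
    aln = align_global(q.aa_sequence, target, SCHEME)
    assert enumerate_indels(aln, q, target) == ["3insY"]


def test_best_hit_finds_exact_match_among_decoys():
    rng = np.random.default_rng(31)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    decoys = [
        _orf("M" + "".join(rng.choice(list(aas), size=int(rng.integers(20, 60)))), start=10 * i + 1)
        for i in range(100)
    ]
    query = _protein("M" + "".join(rng.choice(list(aas), size=40)))
    target = _orf(query.aa_sequence, start=1500)
    orfs = sorted(decoys + [target], key=lambda o: (o.start, o.strand))
    hit_orf, score = best_hit(query, orfs, SCHEME)
    assert hit_orf is target
    assert score == query.length * SCHEME.match


def test_best_hit_prefilter_equivalence_and_tiebreak():
    query = _protein("MKPGAWKPGA")
    twin_a = _orf(query.aa_sequence, start=5)
    twin_b = _orf(query.aa_sequence, start=50)
    decoy = _orf("MHHHHHHHHH", start=20)
    orfs = [twin_a, decoy, twin_b]
    plain = best_hit(query, orfs, SCHEME)
    indexed = best_hit(query, orfs, SCHEME, index=orf_index(orfs, k=3))
    assert plain == indexed
    assert plain[0] is twin_a  # smaller start wins the tie


def test_best_hit_empty_orf_list():
    assert best_hit(_protein("MKP"), [], SCHEME) == (None, None)


def _cds_with(codons):
    return "".join(codons)


def test_detect_truncation_amber_at_codon_141():
    """A 250-codon gene whose codon 141 mutates CAG->TAG (C->T, first base)
    must be reported as an amber stop at codon 141 with that causal change."""
    rng = np.random.default_rng(141)
    codons = ["ATG"] + [str(c) for c in rng.choice(SENSE_CODONS, size=249)] + ["TGA"]
    codons[140] = "CAG"
    ref = _cds_with(codons)
    query = ProteinRecord("fnr-like", translate_cds(ref).aa_sequence, ref)
    assert query.length == 250

    mutant = codons.copy()
    mutant[140] = "TAG"
    ev = detect_truncation(query, _cds_with(mutant))
    assert ev is not None
    assert ev.stop_codon_index == 141
    assert ev.stop_class == "amber"
    assert ev.causal_change == (1, "C", "T")

    # identical region: no truncation
    assert detect_truncation(query, ref) is None

    # TAA instead: ochre
    mutant[140] = "TAA"
    assert detect_truncation(query, _cds_with(mutant)).stop_class == "ochre"


def test_detect_truncation_requires_established_frame():
    rng = np.random.default_rng(9)
    codons = ["ATG"] + [str(c) for c in rng.choice(SENSE_CODONS, size=99)] + ["TAA"]
    ref = _cds_with(codons)
    query = ProteinRecord("q", translate_cds(ref).aa_sequence, ref)
    other = ["ATG"] + [str(c) for c in rng.choice(SENSE_CODONS, size=49)] + ["TAA"]
    assert detect_truncation(query, _cds_with(other)) is None


def test_detect_truncation_ignores_shifted_natural_stop():
    """Deleting one codon near the end shifts the real stop one codon early;
    that is an indel, not a nonsense mutation."""
    rng = np.random.default_rng(5)
    codons = ["ATG"] + [str(c) for c in rng.choice(SENSE_CODONS, size=95)] + ["TAA"]
    ref = _cds_with(codons)
    query = ProteinRecord("q", translate_cds(ref).aa_sequence, ref)
    mutant = codons[:94] + codons[95:]  # drop codon 95
    assert detect_truncation(query, _cds_with(mutant)) is None


def _mini_scan(ref_codons, mut_codons, strand=1):
    """Build a one-gene reference/target pair from codon lists and scan it."""
    ref_nt = _cds_with(ref_codons)
    mut_nt = _cds_with(mut_codons)
    pad5, pad3 = "CCCCCCT", "TCCCCCC"
    ref_seq = pad5 + (ref_nt if strand == 1 else reverse_complement(ref_nt)) + pad3
    mut_seq = pad5 + (mut_nt if strand == 1 else reverse_complement(mut_nt)) + pad3
    reference = GenomeRecord(
        id="ref", sequence=ref_seq,
        annotations=[GeneAnnotation("geneA", "L_0001", len(pad5) + 1, len(pad5) + len(ref_nt), strand)],
    )
    target = GenomeRecord(id="tgt", sequence=mut_seq)
    return run_scan(reference, target, ["geneA"], ScanConfig())


def _random_gene(rng, n_codons):
    return ["ATG"] + [str(c) for c in rng.choice(SENSE_CODONS, size=n_codons - 1)] + ["TAA"]


def test_truncated_takes_precedence_with_upstream_exchanges_listed():
    rng = np.random.default_rng(77)
    ref = _random_gene(rng, 120)
    mut = ref.copy()
    mut[4] = "TGG" if ref[4] != "TGG" else "TGC"  # missense at codon 5
    mut[59] = "TAG"  # premature amber stop at codon 60
    result = _mini_scan(ref, mut)
    row = result.rows[0]
    assert row.status == "truncated"
    assert row.truncation.stop_codon_index == 60
    assert row.truncation.stop_class == "amber"
    assert [e.position for e in row.exchanges] == [5]


def test_truncation_detected_on_minus_strand_gene():
    rng = np.random.default_rng(78)
    ref = _random_gene(rng, 120)
    mut = ref.copy()
    mut[59] = "TAA"
    result = _mini_scan(ref, mut, strand=-1)
    row = result.rows[0]
    assert row.status == "truncated"
    assert (row.truncation.stop_codon_index, row.truncation.stop_class) == (60, "ochre")


def test_missing_called_when_gene_absent():
    rng = np.random.default_rng(79)
    ref = _random_gene(rng, 80)
    reference = GenomeRecord(
        id="ref",
        sequence="CC" + _cds_with(ref) + "CC",
        annotations=[GeneAnnotation("geneA", "L_0001", 3, 2 + 3 * 81, 1)],
    )
    # target shares nothing with the gene
    decoy = _random_gene(np.random.default_rng(80), 60)
    target = GenomeRecord(id="tgt", sequence="CC" + _cds_with(decoy) + "CC")
    result = run_scan(reference, target, ["geneA"], ScanConfig())
    assert result.rows[0].status == "missing"
    assert result.rows[0].exchanges == []


def test_classify_missing_frac_validation():
    with pytest.raises(ValueError):
        classify_gene(_protein("MKP"), (None, None), SCHEME, missing_frac=1.5)


def test_self_scan_reports_all_identical(smoke_pair, default_config):
    ancestor, _, _ = smoke_pair
    genes = [a.gene_name for a in ancestor.annotations]
    result = run_scan(ancestor, ancestor, genes, default_config)
    assert all(r.status == "identical" for r in result.rows)
    assert result.summary.as_tuple() == (len(genes), len(genes), 0, 0, 0, 0)
    assert all(r.best_score == r.query_length for r in result.rows)


def test_smoke_scan_matches_truth(smoke_pair, smoke_result):
    _, _, truth = smoke_pair
    assert truth_check(smoke_result.rows, truth) == []


def test_annotated_mode_matches_truth(smoke_pair, default_config):
    import dataclasses
    from strainscan.config import OrfConfig

    ancestor, mutant, truth = smoke_pair
    config = dataclasses.replace(default_config, orf=OrfConfig(mode="annotated"))
    result = run_scan(ancestor, mutant, [a.gene_name for a in ancestor.annotations], config)
    assert truth_check(result.rows, truth) == []


def test_adding_a_missense_only_changes_that_gene(smoke_pair, smoke_result, default_config):
    """Monotonicity: one extra planted missense never decreases that gene's
    exchange count and leaves every other row untouched."""
    ancestor, mutant, truth = smoke_pair
    victim = next(g for g in truth.genes if not truth.events.get(g))
    ann = next(a for a in mutant.annotations if a.gene_name == victim)
    cds = list(mutant.cds_sequence(ann))
    # codon 10: force a non-synonymous change (His -> Trp, or Trp -> His)
    old_aa = translate_cds("".join(cds[27:30]), bacterial_start=False).aa_sequence
    cds[27:30] = list("CAC" if old_aa != "H" else "TGG")
    edited_cds = "".join(cds)
    nt = edited_cds if ann.strand == 1 else reverse_complement(edited_cds)
    seq = mutant.sequence[: ann.start - 1] + nt + mutant.sequence[ann.end :]
    edited = GenomeRecord(id=mutant.id, sequence=seq, annotations=mutant.annotations)

    genes = [a.gene_name for a in ancestor.annotations]
    result = run_scan(ancestor, edited, genes, default_config)
    before = {r.gene_name: r for r in smoke_result.rows}
    after = {r.gene_name: r for r in result.rows}
    assert after[victim].n_exchanges == before[victim].n_exchanges + 1
    assert after[victim].status == "substituted"
    unchanged_before = render_report([before[g] for g in genes if g != victim])
    unchanged_after = render_report([after[g] for g in genes if g != victim])
    assert unchanged_before == unchanged_after


def test_summary_counts(smoke_result):
    s = summarize(smoke_result.rows)
    assert s.as_tuple() == smoke_result.summary.as_tuple()
    assert s.n_queries == (
        s.n_identical + s.n_substituted + s.n_truncated + s.n_missing
    )
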