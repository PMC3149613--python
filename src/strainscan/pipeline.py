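"""End-to-end proteome scan: candidate proteins vs a target genome.

Ties seqio, the ORF scanner, the aligner and the classifier together into
the single deterministic procedure the rest of the package (CLI, tests,
fixtures) calls.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .classify import GeneComparison, ScanSummary, best_hit, classify_gene, summarize
from .config import MODE_ANNOTATED, ScanConfig
from .orfs import Orf, enumerate_orfs, orf_index, orfs_from_annotations
from .seqio import (
    GenomeRecord,
    ProteinRecord,
    UnresolvedCandidate,
    extract_annotated_proteins,
    read_gene_list,
    read_genome,
    attach_gff3,
)

log = logging.getLogger(__name__)


@dataclass
class ScanResult:
    rows: List[GeneComparison]
    summary: ScanSummary
    unresolved: List[UnresolvedCandidate]
    n_orfs: int
    config: ScanConfig
    timings: dict = field(default_factory=dict)


def proteome_scan(
    queries: Sequence[ProteinRecord],
    target: GenomeRecord,
    config: ScanConfig = ScanConfig(),
) -> Tuple[List[GeneComparison], ScanSummary, int]:
    """Scan every query against the target's translated ORF space.

    Returns one GeneComparison per query (input order), the six-count
    summary, and the size of the ORF search space.  Deterministic given
    inputs and configuration; per-gene problems are recorded in the row,
    never aborting the scan.
    """
    t0 = time.perf_counter()
    if config.orf.mode == MODE_ANNOTATED:
        orfs: List[Orf] = orfs_from_annotations(target)
    else:
        orfs = enumerate_orfs(
            target,
            min_aa=config.orf.min_aa,
            start_codons=frozenset(config.orf.start_codons),
            stop_codons=frozenset(config.orf.stop_codons),
            emit_nested_starts=config.orf.emit_nested_starts,
        )
    log.info("enumerated %d ORFs in %.2fs (mode=%s)", len(orfs), time.perf_counter() - t0, config.orf.mode)
    index = orf_index(orfs, config.prefilter.k) if (config.prefilter.enabled and orfs) else None
    scheme = config.scoring.scheme()
    rows: List[GeneComparison] = []
    t1 = time.perf_counter()
    for query in queries:
        hit = best_hit(query, orfs, scheme, index)
        rows.append(
            classify_gene(
                query,
                hit,
                scheme,
                missing_frac=config.classify.missing_frac,
                trunc_min_identity=config.classify.trunc_min_identity,
                trunc_min_codons=config.classify.trunc_min_codons,
                trunc_min_lost_codons=config.classify.trunc_min_lost_codons,
                target_genome=target,
            )
        )
    log.info("aligned %d queries in %.2fs", len(queries), time.perf_counter() - t1)
    summary = summarize(rows, config.classify.count_indels_as_exchanges)
    return rows, summary, len(orfs)


def run_scan(
    reference: GenomeRecord,
    target: GenomeRecord,
    candidates: Sequence[str],
    config: ScanConfig = ScanConfig(),
) -> ScanResult:
    queries, unresolved = extract_annotated_proteins(reference, candidates)
    for u in unresolved:
        log.warning("candidate %s unresolved: %s", u.name, u.reason)
    rows, summary, n_orfs = proteome_scan(queries, target, config)
    return ScanResult(
        rows=rows,
        summary=summary,
        unresolved=unresolved,
        n_orfs=n_orfs,
        config=config,
    )


def scan_files(
    reference_path,
    target_path,
    genes_path,
    config: ScanConfig = ScanConfig(),
    reference_gff3=None,
    target_gff3=None,
) -> ScanResult:
    """File-level entry point used by the CLI."""
    reference = read_genome(reference_path)
    if reference_gff3 is not None:
        attach_gff3(reference, reference_gff3)
    target = read_genome(target_path)
    if target_gff3 is not None:
        attach_gff3(target, target_gff3)
    candidates = read_gene_list(genes_path)
    return run_scan(reference, target, candidates, config)
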