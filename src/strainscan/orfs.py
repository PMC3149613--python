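"""Exhaustive six-frame ORF enumeration of a target genome.

"Potential ORF" here means every start-to-stop stretch on either strand in
any of the three frames: for each stop codon the maximal ORF from the most
upstream in-frame start since the previous stop is emitted, and (by default)
one ORF per internal start codon as well, so that N-terminally truncated or
mispredicted-start matches remain findable.  There is no gene-prediction
scoring of any kind -- the scan is meant to be the complete search space for
the best-hit alignment.

Minus-strand ORFs are reported on forward-strand coordinates with
``start < end`` and ``strand = -1``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .seqio import GenomeRecord, reverse_complement, translate_cds

log = logging.getLogger(__name__)

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class Orf:
    """One translated potential open reading frame.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of the
    full CDS including the stop codon; ``frame`` is the 0|1|2 offset of the
    reading frame on its own strand.
    """

    genome_id: str
    start: int
    end: int
    strand: int
    frame: int
    aa_sequence: str
    cds: str

    @property
    def header(self) -> str:
        return f"{self.genome_id}|{self.start}..{self.end}|{self.strand:+d}|{self.frame}"


def enumerate_orfs(
    genome: GenomeRecord,
    min_aa: int = 30,
    start_codons: FrozenSet[str] = DEFAULT_START_CODONS,
    stop_codons: FrozenSet[str] = DEFAULT_STOP_CODONS,
    emit_nested_starts: bool = True,
    circular: Optional[bool] = None,
    circular_overhang_aa: int = 100_000,
) -> List[Orf]:
    """Enumerate every maximal (and optionally nested-start) ORF on both strands.

    ORFs shorter than ``min_aa`` residues are excluded; output is sorted by
    (start, strand) and is deterministic.  Codons containing N never match
    the start or stop sets.  Circular genomes are scanned with an origin
    overhang and deduplicated; origin-spanning ORFs are reported with wrapped
    coordinates (end < start).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if not start_codons or not stop_codons:
        raise ValueError("start and stop codon sets must be non-empty")
    if start_codons & stop_codons:
        raise ValueError("start and stop codon sets must be disjoint")
    if circular is None:
        circular = genome.topology == "circular"
    seq = genome.sequence
    L = len(seq)
    if L < 3:
        return []
    overhang = min(L, 3 * circular_overhang_aa) if circular else 0
    scan = seq + seq[:overhang]

    orfs: List[Orf] = []
    seen: Set[Tuple[int, int, int, str]] = set()
    Ls = len(scan)
    for strand in (1, -1):
        s = scan if strand == 1 else reverse_complement(scan)
        for frame in range(3):
            starts: List[int] = []
            for pos in range(frame, Ls - 2, 3):
                codon = s[pos : pos + 3]
                if codon in stop_codons:
                    emit = starts if emit_nested_starts else starts[:1]
                    for st in emit:
                        aa_len = (pos - st) // 3
                        if aa_len < min_aa:
                            continue
                        cds = s[st : pos + 3]
                        if strand == 1:
                            f_lo, f_hi = st + 1, pos + 3
                        else:
                            f_lo, f_hi = Ls - (pos + 3) + 1, Ls - st
                        if circular:
                            # drop duplicates that live entirely in the overhang
                            f_lo = (f_lo - 1) % L + 1
                            f_hi = (f_hi - 1) % L + 1
                        key = (f_lo, strand, frame, cds)
                        if key in seen:
                            continue
                        seen.add(key)
                        aa = translate_cds(cds).aa_sequence
                        orfs.append(
                            Orf(
                                genome_id=genome.id,
                                start=f_lo,
                                end=f_hi,
                                strand=strand,
                                frame=frame,
                                aa_sequence=aa,
                                cds=cds,
                            )
                        )
                    starts = []
                elif codon in start_codons:
                    starts.append(pos)
    orfs.sort(key=lambda o: (o.start, o.strand, o.end, o.frame))
    return orfs


def orfs_from_annotations(genome: GenomeRecord) -> List[Orf]:
    """Annotated-CDS mode: one Orf per annotated CDS, no six-frame scan.

    The stored ``cds`` is the full annotated extent even if translation stops
    early (an internal stop), so downstream truncation detection can inspect
    codons past a premature stop.
    """
    orfs: List[Orf] = []
    for ann in genome.annotations:
        if not ann.is_cds:
            continue
        cds = genome.cds_sequence(ann)
        if len(cds) % 3 != 0:
            log.warning("annotated CDS %s length not divisible by 3; skipped", ann.gene_name)
            continue
        aa = translate_cds(cds).aa_sequence
        orfs.append(
            Orf(
                genome_id=genome.id,
                start=ann.start,
                end=ann.end,
                strand=ann.strand,
                frame=(ann.start - 1) % 3 if ann.strand == 1 else (len(genome) - ann.end) % 3,
                aa_sequence=aa,
                cds=cds,
            )
        )
    orfs.sort(key=lambda o: (o.start, o.strand, o.end, o.frame))
    return orfs


class OrfIndex:
    """Amino-acid k-mer prefilter over an ORF list.

    The index only *orders* candidates for the best-hit search (most shared
    k-mers first, ties by position); it never excludes an ORF from
    consideration, so scans with and without it return identical results.
    """

    def __init__(self, orfs: Sequence[Orf], k: int = 6):
        if k < 3:
            raise ValueError("k must be >= 3")
        self.k = k
        self._map: Dict[str, List[int]] = {}
        for i, orf in enumerate(orfs):
            aa = orf.aa_sequence
            for kmer in {aa[p : p + k] for p in range(len(aa) - k + 1)}:
                self._map.setdefault(kmer, []).append(i)

    def candidates(self, query_aa: str) -> List[int]:
        """ORF indices sharing at least one k-mer with the query, ranked by
        the number of distinct shared k-mers (descending), then position."""
        counts: Counter = Counter()
        k = self.k
        for kmer in {query_aa[p : p + k] for p in range(len(query_aa) - k + 1)}:
            for i in self._map.get(kmer, ()):
                counts[i] += 1
        return [i for i, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def orf_index(orfs: Sequence[Orf], k: int = 6) -> OrfIndex:
    return OrfIndex(orfs, k)


def write_orf_fasta(orfs: Iterable[Orf], path) -> None:
    from .seqio import write_fasta

    write_fasta([(o.header, o.aa_sequence) for o in orfs], path)
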