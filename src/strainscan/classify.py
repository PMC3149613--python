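"""Best-hit search and per-gene variant classification.

For every reference protein the scan finds the translated ORF of the target
genome with the maximal global-alignment similarity score, then classifies
the gene:

* ``identical``   -- score equals query length x match reward (exact copy);
* ``truncated``   -- the target reading frame carries a premature stop codon
  behind a cleanly matching N-terminal prefix (nonsense mutation);
* ``missing``     -- no ORF reaches ``missing_frac`` of the perfect score;
* ``substituted`` -- otherwise, with every mismatch column reported as an
  amino-acid exchange in reference coordinates ("R51L" notation) and gap
  columns reported separately as indel annotations.

Classification precedence is identical > truncated > missing > substituted:
a protein truncated early in its sequence scores far below the missing
threshold (matched prefix minus gapped tail), so the truncation test must
run before the missing cutoff; a gene carrying both a premature stop and
upstream substitutions is called truncated with the exchanges still listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

from .align import (
    AlignmentResult,
    ScoringScheme,
    STATE_MATCH,
    STATE_MISMATCH,
    STATE_QGAP,
    STATE_TGAP,
    align_global,
    align_score_only_encoded,
    encode_protein,
)
from .orfs import Orf, OrfIndex
from .seqio import (
    CODON_TO_AA,
    STOP_CLASS,
    STOP_CODONS,
    GenomeRecord,
    ProteinRecord,
    reverse_complement,
)

log = logging.getLogger(__name__)

STATUS_IDENTICAL = "identical"
STATUS_SUBSTITUTED = "substituted"
STATUS_TRUNCATED = "truncated"
STATUS_MISSING = "missing"


@dataclass(frozen=True)
class Exchange:
    """One amino-acid exchange, positions in reference coordinates (1-based)."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("silent changes never produce an Exchange")

    @property
    def token(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class TruncationEvidence:
    """A premature stop codon in the reference reading frame of the target."""

    stop_codon_index: int  # 1-based codon position in the reference frame
    stop_codon: str
    stop_class: str  # amber | ochre | opal
    #: (within-codon offset 1..3, ref base, alt base) when the codons differ
    #: by exactly one base -- the causal substitution, e.g. C->T for CAG->TAG.
    causal_change: Optional[Tuple[int, str, str]] = None


@dataclass
class GeneComparison:
    """Per-gene verdict with the evidence behind it."""

    gene_name: str
    query_length: int
    status: str
    best_score: Optional[int] = None
    best_orf: Optional[Orf] = None
    exchanges: List[Exchange] = field(default_factory=list)
    indels: List[str] = field(default_factory=list)
    truncation: Optional[TruncationEvidence] = None
    identity: float = 0.0
    coverage: float = 0.0
    note: str = ""

    @property
    def n_exchanges(self) -> int:
        return len(self.exchanges)


@dataclass
class ScanSummary:
    n_queries: int = 0
    n_identical: int = 0
    n_substituted: int = 0
    total_exchanges: int = 0
    n_truncated: int = 0
    n_missing: int = 0

    def as_tuple(self) -> Tuple[int, int, int, int, int, int]:
        return (
            self.n_queries,
            self.n_identical,
            self.n_substituted,
            self.total_exchanges,
            self.n_truncated,
            self.n_missing,
        )

    def as_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "n_identical": self.n_identical,
            "n_substituted": self.n_substituted,
            "total_exchanges": self.total_exchanges,
            "n_truncated": self.n_truncated,
            "n_missing": self.n_missing,
        }


def best_hit(
    query: ProteinRecord,
    orfs: Sequence[Orf],
    scheme: ScoringScheme = ScoringScheme(),
    index: Optional[OrfIndex] = None,
    n_seed_candidates: int = 3,
) -> Tuple[Optional[Orf], Optional[int]]:
    """The ORF maximizing the global similarity score against the query.

    Ties go to the ORF earliest in (start, strand) order, i.e. the order of
    the input list.  An exact branch-and-bound length bound skips ORFs that
    provably cannot beat (or tie better than) the running best, so the
    result is identical to the exhaustive scan.  When a k-mer ``index`` is
    given, its top candidates are aligned first to seed the bound; this
    changes nothing but speed.
    """
    if not orfs:
        return None, None
    qaa = query.aa_sequence
    qc = encode_protein(qaa)
    cache: dict = {}
    lower: Optional[int] = None
    if index is not None:
        for oi in index.candidates(qaa)[:n_seed_candidates]:
            s = align_score_only_encoded(qc, encode_protein(orfs[oi].aa_sequence), scheme)
            cache[oi] = s
            if lower is None or s > lower:
                lower = s
    best_i = -1
    best_s: Optional[int] = None
    for i, orf in enumerate(orfs):
        bound = scheme.score_bound(len(qaa), len(orf.aa_sequence))
        if bound is not None:
            if best_s is not None and bound <= best_s:
                continue
            if best_s is None and lower is not None and bound < lower:
                continue
        s = cache.get(i)
        if s is None:
            s = align_score_only_encoded(qc, encode_protein(orf.aa_sequence), scheme)
        if best_s is None or s > best_s:
            best_s, best_i = s, i
    return orfs[best_i], best_s


def enumerate_exchanges(
    alignment: AlignmentResult, query: ProteinRecord, target_aa: str
) -> List[Exchange]:
    """One Exchange per mismatch column, ascending reference positions.

    Gap columns are *not* exchanges; see :func:`enumerate_indels`.
    """
    out: List[Exchange] = []
    for qpos, tpos, state in alignment.columns:
        if state == STATE_MISMATCH:
            assert qpos is not None and tpos is not None
            out.append(
                Exchange(
                    ref_aa=query.aa_sequence[qpos - 1],
                    position=qpos,
                    alt_aa=target_aa[tpos - 1],
                )
            )
    return out


def enumerate_indels(
    alignment: AlignmentResult, query: ProteinRecord, target_aa: str
) -> List[str]:
    """Human-readable tokens for gap runs, in reference coordinates.

    Deleted reference residues: ``K51del`` (or ``K51_L53del`` for a run);
    inserted target residues: ``51insA`` = residue A inserted after
    reference position 51.
    """
    tokens: List[str] = []
    cols = alignment.columns
    i = 0
    last_qpos = 0
    while i < len(cols):
        qpos, tpos, state = cols[i]
        if state == STATE_TGAP:
            j = i
            while j < len(cols) and cols[j][2] == STATE_TGAP:
                j += 1
            first = cols[i][0]
            last = cols[j - 1][0]
            assert first is not None and last is not None
            if first == last:
                tokens.append(f"{query.aa_sequence[first - 1]}{first}del")
            else:
                tokens.append(
                    f"{query.aa_sequence[first - 1]}{first}_"
                    f"{query.aa_sequence[last - 1]}{last}del"
                )
            last_qpos = last
            i = j
        elif state == STATE_QGAP:
            j = i
            inserted = []
            while j < len(cols) and cols[j][2] == STATE_QGAP:
                inserted.append(target_aa[cols[j][1] - 1])  # type: ignore[index]
                j += 1
            tokens.append(f"{last_qpos}ins{''.join(inserted)}")
            i = j
        else:
            last_qpos = qpos if qpos is not None else last_qpos
            i += 1
    return tokens


def frame_aligned_region(
    query: ProteinRecord, orf: Orf, alignment: AlignmentResult, genome: GenomeRecord
) -> Optional[str]:
    """Target nucleotides covering the query's reading frame, genome-anchored.

    The first aligned (diagonal) column of the best alignment fixes where
    reference codon 1 sits on the target's coding strand relative to the
    ORF start; the returned region then spans the full reference frame
    (query length + stop), clipped at genome bounds.  This matters when the
    best-scoring ORF is only a fragment of the gene -- e.g. the ORF
    downstream of a premature stop -- because the premature stop itself then
    lies upstream of the ORF and is invisible in the ORF's own CDS.
    """
    first = next(
        (c for c in alignment.columns if c[2] in (STATE_MATCH, STATE_MISMATCH)), None
    )
    if first is None:
        return None
    qpos, tpos = first[0], first[1]
    assert qpos is not None and tpos is not None
    shift = qpos - tpos  # codons of reference upstream of the ORF's coding start
    n = 3 * (query.length + 1)
    glen = len(genome.sequence)
    if orf.strand == 1:
        g0 = orf.start - 3 * shift  # forward position of reference codon 1
        if g0 < 1:
            return None
        region = genome.sequence[g0 - 1 : min(glen, g0 - 1 + n)]
    else:
        g0 = orf.end + 3 * shift  # coding start reads downward from here
        if g0 > glen:
            return None
        region = reverse_complement(genome.sequence[max(0, g0 - n) : g0])
    return region[: 3 * (len(region) // 3)]


def detect_truncation(
    query: ProteinRecord,
    orf_or_region: Union[Orf, str],
    min_prefix_identity: float = 0.9,
    min_prefix_codons: int = 10,
    min_lost_codons: int = 5,
) -> Optional[TruncationEvidence]:
    """Codon-by-codon check for a premature stop in the reference frame.

    Compares the query's source CDS against the target nucleotides (an ORF's
    CDS, or any frame-aligned region) codon by codon and returns the first
    target codon that is a stop while the reference codon is not -- provided
    the translated prefix before it matches the reference cleanly enough to
    establish the frame, and the stop removes at least ``min_lost_codons``
    residues.  The latter guard keeps an in-frame deletion near the C
    terminus -- which shifts the natural stop a codon or two earlier -- from
    masquerading as a nonsense mutation.  Returns None when there is no
    premature stop or the frame cannot be established.
    """
    region = orf_or_region.cds if isinstance(orf_or_region, Orf) else str(orf_or_region)
    region = region.upper()
    ref = query.source_cds.upper()
    n_ref = len(ref) // 3
    n_reg = len(region) // 3
    for ci in range(1, min(n_ref, n_reg) + 1):
        rc = ref[3 * (ci - 1) : 3 * ci]
        tc = region[3 * (ci - 1) : 3 * ci]
        t_stop = tc in STOP_CODONS
        r_stop = rc in STOP_CODONS
        if t_stop and r_stop:
            return None  # stops coincide: normal end of gene
        if t_stop and not r_stop:
            if query.length - ci + 1 < min_lost_codons:
                return None  # stop too close to the natural end: indel, not nonsense
            prefix_n = ci - 1
            if prefix_n < min_prefix_codons:
                log.debug("%s: premature stop at codon %d but prefix too short", query.gene_name, ci)
                return None
            matches = 0
            for k in range(prefix_n):
                ra = CODON_TO_AA.get(ref[3 * k : 3 * k + 3])
                ta = CODON_TO_AA.get(tc_k := region[3 * k : 3 * k + 3])
                if ra is not None and ra == ta:
                    matches += 1
            if matches / prefix_n < min_prefix_identity:
                log.debug(
                    "%s: premature stop at codon %d but frame not established "
                    "(prefix identity %.2f)",
                    query.gene_name,
                    ci,
                    matches / prefix_n,
                )
                return None
            diffs = [k for k in range(3) if rc[k] != tc[k]]
            causal = (diffs[0] + 1, rc[diffs[0]], tc[diffs[0]]) if len(diffs) == 1 else None
            return TruncationEvidence(
                stop_codon_index=ci,
                stop_codon=tc,
                stop_class=STOP_CLASS[tc],
                causal_change=causal,
            )
    return None


def classify_gene(
    query: ProteinRecord,
    hit: Tuple[Optional[Orf], Optional[int]],
    scheme: ScoringScheme = ScoringScheme(),
    missing_frac: float = 0.5,
    trunc_min_identity: float = 0.9,
    trunc_min_codons: int = 10,
    trunc_min_lost_codons: int = 5,
    target_genome: Optional[GenomeRecord] = None,
) -> GeneComparison:
    """Turn a best hit into a per-gene verdict (see module docstring).

    When ``target_genome`` is given, truncation detection runs on the
    genome-anchored frame-aligned region rather than the best ORF's own CDS
    (see :func:`frame_aligned_region`); without it, the ORF CDS is used.
    """
    if not 0 < missing_frac < 1:
        raise ValueError("missing_frac must be in (0, 1)")
    orf, score = hit
    L = query.length
    if orf is None or score is None:
        return GeneComparison(
            gene_name=query.gene_name,
            query_length=L,
            status=STATUS_MISSING,
            note="no ORF to align against",
        )
    aln = align_global(query.aa_sequence, orf.aa_sequence, scheme)
    row = GeneComparison(
        gene_name=query.gene_name,
        query_length=L,
        status=STATUS_SUBSTITUTED,
        best_score=score,
        best_orf=orf,
        identity=aln.identity,
        coverage=aln.coverage(L),
    )
    if score == L * scheme.match:
        row.status = STATUS_IDENTICAL
        return row
    probe: Union[Orf, str, None] = orf
    if target_genome is not None:
        probe = frame_aligned_region(query, orf, aln, target_genome) or orf
    evidence = detect_truncation(
        query, probe, trunc_min_identity, trunc_min_codons, trunc_min_lost_codons
    )
    if evidence is not None:
        row.status = STATUS_TRUNCATED
        row.truncation = evidence
        row.exchanges = enumerate_exchanges(aln, query, orf.aa_sequence)
        return row
    if score < missing_frac * L * scheme.match:
        row.status = STATUS_MISSING
        return row
    row.exchanges = enumerate_exchanges(aln, query, orf.aa_sequence)
    row.indels = enumerate_indels(aln, query, orf.aa_sequence)
    return row


def summarize(rows: Sequence[GeneComparison], count_indels_as_exchanges: bool = False) -> ScanSummary:
    summary = ScanSummary(n_queries=len(rows))
    for row in rows:
        if row.status == STATUS_IDENTICAL:
            summary.n_identical += 1
        elif row.status == STATUS_SUBSTITUTED:
            summary.n_substituted += 1
        elif row.status == STATUS_TRUNCATED:
            summary.n_truncated += 1
        else:
            summary.n_missing += 1
        summary.total_exchanges += row.n_exchanges
        if count_indels_as_exchanges:
            summary.total_exchanges += len(row.indels)
    return summary
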