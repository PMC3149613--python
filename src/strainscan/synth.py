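"""Ancestor/mutant genome pairs with planted, fully-ledgered mutations.

This module is the stand-in for a real reference/target strain pair: it
builds an annotated ancestor genome of codon-structured protein-coding genes
and derives a mutant genome carrying planted missense, silent and nonsense
substitutions, single-codon in-frame indels, and whole-gene deletions.
Every event is recorded in a truth table whose protein-level expectations
are computed from the genetic code at planting time, so the whole pipeline
can be validated end to end with no downloads.

Codon sampling is uniform over the 61 sense codons (no codon-usage bias);
mutations are planted on the coding strand with forward-strand bookkeeping
for minus-strand genes, so truth-table codon indices always refer to the
protein reading frame.  At most one event lands in any codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import GeneComparison, STATUS_IDENTICAL, STATUS_MISSING, STATUS_SUBSTITUTED, STATUS_TRUNCATED
from .seqio import (
    AA_TO_CODONS,
    CODON_TO_AA,
    GeneAnnotation,
    GenomeRecord,
    STOP_CLASS,
    reverse_complement,
    translate_cds,
    write_genome_fasta,
    write_gff3,
)

log = logging.getLogger(__name__)

_STOPS = ("TAA", "TAG", "TGA")
_SENSE = tuple(sorted(CODON_TO_AA))
_AAS = tuple(sorted(set(CODON_TO_AA.values())))
_NT = "ACGT"

#: Smallest codon index a random nonsense mutation may hit: the remaining
#: N-terminal prefix must still be discoverable as an ORF (>= default min_aa).
_MIN_NONSENSE_CODON = 31


@dataclass(frozen=True)
class NonsenseSite:
    """An explicitly pinned nonsense mutation (gene, codon, codons involved)."""

    gene_index: int  # 0-based index into the generated gene list
    codon_index: int  # 1-based codon position in the protein reading frame
    ref_codon: str
    stop_codon: str
    gene_length: Optional[int] = None  # force this gene's length (residues)

    def __post_init__(self) -> None:
        if self.stop_codon not in _STOPS:
            raise ValueError(f"{self.stop_codon!r} is not a stop codon")
        if self.ref_codon not in CODON_TO_AA:
            raise ValueError(f"{self.ref_codon!r} is not a sense codon")
        if self.codon_index < 2:
            raise ValueError("nonsense codon index must be internal (>= 2)")


@dataclass(frozen=True)
class MutationSpec:
    """What to build: genome shape plus planted-mutation counts."""

    n_genes: int = 20
    gene_length_range: Tuple[int, int] = (100, 300)  # residues per gene
    n_missense: int = 0
    n_silent: int = 0
    n_nonsense: int = 0
    n_deletions: int = 0
    n_inframe_indels: int = 0
    intergenic_length_range: Tuple[int, int] = (40, 160)
    seed: int = 0
    n_missense_genes: Optional[int] = None  # exact number of genes carrying missense
    nonsense_sites: Tuple[NonsenseSite, ...] = ()
    max_missense_per_gene: int = 12

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("n_missense", "n_silent", "n_nonsense", "n_deletions", "n_inframe_indels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.gene_length_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid gene_length_range")
        ilo, ihi = self.intergenic_length_range
        if not (0 <= ilo <= ihi):
            raise ValueError("invalid intergenic_length_range")
        if self.n_nonsense + self.n_deletions > self.n_genes:
            raise ValueError("n_nonsense + n_deletions cannot exceed n_genes")
        if self.n_nonsense > 0 and lo < _MIN_NONSENSE_CODON + 2 and not self.nonsense_sites:
            raise ValueError(
                f"nonsense mutations need genes of >= {_MIN_NONSENSE_CODON + 2} residues"
            )
        if len(self.nonsense_sites) > self.n_nonsense:
            raise ValueError("more nonsense_sites than n_nonsense")
        if self.n_missense_genes is not None:
            if self.n_missense_genes > self.n_missense:
                raise ValueError("n_missense_genes cannot exceed n_missense")
            if self.n_missense > 0 and self.n_missense_genes < 1:
                raise ValueError("n_missense > 0 needs at least one carrying gene")


@dataclass(frozen=True)
class PlantedEvent:
    gene_name: str
    etype: str  # missense | silent | nonsense | deletion | codon_del | codon_ins
    codon_index: Optional[int]
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    consequence: str  # protein-level expectation, e.g. "R51L", "stop@141:amber"


@dataclass
class ExpectedRow:
    status: str
    exchanges: List[str]
    indels: List[str]
    truncation: Optional[Tuple[int, str]]  # (codon index, stop class)


@dataclass
class TruthTable:
    """Ledger of every planted event; the acceptance oracle for the scan."""

    genes: List[str]
    gene_lengths: Dict[str, int]
    events: Dict[str, List[PlantedEvent]] = field(default_factory=dict)

    def expected_row(self, gene: str) -> ExpectedRow:
        evs = self.events.get(gene, [])
        if any(e.etype == "deletion" for e in evs):
            return ExpectedRow(STATUS_MISSING, [], [], None)
        nonsense = [e for e in evs if e.etype == "nonsense"]
        missense = sorted(
            (e for e in evs if e.etype == "missense"), key=lambda e: e.codon_index or 0
        )
        indels = [e for e in evs if e.etype in ("codon_del", "codon_ins")]
        if nonsense:
            ns = nonsense[0]
            stop_idx = ns.codon_index or 0
            upstream = [e.consequence for e in missense if (e.codon_index or 0) < stop_idx]
            return ExpectedRow(
                STATUS_TRUNCATED, upstream, [], (stop_idx, STOP_CLASS[ns.alt_codon or ""])
            )
        if missense or indels:
            return ExpectedRow(
                STATUS_SUBSTITUTED,
                [e.consequence for e in missense],
                [e.consequence for e in indels],
                None,
            )
        return ExpectedRow(STATUS_IDENTICAL, [], [], None)

    def to_tsv(self, path) -> None:
        lines = ["gene\tgene_length\tevent_type\tcodon_index\tref_codon\talt_codon\tconsequence"]
        for gene in self.genes:
            evs = self.events.get(gene, [])
            if not evs:
                lines.append(f"{gene}\t{self.gene_lengths[gene]}\tnone\t.\t.\t.\t.")
            for e in evs:
                lines.append(
                    "\t".join(
                        [
                            gene,
                            str(self.gene_lengths[gene]),
                            e.etype,
                            str(e.codon_index) if e.codon_index else ".",
                            e.ref_codon or ".",
                            e.alt_codon or ".",
                            e.consequence,
                        ]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        genes: List[str] = []
        lengths: Dict[str, int] = {}
        events: Dict[str, List[PlantedEvent]] = {}
        for line in Path(path).read_text().splitlines()[1:]:
            gene, glen, etype, ci, ref, alt, cons = line.split("\t")
            if gene not in lengths:
                genes.append(gene)
                lengths[gene] = int(glen)
            if etype == "none":
                continue
            events.setdefault(gene, []).append(
                PlantedEvent(
                    gene_name=gene,
                    etype=etype,
                    codon_index=None if ci == "." else int(ci),
                    ref_codon=None if ref == "." else ref,
                    alt_codon=None if alt == "." else alt,
                    consequence=cons,
                )
            )
        return cls(genes=genes, gene_lengths=lengths, events=events)


def _gene_name(i: int) -> str:
    return f"g{i + 1:04d}"


def _locus_tag(i: int) -> str:
    return f"SYN_{i + 1:04d}"


def generate_genome(spec: MutationSpec, genome_id: str = "synthetic_ancestor") -> GenomeRecord:
    """Build the annotated ancestor: ``n_genes`` clean CDSs on random strands
    separated by random intergenic spacers.  Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    lengths = [int(x) for x in rng.integers(lo, hi + 1, size=spec.n_genes)]
    forced_codons: Dict[int, Dict[int, str]] = {}
    for site in spec.nonsense_sites:
        if not 0 <= site.gene_index < spec.n_genes:
            raise ValueError(f"nonsense site gene_index {site.gene_index} out of range")
        if site.gene_length is not None:
            lengths[site.gene_index] = site.gene_length
        if site.codon_index > lengths[site.gene_index]:
            raise ValueError("nonsense site codon_index beyond gene length")
        forced_codons.setdefault(site.gene_index, {})[site.codon_index] = site.ref_codon

    gene_seqs: List[str] = []
    strands: List[int] = []
    for i in range(spec.n_genes):
        L = lengths[i]
        codons = ["ATG"] + [_SENSE[int(k)] for k in rng.integers(0, len(_SENSE), size=L - 1)]
        for ci, codon in forced_codons.get(i, {}).items():
            codons[ci - 1] = codon
        codons.append(_STOPS[int(rng.integers(0, 3))])
        strands.append(1 if int(rng.integers(0, 2)) == 0 else -1)
        gene_seqs.append("".join(codons))

    ilo, ihi = spec.intergenic_length_range
    spacer_lengths = [int(x) for x in rng.integers(ilo, ihi + 1, size=spec.n_genes + 1)]
    spacers = [
        "".join(_NT[int(b)] for b in rng.integers(0, 4, size=sl)) for sl in spacer_lengths
    ]

    parts: List[str] = []
    annotations: List[GeneAnnotation] = []
    pos = 0
    for i in range(spec.n_genes):
        parts.append(spacers[i])
        pos += len(spacers[i])
        nt = gene_seqs[i] if strands[i] == 1 else reverse_complement(gene_seqs[i])
        annotations.append(
            GeneAnnotation(
                gene_name=_gene_name(i),
                locus_tag=_locus_tag(i),
                start=pos + 1,
                end=pos + len(nt),
                strand=strands[i],
            )
        )
        parts.append(nt)
        pos += len(nt)
    parts.append(spacers[-1])
    return GenomeRecord(id=genome_id, sequence="".join(parts), annotations=annotations)


def _sample_position(rng, used: set, lo: int, hi: int, predicate=None, tries: int = 200) -> int:
    """A 1-based codon position in [lo, hi] not already used (rejection sampling)."""
    for _ in range(tries):
        p = int(rng.integers(lo, hi + 1))
        if p in used:
            continue
        if predicate is None or predicate(p):
            used.add(p)
            return p
    raise ValueError("could not place a mutation; gene too small or too crowded")


def plant_mutations(
    ancestor: GenomeRecord, spec: MutationSpec, genome_id: str = "synthetic_mutant"
) -> Tuple[GenomeRecord, TruthTable]:
    """Derive the mutant genome and its truth table from the ancestor."""
    anns = sorted(ancestor.annotations, key=lambda a: a.start)
    if len(anns) != spec.n_genes:
        raise ValueError("ancestor annotation count does not match spec.n_genes")
    rng = np.random.default_rng((spec.seed + 9_999_991) % 2**31)

    codon_lists: List[List[str]] = []
    for ann in anns:
        cds = ancestor.cds_sequence(ann)
        codon_lists.append([cds[k : k + 3] for k in range(0, len(cds), 3)])

    remaining = list(range(spec.n_genes))

    nonsense_idx: List[int] = [s.gene_index for s in spec.nonsense_sites]
    if len(set(nonsense_idx)) != len(nonsense_idx):
        raise ValueError("duplicate gene_index in nonsense_sites")
    extra_nonsense = spec.n_nonsense - len(nonsense_idx)
    pool = [i for i in remaining if i not in nonsense_idx]
    if extra_nonsense > 0:
        eligible = [i for i in pool if len(codon_lists[i]) - 1 >= _MIN_NONSENSE_CODON + 7]
        picked = rng.choice(eligible, size=extra_nonsense, replace=False)
        nonsense_idx += [int(x) for x in picked]
    remaining = [i for i in remaining if i not in nonsense_idx]

    deletion_idx = [int(x) for x in rng.choice(remaining, size=spec.n_deletions, replace=False)] if spec.n_deletions else []
    remaining = [i for i in remaining if i not in deletion_idx]

    indel_idx = [int(x) for x in rng.choice(remaining, size=spec.n_inframe_indels, replace=False)] if spec.n_inframe_indels else []
    remaining = [i for i in remaining if i not in indel_idx]

    missense_counts: Dict[int, int] = {}
    if spec.n_missense > 0:
        m_genes = spec.n_missense_genes or min(spec.n_missense, len(remaining))
        if m_genes > len(remaining):
            raise ValueError("not enough genes left for the requested missense distribution")
        missense_idx = [int(x) for x in rng.choice(remaining, size=m_genes, replace=False)]
        caps = {
            i: max(1, min(spec.max_missense_per_gene, len(codon_lists[i]) // 5))
            for i in missense_idx
        }
        if sum(caps.values()) < spec.n_missense:
            raise ValueError("missense count infeasible under the per-gene cap")
        for i in missense_idx:
            missense_counts[i] = 1
        for _ in range(spec.n_missense - m_genes):
            open_genes = [i for i in missense_idx if missense_counts[i] < caps[i]]
            g = int(rng.choice(open_genes))
            missense_counts[g] += 1
    else:
        missense_idx = []
    untouched_pool = [i for i in remaining if i not in missense_idx]

    truth = TruthTable(
        genes=[a.gene_name for a in anns],
        gene_lengths={a.gene_name: len(codon_lists[i]) - 1 for i, a in enumerate(anns)},
    )

    def add_event(i: int, **kw) -> None:
        truth.events.setdefault(anns[i].gene_name, []).append(
            PlantedEvent(gene_name=anns[i].gene_name, **kw)
        )

    used_positions: Dict[int, set] = {i: set() for i in range(spec.n_genes)}
    for site in spec.nonsense_sites:
        used_positions[site.gene_index].add(site.codon_index)

    # --- nonsense -----------------------------------------------------------
    site_by_gene = {s.gene_index: s for s in spec.nonsense_sites}
    for g in nonsense_idx:
        codons = codon_lists[g]
        L = len(codons) - 1  # residues
        if g in site_by_gene:
            site = site_by_gene[g]
            p, alt = site.codon_index, site.stop_codon
            ref = codons[p - 1]
            if ref != site.ref_codon:
                raise ValueError(
                    f"gene {anns[g].gene_name}: codon {p} is {ref}, expected {site.ref_codon} "
                    "(ancestor not generated from this spec?)"
                )
        else:
            # leave >= 30 prefix residues (ORF discoverability) and lose >= 6
            # tail residues (so the stop is unambiguously premature)
            p = _sample_position(rng, used_positions[g], _MIN_NONSENSE_CODON, L - 6)
            ref = codons[p - 1]
            alt = _STOPS[int(rng.integers(0, 3))]
        codons[p - 1] = alt
        add_event(
            g,
            etype="nonsense",
            codon_index=p,
            ref_codon=ref,
            alt_codon=alt,
            consequence=f"stop@{p}:{STOP_CLASS[alt]}",
        )

    # --- whole-gene deletions ----------------------------------------------
    for g in deletion_idx:
        add_event(g, etype="deletion", codon_index=None, ref_codon=None, alt_codon=None,
                  consequence="gene_deleted")

    # --- missense -----------------------------------------------------------
    for g, count in missense_counts.items():
        codons = codon_lists[g]
        L = len(codons) - 1
        for _ in range(count):
            p = _sample_position(rng, used_positions[g], 2, L)
            ref = codons[p - 1]
            ref_aa = CODON_TO_AA[ref]
            alt_aa = str(rng.choice([a for a in _AAS if a != ref_aa]))
            alt = str(rng.choice(AA_TO_CODONS[alt_aa]))
            codons[p - 1] = alt
            add_event(
                g,
                etype="missense",
                codon_index=p,
                ref_codon=ref,
                alt_codon=alt,
                consequence=f"{ref_aa}{p}{alt_aa}",
            )

    # --- silent --------------------------------------------------------------
    silent_pool = untouched_pool if untouched_pool else missense_idx
    for _ in range(spec.n_silent):
        if not silent_pool:
            raise ValueError("no genes available for silent mutations")
        g = int(rng.choice(silent_pool))
        codons = codon_lists[g]
        L = len(codons) - 1

        def synonymous(p: int, codons=codons) -> bool:
            return len(AA_TO_CODONS[CODON_TO_AA[codons[p - 1]]]) > 1

        p = _sample_position(rng, used_positions[g], 2, L, predicate=synonymous)
        ref = codons[p - 1]
        aa = CODON_TO_AA[ref]
        alt = str(rng.choice([c for c in AA_TO_CODONS[aa] if c != ref]))
        codons[p - 1] = alt
        add_event(g, etype="silent", codon_index=p, ref_codon=ref, alt_codon=alt,
                  consequence="silent")

    # --- in-frame single-codon indels ---------------------------------------
    for n, g in enumerate(indel_idx):
        codons = codon_lists[g]
        L = len(codons) - 1
        aa_of = lambda p: CODON_TO_AA[codons[p - 1]]  # noqa: E731
        if n % 2 == 0:  # deletion of one codon
            def distinct_neighbors(p: int) -> bool:
                return aa_of(p) != aa_of(p - 1) and aa_of(p) != aa_of(p + 1)

            p = _sample_position(rng, used_positions[g], 3, L - 1, predicate=distinct_neighbors)
            ref = codons[p - 1]
            token = f"{aa_of(p)}{p}del"
            del codons[p - 1]
            add_event(g, etype="codon_del", codon_index=p, ref_codon=ref, alt_codon=None,
                      consequence=token)
        else:  # insertion of one codon after position p
            p = _sample_position(rng, used_positions[g], 2, L - 1)
            alt_aa = str(rng.choice([a for a in _AAS if a != aa_of(p) and a != aa_of(p + 1)]))
            alt = str(rng.choice(AA_TO_CODONS[alt_aa]))
            codons.insert(p, alt)
            add_event(g, etype="codon_ins", codon_index=p, ref_codon=None, alt_codon=alt,
                      consequence=f"{p}ins{alt_aa}")

    # --- rebuild the mutant genome ------------------------------------------
    deleted = set(deletion_idx)
    parts: List[str] = []
    new_anns: List[GeneAnnotation] = []
    prev_end = 0
    pos = 0
    for i, ann in enumerate(anns):
        spacer = ancestor.sequence[prev_end : ann.start - 1]
        parts.append(spacer)
        pos += len(spacer)
        prev_end = ann.end
        if i in deleted:
            continue
        cds = "".join(codon_lists[i])
        nt = cds if ann.strand == 1 else reverse_complement(cds)
        new_anns.append(
            GeneAnnotation(
                gene_name=ann.gene_name,
                locus_tag=ann.locus_tag,
                start=pos + 1,
                end=pos + len(nt),
                strand=ann.strand,
            )
        )
        parts.append(nt)
        pos += len(nt)
    parts.append(ancestor.sequence[prev_end:])
    mutant = GenomeRecord(id=genome_id, sequence="".join(parts), annotations=new_anns)
    return mutant, truth


@dataclass
class Discrepancy:
    gene: str
    field: str
    expected: object
    observed: object


def truth_check(rows: Sequence[GeneComparison], truth: TruthTable) -> List[Discrepancy]:
    """Structured diff between a scan report and the planted truth.

    Empty iff every verdict, exchange list, indel annotation, truncation
    codon/class, and missing call matches the ledger.
    """
    out: List[Discrepancy] = []
    by_gene = {r.gene_name: r for r in rows}
    for gene in truth.genes:
        row = by_gene.pop(gene, None)
        if row is None:
            out.append(Discrepancy(gene, "presence", "a report row", "absent"))
            continue
        exp = truth.expected_row(gene)
        if row.status != exp.status:
            out.append(Discrepancy(gene, "status", exp.status, row.status))
        observed_ex = [e.token for e in row.exchanges]
        if observed_ex != exp.exchanges:
            out.append(Discrepancy(gene, "exchanges", exp.exchanges, observed_ex))
        if row.indels != exp.indels:
            out.append(Discrepancy(gene, "indels", exp.indels, row.indels))
        observed_tr = (
            (row.truncation.stop_codon_index, row.truncation.stop_class)
            if row.truncation
            else None
        )
        if observed_tr != exp.truncation:
            out.append(Discrepancy(gene, "truncation", exp.truncation, observed_tr))
    for gene in by_gene:
        out.append(Discrepancy(gene, "presence", "absent", "unexpected report row"))
    return out


# ---------------------------------------------------------------------------
# Shipped fixture shapes
# ---------------------------------------------------------------------------

DEFAULT_FIXTURE_SEED = 101


def flagship_spec(seed: int = DEFAULT_FIXTURE_SEED) -> MutationSpec:
    """The flagship strain-pair shape: 86 candidate genes, 42 of them carrying
    78 missense exchanges in total, 5 whole-gene deletions, and one nonsense
    mutation converting CAG to the amber stop TAG at codon 141 of a
    250-residue gene."""
    return MutationSpec(
        n_genes=86,
        gene_length_range=(150, 450),
        n_missense=78,
        n_missense_genes=42,
        n_silent=0,
        n_nonsense=1,
        n_deletions=5,
        n_inframe_indels=0,
        intergenic_length_range=(40, 160),
        seed=seed,
        nonsense_sites=(
            NonsenseSite(gene_index=45, codon_index=141, ref_codon="CAG",
                         stop_codon="TAG", gene_length=250),
        ),
    )


def silent_spec(seed: int = DEFAULT_FIXTURE_SEED) -> MutationSpec:
    """Silent-substitutions-only mutant: the scan must not see any change."""
    return MutationSpec(
        n_genes=25,
        gene_length_range=(80, 200),
        n_silent=40,
        intergenic_length_range=(30, 100),
        seed=seed,
    )


def smoke_spec(seed: int = DEFAULT_FIXTURE_SEED) -> MutationSpec:
    """A small mixed fixture exercising every event class."""
    return MutationSpec(
        n_genes=12,
        gene_length_range=(60, 150),
        n_missense=5,
        n_missense_genes=3,
        n_silent=2,
        n_nonsense=1,
        n_deletions=1,
        n_inframe_indels=2,
        intergenic_length_range=(20, 80),
        seed=seed,
        nonsense_sites=(
            NonsenseSite(gene_index=7, codon_index=40, ref_codon="CAG",
                         stop_codon="TAA", gene_length=90),
        ),
    )


def make_pair(spec: MutationSpec) -> Tuple[GenomeRecord, GenomeRecord, TruthTable]:
    ancestor = generate_genome(spec)
    mutant, truth = plant_mutations(ancestor, spec)
    return ancestor, mutant, truth


def write_fixture(outdir, spec: MutationSpec, prefix: str) -> Dict[str, Path]:
    """Materialize a fixture pair as FASTA + GFF3 + truth TSV + gene list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ancestor, mutant, truth = make_pair(spec)
    paths = {
        "ancestor_fasta": outdir / f"{prefix}_ancestor.fasta",
        "ancestor_gff3": outdir / f"{prefix}_ancestor.gff3",
        "mutant_fasta": outdir / f"{prefix}_mutant.fasta",
        "mutant_gff3": outdir / f"{prefix}_mutant.gff3",
        "truth_tsv": outdir / f"{prefix}_truth.tsv",
        "genes_txt": outdir / f"{prefix}_genes.txt",
    }
    write_genome_fasta(ancestor, paths["ancestor_fasta"])
    write_gff3(ancestor, paths["ancestor_gff3"])
    write_genome_fasta(mutant, paths["mutant_fasta"])
    write_gff3(mutant, paths["mutant_gff3"])
    truth.to_tsv(paths["truth_tsv"])
    paths["genes_txt"].write_text("\n".join(truth.genes) + "\n")
    return paths
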