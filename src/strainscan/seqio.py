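"""Sequence I/O and genetic-code translation.

Reads genomes from FASTA or GenBank (Biopython), attaches GFF3 annotation
(gffutils), translates CDSs under NCBI genetic code table 11 (the bacterial
code; *E. coli* context) and extracts candidate proteins from annotation.

Coordinates are 1-based inclusive (GenBank convention) at every interface.
Nucleotide alphabet is {A,C,G,T,N}; any other ambiguity character is
rejected with an explicit error rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")

#: Start codons translated as Met when in initial position (bacterial convention).
BACTERIAL_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CLASS = {"TAG": "amber", "TAA": "ochre", "TGA": "opal"}


def _code_table(table_id: int = 11) -> Tuple[Dict[str, str], frozenset]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


CODON_TO_AA, STOP_CODONS = _code_table(11)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 codons for table 11
AA_TO_CODONS: Dict[str, Tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)


class SequenceFormatError(ValueError):
    """Unparsable or malformed input file."""


class FrameError(ValueError):
    """CDS length is not a multiple of three."""


class AmbiguousCandidateError(ValueError):
    """A candidate gene name resolves to more than one CDS annotation."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class GeneAnnotation:
    """A gene/CDS interval on forward-strand 1-based inclusive coordinates."""

    gene_name: str
    locus_tag: str
    start: int
    end: int
    strand: int  # +1 | -1
    is_cds: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"annotation {self.gene_name}: start {self.start} > end {self.end}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"annotation {self.gene_name}: strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with optional gene annotations."""

    id: str
    sequence: str
    annotations: List[GeneAnnotation] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - NUCLEOTIDES
        if bad:
            raise SequenceFormatError(
                f"genome {self.id}: invalid nucleotide(s) {sorted(bad)}; "
                "allowed: A,C,G,T,N"
            )
        for ann in self.annotations:
            if ann.start < 1 or ann.end > len(self.sequence):
                if self.topology != "circular":
                    raise ValueError(
                        f"annotation {ann.gene_name} [{ann.start},{ann.end}] outside "
                        f"genome {self.id} of length {len(self.sequence)}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_sequence(self, ann: GeneAnnotation) -> str:
        """Strand-resolved coding sequence for an annotation."""
        nt = self.sequence[ann.start - 1 : ann.end]
        return reverse_complement(nt) if ann.strand == -1 else nt


@dataclass
class ProteinRecord:
    """An annotation-derived query protein (the reference side of the scan)."""

    gene_name: str
    aa_sequence: str
    source_cds: str

    @property
    def length(self) -> int:
        return len(self.aa_sequence)


@dataclass
class Translation:
    aa_sequence: str
    stop_index: Optional[int]  # 1-based codon index of the first stop, if any
    stop_codon: Optional[str]

    @property
    def has_stop(self) -> bool:
        return self.stop_index is not None


def translate_cds(cds: str, table: int = 11, bacterial_start: bool = True) -> Translation:
    """Translate a CDS up to (excluding) the first stop codon.

    Codons containing ``N`` translate as ``X`` and never count as stops.
    ``ATG``/``GTG``/``TTG`` in initial position translate as ``M`` when
    ``bacterial_start`` is set.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    bad = set(cds) - NUCLEOTIDES
    if bad:
        raise SequenceFormatError(f"invalid nucleotide(s) in CDS: {sorted(bad)}")
    if table == 11:
        forward, stops = CODON_TO_AA, STOP_CODONS
    else:
        forward, stops = _code_table(table)
    residues: List[str] = []
    for idx in range(0, len(cds), 3):
        codon = cds[idx : idx + 3]
        if "N" in codon:
            residues.append("X")
            continue
        if codon in stops:
            return Translation("".join(residues), idx // 3 + 1, codon)
        if idx == 0 and bacterial_start and codon in BACTERIAL_START_CODONS:
            residues.append("M")
        else:
            residues.append(forward[codon])
    return Translation("".join(residues), None, None)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    if suffix in {".gb", ".gbk", ".gbff", ".genbank"}:
        return "genbank"
    raise SequenceFormatError(f"cannot infer sequence format from {path.name!r}")


def read_genome(path, fmt: Optional[str] = None) -> GenomeRecord:
    """Read the first record of a FASTA or GenBank file as a GenomeRecord.

    GenBank CDS features become GeneAnnotation entries; FASTA yields no
    annotations (attach a GFF3 with :func:`attach_gff3`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except ValueError as exc:
        raise SequenceFormatError(f"{path}: {exc}") from exc
    if not records:
        raise SequenceFormatError(f"{path}: no sequence records found")
    if len(records) > 1:
        log.warning("%s: %d records; using the first (%s)", path, len(records), records[0].id)
    rec = records[0]
    sequence = str(rec.seq).upper()
    annotations: List[GeneAnnotation] = []
    topology = "linear"
    if fmt == "genbank":
        topology = rec.annotations.get("topology", "linear")
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) > 1:
                log.warning(
                    "%s: skipping compound-location CDS %s (no splicing support)",
                    path,
                    feat.qualifiers.get("locus_tag", ["?"])[0],
                )
                continue
            locus = feat.qualifiers.get("locus_tag", [""])[0]
            gene = feat.qualifiers.get("gene", [locus])[0]
            annotations.append(
                GeneAnnotation(
                    gene_name=gene or locus,
                    locus_tag=locus or gene,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand=1 if (feat.location.strand or 1) >= 0 else -1,
                )
            )
    return GenomeRecord(id=rec.id, sequence=sequence, annotations=annotations, topology=topology)


def attach_gff3(genome: GenomeRecord, gff_path) -> GenomeRecord:
    """Attach CDS features from a GFF3 file to a genome (in place).

    The GFF3 ``seqid`` must match the genome id.
    """
    import gffutils

    gff_path = Path(gff_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    n = 0
    for feat in db.features_of_type("CDS", order_by="start"):
        if feat.seqid != genome.id:
            raise SequenceFormatError(
                f"{gff_path}: seqid {feat.seqid!r} does not match genome id {genome.id!r}"
            )
        locus = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [""])[0]
        gene = (feat.attributes.get("gene") or feat.attributes.get("Name") or [locus])[0]
        genome.annotations.append(
            GeneAnnotation(
                gene_name=gene or locus,
                locus_tag=locus or gene,
                start=feat.start,
                end=feat.end,
                strand=-1 if feat.strand == "-" else 1,
            )
        )
        n += 1
    if n == 0:
        log.warning("%s: no CDS features found", gff_path)
    genome.__post_init__()  # re-validate intervals
    return genome


@dataclass
class UnresolvedCandidate:
    name: str
    reason: str


def extract_annotated_proteins(
    genome: GenomeRecord, candidates: Sequence[str]
) -> Tuple[List[ProteinRecord], List[UnresolvedCandidate]]:
    """Resolve candidate gene names/locus tags to translated ProteinRecords.

    Candidates that cannot be resolved (absent, frame violation, internal or
    missing stop) are returned in the unresolved list, never silently fixed.
    A candidate matching more than one CDS raises AmbiguousCandidateError.
    """
    by_name: Dict[str, List[GeneAnnotation]] = {}
    for ann in genome.annotations:
        if not ann.is_cds:
            continue
        by_name.setdefault(ann.gene_name, []).append(ann)
        if ann.locus_tag != ann.gene_name:
            by_name.setdefault(ann.locus_tag, []).append(ann)
    proteins: List[ProteinRecord] = []
    unresolved: List[UnresolvedCandidate] = []
    for name in candidates:
        matches = by_name.get(name, [])
        if not matches:
            unresolved.append(UnresolvedCandidate(name, "no matching CDS annotation"))
            continue
        if len(matches) > 1:
            where = ", ".join(f"{a.start}..{a.end}" for a in matches)
            raise AmbiguousCandidateError(
                f"candidate {name!r} matches {len(matches)} CDS annotations ({where})"
            )
        ann = matches[0]
        cds = genome.cds_sequence(ann)
        if len(cds) % 3 != 0:
            unresolved.append(
                UnresolvedCandidate(name, f"CDS length {len(cds)} not divisible by 3")
            )
            continue
        tr = translate_cds(cds)
        n_codons = len(cds) // 3
        if not tr.has_stop:
            unresolved.append(UnresolvedCandidate(name, "CDS has no stop codon"))
            continue
        if tr.stop_index != n_codons:
            unresolved.append(
                UnresolvedCandidate(name, f"internal stop at codon {tr.stop_index}")
            )
            continue
        proteins.append(ProteinRecord(gene_name=name, aa_sequence=tr.aa_sequence, source_cds=cds))
    return proteins, unresolved


def write_fasta(entries: Iterable[Tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as a FASTA file."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def write_genome_fasta(genome: GenomeRecord, path) -> None:
    write_fasta([(genome.id, genome.sequence)], path)


def write_gff3(genome: GenomeRecord, path) -> None:
    """Write the genome's CDS annotations as GFF3."""
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {len(genome)}"]
    for ann in genome.annotations:
        strand = "+" if ann.strand == 1 else "-"
        attrs = f"ID={ann.locus_tag};locus_tag={ann.locus_tag};gene={ann.gene_name}"
        lines.append(
            "\t".join(
                [genome.id, "strainscan", "CDS", str(ann.start), str(ann.end), ".", strand, "0", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> List[str]:
    """One gene name or locus tag per line; blank lines and '#' comments skipped."""
    names: List[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names
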