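"""Report rendering: per-gene TSV and summary JSON.

The TSV schema mirrors a strain-comparison supplementary table: one row per
candidate gene with its verdict, the semicolon-joined exchange tokens
("R51L" style), indel annotations, best score/identity/coverage, the best
ORF's coordinates, and truncation evidence.  Rendering is deterministic so
repeated scans produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .classify import GeneComparison, ScanSummary
from .config import ScanConfig
from .seqio import UnresolvedCandidate

REPORT_COLUMNS = [
    "gene",
    "query_length",
    "status",
    "n_exchanges",
    "exchanges",
    "indels",
    "best_score",
    "identity",
    "coverage",
    "orf_coordinates",
    "truncation_codon",
    "stop_class",
    "notes",
]

_MISSING_FIELD = "."


def _orf_coords(row: GeneComparison) -> str:
    if row.best_orf is None:
        return _MISSING_FIELD
    o = row.best_orf
    return f"{o.start}..{o.end}({'+' if o.strand == 1 else '-'})"


def render_report(rows: Sequence[GeneComparison]) -> str:
    lines = ["\t".join(REPORT_COLUMNS)]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    row.gene_name,
                    str(row.query_length),
                    row.status,
                    str(row.n_exchanges),
                    ";".join(e.token for e in row.exchanges) or _MISSING_FIELD,
                    ";".join(row.indels) or _MISSING_FIELD,
                    str(row.best_score) if row.best_score is not None else _MISSING_FIELD,
                    f"{row.identity:.4f}",
                    f"{row.coverage:.4f}",
                    _orf_coords(row),
                    str(row.truncation.stop_codon_index) if row.truncation else _MISSING_FIELD,
                    row.truncation.stop_class if row.truncation else _MISSING_FIELD,
                    row.note or _MISSING_FIELD,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_report(rows: Sequence[GeneComparison], path) -> None:
    Path(path).write_text(render_report(rows))


def render_summary(
    summary: ScanSummary,
    config: ScanConfig,
    unresolved: Sequence[UnresolvedCandidate] = (),
    extra: Optional[Dict] = None,
) -> str:
    payload: Dict = {
        "summary": summary.as_dict(),
        "unresolved": [{"gene": u.name, "reason": u.reason} for u in unresolved],
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def write_summary(
    summary: ScanSummary,
    config: ScanConfig,
    path,
    unresolved: Sequence[UnresolvedCandidate] = (),
    extra: Optional[Dict] = None,
) -> None:
    Path(path).write_text(render_summary(summary, config, unresolved, extra))
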