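"""Scan configuration: defaults, YAML loading, and CLI overrides.

Precedence is CLI flag > config file > built-in default.  The full resolved
configuration is echoed verbatim into the summary JSON so a scan can be
rerun identically from its own output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, List, Optional

import yaml

from .align import ScoringScheme
from .orfs import DEFAULT_START_CODONS, DEFAULT_STOP_CODONS

MODE_SIX_FRAME = "six-frame"
MODE_ANNOTATED = "annotated"


@dataclass(frozen=True)
class ScoringConfig:
    match: int = 1
    mismatch: int = -1
    gap: int = -1
    affine: bool = False
    gap_open: int = -2
    gap_extend: int = -1

    def scheme(self) -> ScoringScheme:
        if self.affine:
            return ScoringScheme(
                match=self.match,
                mismatch=self.mismatch,
                gap=self.gap,
                gap_open=self.gap_open,
                gap_extend=self.gap_extend,
            )
        return ScoringScheme(match=self.match, mismatch=self.mismatch, gap=self.gap)


@dataclass(frozen=True)
class OrfConfig:
    min_aa: int = 30
    start_codons: tuple = tuple(sorted(DEFAULT_START_CODONS))
    stop_codons: tuple = tuple(sorted(DEFAULT_STOP_CODONS))
    emit_nested_starts: bool = True
    mode: str = MODE_SIX_FRAME  # six-frame | annotated

    def __post_init__(self) -> None:
        if self.mode not in (MODE_SIX_FRAME, MODE_ANNOTATED):
            raise ValueError(f"unknown ORF mode {self.mode!r}")


@dataclass(frozen=True)
class ClassifyConfig:
    missing_frac: float = 0.5
    count_indels_as_exchanges: bool = False
    trunc_min_identity: float = 0.9
    trunc_min_codons: int = 10
    trunc_min_lost_codons: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.missing_frac < 1:
            raise ValueError("missing_frac must be in (0, 1)")


@dataclass(frozen=True)
class PrefilterConfig:
    enabled: bool = True
    k: int = 6


@dataclass(frozen=True)
class ScanConfig:
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    orf: OrfConfig = field(default_factory=OrfConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    seed: int = 0

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["orf"]["start_codons"] = list(d["orf"]["start_codons"])
        d["orf"]["stop_codons"] = list(d["orf"]["stop_codons"])
        return d

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "ScanConfig":
        def sub(klass, key):
            payload = dict(data.get(key, {}))
            if key == "orf":
                for f in ("start_codons", "stop_codons"):
                    if f in payload:
                        payload[f] = tuple(sorted(payload[f]))
            return klass(**payload)

        return cls(
            scoring=sub(ScoringConfig, "scoring"),
            orf=sub(OrfConfig, "orf"),
            classify=sub(ClassifyConfig, "classify"),
            prefilter=sub(PrefilterConfig, "prefilter"),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def with_overrides(self, **overrides: Any) -> "ScanConfig":
        """Apply flat dotted overrides, e.g. scoring_match=2, prefilter_enabled=False.

        None values are ignored so absent CLI flags fall through to the
        config-file / default value.
        """
        cfg = self
        groups: Dict[str, Dict[str, Any]] = {}
        for key, value in overrides.items():
            if value is None:
                continue
            group, _, name = key.partition("_")
            groups.setdefault(group, {})[name] = value
        for group, fields in groups.items():
            if group == "seed":
                cfg = replace(cfg, seed=fields[""])
                continue
            current = getattr(cfg, group)
            cfg = replace(cfg, **{group: replace(current, **fields)})
        return cfg
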