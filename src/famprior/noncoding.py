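"""Non-coding variant prioritization.

Restricts a classified call set to non-coding classes, applies the same
three-database rarity rule as the coding funnel, then requires evolutionary
constraint (containment in a conserved element scoring > 2 rejected
substitutions) and regulatory evidence (an "active promoter" or "strong
enhancer" chromatin state from a 15-state segmentation of the GM12878
lymphoblastoid line).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .coding import FunnelReport, filter_by_frequency
from .intervals import GenomicInterval
from .variants import AnnotatedVariant, NONCODING_CLASSES

__all__ = [
    "ConservedElement",
    "ChromatinStateMap",
    "filter_noncoding",
    "filter_conserved",
    "filter_chromatin_state",
    "run_noncoding_funnel",
]


@dataclass(frozen=True)
class ConservedElement:
    """An evolutionarily constrained element with its rejected-substitution score."""

    interval: GenomicInterval
    element_score: float


class _IntervalLookup:
    """Sorted per-chromosome point-in-interval lookup (intervals may be assumed
    non-overlapping, as in chromatin segmentations; for conserved elements the
    best-scoring containing element wins)."""

    def __init__(self, records: Sequence[Tuple[GenomicInterval, object]]) -> None:
        self._by_chrom: Dict[str, List[Tuple[int, int, object]]] = {}
        for iv, payload in records:
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, payload))
        for spans in self._by_chrom.values():
            spans.sort()

    def at(self, chrom: str, pos: int) -> List[object]:
        spans = self._by_chrom.get(chrom, [])
        out = []
        i = bisect.bisect_right(spans, (pos, float("inf"), None))
        for s, e, payload in spans[:i]:
            if s <= pos <= e:
                out.append(payload)
        return out


class ChromatinStateMap:
    """Genome segmentation into numbered chromatin states (1..15)."""

    def __init__(self, intervals: Sequence[Tuple[GenomicInterval, int]]) -> None:
        for iv, state in intervals:
            if not 1 <= int(state) <= 15:
                raise ValueError(f"chromatin state {state} outside 1..15 at {iv}")
        self._lookup = _IntervalLookup([(iv, int(s)) for iv, s in intervals])

    @classmethod
    def from_bed_records(cls, records: Sequence[Tuple[GenomicInterval, Optional[str]]]):
        parsed = []
        for iv, label in records:
            if label is None:
                raise ValueError(f"chromatin BED record at {iv} lacks a state column")
            # accept "4" or chromHMM-style "4_Strong_Enhancer"
            parsed.append((iv, int(str(label).split("_")[0])))
        return cls(parsed)

    def state_at(self, chrom: str, pos: int) -> Optional[int]:
        states = self._lookup.at(chrom, pos)
        return states[0] if states else None


def filter_noncoding(variants: Sequence[AnnotatedVariant]) -> List[AnnotatedVariant]:
    """Keep variants outside protein-coding sequence and canonical splice sites."""
    return [v for v in variants if v.function_class in NONCODING_CLASSES]


def filter_conserved(
    variants: Sequence[AnnotatedVariant],
    elements: Sequence[ConservedElement],
    score_min: float = 2.0,
) -> List[AnnotatedVariant]:
    """Keep variants inside a conserved element with score > ``score_min``."""
    lookup = _IntervalLookup([(e.interval, e.element_score) for e in elements])
    out = []
    for v in variants:
        scores = lookup.at(v.variant.chrom, v.variant.pos)
        if any(s > score_min for s in scores):
            out.append(v)
    return out


def filter_chromatin_state(
    variants: Sequence[AnnotatedVariant],
    states: ChromatinStateMap,
    keep: Optional[Mapping[int, str]] = None,
) -> List[Tuple[AnnotatedVariant, str]]:
    """Keep variants in retained chromatin states, labelled with the state class."""
    if keep is None:
        keep = {1: "active promoter", 4: "strong enhancer", 5: "strong enhancer"}
    out = []
    for v in variants:
        st = states.state_at(v.variant.chrom, v.variant.pos)
        if st is not None and st in keep:
            out.append((v, keep[st]))
    return out


@dataclass
class NoncodingFunnelResult:
    prioritized: List[Tuple[AnnotatedVariant, str]]
    report: FunnelReport = field(default_factory=FunnelReport)

    def by_class(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for _, cls in self.prioritized:
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def run_noncoding_funnel(
    variants: Sequence[AnnotatedVariant],
    elements: Sequence[ConservedElement],
    states: ChromatinStateMap,
    known_databases: Sequence[str],
    config: Optional[dict] = None,
) -> NoncodingFunnelResult:
    """Chain the non-coding filters over (already shared) classified variants."""
    from .config import DEFAULTS, get

    cfg = config or DEFAULTS
    report = FunnelReport()
    sample = "shared"

    nc = filter_noncoding(variants)
    report.add("noncoding_classes", sample, len(variants), len(nc))

    try:
        rare = filter_by_frequency(
            nc,
            list(get(cfg, "maf.databases")),
            get(cfg, "maf.threshold"),
            known_databases=known_databases,
        )
    except ValueError as exc:
        raise ValueError(f"stage 'maf' failed: {exc}") from exc
    report.add("maf", sample, len(nc), len(rare))

    conserved = filter_conserved(rare, elements, get(cfg, "noncoding.conserved_score_min"))
    report.add("conserved_elements", sample, len(rare), len(conserved))

    keep = {int(k): v for k, v in get(cfg, "noncoding.chromatin_keep").items()}
    prioritized = filter_chromatin_state(conserved, states, keep)
    report.add("chromatin_states", sample, len(conserved), len(prioritized))

    return NoncodingFunnelResult(prioritized=prioritized, report=report)
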