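"""Variant and gene-model data types.

A :class:`Variant` is a called SNV or small indel with zygosity and a call
quality on the scale ``10*log10[P(call true)/P(call false)]``.  An
:class:`AnnotatedVariant` adds its functional class relative to a gene model,
per-database minor allele frequencies, and deleteriousness scores (SIFT,
PolyPhen, GERP++) consumed as annotation inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

from .intervals import GenomicInterval

__all__ = [
    "Variant",
    "AnnotatedVariant",
    "GeneModel",
    "FUNCTION_CLASSES",
    "CODING_CLASSES",
    "NONCODING_CLASSES",
    "SEVERITY_ORDER",
]

#: All recognized functional classes.
FUNCTION_CLASSES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "stopgain",
        "stoploss",
        "frameshift",
        "nonframeshift",
        "splicing",
        "UTR",
        "intronic",
        "upstream",
        "downstream",
        "intergenic",
        "noncoding-gene",
    }
)

#: Classes that change a protein product or canonical splicing.
CODING_CLASSES = frozenset(
    {"nonsynonymous", "stopgain", "stoploss", "frameshift", "nonframeshift", "splicing"}
)

#: The complement: classes retained by the non-coding pipeline.  Synonymous
#: variants are exonic, so they belong to neither funnel's keep-set.
NONCODING_CLASSES = frozenset(
    {"UTR", "intronic", "upstream", "downstream", "intergenic", "noncoding-gene"}
)

#: Most to least deleterious; used when a variant hits several transcripts.
SEVERITY_ORDER: Sequence[str] = (
    "stopgain",
    "frameshift",
    "stoploss",
    "splicing",
    "nonsynonymous",
    "nonframeshift",
    "synonymous",
    "UTR",
    "noncoding-gene",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)


@dataclass(frozen=True)
class Variant:
    """A called variant: single base for SNVs, a span for indels."""

    interval: GenomicInterval
    ref: str
    alt: str
    zygosity: str  # "het" or "hom"
    quality: Optional[float] = None  # 10*log10[P(true)/P(false)]; None = absent

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.interval}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be 'het' or 'hom', got {self.zygosity!r}")
        if self.quality is not None and self.quality < 0:
            raise ValueError(f"negative quality {self.quality} at {self.interval}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def pos(self) -> int:
        return self.interval.start

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple:
        """Site identity used to match variants between individuals."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant plus functional annotation.

    ``maf`` maps database name -> minor allele frequency; an absent key means
    the variant was not observed in that database.  Score fields are ``None``
    when the upstream annotator provides no prediction (typical for
    frameshift and splicing variants).
    """

    variant: Variant
    function_class: str
    gene: Optional[str] = None
    maf: Dict[str, float] = field(default_factory=dict)
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    gerp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.function_class not in FUNCTION_CLASSES:
            raise ValueError(f"unknown function class {self.function_class!r}")
        for db, f in self.maf.items():
            if not 0.0 <= f <= 0.5:
                raise ValueError(f"MAF {f} for {db!r} outside [0, 0.5]")
        for name, score in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} score {score} outside [0, 1]")

    @property
    def key(self) -> tuple:
        return self.variant.key

    def with_scores(self, sift=None, polyphen=None, gerp=None) -> "AnnotatedVariant":
        return replace(self, sift=sift, polyphen=polyphen, gerp=gerp)


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered exons, coding subintervals, optional CDS sequence.

    ``cds_seq`` is the spliced coding sequence read 5'→3' on the coding strand;
    when present, exonic SNVs are classified by codon translation.  ``cds``
    intervals are in genomic coordinates and must lie inside exons.
    """

    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: Sequence[GenomicInterval]
    cds: Sequence[GenomicInterval] = ()
    cds_seq: Optional[str] = None
    splice_window: int = 2

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ex = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(ex, ex[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping exons in {self.gene}: {a} / {b}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in ex):
                raise ValueError(f"CDS interval {c} of {self.gene} outside exons")
        cds_len = sum(c.length for c in self.cds)
        if self.cds_seq is not None and len(self.cds_seq) != cds_len:
            raise ValueError(
                f"{self.gene}: CDS sequence length {len(self.cds_seq)} != "
                f"CDS interval total {cds_len}"
            )

    @property
    def tx_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def tx_end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return len(self.cds) > 0

    def sorted_exons(self) -> List[GenomicInterval]:
        return sorted(self.exons, key=lambda iv: iv.start)

    def sorted_cds(self) -> List[GenomicInterval]:
        return sorted(self.cds, key=lambda iv: iv.start)

    def cds_offset(self, pos: int) -> Optional[int]:
        """0-based offset of genomic ``pos`` in the spliced CDS (strand-aware)."""
        fwd = 0
        found = None
        for c in self.sorted_cds():
            if c.start <= pos <= c.end:
                found = fwd + (pos - c.start)
            fwd += c.length
        if found is None:
            return None
        return found if self.strand == "+" else fwd - 1 - found
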