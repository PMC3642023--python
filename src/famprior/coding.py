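"""Coding-variant reduction funnel and recessive gene model.

The funnel shrinks a whole-genome call set to a shortlist of candidate genes
for each sequenced proband:

1. call-quality filter (homozygous >= 20, heterozygous >= 40);
2. gene-based functional classification, keeping variants that alter the
   protein or canonical splicing;
3. rarity filter: drop anything with MAF > 1% in any reference database;
4. recessive gene model: a gene qualifies when it carries a homozygous
   qualifying variant or at least two distinct heterozygous ones (compound
   heterozygosity, unphased);
5. intersection of the two probands' candidate gene sets.

An alternative model-free route takes the rare coding variants shared by both
probands and keeps those concordantly predicted deleterious by SIFT, PolyPhen
and GERP++ (missing predictions passing by default).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Seq import Seq

from .variants import (
    AnnotatedVariant,
    CODING_CLASSES,
    GeneModel,
    SEVERITY_ORDER,
    Variant,
)

__all__ = [
    "FunnelReport",
    "filter_by_quality",
    "classify_variant",
    "classify_variants",
    "filter_coding_changes",
    "filter_by_frequency",
    "recessive_gene_candidates",
    "shared_candidates",
    "deleteriousness_filter",
    "run_coding_funnel",
]

_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass
class FunnelReport:
    """Per-stage, per-sample bookkeeping of the variants-reduction cascade."""

    rows: List[Tuple[str, str, int, int]] = field(default_factory=list)  # stage, sample, in, out

    def add(self, stage: str, sample: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r} grew the variant set ({n_in} -> {n_out})")
        self.rows.append((stage, sample, n_in, n_out))

    def counts(self, sample: str) -> List[Tuple[str, int, int]]:
        return [(s, i, o) for s, smp, i, o in self.rows if smp == sample]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tsample\tvariants_in\tvariants_out\n")
            for stage, sample, n_in, n_out in self.rows:
                fh.write(f"{stage}\t{sample}\t{n_in}\t{n_out}\n")


# ---------------------------------------------------------------------------
# Stage 1: call quality
# ---------------------------------------------------------------------------

def filter_by_quality(
    variants: Sequence[Variant], hom_min: float = 20.0, het_min: float = 40.0
) -> Tuple[List[Variant], int]:
    """Drop low-confidence calls; returns (survivors, n_missing_quality).

    Homozygous calls need quality >= ``hom_min``, heterozygous calls
    >= ``het_min``.  Calls with no quality at all are removed and counted
    separately — they signal an upstream caller omission.
    """
    kept: List[Variant] = []
    n_missing = 0
    for v in variants:
        if v.quality is None:
            n_missing += 1
            continue
        cutoff = hom_min if v.zygosity == "hom" else het_min
        if v.quality >= cutoff:
            kept.append(v)
    return kept, n_missing


# ---------------------------------------------------------------------------
# Stage 2: gene-based classification
# ---------------------------------------------------------------------------

class GeneIndex:
    """Per-chromosome sorted index of gene models for interval queries."""

    def __init__(self, genes: Iterable[GeneModel], flank_bp: int = 1000) -> None:
        self.flank_bp = flank_bp
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: Dict[str, List[int]] = {}
        for chrom, gs in self._by_chrom.items():
            gs.sort(key=lambda g: g.tx_start)
            self._starts[chrom] = [g.tx_start for g in gs]

    def overlapping(self, chrom: str, start: int, end: int) -> List[GeneModel]:
        gs = self._by_chrom.get(chrom, [])
        if not gs:
            return []
        lo, hi = start - self.flank_bp, end + self.flank_bp
        # genes are point-indexed by tx_start; scan a generous left window
        i = bisect.bisect_right(self._starts[chrom], hi)
        out = []
        for g in gs[:i]:
            if g.tx_end + self.flank_bp >= start and g.tx_start - self.flank_bp <= end:
                out.append(g)
        return out


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _classify_in_gene(v: Variant, g: GeneModel, flank_bp: int) -> Optional[str]:
    pos = v.pos
    if not (g.tx_start - flank_bp <= pos <= g.tx_end + flank_bp):
        return None
    exons = g.sorted_exons()
    if g.tx_start <= pos <= g.tx_end:
        in_exon = any(e.start <= pos <= e.end for e in exons)
        if in_exon:
            if not g.is_coding:
                return "noncoding-gene"
            in_cds = any(c.start <= pos <= c.end for c in g.sorted_cds())
            if not in_cds:
                return "UTR"
            if v.is_snv:
                return _classify_snv_in_cds(v, g)
            indel_len = abs(len(v.ref) - len(v.alt))
            return "frameshift" if indel_len % 3 != 0 else "nonframeshift"
        # intronic side: within splice_window bp of an exon boundary -> splicing
        for e in exons:
            if 0 < e.start - pos <= g.splice_window or 0 < pos - e.end <= g.splice_window:
                return "splicing"
        return "intronic"
    # flanking region, strand-aware
    if pos < g.tx_start:
        return "upstream" if g.strand == "+" else "downstream"
    return "downstream" if g.strand == "+" else "upstream"


def _classify_snv_in_cds(v: Variant, g: GeneModel) -> str:
    if g.cds_seq is None:
        # no sequence on the model: keep the variant in the funnel
        return "nonsynonymous"
    off = g.cds_offset(v.pos)
    assert off is not None
    ref_base, alt_base = v.ref, v.alt
    if g.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if g.cds_seq[off].upper() != ref_base.upper():
        raise ValueError(
            f"reference mismatch at {v.interval} in {g.gene}: "
            f"model has {g.cds_seq[off]!r}, variant ref implies {ref_base!r}"
        )
    ci = off // 3
    codon = g.cds_seq[3 * ci : 3 * ci + 3]
    if len(codon) < 3:  # trailing partial codon in a toy model
        return "nonsynonymous"
    mutant = codon[: off % 3] + alt_base + codon[off % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutant).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stopgain"
    if aa_ref == "*":
        return "stoploss"
    return "nonsynonymous"


def classify_variant(
    v: Variant, genes: "GeneIndex | Sequence[GeneModel]", flank_bp: int = 1000
) -> AnnotatedVariant:
    """Assign the single most deleterious functional class across gene models."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, flank_bp)
    if len(v.ref) != v.interval.length:
        raise ValueError(
            f"ref allele length {len(v.ref)} inconsistent with interval {v.interval}"
        )
    best_class, best_gene = "intergenic", None
    for g in index.overlapping(v.chrom, v.interval.start, v.interval.end):
        cls = _classify_in_gene(v, g, index.flank_bp)
        if cls is not None and _SEVERITY_RANK[cls] < _SEVERITY_RANK[best_class]:
            best_class, best_gene = cls, g.gene
    return AnnotatedVariant(variant=v, function_class=best_class, gene=best_gene)


def classify_variants(
    variants: Sequence[Variant], genes: Sequence[GeneModel], flank_bp: int = 1000
) -> List[AnnotatedVariant]:
    index = GeneIndex(genes, flank_bp)
    return [classify_variant(v, index) for v in variants]


# ---------------------------------------------------------------------------
# Stage 3+: class, rarity, deleteriousness filters
# ---------------------------------------------------------------------------

def filter_coding_changes(variants: Sequence[AnnotatedVariant]) -> List[AnnotatedVariant]:
    """Keep variants that alter the protein or canonical splicing."""
    return [v for v in variants if v.function_class in CODING_CLASSES]


def filter_by_frequency(
    variants: Sequence[AnnotatedVariant],
    databases: Sequence[str],
    threshold: float = 0.01,
    known_databases: Optional[Sequence[str]] = None,
) -> List[AnnotatedVariant]:
    """Drop variants with MAF strictly above ``threshold`` in ANY listed database.

    A variant absent from every database is retained (novel variants are the
    interesting ones).  ``known_databases``, when given, validates the
    configured names against the loaded frequency resource.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError(f"MAF threshold {threshold} outside (0, 0.5]")
    if known_databases is not None:
        unknown = [d for d in databases if d not in known_databases]
        if unknown:
            raise ValueError(
                f"unknown frequency database(s) {unknown}; available: {sorted(known_databases)}"
            )
    return [
        v
        for v in variants
        if all(v.maf.get(db, 0.0) <= threshold for db in databases)
    ]


def deleteriousness_filter(
    variants: Sequence[AnnotatedVariant],
    sift_max: float = 0.05,
    polyphen_min: float = 0.85,
    gerp_min: float = 2.0,
    missing_passes: bool = True,
) -> List[AnnotatedVariant]:
    """Keep variants concordantly predicted deleterious.

    Criteria: SIFT < ``sift_max``, PolyPhen > ``polyphen_min``, GERP++ >
    ``gerp_min``.  With ``missing_passes`` each missing score passes its own
    criterion (frameshift and splicing variants typically carry no SIFT or
    PolyPhen prediction); with ``missing_passes=False`` a missing score fails.
    """

    def one(score: Optional[float], ok) -> bool:
        if score is None:
            return missing_passes
        return ok(score)

    return [
        v
        for v in variants
        if one(v.sift, lambda s: s < sift_max)
        and one(v.polyphen, lambda s: s > polyphen_min)
        and one(v.gerp, lambda s: s > gerp_min)
    ]


# ---------------------------------------------------------------------------
# Recessive gene model
# ---------------------------------------------------------------------------

def recessive_gene_candidates(
    variants: Sequence[AnnotatedVariant],
) -> Dict[str, List[AnnotatedVariant]]:
    """Collapse one individual's qualifying variants into recessive candidate genes.

    A gene qualifies with >= 1 homozygous variant or >= 2 distinct heterozygous
    variants (putative compound heterozygote; phase is not checked — parental
    genotypes do not enter the funnel at this stage).  Variants with no gene
    assignment cannot collapse and are ignored.
    """
    by_gene: Dict[str, List[AnnotatedVariant]] = {}
    for v in variants:
        if v.gene is not None:
            by_gene.setdefault(v.gene, []).append(v)
    out: Dict[str, List[AnnotatedVariant]] = {}
    for gene, vs in by_gene.items():
        n_hom = sum(1 for v in vs if v.variant.zygosity == "hom")
        het_sites = {v.key for v in vs if v.variant.zygosity == "het"}
        if n_hom >= 1 or len(het_sites) >= 2:
            out[gene] = sorted(vs, key=lambda v: v.key)
    return out


def shared_candidates(
    a: Mapping[str, Sequence[AnnotatedVariant]],
    b: Mapping[str, Sequence[AnnotatedVariant]],
) -> Set[str]:
    """Genes that are recessive candidates in both probands."""
    return set(a) & set(b)


# ---------------------------------------------------------------------------
# Annotation helpers + the full funnel
# ---------------------------------------------------------------------------

def attach_annotations(
    variants: Sequence[AnnotatedVariant],
    freqs: Mapping[tuple, Mapping[str, float]],
    scores: Mapping[tuple, Mapping[str, float]],
) -> List[AnnotatedVariant]:
    out = []
    for v in variants:
        f = freqs.get(v.key, {})
        s = scores.get(v.key, {})
        out.append(
            replace(
                v,
                maf=dict(f),
                sift=s.get("sift"),
                polyphen=s.get("polyphen"),
                gerp=s.get("gerp"),
            )
        )
    return out


@dataclass
class CodingFunnelResult:
    per_proband_candidates: Dict[str, Dict[str, List[AnnotatedVariant]]]
    shared_genes: Set[str]
    shared_deleterious_variants: List[AnnotatedVariant]
    report: FunnelReport


def run_coding_funnel(
    proband_variants: Mapping[str, Sequence[Variant]],
    genes: Sequence[GeneModel],
    freqs: Mapping[tuple, Mapping[str, float]],
    known_databases: Sequence[str],
    scores: Mapping[tuple, Mapping[str, float]],
    config: Optional[dict] = None,
) -> CodingFunnelResult:
    """Run the whole coding funnel for two (or more) probands.

    Chains quality → classification → coding classes → per-database rarity →
    recessive gene model, intersects candidate genes across probands, and also
    produces the model-free shared-deleterious-variant list.
    """
    from .config import DEFAULTS, get

    cfg = config or DEFAULTS
    if len(proband_variants) < 2:
        raise ValueError("the funnel needs at least two probands to intersect")

    report = FunnelReport()
    index = GeneIndex(genes, flank_bp=get(cfg, "genes.flank_bp"))
    databases = list(get(cfg, "maf.databases"))
    rare_coding: Dict[str, List[AnnotatedVariant]] = {}
    candidates: Dict[str, Dict[str, List[AnnotatedVariant]]] = {}

    for sample, raw in proband_variants.items():
        raw = list(raw)
        try:
            passed, n_missing = filter_by_quality(
                raw, get(cfg, "quality.hom_min"), get(cfg, "quality.het_min")
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage 'quality' failed for {sample}: {exc}") from exc
        report.add("quality", sample, len(raw), len(passed))
        if n_missing:
            report.add("quality_missing_score", sample, n_missing, 0)

        annotated = attach_annotations(
            [classify_variant(v, index) for v in passed], freqs, scores
        )
        coding = filter_coding_changes(annotated)
        report.add("coding_classes", sample, len(annotated), len(coding))

        current = coding
        for db in databases:
            try:
                nxt = filter_by_frequency(
                    current,
                    [db],
                    get(cfg, "maf.threshold"),
                    known_databases=known_databases,
                )
            except ValueError as exc:
                raise ValueError(f"stage 'maf:{db}' failed for {sample}: {exc}") from exc
            report.add(f"maf_{db}", sample, len(current), len(nxt))
            current = nxt
        rare_coding[sample] = current

        cand = recessive_gene_candidates(current)
        n_cand_vars = sum(len(vs) for vs in cand.values())
        report.add("recessive_model", sample, len(current), n_cand_vars)
        candidates[sample] = cand

    samples = list(proband_variants)
    shared: Set[str] = set(candidates[samples[0]])
    for s in samples[1:]:
        shared &= set(candidates[s])

    # model-free route: rare coding variants present in every proband,
    # filtered on concordant deleteriousness predictions
    shared_keys = set.intersection(*(set(v.key for v in rare_coding[s]) for s in samples))
    shared_vars = [v for v in rare_coding[samples[0]] if v.key in shared_keys]
    deleterious = deleteriousness_filter(
        shared_vars,
        sift_max=get(cfg, "scores.sift_max"),
        polyphen_min=get(cfg, "scores.polyphen_min"),
        gerp_min=get(cfg, "scores.gerp_min"),
        missing_passes=get(cfg, "scores.missing_passes"),
    )
    report.add("shared_variants", "shared", len(rare_coding[samples[0]]), len(shared_vars))
    report.add("deleteriousness", "shared", len(shared_vars), len(deleterious))

    return CodingFunnelResult(
        per_proband_candidates=candidates,
        shared_genes=shared,
        shared_deleterious_variants=sorted(deleterious, key=lambda v: v.key),
        report=report,
    )
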