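"""CNV call post-filtering, family segregation, and read-signal validation.

The upstream callers (an array HMM and a read-depth caller) are external;
this module implements what happens after calling: marker-support and
marker-density filters, blacklist-overlap removal (immunoglobulin regions and
centromeres are prone to somatic artifacts), confident-call thresholds for
read-depth calls, grouping per-sample calls into family-level CNV regions,
inheritance and disease-segregation assessment, and validation of deletions
from sequencing signals — normalized read depth ("sequence count", diploid
baseline 1.0) and B-allele frequency computed from pileup counts.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .intervals import GenomicInterval, RegionSet, overlap_fraction
from .pedigree import Pedigree

__all__ = [
    "CNVCall",
    "SitePileup",
    "SignalTrack",
    "FamilyCNVRegion",
    "read_cnv_table",
    "read_pileup_table",
    "immunoglobulin_regions",
    "filter_min_snps",
    "filter_sparse",
    "filter_blacklist",
    "erds_confident_filter",
    "group_family_calls",
    "assess_inheritance",
    "segregation_check",
    "compute_baf",
    "compute_sequence_count",
    "deletion_evidence",
]


@dataclass(frozen=True)
class CNVCall:
    """A copy-number event in one sample."""

    interval: GenomicInterval
    kind: str  # "del" or "dup"
    sample: str
    n_snps: int
    start_snp: Optional[str] = None
    end_snp: Optional[str] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("del", "dup"):
            raise ValueError(f"CNV kind must be 'del' or 'dup', got {self.kind!r}")
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def span(self) -> int:
        """Distance between the first and last supporting marker positions."""
        return self.interval.end - self.interval.start


@dataclass(frozen=True)
class SitePileup:
    """Reference/alternate read counts at a single position."""

    chrom: str
    pos: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class SignalTrack:
    """Per-position normalized depth and (at SNV sites) B-allele frequency."""

    chrom: str
    positions: np.ndarray  # int64
    sequence_count: np.ndarray  # float, diploid baseline = 1.0
    baf: np.ndarray  # float, NaN where no SNV

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.baf, initial=0.0) < 0 or np.nanmax(self.baf, initial=0.0) > 1:
                raise ValueError("BAF outside [0, 1]")
        if (self.sequence_count < 0).any():
            raise ValueError("negative sequence count")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_KIND_ALIASES = {"del": "del", "deletion": "del", "dup": "dup", "duplication": "dup"}


def read_cnv_table(path) -> List[CNVCall]:
    """TSV: chrom, start, end, type, sample, n_snps [, start_snp, end_snp, confidence]."""
    out: List[CNVCall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for c in ("chrom", "start", "end", "type", "sample", "n_snps"):
            if c not in (reader.fieldnames or []):
                raise ValueError(f"{path}: missing column {c!r}")
        for lineno, row in enumerate(reader, 2):
            kind = _KIND_ALIASES.get(row["type"].strip().lower())
            if kind is None:
                raise ValueError(f"{path}:{lineno}: unknown CNV type {row['type']!r}")
            conf = (row.get("confidence") or "").strip()
            out.append(
                CNVCall(
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    kind=kind,
                    sample=row["sample"],
                    n_snps=int(row["n_snps"]),
                    start_snp=(row.get("start_snp") or "").strip() or None,
                    end_snp=(row.get("end_snp") or "").strip() or None,
                    confidence=float(conf) if conf else None,
                )
            )
    return out


def read_pileup_table(path) -> List[SitePileup]:
    """TSV: chrom, pos, ref_count, alt_count."""
    out: List[SitePileup] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                SitePileup(row["chrom"], int(row["pos"]), int(row["ref_count"]), int(row["alt_count"]))
            )
    return out


def immunoglobulin_regions() -> RegionSet:
    """The four immunoglobulin loci (hg18) excluded from CNV analysis because
    somatic rearrangement mimics germline CNVs there."""
    from .io import read_bed

    with resources.as_file(
        resources.files("famprior").joinpath("data/immunoglobulin_hg18.bed")
    ) as p:
        return read_bed(p)


# ---------------------------------------------------------------------------
# Post-filters
# ---------------------------------------------------------------------------

def filter_min_snps(calls: Sequence[CNVCall], min_snps: int = 10) -> List[CNVCall]:
    """Keep calls supported by at least ``min_snps`` array markers."""
    return [c for c in calls if c.n_snps >= min_snps]


def filter_sparse(calls: Sequence[CNVCall], max_mean_gap: float = 50000.0) -> List[CNVCall]:
    """Drop calls whose average inter-marker distance exceeds ``max_mean_gap``.

    The mean gap over n markers is span/(n-1) where span is the distance
    between the outermost markers.  Single-marker calls have no defined gap
    and are removed with a warning.
    """
    out: List[CNVCall] = []
    for c in calls:
        if c.n_snps < 2:
            warnings.warn(f"single-marker call {c.interval} removed (gap undefined)")
            continue
        if c.span / (c.n_snps - 1) <= max_mean_gap:
            out.append(c)
    return out


def filter_blacklist(
    calls: Sequence[CNVCall],
    masks: Mapping[str, RegionSet],
    max_frac: float = 0.5,
) -> List[CNVCall]:
    """Drop calls with more than ``max_frac`` of their span inside any mask."""
    return [
        c
        for c in calls
        if all(overlap_fraction(c.interval, mask) <= max_frac for mask in masks.values())
    ]


def erds_confident_filter(
    calls: Sequence[CNVCall],
    del_min_bp: int = 10000,
    dup_min_bp: int = 200000,
    conf_min: float = 300.0,
) -> List[CNVCall]:
    """Keep confident read-depth calls: deletions > 10 kb and duplications
    > 200 kb, each with confidence > 300.  Calls with no confidence are
    removed with a warning."""
    out: List[CNVCall] = []
    for c in calls:
        if c.confidence is None:
            warnings.warn(f"call {c.interval} has no confidence score; removed")
            continue
        min_bp = del_min_bp if c.kind == "del" else dup_min_bp
        if c.length > min_bp and c.confidence > conf_min:
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Family-level grouping, inheritance, segregation
# ---------------------------------------------------------------------------

@dataclass
class FamilyCNVRegion:
    """One CNV event shared across family members (union span of matched calls)."""

    interval: GenomicInterval
    kind: str
    carriers: Set[str]
    calls: List[CNVCall] = field(default_factory=list)


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    ov = a.overlap_bp(b)
    return min(ov / a.length, ov / b.length) if ov else 0.0


def group_family_calls(
    calls: Sequence[CNVCall], reciprocal_min: float = 0.5
) -> List[FamilyCNVRegion]:
    """Merge same-kind calls with >= ``reciprocal_min`` reciprocal overlap into
    family-level regions (single-linkage over the overlap graph)."""
    calls = list(calls)
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if a.kind == b.kind and _reciprocal_overlap(a.interval, b.interval) >= reciprocal_min:
                parent[find(i)] = find(j)

    groups: Dict[int, List[CNVCall]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(calls[i])

    regions = []
    for members in groups.values():
        chrom = members[0].interval.chrom
        regions.append(
            FamilyCNVRegion(
                interval=GenomicInterval(
                    chrom,
                    min(c.interval.start for c in members),
                    max(c.interval.end for c in members),
                ),
                kind=members[0].kind,
                carriers={c.sample for c in members},
                calls=sorted(members, key=lambda c: (c.sample, c.interval)),
            )
        )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions


def assess_inheritance(region: FamilyCNVRegion, ped: Pedigree) -> Dict[str, str]:
    """Label each child carrier by parental origin.

    ``inherited-from-father`` / ``inherited-from-mother`` when exactly that
    parent carries the same family-level region, ``inherited-from-either``
    when both do, ``de-novo-candidate`` when neither does.
    """
    father, mother = ped.require_nuclear()
    out: Dict[str, str] = {}
    pat = father in region.carriers
    mat = mother in region.carriers
    for child in ped.children:
        if child.member_id not in region.carriers:
            continue
        if pat and mat:
            out[child.member_id] = "inherited-from-either"
        elif pat:
            out[child.member_id] = "inherited-from-father"
        elif mat:
            out[child.member_id] = "inherited-from-mother"
        else:
            out[child.member_id] = "de-novo-candidate"
    return out


def segregation_check(region: FamilyCNVRegion, ped: Pedigree) -> bool:
    """True iff the child carriers are exactly the affected children.

    Parents are exempt: a transmitting unaffected parent is expected under
    incomplete penetrance and does not break segregation.
    """
    child_carriers = {c.member_id for c in ped.children if c.member_id in region.carriers}
    affected = {c.member_id for c in ped.affected_children}
    return child_carriers == affected


# ---------------------------------------------------------------------------
# Sequencing signals
# ---------------------------------------------------------------------------

def compute_baf(p: SitePileup) -> Optional[float]:
    """Fraction of reads supporting the non-reference allele; None with no reads."""
    total = p.ref_count + p.alt_count
    return None if total == 0 else p.alt_count / total


def compute_sequence_count(
    chrom: str,
    positions: Sequence[int],
    raw_depths: Sequence[float],
    baseline: float,
    snv_positions: Optional[Set[int]] = None,
    bafs: Optional[Mapping[int, float]] = None,
) -> SignalTrack:
    """Normalize raw depth against the sample's diploid ``baseline``.

    SNV positions keep their own normalized depth; each run of consecutive
    non-SNV positions is reported as the run mean.  ``bafs`` supplies B-allele
    frequencies for SNV positions (others are NaN).
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    pos = np.asarray(positions, dtype=np.int64)
    norm = np.asarray(raw_depths, dtype=float) / baseline
    snvs = snv_positions or set()

    out = norm.copy()
    i = 0
    while i < len(pos):
        if int(pos[i]) in snvs:
            i += 1
            continue
        j = i
        while j < len(pos) and int(pos[j]) not in snvs:
            j += 1
        out[i:j] = norm[i:j].mean()
        i = j

    baf = np.full(len(pos), np.nan)
    if bafs:
        for k, p_ in enumerate(pos):
            if int(p_) in bafs:
                baf[k] = bafs[int(p_)]
    return SignalTrack(chrom=chrom, positions=pos, sequence_count=out, baf=baf)


def deletion_evidence(
    region: GenomicInterval,
    track: SignalTrack,
    depth_max: float = 0.75,
    het_band: Tuple[float, float] = (0.25, 0.75),
    het_frac_max: float = 0.1,
) -> Tuple[bool, Dict[str, object]]:
    """Decide whether sequencing signals support a one-copy deletion.

    Evidence requires BOTH a depressed mean sequence count (< ``depth_max``)
    and the absence of a heterozygous BAF cluster: fewer than ``het_frac_max``
    of SNV sites with BAF inside ``het_band``.  A region with no SNV sites is
    decided on depth alone and flagged.
    """
    if track.chrom != region.chrom:
        raise ValueError(f"track is for {track.chrom}, region on {region.chrom}")
    mask = (track.positions >= region.start) & (track.positions <= region.end)
    if not mask.any():
        raise ValueError(f"region {region} does not overlap the signal track")

    mean_depth = float(track.sequence_count[mask].mean())
    baf = track.baf[mask]
    snv = ~np.isnan(baf)
    summary: Dict[str, object] = {
        "mean_sequence_count": mean_depth,
        "n_positions": int(mask.sum()),
        "n_snv_sites": int(snv.sum()),
    }
    depth_ok = mean_depth < depth_max
    if not snv.any():
        summary["het_fraction"] = None
        summary["no_het_sites"] = True
        return depth_ok, summary

    lo, hi = het_band
    het_frac = float(((baf[snv] >= lo) & (baf[snv] <= hi)).mean())
    summary["het_fraction"] = het_frac
    summary["no_het_sites"] = False
    return depth_ok and het_frac < het_frac_max, summary
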