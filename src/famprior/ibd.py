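"""Transmission phasing and identity-by-descent inference in a nuclear family.

Given dense bi-allelic marker genotypes for two parents and their children,
this module reconstructs which parental haplotype each child inherited at
each informative marker (a *transmission track*), under a minimal-recombination
assumption appropriate for SNP-array density.  From pairs of transmission
tracks it derives IBD segments: at a locus two siblings share 0, 1, or 2
parental haplotypes identically by descent.

The candidate-region selection implements the multiplex-family strategy:
keep the regions where the two affected siblings are IBD=2, then remove any
region where an unaffected sibling is also IBD=2 with a proband.

Phasing is exact, not heuristic: for each parent and chromosome the
assignment of the parent's two alleles to haplotypes is chosen by a dynamic
program that minimizes the total number of implied crossovers across all
children (state = each child's most recent known haplotype origin, so
children uninformative at some markers are costed between their own
consecutive informative markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, RegionSet
from .pedigree import Pedigree

__all__ = [
    "MarkerGenotypes",
    "TransmissionTrack",
    "IBDSegment",
    "MendelianError",
    "read_genotype_table",
    "write_genotype_table",
    "phase_nuclear_family",
    "ibd_states",
    "ibd2_regions",
    "select_candidate_regions",
    "expected_ibd2_fraction",
    "sib_ibd_state_fractions",
    "sample_crossover_positions",
    "DEFAULT_AUTOSOMES",
]

Genotype = Optional[Tuple[str, str]]  # unordered allele pair, None = missing

#: Chromosome names treated as the X chromosome (excluded by default).
_X_NAMES = {"x", "chrx", "23", "chr23"}


@dataclass(frozen=True)
class MarkerGenotypes:
    """One bi-allelic marker: position plus each member's unordered allele pair."""

    marker_id: str
    chrom: str
    pos: int
    genotypes: Mapping[str, Genotype]

    def alleles(self) -> List[str]:
        seen = set()
        for g in self.genotypes.values():
            if g is not None:
                seen.update(g)
        return sorted(seen)


class MendelianError(ValueError):
    """A child's genotype is inconsistent with its parents at a named marker."""


@dataclass
class _ChromTrack:
    positions: np.ndarray  # int64, sorted marker positions
    marker_ids: List[str]
    # (child_id, role) -> int8 array over markers: 0 = hapA, 1 = hapB, -1 = unknown
    origins: Dict[Tuple[str, str], np.ndarray]


@dataclass
class TransmissionTrack:
    """Per-child, per-parent haplotype-origin labels along each chromosome.

    ``origin(chrom, child, role)[i]`` is 0 (hapA), 1 (hapB) or -1 (unknown)
    at the i-th marker; hapA/hapB name one parent's two haplotypes with a
    meaning that is constant along a chromosome.  ``role`` is ``"father"`` or
    ``"mother"``.
    """

    children: List[str]
    chroms: Dict[str, _ChromTrack] = field(default_factory=dict)

    def positions(self, chrom: str) -> np.ndarray:
        return self.chroms[chrom].positions

    def origin(self, chrom: str, child: str, role: str) -> np.ndarray:
        return self.chroms[chrom].origins[(child, role)]


@dataclass(frozen=True)
class IBDSegment:
    """Number of parental haplotypes (0/1/2) a sibling pair shares over a span."""

    pair: Tuple[str, str]
    interval: GenomicInterval
    state: int

    def __post_init__(self) -> None:
        if self.state not in (0, 1, 2):
            raise ValueError(f"IBD state must be 0, 1 or 2, got {self.state}")


# ---------------------------------------------------------------------------
# Genotype table I/O
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> List[MarkerGenotypes]:
    """TSV with columns marker, chrom, pos, then one allele-pair column per member."""
    import csv

    out: List[MarkerGenotypes] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        for c in ("marker", "chrom", "pos"):
            if c not in cols:
                raise ValueError(f"{path}: missing column {c!r}")
        members = [c for c in cols if c not in ("marker", "chrom", "pos")]
        for lineno, row in enumerate(reader, 2):
            mid = row["marker"]
            if mid in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate marker id {mid!r} (first at line {seen[mid]})"
                )
            seen[mid] = lineno
            gts: Dict[str, Genotype] = {}
            for m in members:
                raw = (row[m] or "").strip()
                if raw in ("", "./.", ".", "NA"):
                    gts[m] = None
                else:
                    a = raw.split("/")
                    if len(a) != 2:
                        raise ValueError(f"{path}:{lineno}: bad genotype {raw!r} for {m}")
                    gts[m] = (a[0], a[1])
            out.append(MarkerGenotypes(mid, row["chrom"], int(row["pos"]), gts))
    return out


def write_genotype_table(markers: Sequence[MarkerGenotypes], members: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tpos\t" + "\t".join(members) + "\n")
        for m in markers:
            cells = []
            for mem in members:
                g = m.genotypes.get(mem)
                cells.append("./." if g is None else f"{g[0]}/{g[1]}")
            fh.write(f"{m.marker_id}\t{m.chrom}\t{m.pos}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

def _check_mendelian(m: MarkerGenotypes, father: str, mother: str, children: Sequence[str]) -> None:
    gf, gm = m.genotypes.get(father), m.genotypes.get(mother)
    for child in children:
        gc = m.genotypes.get(child)
        if gc is None or gf is None or gm is None:
            continue
        ok = any(
            sorted((pf, pm)) == sorted(gc) for pf in gf for pm in gm
        )
        if not ok:
            raise MendelianError(
                f"marker {m.marker_id} ({m.chrom}:{m.pos}): child {child} genotype "
                f"{gc} inconsistent with father {gf} / mother {gm}"
            )


def _transmitted_allele(
    child_gt: Genotype, het_gt: Tuple[str, str], other_gt: Genotype
) -> Optional[str]:
    """Allele the heterozygous parent transmitted, if deducible."""
    if child_gt is None:
        return None
    a, b = child_gt
    het = set(het_gt)
    if a == b:
        return a if a in het else None
    options = []
    for t, rest in ((a, b), (b, a)):
        if t in het and (other_gt is None or rest in other_gt):
            options.append(t)
    options = sorted(set(options))
    return options[0] if len(options) == 1 else None


def _phase_one_parent(
    markers: Sequence[MarkerGenotypes],
    parent: str,
    other: str,
    children: Sequence[str],
) -> Dict[str, np.ndarray]:
    """Minimal-recombination phasing of one parent on one chromosome.

    Returns per-child origin arrays over all markers (-1 where unknown).
    The dynamic program is exact: its state is each child's most recent
    known origin, so a child's crossovers are counted between that child's
    own consecutive informative markers even across gaps.
    """
    n = len(markers)
    origins = {c: np.full(n, -1, dtype=np.int8) for c in children}

    # transmitted-allele bits: v=0 for the lexicographically smaller parent allele
    informative: List[Tuple[int, Dict[str, int]]] = []
    for i, m in enumerate(markers):
        gp = m.genotypes.get(parent)
        if gp is None or gp[0] == gp[1]:
            continue
        if len(m.alleles()) < 2:  # monomorphic: skipped silently
            continue
        x, y = sorted(gp)
        bits: Dict[str, int] = {}
        for c in children:
            t = _transmitted_allele(m.genotypes.get(c), gp, m.genotypes.get(other))
            if t is not None:
                bits[c] = 0 if t == x else 1
        if bits:
            informative.append((i, bits))

    if not informative:
        return origins

    # DP over phase flips f_i: origin(child) = bit XOR f.  hapA is anchored to
    # the smaller allele at the first informative marker (f forced to 0 there;
    # the mirror solution has identical cost, so optimality is unaffected).
    child_list = list(children)
    start = tuple([-1] * len(child_list))
    states: Dict[tuple, int] = {start: 0}
    back: List[Dict[tuple, Tuple[tuple, int]]] = []
    for k, (_, bits) in enumerate(informative):
        nxt: Dict[tuple, int] = {}
        bk: Dict[tuple, Tuple[tuple, int]] = {}
        flips = (0,) if k == 0 else (0, 1)
        for state, cost in sorted(states.items()):
            for f in flips:
                new = list(state)
                c_add = 0
                for ci, c in enumerate(child_list):
                    if c in bits:
                        o = bits[c] ^ f
                        if state[ci] != -1 and state[ci] != o:
                            c_add += 1
                        new[ci] = o
                key = tuple(new)
                total = cost + c_add
                if key not in nxt or total < nxt[key]:
                    nxt[key] = total
                    bk[key] = (state, f)
        states = nxt
        back.append(bk)

    # backtrack the cheapest final state (deterministic tie-break on the tuple)
    final = min(states.items(), key=lambda kv: (kv[1], kv[0]))[0]
    flips_chosen = np.zeros(len(informative), dtype=np.int8)
    cur = final
    for k in range(len(informative) - 1, -1, -1):
        prev, f = back[k][cur]
        flips_chosen[k] = f
        cur = prev

    for (i, bits), f in zip(informative, flips_chosen):
        for c, v in bits.items():
            origins[c][i] = v ^ f
    return origins


def phase_nuclear_family(
    markers: Sequence[MarkerGenotypes],
    ped: Pedigree,
    include_x: bool = False,
) -> TransmissionTrack:
    """Infer grandparental-origin labels for every child at informative markers.

    Markers are grouped per chromosome and sorted by position; Mendelian
    inconsistencies abort with the marker and child named.  The X chromosome
    is excluded unless ``include_x`` (hemizygous males break the two-haplotype
    model).
    """
    father, mother = ped.require_nuclear()
    children = [c.member_id for c in ped.children]

    by_chrom: Dict[str, List[MarkerGenotypes]] = {}
    for m in markers:
        if not include_x and m.chrom.lower() in _X_NAMES:
            continue
        by_chrom.setdefault(m.chrom, []).append(m)

    track = TransmissionTrack(children=children)
    for chrom, ms in by_chrom.items():
        ms.sort(key=lambda m: m.pos)
        for m in ms:
            _check_mendelian(m, father, mother, children)
        pat = _phase_one_parent(ms, father, mother, children)
        mat = _phase_one_parent(ms, mother, father, children)
        origins: Dict[Tuple[str, str], np.ndarray] = {}
        for c in children:
            origins[(c, "father")] = pat[c]
            origins[(c, "mother")] = mat[c]
        track.chroms[chrom] = _ChromTrack(
            positions=np.array([m.pos for m in ms], dtype=np.int64),
            marker_ids=[m.marker_id for m in ms],
            origins=origins,
        )
    return track


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

def ibd_states(track: TransmissionTrack, pair: Tuple[str, str], ped: Optional[Pedigree] = None) -> List[IBDSegment]:
    """Segment the genome by the number of parental haplotypes a sib pair shares.

    Only markers where both children have a known origin from both parents are
    used; runs of equal state merge into segments, with boundaries placed at
    the midpoint between the flanking informative markers and ends clipped to
    the first/last informative marker.
    """
    c1, c2 = pair
    if ped is not None:
        founders = {m.member_id for m in ped.founders}
        if c1 in founders or c2 in founders:
            raise ValueError(f"IBD states are defined for siblings, got founder in pair {pair}")
    for c in pair:
        if c not in track.children:
            raise ValueError(f"{c!r} has no transmission data")

    segments: List[IBDSegment] = []
    for chrom in sorted(track.chroms):
        ct = track.chroms[chrom]
        of1, om1 = ct.origins[(c1, "father")], ct.origins[(c1, "mother")]
        of2, om2 = ct.origins[(c2, "father")], ct.origins[(c2, "mother")]
        known = (of1 >= 0) & (of2 >= 0) & (om1 >= 0) & (om2 >= 0)
        idx = np.nonzero(known)[0]
        if idx.size == 0:
            continue
        state = (of1[idx] == of2[idx]).astype(int) + (om1[idx] == om2[idx]).astype(int)
        pos = ct.positions[idx]
        run_start = 0
        for k in range(1, len(idx) + 1):
            if k == len(idx) or state[k] != state[run_start]:
                seg_start = (
                    int(pos[run_start])
                    if run_start == 0
                    else (int(pos[run_start - 1]) + int(pos[run_start])) // 2 + 1
                )
                seg_end = (
                    int(pos[k - 1])
                    if k == len(idx)
                    else (int(pos[k - 1]) + int(pos[k])) // 2
                )
                segments.append(
                    IBDSegment(
                        pair=(c1, c2),
                        interval=GenomicInterval(chrom, seg_start, seg_end),
                        state=int(state[run_start]),
                    )
                )
                run_start = k
    return segments


def ibd2_regions(track: TransmissionTrack, pair: Tuple[str, str]) -> RegionSet:
    return RegionSet(s.interval for s in ibd_states(track, pair) if s.state == 2)


def select_candidate_regions(track: TransmissionTrack, ped: Pedigree) -> RegionSet:
    """IBD2 between the two probands, minus anywhere an unaffected sib is IBD2
    with either proband."""
    probands = ped.probands
    if len(probands) != 2:
        raise ValueError(f"exactly two probands required, found {len(probands)}")
    p1, p2 = probands
    candidate = ibd2_regions(track, (p1, p2))
    excluded = RegionSet()
    for sib in ped.unaffected_children:
        if sib.member_id not in track.children:
            continue
        has_data = any(
            (ct.origins[(sib.member_id, "father")] >= 0).any()
            or (ct.origins[(sib.member_id, "mother")] >= 0).any()
            for ct in track.chroms.values()
        )
        if not has_data:
            continue  # ungenotyped sibling cannot exclude anything
        for p in (p1, p2):
            excluded = excluded.union(ibd2_regions(track, (p, sib.member_id)))
    return candidate.subtract(excluded)


# ---------------------------------------------------------------------------
# Expected IBD2 fraction by simulation
# ---------------------------------------------------------------------------

#: Approximate physical lengths (bp) of the 22 human autosomes; with the
#: default uniform 1 cM/Mb map the genome totals ~28.8 Morgans.
DEFAULT_AUTOSOMES: List[Tuple[str, int]] = [
    ("chr1", 247_000_000), ("chr2", 243_000_000), ("chr3", 199_000_000),
    ("chr4", 191_000_000), ("chr5", 181_000_000), ("chr6", 171_000_000),
    ("chr7", 159_000_000), ("chr8", 146_000_000), ("chr9", 140_000_000),
    ("chr10", 135_000_000), ("chr11", 134_000_000), ("chr12", 132_000_000),
    ("chr13", 114_000_000), ("chr14", 106_000_000), ("chr15", 100_000_000),
    ("chr16", 89_000_000), ("chr17", 79_000_000), ("chr18", 76_000_000),
    ("chr19", 64_000_000), ("chr20", 62_000_000), ("chr21", 47_000_000),
    ("chr22", 50_000_000),
]


def sample_crossover_positions(length_bp: int, morgans: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover positions for one meiosis: Poisson count over the genetic
    length, positions uniform on the chromosome, no interference."""
    k = rng.poisson(morgans)
    return np.sort(rng.uniform(0, length_bp, size=k)) if k else np.empty(0)


def _pair_chrom_state_lengths(
    length_bp: int, morgans: float, rng: np.random.Generator
) -> np.ndarray:
    """Base pairs of one chromosome spent in IBD state 0/1/2 for one sib pair."""
    lengths = np.zeros(3)
    # per parent: indicator that the sibs' origins differ flips at every
    # crossover of either child's meiosis from that parent
    events = []  # (position, parent_index)
    diff = np.empty(2, dtype=int)
    for p in range(2):
        d = int(rng.integers(2)) ^ int(rng.integers(2))  # starting origins
        bps = np.concatenate(
            [
                sample_crossover_positions(length_bp, morgans, rng),
                sample_crossover_positions(length_bp, morgans, rng),
            ]
        )
        events.extend((float(b), p) for b in bps)
        diff[p] = d
    events.sort()
    prev = 0.0
    for x, p in events:
        state = int(diff[0] == 0) + int(diff[1] == 0)
        lengths[state] += x - prev
        diff[p] ^= 1
        prev = x
    state = int(diff[0] == 0) + int(diff[1] == 0)
    lengths[state] += length_bp - prev
    return lengths


def sib_ibd_state_fractions(
    n: int,
    genome: Optional[Sequence[Tuple[str, int]]] = None,
    cm_per_mb: float = 1.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Monte-Carlo genome fractions of IBD states (0, 1, 2) for full-sib pairs.

    ``genome`` is a list of (name, physical length in bp); the genetic map is
    uniform at ``cm_per_mb``.  Returns an array (f0, f1, f2) summing to 1.
    By Mendelian transmission these converge to (1/4, 1/2, 1/4).
    """
    if n < 1:
        raise ValueError("need at least one simulated pair")
    chroms = list(genome) if genome is not None else list(DEFAULT_AUTOSOMES)
    rng = np.random.default_rng(seed)
    totals = np.zeros(3)
    for _ in range(n):
        for _, length_bp in chroms:
            morgans = length_bp / 1e6 * cm_per_mb / 100.0
            totals += _pair_chrom_state_lengths(length_bp, morgans, rng)
    return totals / totals.sum()


def expected_ibd2_fraction(
    n: int = 2000,
    genome: Optional[Sequence[Tuple[str, int]]] = None,
    cm_per_mb: float = 1.0,
    seed: Optional[int] = None,
) -> float:
    """Expected genome fraction where a full-sib pair is IBD=2 (converges to 0.25)."""
    return float(sib_ibd_state_fractions(n, genome, cm_per_mb, seed)[2])
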