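"""Seedable generator of a complete synthetic family study with planted truth.

Emulates the study design the pipeline targets: two parents and eight
children, two of whom are affected, dense SNP-array genotypes for every
DNA-available member, whole-genome variant calls for the two affected
children (probands), annotation resources, inherited CNVs and per-site read
signals.  The affected children are compound heterozygous at one planted gene
(one rare deleterious variant inherited from each parent), every unaffected
child lacks at least one of the two variants, and one rare non-coding variant
is planted inside a conserved element overlapping an active-promoter
chromatin state.  Everything is written as standard text formats (PED, TSV,
VCF, BED) plus a ``truth.json``, so every pipeline stage can be tested by
parameter recovery without any external download.

The genome is scaled down (default four 20-Mb chromosomes, 2,000 markers,
~1,000 background variants per proband) so the full pipeline runs in seconds;
all scales are config-driven.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .coding import GeneIndex
from .intervals import GenomicInterval
from .io import write_bed, write_gene_models, write_ped, write_vcf
from .pedigree import Pedigree, PedigreeMember
from .ibd import (
    MarkerGenotypes,
    TransmissionTrack,
    _ChromTrack,
    sample_crossover_positions,
    write_genotype_table,
)
from .cnv import SitePileup
from .variants import GeneModel, Variant

__all__ = ["SimulationConfig", "PlantedCNV", "TruthSet", "simulate_meiosis", "simulate_family", "simulate_pileup"]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PlantedCNV:
    interval: GenomicInterval
    kind: str  # "del" / "dup"
    carrier_parent: str  # member id of the transmitting parent
    carrier_children: Tuple[str, ...]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic family.

    Defaults reproduce the target pedigree shape: eight children, two
    affected (the probands), one child without DNA, ~50x coverage.
    """

    seed: int = 0
    genome: List[Tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i}", 20_000_000) for i in range(1, 5)]
    )
    cm_per_mb: float = 1.0
    n_markers: int = 2000
    n_children: int = 8
    affected_children: Tuple[str, ...] = ("8", "10")
    ungenotyped_children: Tuple[str, ...] = ("9",)
    n_genes: int = 30
    n_background_variants: int = 1000
    shared_background_frac: float = 0.2
    common_maf_frac: float = 0.3  # background variants with MAF > 1%
    low_quality_frac: float = 0.1
    plant_causal_gene: bool = True
    plant_noncoding: bool = True
    planted_cnvs: Optional[List[PlantedCNV]] = None  # None = defaults
    coverage: float = 50.0
    n_conserved_elements: int = 150

    def __post_init__(self) -> None:
        if self.n_markers < 10:
            raise ValueError("n_markers too small to phase anything")
        if self.n_children < 2 or len(self.affected_children) != 2:
            raise ValueError("need >= 2 children with exactly two affected")
        if self.coverage <= 0 or self.n_background_variants < 0:
            raise ValueError("rates must be positive")

    @property
    def child_ids(self) -> List[str]:
        return [str(i) for i in range(3, 3 + self.n_children)]

    @property
    def father_id(self) -> str:
        return "2"

    @property
    def mother_id(self) -> str:
        return "1"


@dataclass
class TruthSet:
    """Ground truth recorded while generating the synthetic study."""

    marker_positions: Dict[str, np.ndarray]
    # (child, role) -> chrom -> 0/1 origin per marker
    transmissions: Dict[Tuple[str, str], Dict[str, np.ndarray]]
    children: List[str]
    affected: List[str]
    planted_gene: Optional[str]
    planted_variant_keys: List[tuple]
    planted_noncoding_key: Optional[tuple]
    cnvs: List[PlantedCNV]
    deletion_region: Optional[GenomicInterval]
    control_region: Optional[GenomicInterval]

    def track(self) -> TransmissionTrack:
        """The true transmissions as a fully-known TransmissionTrack."""
        track = TransmissionTrack(children=list(self.children))
        for chrom, pos in self.marker_positions.items():
            origins = {}
            for child in self.children:
                for role in ("father", "mother"):
                    vec = self.transmissions.get((child, role), {}).get(chrom)
                    if vec is None:
                        vec = np.full(len(pos), -1, dtype=np.int8)
                    origins[(child, role)] = vec.astype(np.int8)
            track.chroms[chrom] = _ChromTrack(
                positions=pos.astype(np.int64),
                marker_ids=[f"m_{chrom}_{i}" for i in range(len(pos))],
                origins=origins,
            )
        return track


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    marker_pos: np.ndarray,
    length_bp: int,
    morgans: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One gamete from a parent's two haplotypes.

    Crossover count is Poisson over the chromosome's genetic length, positions
    uniform, no interference.  Returns (gamete alleles, per-marker origin
    0=hap_a/1=hap_b, crossover positions).
    """
    breaks = sample_crossover_positions(length_bp, morgans, rng)
    start = int(rng.integers(2))
    origin = (start + np.searchsorted(breaks, marker_pos)) % 2
    gamete = np.where(origin == 0, hap_a, hap_b)
    return gamete, origin.astype(np.int8), breaks


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def simulate_pileup(
    copy_number: int,
    het_positions: Sequence[int],
    depth: float,
    rng: np.random.Generator,
    chrom: str = "chr1",
) -> List[SitePileup]:
    """Read counts at (former) heterozygous sites for a region of given copy number.

    Total reads per site ~ Poisson(depth * copy/2); alternate reads ~
    Binomial(total, dose/copy) where the alt-allele dose is 1 at a diploid het
    site, 0 or 1 (random) under a hemizygous deletion — producing B-allele
    frequencies at 0 or 1 — and 1 or 2 under a duplication.
    """
    if copy_number not in (1, 2, 3):
        raise ValueError(f"copy number must be 1, 2 or 3, got {copy_number}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    out = []
    for pos in het_positions:
        total = int(rng.poisson(depth * copy_number / 2.0))
        if copy_number == 1:
            dose = int(rng.integers(2))
        elif copy_number == 2:
            dose = 1
        else:
            dose = int(rng.integers(1, 3))
        alt = int(rng.binomial(total, dose / copy_number)) if total else 0
        out.append(SitePileup(chrom, int(pos), total - alt, alt))
    return out


# ---------------------------------------------------------------------------
# Gene models and annotation resources
# ---------------------------------------------------------------------------

def _random_cds_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> List[GeneModel]:
    genes: List[GeneModel] = []
    per_chrom = max(1, cfg.n_genes // len(cfg.genome))
    gi = 0
    for chrom, length in cfg.genome:
        cursor = int(0.05 * length)
        for _ in range(per_chrom):
            n_ex = int(rng.integers(2, 5))
            exons = []
            pos = cursor + int(rng.integers(50_000, 400_000))
            for _ in range(n_ex):
                ex_len = int(rng.integers(150, 400))
                exons.append(GenomicInterval(chrom, pos, pos + ex_len - 1))
                pos += ex_len + int(rng.integers(500, 3000))
            cursor = pos + 10_000
            if cursor > length - 500_000:
                break
            gi += 1
            name = f"GENE{gi:03d}"
            strand = "+" if rng.random() < 0.7 else "-"
            coding = rng.random() > 0.15
            if not coding:
                genes.append(GeneModel(name, chrom, strand, exons))
                continue
            # trim UTRs off the transcript ends and keep CDS length % 3 == 0
            cds = [GenomicInterval(chrom, e.start, e.end) for e in exons]
            first, last = cds[0], cds[-1]
            cds[0] = GenomicInterval(chrom, first.start + 30, first.end)
            cds[-1] = GenomicInterval(chrom, last.start, last.end - 30)
            total = sum(c.length for c in cds)
            trim = total % 3
            if trim:
                cds[-1] = GenomicInterval(chrom, cds[-1].start, cds[-1].end - trim)
            seq = _random_cds_seq(sum(c.length for c in cds), rng)
            genes.append(GeneModel(name, chrom, strand, exons, cds, seq))
    return genes


def _cds_ref_base(g: GeneModel, pos: int) -> Optional[str]:
    """Genomic reference base at ``pos`` implied by the model's CDS sequence."""
    if g.cds_seq is None:
        return None
    off = g.cds_offset(pos)
    if off is None:
        return None
    base = g.cds_seq[off]
    return base if g.strand == "+" else base.translate(_COMPLEMENT)


def _pick_nonsynonymous(g: GeneModel, rng: np.random.Generator) -> Tuple[int, str, str]:
    """A CDS position plus ref/alt (genomic strand) giving a nonsynonymous change."""
    from Bio.Seq import Seq

    cds_positions = [p for c in g.sorted_cds() for p in range(c.start, c.end + 1)]
    for _ in range(200):
        pos = int(cds_positions[int(rng.integers(len(cds_positions)))])
        off = g.cds_offset(pos)
        ci, within = off // 3, off % 3
        codon = g.cds_seq[3 * ci : 3 * ci + 3]
        if len(codon) < 3:
            continue
        for alt_cds in map(str, rng.permutation(list(_BASES))):
            if alt_cds == codon[within]:
                continue
            mutant = codon[:within] + alt_cds + codon[within + 1 :]
            aa0, aa1 = str(Seq(codon).translate()), str(Seq(mutant).translate())
            if aa0 != aa1 and aa1 != "*" and aa0 != "*":
                ref = codon[within] if g.strand == "+" else codon[within].translate(_COMPLEMENT)
                alt = alt_cds if g.strand == "+" else alt_cds.translate(_COMPLEMENT)
                return pos, ref, alt
    raise RuntimeError(f"could not plant a nonsynonymous variant in {g.gene}")


# ---------------------------------------------------------------------------
# The full study
# ---------------------------------------------------------------------------

def _default_cnvs(cfg: SimulationConfig) -> List[PlantedCNV]:
    chrom2 = cfg.genome[1][0] if len(cfg.genome) > 1 else cfg.genome[0][0]
    chrom3 = cfg.genome[2][0] if len(cfg.genome) > 2 else cfg.genome[0][0]
    return [
        PlantedCNV(
            GenomicInterval(chrom2, 5_000_001, 6_000_000),
            "del",
            cfg.father_id,
            ("4", "10"),
        ),
        PlantedCNV(
            GenomicInterval(chrom3, 12_000_001, 13_200_000),
            "dup",
            cfg.mother_id,
            ("6", "7", "8"),
        ),
    ]


def simulate_family(
    config: Optional[SimulationConfig] = None,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> Tuple[Dict[str, Path], TruthSet]:
    """Generate the complete synthetic study and write all files to ``out_dir``.

    Returns (file manifest, truth set).  ``seed`` overrides ``config.seed``.
    Output is byte-identical for a fixed seed and config.
    """
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    if cfg.planted_cnvs is None:
        cfg = SimulationConfig(**{**cfg.__dict__, "planted_cnvs": _default_cnvs(cfg)})
    out = Path(out_dir) if out_dir is not None else Path("famprior_sim")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # -- pedigree -----------------------------------------------------------
    members = [
        PedigreeMember(cfg.mother_id, None, None, 2, False),
        PedigreeMember(cfg.father_id, None, None, 1, False),
    ]
    for c in cfg.child_ids:
        members.append(
            PedigreeMember(
                c,
                cfg.father_id,
                cfg.mother_id,
                int(rng.integers(1, 3)),
                c in cfg.affected_children,
            )
        )
    ped = Pedigree("FAM1", members)
    genotyped = [m.member_id for m in members if m.member_id not in cfg.ungenotyped_children]

    # -- markers and founder haplotypes -------------------------------------
    total_bp = sum(l for _, l in cfg.genome)
    marker_pos: Dict[str, np.ndarray] = {}
    founder_haps: Dict[Tuple[str, int], Dict[str, np.ndarray]] = {}
    for chrom, length in cfg.genome:
        n = max(10, round(cfg.n_markers * length / total_bp))
        pos = np.sort(rng.choice(np.arange(10_000, length - 10_000), size=n, replace=False))
        marker_pos[chrom] = pos.astype(np.int64)
        freq = rng.uniform(0.2, 0.8, size=n)
        for parent in (cfg.father_id, cfg.mother_id):
            for h in (0, 1):
                alleles = np.where(rng.random(n) < freq, "A", "B")
                founder_haps.setdefault((parent, h), {})[chrom] = alleles

    # -- the planted gene and causal haplotypes -----------------------------
    genes = _make_genes(cfg, rng)
    planted_gene: Optional[GeneModel] = None
    planted_keys: List[tuple] = []
    if cfg.plant_causal_gene:
        coding = [g for g in genes if g.is_coding and g.strand == "+" and g.chrom == cfg.genome[0][0]]
        planted_gene = coding[len(coding) // 2]
    causal_chrom = planted_gene.chrom if planted_gene else None
    causal_pos = (planted_gene.tx_start + planted_gene.tx_end) // 2 if planted_gene else None
    # the causal variant sits on haplotype 0 of each parent

    # -- meioses with rejection at the causal locus -------------------------
    transmissions: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    for child in cfg.child_ids:
        affected = child in cfg.affected_children
        for chrom, length in cfg.genome:
            morgans = length / 1e6 * cfg.cm_per_mb / 100.0
            pos = marker_pos[chrom]
            while True:
                orig = {}
                for role, parent in (("father", cfg.father_id), ("mother", cfg.mother_id)):
                    _, o, breaks = simulate_meiosis(
                        founder_haps[(parent, 0)][chrom],
                        founder_haps[(parent, 1)][chrom],
                        pos,
                        length,
                        morgans,
                        rng,
                    )
                    orig[role] = (o, breaks)
                if causal_chrom != chrom or causal_pos is None:
                    break
                got_f = _origin_at(orig["father"], pos, causal_pos)
                got_m = _origin_at(orig["mother"], pos, causal_pos)
                if affected and got_f == 0 and got_m == 0:
                    break
                if not affected and not (got_f == 0 and got_m == 0):
                    break
            for role in ("father", "mother"):
                transmissions.setdefault((child, role), {})[chrom] = orig[role][0]

    # -- marker genotypes ----------------------------------------------------
    markers: List[MarkerGenotypes] = []
    for chrom, _ in cfg.genome:
        pos = marker_pos[chrom]
        for i, p in enumerate(pos):
            gts: Dict[str, Optional[Tuple[str, str]]] = {}
            for parent in (cfg.father_id, cfg.mother_id):
                a = founder_haps[(parent, 0)][chrom][i]
                b = founder_haps[(parent, 1)][chrom][i]
                gts[parent] = (str(a), str(b))
            for child in cfg.child_ids:
                if child in cfg.ungenotyped_children:
                    continue
                fo = transmissions[(child, "father")][chrom][i]
                mo = transmissions[(child, "mother")][chrom][i]
                fa = founder_haps[(cfg.father_id, int(fo))][chrom][i]
                ma = founder_haps[(cfg.mother_id, int(mo))][chrom][i]
                gts[child] = (str(fa), str(ma))
            markers.append(MarkerGenotypes(f"m_{chrom}_{i}", chrom, int(p), gts))

    # -- background variants, frequencies, scores ---------------------------
    index = GeneIndex(genes)
    freqs: Dict[tuple, Dict[str, float]] = {}
    scores: Dict[tuple, Dict[str, float]] = {}
    databases = ["thousand_genomes", "esp5400", "cg46"]

    def background_variant() -> Variant:
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        p = int(rng.integers(10_000, length - 10_000))
        ref = None
        for g in index.overlapping(chrom, p, p):
            b = _cds_ref_base(g, p)
            if b is not None:
                ref = b
                break
        if ref is None:
            ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        zyg = "hom" if rng.random() < 0.3 else "het"
        if rng.random() < cfg.low_quality_frac:
            q = float(rng.uniform(0, 40 if zyg == "het" else 20))
        else:
            q = float(rng.uniform(45, 250))
        return Variant(GenomicInterval(chrom, p, p), ref, alt, zyg, round(q, 1))

    def annotate_site(key: tuple) -> None:
        if key in freqs:
            return
        fr: Dict[str, float] = {}
        if rng.random() < cfg.common_maf_frac:
            maf = float(rng.uniform(0.011, 0.4))
        else:
            maf = float(rng.uniform(0, 0.01)) if rng.random() < 0.6 else None
        if maf is not None:
            for db in databases:
                if rng.random() < 0.8:
                    fr[db] = round(min(0.5, max(0.0, maf * float(rng.uniform(0.8, 1.2)))), 5)
        freqs[key] = fr
        sc: Dict[str, float] = {}
        if rng.random() < 0.85:
            sc["sift"] = round(float(rng.uniform(0, 1)), 3)
            sc["polyphen"] = round(float(rng.uniform(0, 1)), 3)
        if rng.random() < 0.9:
            sc["gerp"] = round(float(rng.normal(0, 2.5)), 3)
        scores[key] = sc

    n_shared = int(cfg.n_background_variants * cfg.shared_background_frac)
    shared_pool = [background_variant() for _ in range(n_shared)]
    proband_ids = list(cfg.affected_children)
    proband_variants: Dict[str, List[Variant]] = {}
    for pid in proband_ids:
        own = [background_variant() for _ in range(cfg.n_background_variants - n_shared)]
        allv = {v.key: v for v in shared_pool + own}
        proband_variants[pid] = sorted(allv.values(), key=lambda v: v.key)
    for pid in proband_ids:
        for v in proband_variants[pid]:
            annotate_site(v.key)

    # -- planted compound-het variants --------------------------------------
    if planted_gene is not None:
        for _ in range(2):
            while True:
                pos_, ref_, alt_ = _pick_nonsynonymous(planted_gene, rng)
                key = (planted_gene.chrom, pos_, ref_, alt_)
                if key not in freqs and all(k[1] != pos_ for k in planted_keys):
                    break
            planted_keys.append(key)
            freqs[key] = {"thousand_genomes": 0.0027}
            scores[key] = {"sift": 0.01, "polyphen": 0.97, "gerp": 3.5}
            v = Variant(GenomicInterval(*key[:2], key[1]), ref_, alt_, "het", 180.0)
            for pid in proband_ids:
                proband_variants[pid] = sorted(
                    proband_variants[pid] + [v], key=lambda x: x.key
                )

    # -- planted non-coding variant + conservation/chromatin resources ------
    noncoding_key: Optional[tuple] = None
    elements: List[Tuple[GenomicInterval, float]] = []
    if cfg.plant_noncoding:
        chrom, length = cfg.genome[-1]
        p = int(length * 0.8)
        while index.overlapping(chrom, p, p):
            p += 5_000
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[int(rng.integers(4))]
        while alt == ref:
            alt = _BASES[int(rng.integers(4))]
        noncoding_key = (chrom, p, ref, alt)
        v = Variant(GenomicInterval(chrom, p, p), ref, alt, "het", 160.0)
        for pid in proband_ids:
            proband_variants[pid] = sorted(proband_variants[pid] + [v], key=lambda x: x.key)
        freqs[noncoding_key] = {"cg46": 0.001}
        scores[noncoding_key] = {"gerp": 4.2}
        elements.append((GenomicInterval(chrom, p - 200, p + 200), 3.4))
    for _ in range(cfg.n_conserved_elements):
        chrom, length = cfg.genome[int(rng.integers(len(cfg.genome)))]
        s = int(rng.integers(10_000, length - 2_000))
        elements.append(
            (GenomicInterval(chrom, s, s + int(rng.integers(100, 800))), round(float(rng.normal(2.0, 1.0)), 2))
        )

    # chromatin: tile each chromosome; the planted site gets state 1
    states: List[Tuple[GenomicInterval, int]] = []
    state_choices = np.arange(1, 16)
    for chrom, length in cfg.genome:
        cur = 1
        while cur < length:
            seg = int(rng.integers(5_000, 50_000))
            end = min(cur + seg - 1, length)
            st = int(rng.choice(state_choices))
            if noncoding_key is not None and chrom == noncoding_key[0] and cur <= noncoding_key[1] <= end:
                st = 1
            states.append((GenomicInterval(chrom, cur, end), st))
            cur = end + 1

    # -- CNV call table and pileup signals ----------------------------------
    cnvs: List[PlantedCNV] = list(cfg.planted_cnvs or [])
    cnv_rows: List[str] = []
    for cnv in cnvs:
        pos = marker_pos[cnv.interval.chrom]
        inside = (pos >= cnv.interval.start) & (pos <= cnv.interval.end)
        n_snps = max(2, int(inside.sum()))
        idx = np.nonzero(inside)[0]
        s_snp = f"m_{cnv.interval.chrom}_{idx[0]}" if idx.size else ""
        e_snp = f"m_{cnv.interval.chrom}_{idx[-1]}" if idx.size else ""
        for carrier in (cnv.carrier_parent,) + cnv.carrier_children:
            conf = round(float(rng.uniform(320, 900)), 1)
            cnv_rows.append(
                "\t".join(
                    [
                        cnv.interval.chrom,
                        str(cnv.interval.start),
                        str(cnv.interval.end),
                        cnv.kind,
                        carrier,
                        str(n_snps),
                        s_snp,
                        e_snp,
                        str(conf),
                    ]
                )
            )

    deletion_region = next((c.interval for c in cnvs if c.kind == "del"), None)
    control_region = None
    if deletion_region is not None:
        span = deletion_region.length
        chrom = deletion_region.chrom
        ctrl_start = deletion_region.end + span
        control_region = GenomicInterval(chrom, ctrl_start, ctrl_start + span - 1)

    manifest: Dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest[name] = path

    emit("family.ped", lambda p: write_ped(ped, p))
    emit(
        "genotypes.tsv",
        lambda p: write_genotype_table(markers, genotyped, p),
    )
    for pid in proband_ids:
        emit(f"proband_{pid}.vcf", lambda p, pid=pid: write_vcf(proband_variants[pid], p, sample=pid))
    emit("genes.tsv", lambda p: write_gene_models(genes, p))

    def write_freqs(path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\t" + "\t".join(databases) + "\n")
            for key in sorted(freqs):
                row = [key[0], str(key[1]), key[2], key[3]]
                row += [
                    ("" if db not in freqs[key] else f"{freqs[key][db]:g}") for db in databases
                ]
                fh.write("\t".join(row) + "\n")

    def write_scores(path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\tsift\tpolyphen\tgerp\n")
            for key in sorted(scores):
                sc = scores[key]
                row = [key[0], str(key[1]), key[2], key[3]]
                row += [("" if c not in sc else f"{sc[c]:g}") for c in ("sift", "polyphen", "gerp")]
                fh.write("\t".join(row) + "\n")

    emit("frequencies.tsv", write_freqs)
    emit("scores.tsv", write_scores)
    emit(
        "conserved_elements.bed",
        lambda p: write_bed([iv for iv, _ in elements], p, names=[f"{s:g}" for _, s in elements]),
    )
    emit(
        "chromatin_states.bed",
        lambda p: write_bed([iv for iv, _ in states], p, names=[str(s) for _, s in states]),
    )

    def write_cnvs(path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\ttype\tsample\tn_snps\tstart_snp\tend_snp\tconfidence\n")
            for row in cnv_rows:
                fh.write(row + "\n")

    emit("cnv_calls.tsv", write_cnvs)

    # depth + pileups over the deletion and a control region for proband 1
    if deletion_region is not None and control_region is not None:
        for label, region, copy in (
            ("deletion", deletion_region, 1),
            ("control", control_region, 2),
        ):
            positions = np.arange(region.start, region.end + 1, 500, dtype=np.int64)
            depths = rng.poisson(cfg.coverage * copy / 2.0, size=len(positions))
            het_sites = positions[:: max(1, len(positions) // 60)]
            piles = simulate_pileup(copy, het_sites.tolist(), cfg.coverage, rng, chrom=region.chrom)

            def write_depth(path, positions=positions, depths=depths, region=region):
                with open(path, "w") as fh:
                    fh.write("chrom\tpos\tdepth\n")
                    for p_, d in zip(positions, depths):
                        fh.write(f"{region.chrom}\t{p_}\t{d}\n")

            def write_piles(path, piles=piles):
                with open(path, "w") as fh:
                    fh.write("chrom\tpos\tref_count\talt_count\n")
                    for sp in piles:
                        fh.write(f"{sp.chrom}\t{sp.pos}\t{sp.ref_count}\t{sp.alt_count}\n")

            emit(f"depth_{label}.tsv", write_depth)
            emit(f"pileup_{label}.tsv", write_piles)

    truth = TruthSet(
        marker_positions=marker_pos,
        transmissions=transmissions,
        children=cfg.child_ids,
        affected=list(cfg.affected_children),
        planted_gene=planted_gene.gene if planted_gene else None,
        planted_variant_keys=planted_keys,
        planted_noncoding_key=noncoding_key,
        cnvs=cnvs,
        deletion_region=deletion_region,
        control_region=control_region,
    )

    def write_truth(path) -> None:
        doc = {
            "planted_gene": truth.planted_gene,
            "planted_variants": [list(k) for k in truth.planted_variant_keys],
            "planted_noncoding": list(noncoding_key) if noncoding_key else None,
            "affected": truth.affected,
            "cnvs": [
                {
                    "region": str(c.interval),
                    "kind": c.kind,
                    "carriers": sorted((c.carrier_parent,) + c.carrier_children),
                }
                for c in cnvs
            ],
            "transmissions": {
                f"{child}:{role}": {
                    chrom: "".join(map(str, vec.tolist())) for chrom, vec in per.items()
                }
                for (child, role), per in sorted(transmissions.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    emit("truth.json", write_truth)
    return manifest, truth


def _origin_at(orig: Tuple[np.ndarray, np.ndarray], marker_pos: np.ndarray, pos: int) -> int:
    """Origin of a gamete at an arbitrary position, from its crossover list."""
    origins, breaks = orig
    if len(origins) == 0:
        return 0
    # start parity = origin at the first marker minus crossovers before it
    start = (int(origins[0]) - int(np.searchsorted(breaks, marker_pos[0]))) % 2
    return (start + int(np.searchsorted(breaks, pos))) % 2
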