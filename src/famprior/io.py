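"""Readers and writers for the standard formats the pipeline consumes.

Conventions
-----------
* Package-internal coordinates are 1-based inclusive; BED files are converted
  to/from 0-based half-open at this boundary.
* PED is the classic 6-column format (family, id, father, mother, sex,
  phenotype) with ``0`` meaning "missing parent" and phenotype 2 = affected.
* All TSV parsers reject duplicate identifiers and report the offending line
  number in the error message.
* VCF is read with cyvcf2 (zygosity from GT, quality from QUAL); multi-allelic
  records are decomposed into bi-allelic variants on read.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .intervals import GenomicInterval, RegionSet
from .pedigree import Pedigree, PedigreeMember
from .variants import GeneModel, Variant

__all__ = [
    "read_ped",
    "write_ped",
    "read_bed",
    "read_bed_records",
    "write_bed",
    "read_vcf",
    "write_vcf",
    "read_gene_models",
    "write_gene_models",
    "read_frequency_table",
    "read_score_table",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def _err(path, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path) -> Pedigree:
    members: List[PedigreeMember] = []
    seen: Dict[str, int] = {}
    family_id = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise _err(path, lineno, f"expected 6 PED columns, got {len(fields)}")
            fam, mid, fid, moid, sex, pheno = fields[:6]
            if family_id is None:
                family_id = fam
            if mid in seen:
                raise _err(path, lineno, f"duplicate member id {mid!r} (first at line {seen[mid]})")
            seen[mid] = lineno
            members.append(
                PedigreeMember(
                    member_id=mid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if moid == "0" else moid,
                    sex=int(sex),
                    affected=pheno == "2",
                )
            )
    return Pedigree(family_id=family_id or "FAM", members=members)


def write_ped(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for m in ped.members:
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        m.member_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        str(m.sex),
                        "2" if m.affected else "1",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk)
# ---------------------------------------------------------------------------

def read_bed_records(path) -> List[Tuple[GenomicInterval, Optional[str]]]:
    """Read BED rows as (1-based inclusive interval, 4th-column value or None)."""
    out: List[Tuple[GenomicInterval, Optional[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _err(path, lineno, "BED line has fewer than 3 columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if end0 <= start0:
                raise _err(path, lineno, f"empty BED interval {start0}-{end0}")
            name = fields[3] if len(fields) > 3 else None
            out.append((GenomicInterval(chrom, start0 + 1, end0), name))
    return out


def read_bed(path) -> RegionSet:
    return RegionSet(iv for iv, _ in read_bed_records(path))


def write_bed(intervals, path, names: Optional[Sequence[str]] = None) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED rows."""
    ivs = list(intervals)
    if names is not None and len(names) != len(ivs):
        raise ValueError("names must match intervals one-to-one")
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            row = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if names is not None:
                row.append(str(names[i]))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> List[Variant]:
    """Read a single-sample VCF into :class:`Variant` records.

    Multi-allelic sites are decomposed into one bi-allelic record per ALT
    allele; zygosity comes from GT (two identical non-reference alleles =
    ``hom``), quality from the QUAL column.
    """
    from cyvcf2 import VCF

    out: List[Variant] = []
    vcf = VCF(str(path))
    try:
        if len(vcf.samples) != 1:
            raise ValueError(f"{path}: expected a single-sample VCF, got {len(vcf.samples)}")
        for rec in vcf:
            gt = rec.genotypes[0][:2] if rec.genotypes else None
            for ai, alt in enumerate(rec.ALT, start=1):
                if gt is not None:
                    n_alt = sum(1 for a in gt if a == ai)
                    if n_alt == 0:
                        continue
                    zyg = "hom" if n_alt == 2 else "het"
                else:
                    zyg = "het"
                end = rec.POS + max(len(rec.REF), 1) - 1
                out.append(
                    Variant(
                        interval=GenomicInterval(rec.CHROM, rec.POS, end),
                        ref=rec.REF,
                        alt=alt,
                        zygosity=zyg,
                        quality=None if rec.QUAL is None else float(rec.QUAL),
                    )
                )
    finally:
        vcf.close()
    return out


def write_vcf(variants: Sequence[Variant], path, sample: str = "SAMPLE") -> None:
    """Write variants as a minimal uncompressed VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({v.chrom for v in variants}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            gt = "1/1" if v.zygosity == "hom" else "0/1"
            qual = "." if v.quality is None else f"{v.quality:g}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\tPASS\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# Gene-model TSV
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene", "chrom", "strand", "exon_starts", "exon_ends", "cds_starts", "cds_ends", "cds_seq"]


def _int_list(s: str) -> List[int]:
    s = s.strip()
    return [int(x) for x in s.split(",") if x] if s else []


def read_gene_models(path) -> List[GeneModel]:
    """Read transcript models from a TSV with comma-separated exon/CDS bounds."""
    out: List[GeneModel] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _GENE_COLS[:5] if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"{path}: missing gene-model columns {missing}")
        for lineno, row in enumerate(reader, 2):
            gene = row["gene"]
            if gene in seen:
                raise _err(path, lineno, f"duplicate gene id {gene!r} (first at line {seen[gene]})")
            seen[gene] = lineno
            chrom = row["chrom"]
            ex = [
                GenomicInterval(chrom, s, e)
                for s, e in zip(_int_list(row["exon_starts"]), _int_list(row["exon_ends"]))
            ]
            cds = [
                GenomicInterval(chrom, s, e)
                for s, e in zip(_int_list(row.get("cds_starts", "")), _int_list(row.get("cds_ends", "")))
            ]
            seq = (row.get("cds_seq") or "").strip() or None
            out.append(GeneModel(gene=gene, chrom=chrom, strand=row["strand"], exons=ex, cds=cds, cds_seq=seq))
    return out


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            ex = g.sorted_exons()
            cds = g.sorted_cds()
            fh.write(
                "\t".join(
                    [
                        g.gene,
                        g.chrom,
                        g.strand,
                        ",".join(str(e.start) for e in ex),
                        ",".join(str(e.end) for e in ex),
                        ",".join(str(c.start) for c in cds),
                        ",".join(str(c.end) for c in cds),
                        g.cds_seq or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Frequency and score tables (keyed by chrom, pos, ref, alt)
# ---------------------------------------------------------------------------

def _read_site_table(path, value_cols: Optional[Sequence[str]] = None):
    rows: Dict[tuple, Dict[str, float]] = {}
    seen: Dict[tuple, int] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        for key_col in ("chrom", "pos", "ref", "alt"):
            if key_col not in cols:
                raise ParseError(f"{path}: missing key column {key_col!r}")
        vcols = list(value_cols) if value_cols is not None else [
            c for c in cols if c not in ("chrom", "pos", "ref", "alt")
        ]
        for lineno, row in enumerate(reader, 2):
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            if key in seen:
                raise _err(path, lineno, f"duplicate site {key} (first at line {seen[key]})")
            seen[key] = lineno
            vals = {}
            for c in vcols:
                raw = (row.get(c) or "").strip()
                if raw not in ("", ".", "NA"):
                    vals[c] = float(raw)
            rows[key] = vals
    return rows, vcols


def read_frequency_table(path) -> Tuple[Dict[tuple, Dict[str, float]], List[str]]:
    """Per-site MAF table; returns (site -> {database: MAF}, database names)."""
    return _read_site_table(path)


def read_score_table(path) -> Dict[tuple, Dict[str, float]]:
    """Per-site deleteriousness scores with columns sift, polyphen, gerp."""
    rows, _ = _read_site_table(path, value_cols=["sift", "polyphen", "gerp"])
    return rows
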