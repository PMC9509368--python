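"""File-format edge of the pipeline.

SNP and SV VCFs go through pysam; GFF3 through gffutils; BED, occupancy /
genotype / expression matrices, and window tracks are plain TSV via pandas.
All writers are deterministic (no timestamps), so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .popgen import GenotypeMatrix, WindowTrack
from .sv import SVRecord

__all__ = [
    "GeneModel",
    "write_snp_vcf",
    "read_snp_vcf",
    "write_sv_vcf",
    "read_sv_vcf",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "read_bed",
    "write_track",
    "read_track",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_truth_json",
]


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """Gene with exon/CDS structure; all intervals 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models (gene + exon + CDS features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon", order_by="start")]
        cds = [(c.start - 1, c.end) for c in db.children(g, featuretype="CDS", order_by="start")]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand or "+",
                exons=exons,
                cds=cds,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            f"{g.chrom}\tsilkpan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\tsilkpan\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for i, (lo, hi) in enumerate(g.exons):
            lines.append(
                f"{g.chrom}\tsilkpan\texon\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={mrna}.exon{i + 1};Parent={mrna}"
            )
        for i, (lo, hi) in enumerate(g.cds):
            lines.append(
                f"{g.chrom}\tsilkpan\tCDS\t{lo + 1}\t{hi}\t.\t{g.strand}\t0\t"
                f"ID={mrna}.cds{i + 1};Parent={mrna}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SNP VCF


_DOSAGE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}


def _vcf_header(sample_ids, chrom_lengths=None, sv: bool = False) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in (chrom_lengths or {}).items():
        header.contigs.add(str(chrom), length=int(length))
    if sv:
        header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
        header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
        for t in ("DEL", "INS", "DUP", "INV"):
            header.add_line(f"##ALT=<ID={t},Description={t}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in sample_ids:
        header.add_sample(s)
    return header


def write_snp_vcf(gm: GenotypeMatrix, path, chrom_lengths=None) -> None:
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(gm.positions[gm.chroms == c].max()) + 1000 for c in np.unique(gm.chroms)
        }
    header = _vcf_header(gm.sample_ids, chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(gm.n_sites):
            rec = out.new_record(
                contig=str(gm.chroms[j]),
                start=int(gm.positions[j]) - 1,
                stop=int(gm.positions[j]),
                alleles=("A", "T"),
            )
            for i, s in enumerate(gm.sample_ids):
                rec.samples[s]["GT"] = _DOSAGE_TO_GT[int(gm.dosages[i, j])]
            out.write(rec)


def read_snp_vcf(path, populations: dict | None = None) -> GenotypeMatrix:
    """Load biallelic SNP records into a dosage matrix (multi-allelic skipped)."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        chroms, positions, rows = [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            row = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[i] = -1
                else:
                    row[i] = sum(gt)
            rows.append(row)
    dosages = np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=samples,
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        dosages=dosages,
        populations=populations or {},
    )


# ---------------------------------------------------------------------------
# SV VCF


def write_sv_vcf(svs: list[SVRecord], path, sample_ids=None, chrom_lengths=None) -> None:
    """Write SV records with SVTYPE/SVLEN/END INFO and per-sample GT.

    When ``sample_ids`` is omitted the union of record samples is used; a
    record contributes its genotype to its own sample and 0/0 elsewhere.
    """
    if sample_ids is None:
        sample_ids = sorted({r.sample for r in svs if r.sample is not None}) or ["sample1"]
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in svs:
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), r.end + 1000)
    header = _vcf_header(sample_ids, chrom_lengths, sv=True)
    recs = sorted(svs, key=lambda r: (r.chrom, r.pos, r.svtype, r.sample or ""))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in recs:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                stop=max(r.end, r.pos),
                alleles=("N", f"<{r.svtype}>"),
            )
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = r.length if r.svtype != "DEL" else -r.length
            # END is reserved in htslib and derived from rec.stop automatically
            gt = tuple(int(x) if x != "." else None for x in r.genotype.replace("|", "/").split("/"))
            for s in sample_ids:
                rec.samples[s]["GT"] = gt if s == r.sample else (0, 0)
            out.write(rec)


def read_sv_vcf(path) -> list[SVRecord]:
    """Read SV records; one SVRecord per (site, sample) with a non-0/0 call."""
    out: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            svlen = abs(int(rec.info.get("SVLEN", 0)))
            # SVLEN is authoritative: htslib rewrites END around the padding
            # base for symbolic alleles, so END conventions vary by producer.
            end = rec.pos if svtype == "INS" else rec.pos + svlen - 1
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a in (0, None) for a in gt):
                    continue
                gt_str = "/".join("." if a is None else str(a) for a in gt)
                out.append(
                    SVRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        end=end,
                        svtype=svtype,
                        length=svlen,
                        sample=s,
                        genotype=gt_str,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# BED / tracks / matrices


def write_bed(intervals, path, scores=None) -> None:
    """(chrom, start, end) triples as BED; optional fourth score column."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            if scores is None:
                fh.write(f"{chrom}\t{start}\t{end}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{scores[i]}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_track(track: WindowTrack, path) -> None:
    """One-line-header TSV dialect: chrom, start, end, <statistic>."""
    track.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
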