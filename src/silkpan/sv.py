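"""Structural-variant cohort toolkit.

Builds a non-redundant SV site set from per-sample calls by breakpoint
clustering, applies the cohort filters (size cap, 0/0 genotypes, error-prone
regions), computes group allele frequencies and divergence scans, annotates
genomic context against gene models, and derives summary statistics
(rare-allele fraction, multi-allelic loci, TE-window correlation, pan-SV
accumulation, group-specific SVs).

SV intervals are half-open after conversion from 1-based coordinates;
insertions are treated as 1-bp point intervals for every overlap test.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import stats
from .pangene import accumulation_curves

SV_TYPES = ("INS", "DEL", "DUP", "INV")
MIN_SV_LEN = 50

__all__ = [
    "SVRecord",
    "NrSVSite",
    "GeneContext",
    "merge_svs",
    "filter_svs",
    "allele_frequency",
    "rare_fraction",
    "sv_divergence_scan",
    "annotate_sv_context",
    "multiallelic_summary",
    "sv_te_window_correlation",
    "pan_sv_accumulation",
    "group_specific_svs",
]


@dataclass
class SVRecord:
    """One structural-variant call, optionally tied to a source sample."""

    chrom: str
    pos: int  # 1-based start
    end: int  # 1-based inclusive end; == pos for insertions
    svtype: str
    length: int
    sample: str | None = None
    genotype: str = "0/1"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.length < MIN_SV_LEN:
            raise ValueError(f"SV length {self.length} below the {MIN_SV_LEN} bp minimum")
        if self.svtype == "INS":
            if self.end != self.pos:
                raise ValueError("insertion end must equal pos")
        elif self.end - self.pos + 1 != self.length:
            raise ValueError("end - pos inconsistent with length")

    def interval(self) -> tuple[int, int]:
        """0-based half-open interval; insertions are 1-bp points."""
        if self.svtype == "INS":
            return self.pos - 1, self.pos
        return self.pos - 1, self.end


@dataclass
class NrSVSite:
    site_id: str
    representative: SVRecord
    members: list[SVRecord] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len({m.sample for m in self.members})


def _dosage(gt: str) -> int:
    if gt in ("./.", ".", None):
        return -1
    try:
        return sum(int(x) for x in gt.replace("|", "/").split("/"))
    except ValueError:
        return -1


def _seq_identity(a: str, b: str) -> float:
    import edlib

    if not a or not b:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _single_linkage(records: list[SVRecord], max_dist: int, predicate) -> list[list[SVRecord]]:
    """Single-linkage clusters over records sorted by position.

    Pairs farther apart than ``max_dist`` can never link, so each record only
    needs to be compared against the positional window behind it.
    """
    order = sorted(range(len(records)), key=lambda i: (records[i].pos, records[i].sample or ""))
    uf = _UnionFind(len(records))
    for oi in range(len(order)):
        i = order[oi]
        oj = oi - 1
        while oj >= 0:
            j = order[oj]
            if records[i].pos - records[j].pos > max_dist:
                break
            if predicate(records[i], records[j]):
                uf.union(i, j)
            oj -= 1
    clusters: dict[int, list[SVRecord]] = {}
    for i in range(len(records)):
        clusters.setdefault(uf.find(i), []).append(records[i])
    return list(clusters.values())


def merge_svs(
    per_sample_svs: list[SVRecord],
    max_dist: int = 500,
    size_ratio_min: float = 0.7,
    require_same_type: bool = True,
    min_seq_identity: float = 0.25,
) -> tuple[list[NrSVSite], pd.DataFrame]:
    """Collapse per-sample calls into non-redundant SV sites.

    Single-linkage clustering within (chrom, type): records link when their
    start positions differ by at most ``max_dist`` bp and min(len)/max(len)
    >= ``size_ratio_min``; when both records carry sequences the sequence
    identity must additionally reach ``min_seq_identity``.  The representative
    is the member with the median position (ties broken by the smallest
    sample id).  Returns the sites and a site x sample dosage matrix
    (0/1/2, -1 missing; samples without a member call are 0).
    """

    def linked(a: SVRecord, b: SVRecord) -> bool:
        if abs(a.pos - b.pos) > max_dist:
            return False
        if min(a.length, b.length) / max(a.length, b.length) < size_ratio_min:
            return False
        if a.sequence and b.sequence and _seq_identity(a.sequence, b.sequence) < min_seq_identity:
            return False
        return True

    keys = sorted({(r.chrom, r.svtype if require_same_type else "") for r in per_sample_svs})
    samples = sorted({r.sample for r in per_sample_svs if r.sample is not None})
    sites: list[NrSVSite] = []
    for chrom, svtype in keys:
        group = [
            r
            for r in per_sample_svs
            if r.chrom == chrom and (not require_same_type or r.svtype == svtype)
        ]
        for members in _single_linkage(group, max_dist, linked):
            members = sorted(members, key=lambda m: (m.pos, m.sample or ""))
            rep = members[(len(members) - 1) // 2]
            sites.append(NrSVSite(site_id="", representative=rep, members=members))
    sites.sort(key=lambda s: (s.representative.chrom, s.representative.pos, s.representative.svtype))
    rows = {}
    for i, site in enumerate(sites):
        site.site_id = f"nrSV{i + 1:06d}"
        row = dict.fromkeys(samples, 0)
        for m in site.members:
            if m.sample is not None:
                row[m.sample] = max(row[m.sample], _dosage(m.genotype))
        rows[site.site_id] = row
    geno = pd.DataFrame.from_dict(rows, orient="index", columns=samples, dtype=int)
    return sites, geno


def filter_svs(
    svs: list[SVRecord],
    error_regions: list[tuple[str, int, int]] | None = None,
    flank: int = 2500,
    max_len: int = 100_000,
) -> tuple[list[SVRecord], dict]:
    """Apply the cohort SV filters; returns survivors and a removal tally.

    A record is removed when (checked in this order) it is strictly longer
    than ``max_len``, its genotype is homozygous reference (0/0), or its
    interval intersects any error-prone region expanded by ``flank`` bp on
    both sides.  Error regions are (chrom, start, end) half-open 0-based.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in error_regions or []:
        trees.setdefault(chrom, IntervalTree()).addi(max(0, start - flank), end + flank)
    survivors: list[SVRecord] = []
    tally = {"size": 0, "genotype": 0, "region": 0}
    for sv in svs:
        if sv.length > max_len:
            tally["size"] += 1
            continue
        if _dosage(sv.genotype) == 0:
            tally["genotype"] += 1
            continue
        lo, hi = sv.interval()
        tree = trees.get(sv.chrom)
        if tree is not None and tree.overlap(lo, hi):
            tally["region"] += 1
            continue
        survivors.append(sv)
    return survivors, tally


def allele_frequency(geno: pd.DataFrame, samples: list[str] | None = None) -> pd.Series:
    """Alternate allele frequency per site: alt alleles / (2 x called samples)."""
    sub = geno if samples is None else geno[list(samples)]
    mat = sub.to_numpy()
    called = mat >= 0
    n_called = called.sum(axis=1)
    alt = np.where(called, mat, 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        af = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    return pd.Series(af, index=geno.index, name="af")


def rare_fraction(af: pd.Series, threshold: float = 0.05) -> float:
    """Fraction of sites with allele frequency strictly below ``threshold``."""
    vals = af.dropna().to_numpy()
    if vals.size == 0:
        raise ValueError("no sites with a defined allele frequency")
    return float(np.mean(vals < threshold))


def carrier_counts(geno: pd.DataFrame, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(carriers, called) per site; carrier = genotype with >= 1 alt allele."""
    mat = geno[list(samples)].to_numpy()
    called = mat >= 0
    carriers = (mat > 0).sum(axis=1)
    return carriers, called.sum(axis=1)


def sv_divergence_scan(
    geno: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    fdr: float = 1e-4,
    fc: float = 2.0,
) -> pd.DataFrame:
    """Carrier-frequency divergence scan between two sample groups.

    Per site, a 2x2 carrier/non-carrier table is tested with Fisher's exact
    test, p-values undergo Benjamini-Hochberg correction across all sites,
    and the fold change compares carrier frequencies.  Significant means
    q < ``fdr`` and fold change > ``fc``.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need at least two samples")
    if set(samples_a) & set(samples_b):
        raise ValueError("sample groups must be disjoint")
    car_a, n_a = carrier_counts(geno, samples_a)
    car_b, n_b = carrier_counts(geno, samples_b)
    pvals = np.ones(len(geno))
    for i in range(len(geno)):
        if n_a[i] == 0 or n_b[i] == 0:
            pvals[i] = 1.0
            continue
        pvals[i] = stats.fisher_exact_two_sided(
            [[int(car_a[i]), int(n_a[i] - car_a[i])], [int(car_b[i]), int(n_b[i] - car_b[i])]]
        )
    qvals = stats.bh_fdr(pvals)
    with np.errstate(invalid="ignore"):
        freq_a = np.where(n_a > 0, car_a / np.maximum(n_a, 1), np.nan)
        freq_b = np.where(n_b > 0, car_b / np.maximum(n_b, 1), np.nan)
    fcs = np.array(
        [
            stats.fold_change(fa, fb) if np.isfinite(fa) and np.isfinite(fb) else math.nan
            for fa, fb in zip(freq_a, freq_b)
        ]
    )
    significant = (qvals < fdr) & (fcs > fc)
    direction = np.where(freq_b > freq_a, "increased", np.where(freq_b < freq_a, "reduced", "unchanged"))
    return pd.DataFrame(
        {
            "carrier_freq_a": freq_a,
            "carrier_freq_b": freq_b,
            "p": pvals,
            "q": qvals,
            "fold_change": fcs,
            "significant": significant,
            "direction": direction,
        },
        index=geno.index,
    )


# ---------------------------------------------------------------------------
# genomic context


@dataclass
class GeneContext:
    category: str  # CDS > regulatory > intergenic
    genes: list[str] = field(default_factory=list)
    relations: list[tuple[str, str]] = field(default_factory=list)  # (gene, relation)


def annotate_sv_context(svs, gene_models, flank: int = 5000) -> list[GeneContext]:
    """Genomic context per SV against gene models with CDS/exon structure.

    Category CDS when the SV interval overlaps any CDS exon; otherwise
    regulatory when it overlaps a gene body outside CDS (introns, UTR exons)
    or the +/- ``flank`` bp around the gene; otherwise intergenic.  Relations
    recorded per overlapped gene: cds, intron, genebody (non-CDS exonic),
    flank_up, flank_down.  ``svs`` may be SVRecord objects or (chrom, start,
    end) half-open tuples.
    """
    cds_tree: dict[str, IntervalTree] = {}
    exon_tree: dict[str, IntervalTree] = {}
    body_tree: dict[str, IntervalTree] = {}
    up_tree: dict[str, IntervalTree] = {}
    down_tree: dict[str, IntervalTree] = {}

    def _add(trees, chrom, lo, hi, data):
        if hi > lo:
            trees.setdefault(chrom, IntervalTree()).addi(lo, hi, data)

    for g in gene_models:
        _add(body_tree, g.chrom, g.start, g.end, g.gene_id)
        for lo, hi in getattr(g, "cds", []) or []:
            _add(cds_tree, g.chrom, lo, hi, g.gene_id)
        for lo, hi in getattr(g, "exons", []) or []:
            _add(exon_tree, g.chrom, lo, hi, g.gene_id)
        upstream = (max(0, g.start - flank), g.start)
        downstream = (g.end, g.end + flank)
        if getattr(g, "strand", "+") == "-":
            upstream, downstream = (g.end, g.end + flank), (max(0, g.start - flank), g.start)
        _add(up_tree, g.chrom, *upstream, g.gene_id)
        _add(down_tree, g.chrom, *downstream, g.gene_id)

    out: list[GeneContext] = []
    for sv in svs:
        if isinstance(sv, SVRecord):
            chrom, (lo, hi) = sv.chrom, sv.interval()
        else:
            chrom, lo, hi = sv
        relations: list[tuple[str, str]] = []

        def hits(trees):
            t = trees.get(chrom)
            return {iv.data for iv in t.overlap(lo, hi)} if t is not None else set()

        cds_genes = hits(cds_tree)
        exon_genes = hits(exon_tree)
        body_genes = hits(body_tree)
        up_genes = hits(up_tree)
        down_genes = hits(down_tree)
        for gid in sorted(body_genes | up_genes | down_genes):
            if gid in cds_genes:
                relations.append((gid, "cds"))
            elif gid in body_genes and gid not in exon_genes:
                relations.append((gid, "intron"))
            elif gid in body_genes:
                relations.append((gid, "genebody"))
            elif gid in up_genes:
                relations.append((gid, "flank_up"))
            else:
                relations.append((gid, "flank_down"))
        if cds_genes:
            category = "CDS"
        elif relations:
            category = "regulatory"
        else:
            category = "intergenic"
        out.append(GeneContext(category=category, genes=[g for g, _ in relations], relations=relations))
    return out


def multiallelic_summary(sites: list[NrSVSite], max_dist: int = 500) -> dict:
    """Allele-count distribution of co-located non-redundant SVs.

    Loci are single-linkage clusters of nrSVs of any type whose start
    positions lie within ``max_dist`` (no size or type constraint).  Returns
    the histogram of alleles per locus, the maximum, and the fraction of loci
    with two or more alleles.
    """
    reps = [s.representative for s in sites]
    clusters: list[list[SVRecord]] = []
    for chrom in sorted({r.chrom for r in reps}):
        group = [r for r in reps if r.chrom == chrom]
        clusters.extend(
            _single_linkage(group, max_dist, lambda a, b: abs(a.pos - b.pos) <= max_dist)
        )
    counts = Counter(len(c) for c in clusters)
    n_loci = len(clusters)
    multi = sum(v for k, v in counts.items() if k >= 2)
    return {
        "histogram": dict(sorted(counts.items())),
        "n_loci": n_loci,
        "max_alleles": max(counts) if counts else 0,
        "multiallelic_fraction": multi / n_loci if n_loci else math.nan,
    }


def sv_te_window_correlation(
    sv_positions: list[tuple[str, int]],
    te_intervals: list[tuple[str, int, int]],
    chrom_lengths: dict,
    window: int = 500_000,
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """SV and TE counts in non-overlapping windows plus their Pearson fit.

    TEs are assigned to the window containing their midpoint; SVs by their
    position (1-based).  Requires at least three windows and non-constant
    counts.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, int(length), window):
            rows.append((str(chrom), start, min(start + window, int(length))))
    if len(rows) < 3:
        raise ValueError("need at least three windows")
    index = {(c, s): i for i, (c, s, _) in enumerate(rows)}
    sv_counts = np.zeros(len(rows))
    te_counts = np.zeros(len(rows))
    for chrom, pos in sv_positions:
        key = (str(chrom), ((pos - 1) // window) * window)
        if key in index:
            sv_counts[index[key]] += 1
    for chrom, start, end in te_intervals:
        mid = (start + end) // 2
        key = (str(chrom), (mid // window) * window)
        if key in index:
            te_counts[index[key]] += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["sv_count"] = sv_counts
    df["te_count"] = te_counts
    r, r2, p = stats.pearson_linear(te_counts, sv_counts)
    return df, (r, r2, p)


def pan_sv_accumulation(
    geno: pd.DataFrame,
    n_permutations: int = 100,
    seed: int | None = None,
    order: list | None = None,
) -> pd.DataFrame:
    """Pan-/core-SV counts versus genomes added, on presence (dosage > 0)."""
    presence = geno > 0
    return accumulation_curves(presence, n_permutations=n_permutations, seed=seed, order=order)


def group_specific_svs(
    geno: pd.DataFrame,
    target_samples: list[str],
    contrast_samples: list[str],
    population_af_max: float = 0.05,
) -> pd.DataFrame:
    """Sites carried by every target, absent from every contrast, rare overall.

    Cohort allele frequency is computed over all samples in the matrix and
    must be strictly below ``population_af_max``.
    """
    if set(target_samples) & set(contrast_samples):
        raise ValueError("target and contrast sample sets must be disjoint")
    tgt = geno[list(target_samples)].to_numpy()
    ctr = geno[list(contrast_samples)].to_numpy()
    present_all = np.all(tgt > 0, axis=1)
    absent_all = np.all(ctr == 0, axis=1)
    af = allele_frequency(geno).to_numpy()
    keep = present_all & absent_all & (af < population_af_max)
    out = pd.DataFrame({"af": af[keep]}, index=geno.index[keep])
    return out
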