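"""SV merging, filtering, frequencies, context annotation, and summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from silkpan import sv
from silkpan.io import GeneModel
from silkpan.sv import SVRecord


def rec(pos, length=500, svtype="DEL", sample="s1", chrom="chr1", genotype="0/1", seq=None):
    end = pos if svtype == "INS" else pos + length - 1
    return SVRecord(chrom=chrom, pos=pos, end=end, svtype=svtype, length=length,
                    sample=sample, genotype=genotype, sequence=seq)


# ---------------------------------------------------------------------------
# record validation and merging


def test_record_validation():
    with pytest.raises(ValueError):
        rec(100, length=49)
    with pytest.raises(ValueError):
        SVRecord("chr1", 100, 100, "DEL", 500)  # end inconsistent
    with pytest.raises(ValueError):
        SVRecord("chr1", 100, 200, "INS", 500)  # insertion end must equal pos


def test_merge_identical_calls_single_site():
    sites, geno = sv.merge_svs([rec(1000, sample="s1"), rec(1000, sample="s2")])
    assert len(sites) == 1
    assert sites[0].support == 2
    assert geno.loc[sites[0].site_id].tolist() == [1, 1]


def test_merge_distance_and_size_ratio():
    calls = [
        rec(1000, length=500, sample="s1"),
        rec(1200, length=480, sample="s2"),  # dist 200, ratio 0.96 -> clusters
        rec(5000, length=500, sample="s3"),  # far away
    ]
    sites, _ = sv.merge_svs(calls)
    assert len(sites) == 2
    supports = sorted(s.support for s in sites)
    assert supports == [1, 2]


def test_merge_never_joins_types():
    sites, _ = sv.merge_svs([rec(1000, svtype="DEL"), rec(1000, svtype="INS", sample="s2")])
    assert len(sites) == 2


def test_merge_size_ratio_blocks():
    sites, _ = sv.merge_svs([rec(1000, length=500), rec(1100, length=100, sample="s2")])
    assert len(sites) == 2


def test_merge_sequence_identity_gate():
    a = rec(1000, svtype="INS", length=60, sample="s1", seq="A" * 60)
    b = rec(1050, svtype="INS", length=60, sample="s2", seq="A" * 60)
    c = rec(1050, svtype="INS", length=60, sample="s3", seq="T" * 60)
    sites, _ = sv.merge_svs([a, b])
    assert len(sites) == 1
    sites, _ = sv.merge_svs([a, c])
    assert len(sites) == 2


def test_merge_idempotent_and_shuffle_invariant():
    rng = np.random.default_rng(0)
    calls = []
    for i, base in enumerate(range(0, 50_000, 2000)):  # clusters separated by > max_dist
        for j in range(3):
            calls.append(rec(base + 1000 + int(rng.integers(0, 200)),
                             length=500 + int(rng.integers(0, 50)), sample=f"s{j}"))
    sites1, geno1 = sv.merge_svs(calls)
    shuffled = list(calls)
    rng.shuffle(shuffled)
    sites2, geno2 = sv.merge_svs(shuffled)
    key = lambda ss: [(s.representative.pos, s.support) for s in ss]
    assert key(sites1) == key(sites2)
    pd.testing.assert_frame_equal(geno1, geno2)
    # merging representatives again changes nothing
    reps = [s.representative for s in sites1]
    sites3, _ = sv.merge_svs(reps)
    assert len(sites3) == len(sites1)


def test_merge_representative_median_position():
    calls = [rec(1000, sample="s3"), rec(1100, sample="s1"), rec(1200, sample="s2")]
    sites, _ = sv.merge_svs(calls)
    assert sites[0].representative.pos == 1100


# ---------------------------------------------------------------------------
# filters


def test_filter_toy_tally():
    svs = [
        rec(1000, length=150_000),          # size
        rec(2000, genotype="0/0"),          # genotype
        rec(10_000),                        # inside region + flank
        rec(50_000),                        # clean
    ]
    kept, tally = sv.filter_svs(svs, error_regions=[("chr1", 11_000, 12_000)], flank=2500)
    assert tally == {"size": 1, "genotype": 1, "region": 1}
    assert len(kept) == 1 and kept[0].pos == 50_000
    assert len(kept) + sum(tally.values()) == len(svs)


def test_filter_size_boundary_strict():
    kept, tally = sv.filter_svs([rec(1000, length=100_000)])
    assert len(kept) == 1 and tally["size"] == 0
    kept, tally = sv.filter_svs([rec(1000, length=100_001)])
    assert len(kept) == 0 and tally["size"] == 1


def test_filter_no_regions():
    kept, tally = sv.filter_svs([rec(1000), rec(2000, genotype="0/0")])
    assert len(kept) == 1 and tally == {"size": 0, "genotype": 1, "region": 0}


# ---------------------------------------------------------------------------
# allele frequencies and divergence


def test_allele_frequency_counting():
    geno = pd.DataFrame([[1, 1, 1] + [0] * 7], index=["sv1"],
                        columns=[f"s{i}" for i in range(10)])
    assert sv.allele_frequency(geno).iloc[0] == pytest.approx(0.15)
    geno2 = pd.DataFrame([[2] * 10], index=["sv2"], columns=geno.columns)
    assert sv.allele_frequency(geno2).iloc[0] == 1.0
    geno3 = pd.DataFrame([[-1] * 10], index=["sv3"], columns=geno.columns)
    assert math.isnan(sv.allele_frequency(geno3).iloc[0])


def test_rare_fraction_constructed_cohort():
    # 40 of 100 sites at AF 0.025 (< 0.05), 60 at AF 0.5 across 20 samples
    rows = [[1] + [0] * 19] * 40 + [[1] * 20] * 60
    geno = pd.DataFrame(rows, index=[f"sv{i}" for i in range(100)],
                        columns=[f"s{i}" for i in range(20)])
    assert sv.rare_fraction(sv.allele_frequency(geno)) == pytest.approx(0.40)


def test_divergence_scan_toy():
    a = [f"a{i}" for i in range(40)]
    b = [f"b{i}" for i in range(40)]
    shifted = [1] * 30 + [0] * 10 + [1] * 2 + [0] * 38
    same = [1] * 10 + [0] * 30 + [1] * 10 + [0] * 30
    geno = pd.DataFrame([shifted, same], index=["hit", "null"], columns=a + b)
    table = sv.sv_divergence_scan(geno, a, b)
    assert bool(table.loc["hit", "significant"])
    assert table.loc["hit", "direction"] == "reduced"
    assert not table.loc["null", "significant"]
    with pytest.raises(ValueError):
        sv.sv_divergence_scan(geno, a, a)


# ---------------------------------------------------------------------------
# genomic context


def demo_gene():
    return GeneModel(
        "gene1", "chr1", 10_000, 20_000, "+",
        exons=[(10_000, 12_000), (15_000, 20_000)],
        cds=[(10_000, 12_000), (15_000, 20_000)],
    )


@pytest.mark.parametrize(
    "point,expected",
    [
        (13_000, "regulatory"),  # intron
        (7_000, "regulatory"),   # upstream flank
        (26_000, "intergenic"),  # beyond +5 kb
        (11_000, "CDS"),
    ],
)
def test_annotate_hand_built_coordinates(point, expected):
    ctx = sv.annotate_sv_context([("chr1", point, point + 1)], [demo_gene()])[0]
    assert ctx.category == expected


def test_annotate_precedence_multi_gene():
    g2 = GeneModel("gene2", "chr1", 23_000, 30_000, "+",
                   exons=[(23_000, 30_000)], cds=[(23_000, 30_000)])
    # overlaps CDS of gene2 and downstream flank of gene1
    ctx = sv.annotate_sv_context([("chr1", 23_500, 24_000)], [demo_gene(), g2])[0]
    assert ctx.category == "CDS"
    assert set(ctx.genes) == {"gene1", "gene2"}


def test_annotate_empty_models_all_intergenic():
    ctxs = sv.annotate_sv_context([("chr1", 100, 200), ("chr2", 5, 6)], [])
    assert all(c.category == "intergenic" for c in ctxs)


def bruteforce_category(lo, hi, genes, flank=5000):
    cat = "intergenic"
    for g in genes:
        if any(lo < e and hi > s for s, e in g.cds):
            return "CDS"
        body = lo < g.end and hi > g.start
        flank_hit = (lo < g.start and hi > g.start - flank) or (lo < g.end + flank and hi > g.end)
        if body or flank_hit:
            cat = "regulatory"
    return cat


def test_annotate_randomized_vs_bruteforce():
    rng = np.random.default_rng(13)
    genes = []
    for i in range(30):
        start = int(rng.integers(0, 200_000))
        end = start + int(rng.integers(500, 8000))
        n_ex = int(rng.integers(1, 4))
        bounds = np.sort(rng.integers(start, end, 2 * n_ex))
        exons = [(int(bounds[2 * j]), int(bounds[2 * j + 1])) for j in range(n_ex)]
        exons = [(s, e) for s, e in exons if e > s] or [(start, end)]
        genes.append(GeneModel(f"g{i}", "chr1", start, end, "+", exons=exons, cds=exons))
    queries = []
    for _ in range(1000):
        lo = int(rng.integers(0, 210_000))
        hi = lo + int(rng.integers(1, 3000))
        queries.append(("chr1", lo, hi))
    ctxs = sv.annotate_sv_context(queries, genes)
    for (chrom, lo, hi), ctx in zip(queries, ctxs):
        assert ctx.category == bruteforce_category(lo, hi, genes)


# ---------------------------------------------------------------------------
# summaries


def nr_site(r):
    return sv.NrSVSite(site_id="x", representative=r, members=[r])


def test_multiallelic_isolated_and_colocated():
    isolated = [nr_site(rec(p)) for p in (1000, 5000, 9000)]
    out = sv.multiallelic_summary(isolated)
    assert out["multiallelic_fraction"] == 0.0
    colocated = [nr_site(rec(1000 + d, svtype="INS", length=60 + d)) for d in (0, 50, 100)]
    out = sv.multiallelic_summary(colocated)
    assert out["n_loci"] == 1 and out["max_alleles"] == 3
    assert out["multiallelic_fraction"] == 1.0


def test_multiallelic_matches_bruteforce_clustering():
    rng = np.random.default_rng(2)
    positions = sorted(int(p) for p in rng.integers(0, 30_000, 20))
    sites = [nr_site(rec(p, svtype=("DEL", "INS")[i % 2], length=500))
             for i, p in enumerate(positions)]
    out = sv.multiallelic_summary(sites, max_dist=500)
    # brute force single-linkage on sorted positions
    clusters, current = [], [positions[0]]
    for p in positions[1:]:
        if p - current[-1] <= 500:
            current.append(p)
        else:
            clusters.append(current)
            current = [p]
    clusters.append(current)
    assert out["n_loci"] == len(clusters)
    assert out["max_alleles"] == max(len(c) for c in clusters)


def test_te_window_correlation_perfect_and_errors():
    lengths = {"chr1": 2_000_000}
    svpos = [("chr1", 100 + i * 500_000) for i in range(4) for _ in range(i + 1)]
    tes = [("chr1", i * 500_000 + 10, i * 500_000 + 400) for i in range(4) for _ in range(i + 1)]
    df, (r, r2, p) = sv.sv_te_window_correlation(svpos, tes, lengths)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sv.sv_te_window_correlation(svpos, [], lengths)  # constant zero TE counts
    with pytest.raises(ValueError):
        sv.sv_te_window_correlation(svpos, tes, {"chr1": 600_000})  # < 3 windows


def test_pan_sv_accumulation_toy():
    geno = pd.DataFrame(
        {"G1": [1, 1, 0, 0], "G2": [0, 1, 1, 0], "G3": [0, 2, 0, 1]},
        index=["a", "b", "c", "d"],
    )
    curves = sv.pan_sv_accumulation(geno, order=["G1", "G2", "G3"])
    assert curves["pan"].tolist() == [2.0, 3.0, 4.0]
    assert curves["pan"].iloc[-1] == len(geno)


def test_group_specific_svs():
    cols = ["t1", "t2", "c1", "c2"] + [f"o{i}" for i in range(96)]
    unique = [1, 1, 0, 0] + [0] * 96          # AF 2/200 = 0.01
    leaky = [1, 1, 1, 0] + [0] * 96           # carried by a contrast
    common = [1, 1, 0, 0] + [1] * 96          # cohort AF too high
    geno = pd.DataFrame([unique, leaky, common], index=["u", "l", "c"], columns=cols)
    out = sv.group_specific_svs(geno, ["t1", "t2"], ["c1", "c2"])
    assert list(out.index) == ["u"]
    with pytest.raises(ValueError):
        sv.group_specific_svs(geno, ["t1"], ["t1", "c1"])
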