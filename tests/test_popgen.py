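"""Window statistics against brute-force and quadrature oracles."""

import math

import numpy as np
import pytest

from silkpan import popgen
from silkpan.popgen import GenotypeMatrix, SweepModelParams


def make_gm(dosages, positions=None, chrom="chr1"):
    d = np.asarray(dosages, dtype=np.int8)
    pos = np.arange(1, d.shape[1] + 1) if positions is None else np.asarray(positions)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(d.shape[0])],
        chroms=np.full(d.shape[1], chrom, dtype=object),
        positions=pos,
        dosages=d,
    )


# ---------------------------------------------------------------------------
# windows


def test_sliding_windows_single_exact():
    w = popgen.sliding_windows({"c": 5000}, 5000, 5000)
    assert [(x.start, x.end) for x in w] == [(0, 5000)]


def test_sliding_windows_truncation_policy():
    w = popgen.sliding_windows({"c": 7000}, 5000, 500)
    full = [x for x in w if x.end - x.start == 5000]
    assert len(full) == 5
    assert [x.start for x in full] == [0, 500, 1000, 1500, 2000]
    assert all(x.start < 7000 for x in w)
    assert w[-1].end == 7000
    assert len(w) == 14


def test_sliding_windows_short_chromosome():
    w = popgen.sliding_windows({"c": 400}, 5000, 500)
    assert [(x.start, x.end) for x in w] == [(0, 400)]


def test_sliding_windows_invalid():
    with pytest.raises(ValueError):
        popgen.sliding_windows({"c": 1000}, 0, 500)
    with pytest.raises(ValueError):
        popgen.sliding_windows({"c": 1000}, 100, 500)


# ---------------------------------------------------------------------------
# pi and Tajima's D


def pairwise_pi_oracle(k, n):
    """Mean pairwise differences: per site, k*(n-k) differing pairs of C(n,2)."""
    total = 0.0
    for ki, ni in zip(k, n):
        if ni < 2:
            continue
        total += ki * (ni - ki) / (ni * (ni - 1) / 2)
    return total


def tajima_oracle(dosages):
    d = np.asarray(dosages)
    d = d[:, np.all(d >= 0, axis=0)]
    n = 2 * d.shape[0]
    k = d.sum(axis=0)
    seg = (k > 0) & (k < n)
    s = int(seg.sum())
    if s == 0 or n < 3:
        return math.nan
    pi_hat = pairwise_pi_oracle(k[seg], np.full(s, n))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def test_pi_monomorphic_zero():
    gm = make_gm([[0, 2], [0, 2]])
    k, n = gm.allele_counts()
    assert popgen.pi(k, n) == 0.0


def test_pi_two_haplotypes_counts_differences():
    # one diploid = two lineages; heterozygous at 3 of 5 sites -> pi = 3
    gm = make_gm([[1, 1, 1, 0, 2]])
    k, n = gm.allele_counts()
    assert popgen.pi(k, n) == pytest.approx(3.0)


def test_pi_matches_pairwise_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        d = rng.integers(0, 3, size=(rng.integers(2, 6), rng.integers(1, 15)))
        gm = make_gm(d)
        k, n = gm.allele_counts()
        assert popgen.pi(k, n) == pytest.approx(pairwise_pi_oracle(k, n), abs=1e-10)


def test_tajimas_d_missing_cases():
    assert math.isnan(popgen.tajimas_d(np.zeros((4, 6), dtype=np.int8)))  # S = 0
    assert math.isnan(popgen.tajimas_d(np.array([[0, 1, 1]])))  # n = 2


def test_tajimas_d_matches_oracle_on_random_matrices():
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(250):
        d = rng.integers(0, 3, size=(rng.integers(2, 6), rng.integers(1, 21)))
        ours = popgen.tajimas_d(d)
        ref = tajima_oracle(d)
        if math.isnan(ref):
            assert math.isnan(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-10)
            checked += 1
    assert checked >= 200


# ---------------------------------------------------------------------------
# FST


def test_fst_fixed_difference_is_one():
    k1, n1 = np.array([200]), np.array([200])
    k2, n2 = np.array([0]), np.array([200])
    assert popgen.fst_window(k1, n1, k2, n2) == pytest.approx(1.0, abs=1e-2)


def test_fst_monomorphic_sites_skipped():
    # every site monomorphic across both populations -> window missing
    assert math.isnan(
        popgen.fst_window(np.array([0]), np.array([10]), np.array([0]), np.array([10]))
    )
    # adding a cross-population-monomorphic site leaves the estimate unchanged
    base = popgen.fst_window(np.array([8]), np.array([10]), np.array([2]), np.array([10]))
    padded = popgen.fst_window(
        np.array([8, 0]), np.array([10, 10]), np.array([2, 0]), np.array([10, 10])
    )
    assert padded == pytest.approx(base, abs=1e-12)


def test_fst_two_site_hand_example():
    k1 = np.array([8, 3])
    k2 = np.array([2, 3])
    n = np.array([10, 10])
    num1 = (0.8 - 0.2) ** 2 - 0.8 * 0.2 / 9 - 0.2 * 0.8 / 9
    den1 = 0.8 * 0.8 + 0.2 * 0.2
    num2 = 0.0 - 2 * (0.3 * 0.7 / 9)
    den2 = 2 * 0.3 * 0.7
    expected = (num1 + num2) / (den1 + den2)
    assert popgen.fst_window(k1, n, k2, n) == pytest.approx(expected, abs=1e-12)


def test_fst_estimators_agree_on_balanced_data():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.05, 0.95, 2000)
    f = 0.1
    p1 = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    p2 = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    k1 = rng.binomial(100, p1)
    k2 = rng.binomial(100, p2)
    n = np.full(2000, 100)
    hudson = popgen.fst_window(k1, n, k2, n)
    wc = popgen.fst_window(k1, n, k2, n, estimator="weir_cockerham")
    assert abs(hudson - wc) < 0.02


# ---------------------------------------------------------------------------
# omega and XP-CLR


def test_estimate_omega_zero_and_scaling():
    p = np.linspace(0.05, 0.95, 2000)
    assert popgen.estimate_omega(p, p.copy()) == 0.0
    delta = 0.01 * np.sin(np.arange(2000))
    w1 = popgen.estimate_omega(p, p + delta)
    w2 = popgen.estimate_omega(p, p + 2 * delta)
    assert w2 == pytest.approx(4 * w1)
    with pytest.raises(ValueError):
        popgen.estimate_omega(p[:10], p[:10])


def test_estimate_omega_monte_carlo_consistency():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.05, 0.95, 50_000)
    f = 0.1
    pobj = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    assert popgen.estimate_omega(p, pobj) == pytest.approx(0.1, abs=0.01)


def trapezoid_logcl(p1, k, n, r, s, omega, Ne, npts=10_000):
    """Independent quadrature oracle for the per-SNP composite likelihood."""
    from scipy.stats import binom, norm

    sigma = math.sqrt(omega * p1 * (1 - p1))
    c = 1.0 if (s <= 0 or 2 * Ne * s <= 1) else 1 - math.exp(-r * math.log(2 * Ne * s) / s)
    grid = np.linspace(0.0, 1.0, npts)
    q = np.clip(1 - c + c * grid, 1e-12, 1 - 1e-12)
    integrand = norm.pdf(grid, p1, sigma) * binom.pmf(k, n, q)
    q0 = min(max(1 - c, 1e-12), 1 - 1e-12)
    like = (
        norm.cdf((0 - p1) / sigma) * binom.pmf(k, n, q0)
        + (1 - norm.cdf((1 - p1) / sigma)) * (1.0 if k == n else 0.0)
        + np.trapezoid(integrand, grid)
    )
    return math.log(like)


def test_xpclr_single_snp_matches_quadrature_oracle():
    params = SweepModelParams(omega=0.05, Ne=10_000.0, s_grid=np.array([0.0, 0.05]))
    r = 1e-4
    ours = 2 * (
        float(popgen.xpclr_site_logcl(0.5, 18, 20, r, 0.05, params)[0])
        - float(popgen.xpclr_site_logcl(0.5, 18, 20, r, 0.0, params)[0])
    )
    oracle = 2 * (
        trapezoid_logcl(0.5, 18, 20, r, 0.05, 0.05, 1e4)
        - trapezoid_logcl(0.5, 18, 20, r, 0.0, 0.05, 1e4)
    )
    assert ours == pytest.approx(oracle, abs=1e-6)


def test_xpclr_zero_grid_and_empty_window():
    params = SweepModelParams(omega=0.05, s_grid=np.array([0.0]))
    pos = np.array([100.0, 200.0, 300.0, 400.0])
    p_ref = np.array([0.3, 0.5, 0.7, 0.4])
    k = np.array([5, 8, 9, 2])
    n = np.full(4, 20)
    assert popgen.xpclr_window(pos, p_ref, k, n, params, 250.0) == 0.0
    empty = popgen.xpclr_window(pos[:2], p_ref[:2], k[:2], n[:2], params, 150.0)
    assert math.isnan(empty)  # < 3 usable SNPs


def test_xpclr_requires_zero_in_grid_and_positive_omega():
    with pytest.raises(ValueError):
        SweepModelParams(omega=0.05, s_grid=np.array([0.1]))
    with pytest.raises(ValueError):
        SweepModelParams(omega=0.0)


def test_xpclr_increases_under_matching_sweep_transform():
    rng = np.random.default_rng(5)
    m, s = 30, 0.1
    params = SweepModelParams(omega=0.1, recomb_rate=1e-6, s_grid=np.array([0.0, s]))
    pos = np.sort(rng.choice(5000, m, replace=False)).astype(float)
    p_ref = rng.uniform(0.2, 0.8, m)
    n = np.full(m, 50)
    k_neutral = rng.binomial(50, p_ref)
    c = popgen.escape_probability(np.abs(pos - 2500.0) * params.recomb_rate, s, params.Ne)
    k_swept = rng.binomial(50, 1 - c + c * p_ref)
    score_neutral = popgen.xpclr_window(pos, p_ref, k_neutral, n, params, 2500.0)
    score_swept = popgen.xpclr_window(pos, p_ref, k_swept, n, params, 2500.0)
    assert score_swept > score_neutral
    assert score_swept > 0.0


def test_genotype_matrix_validation():
    with pytest.raises(ValueError):
        make_gm([[0, 3]])
    with pytest.raises(ValueError):
        make_gm([[0, 1]], positions=[5, 5])
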