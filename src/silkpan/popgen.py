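"""Sliding-window population-genetic statistics.

Diversity (pi), Tajima's D, Hudson / Weir-Cockerham FST, and a
cross-population composite-likelihood sweep score (XP-CLR style) computed on
a shared 5 kb / 500 bp sliding-window grid.

Conventions
-----------
* Diploid genotypes are treated as 2n exchangeable lineages; phasing is never
  required.  Missing genotypes are dropped per site.
* Coordinates are 0-based half-open internally; VCF I/O converts at the edge.
* Windows with fewer than three usable sites receive missing (NaN) scores and
  are excluded from downstream percentile ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, ndtr

MIN_WINDOW_SITES = 3

__all__ = [
    "GenotypeMatrix",
    "Window",
    "WindowTrack",
    "TajimaConstants",
    "SweepModelParams",
    "sliding_windows",
    "pi",
    "tajima_constants",
    "tajimas_d",
    "fst_window",
    "estimate_omega",
    "escape_probability",
    "xpclr_site_logcl",
    "xpclr_window",
    "scan_diversity",
    "scan_fst",
    "scan_xpclr",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Biallelic SNP allele dosages for one cohort.

    dosages: (n_samples, n_sites) int8 array with values {0, 1, 2} and -1 for
    missing.  Sites may span several chromosomes; ``chroms``/``positions`` are
    parallel per-site arrays with positions 1-based and strictly increasing
    within a chromosome.
    """

    sample_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sample_ids), self.positions.size):
            raise ValueError("dosage matrix shape does not match samples x sites")
        if not np.all(np.isin(self.dosages, [-1, 0, 1, 2])):
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        for chrom in np.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            chroms=self.chroms,
            positions=self.positions,
            dosages=self.dosages[idx],
            populations={s: self.populations.get(s, "") for s in sample_ids},
        )

    def population(self, label: str) -> "GenotypeMatrix":
        chosen = [s for s in self.sample_ids if self.populations.get(s) == label]
        if not chosen:
            raise KeyError(f"no samples labelled {label!r}")
        return self.subset_samples(chosen)

    def site_slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Column indices of sites on ``chrom`` with 0-based pos in [start, end)."""
        pos0 = self.positions - 1
        mask = (self.chroms == chrom) & (pos0 >= start) & (pos0 < end)
        return np.nonzero(mask)[0]

    def allele_counts(self, cols=None) -> tuple[np.ndarray, np.ndarray]:
        """(derived count k, called alleles n) per site, missing dropped."""
        d = self.dosages if cols is None else self.dosages[:, cols]
        called = d >= 0
        n = 2 * called.sum(axis=0)
        k = np.where(called, d, 0).sum(axis=0)
        return k.astype(np.int64), n.astype(np.int64)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    site_count: int = 0


@dataclass
class WindowTrack:
    """Per-window scores for one named statistic (NaN = missing)."""

    name: str
    windows: list[Window]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.windows):
            raise ValueError("one score per window required")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                self.name: self.scores,
            }
        )

    def same_grid(self, other: "WindowTrack") -> bool:
        return len(self.windows) == len(other.windows) and all(
            a.chrom == b.chrom and a.start == b.start and a.end == b.end
            for a, b in zip(self.windows, other.windows)
        )


# ---------------------------------------------------------------------------
# window grid


def sliding_windows(chrom_lengths: dict, size: int = 5000, step: int = 500) -> list[Window]:
    """Sliding windows starting at 0 every ``step`` bp, truncated at chromosome end."""
    if step <= 0 or size <= 0:
        raise ValueError("window size and step must be positive")
    if size < step:
        raise ValueError("window size must be >= step")
    out: list[Window] = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            out.append(Window(chrom=str(chrom), start=start, end=min(start + size, int(length))))
            start += step
    return out


# ---------------------------------------------------------------------------
# diversity and Tajima's D


def pi(k: np.ndarray, n: np.ndarray) -> float:
    """Average pairwise differences from per-site allele counts.

    Unbiased per-site estimator 2*p*(1-p)*n/(n-1) summed over sites; sites
    with fewer than two called alleles are skipped.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.size == 0:
        return 0.0
    if np.all(n < 2):
        raise ValueError("pi requires at least two called lineages")
    use = n >= 2
    kk, nn = k[use], n[use]
    p = kk / nn
    return float(np.sum(2.0 * p * (1.0 - p) * nn / (nn - 1.0)))


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Closed-form constants of the D statistic for n haploid lineages."""
    if n < 2:
        raise ValueError("need at least two lineages")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(dosages: np.ndarray) -> float:
    """Tajima's D for one window of diploid dosages (samples x sites).

    Sites carrying any missing genotype are dropped so that every retained
    site is observed on the same 2n lineages.  Returns NaN when there are no
    segregating sites or fewer than three lineages (zero-variance cases).
    """
    d = np.asarray(dosages)
    if d.ndim != 2:
        raise ValueError("expected a samples x sites matrix")
    complete = np.all(d >= 0, axis=0)
    d = d[:, complete]
    n = 2 * d.shape[0]
    if n < 3 or d.shape[1] == 0:
        return math.nan
    k = d.sum(axis=0)
    seg = (k > 0) & (k < n)
    s = int(seg.sum())
    if s == 0:
        return math.nan
    const = tajima_constants(n)
    p = k[seg] / n
    pi_hat = float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)))
    var = const.e1 * s + const.e2 * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi_hat - s / const.a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# FST


def _hudson_site_terms(k1, n1, k2, n2):
    p1 = k1 / n1
    p2 = k2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _weir_cockerham_site_terms(k1, n1, k2, n2):
    # Allele-count (haploid-lineage) form of the two-population theta.
    p1, p2 = k1 / n1, k2 / n2
    nbar = (n1 + n2) / 2.0
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))  # r - 1 = 1
    pbar = (k1 + k2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # (r-1) = 1
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2.0)
    return a, a + b


def fst_window(
    k1: np.ndarray,
    n1: np.ndarray,
    k2: np.ndarray,
    n2: np.ndarray,
    estimator: str = "hudson",
) -> float:
    """Window FST as a ratio of per-site sums from allele counts.

    Sites with fewer than two called alleles in either population, or
    monomorphic across both populations, are skipped.  Returns NaN when no
    usable site remains.
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    use = (n1 >= 2) & (n2 >= 2)
    tot_k = k1 + k2
    tot_n = n1 + n2
    use &= (tot_k > 0) & (tot_k < tot_n)
    if not np.any(use):
        return math.nan
    if estimator == "hudson":
        num, den = _hudson_site_terms(k1[use], n1[use], k2[use], n2[use])
    elif estimator == "weir_cockerham":
        num, den = _weir_cockerham_site_terms(k1[use], n1[use], k2[use], n2[use])
    else:
        raise ValueError("estimator must be 'hudson' or 'weir_cockerham'")
    den_sum = float(np.sum(den))
    if den_sum == 0.0:
        return math.nan
    return float(np.sum(num)) / den_sum


# ---------------------------------------------------------------------------
# XP-CLR style composite likelihood


@dataclass
class SweepModelParams:
    """Parameters of the drift + hitchhiking frequency model.

    omega scales the neutral drift variance (Var(p2|p1) = omega*p1*(1-p1));
    Ne and recomb_rate enter only through the escape probability
    c = 1 - exp(-r*ln(2*Ne*s)/s) with r the recombination fraction to the
    putative sweep site.
    """

    omega: float
    Ne: float = 10_000.0
    recomb_rate: float = 1e-6
    s_grid: np.ndarray = field(default_factory=lambda: default_s_grid())
    n_quad: int = 300

    def __post_init__(self) -> None:
        if not (self.omega > 0):
            raise ValueError("omega must be positive")
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if not np.any(self.s_grid == 0.0):
            raise ValueError("s_grid must contain 0")


def default_s_grid(n: int = 20, lo: float = 1e-4, hi: float = 0.5) -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


def estimate_omega(p_ref: np.ndarray, p_obj: np.ndarray, min_sites: int = 1000) -> float:
    """Method-of-moments drift variance scale from genome-wide frequency pairs.

    omega = mean over sites of (p_obj - p_ref)^2 / (p_ref*(1-p_ref)), using
    only sites polymorphic in the reference population.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_obj = np.asarray(p_obj, dtype=float)
    use = (p_ref > 0.0) & (p_ref < 1.0)
    if int(use.sum()) < min_sites:
        raise ValueError(f"need at least {min_sites} polymorphic reference sites")
    pr, po = p_ref[use], p_obj[use]
    return float(np.mean((po - pr) ** 2 / (pr * (1.0 - pr))))


def escape_probability(r, s: float, Ne: float):
    """Probability that a lineage at recombination fraction r escapes the sweep.

    c = 1 - exp(-r * ln(2*Ne*s)/s); s = 0 (or 2*Ne*s <= 1, too weak to model)
    degenerates to the neutral c = 1.
    """
    r = np.asarray(r, dtype=float)
    if s <= 0 or 2.0 * Ne * s <= 1.0:
        return np.ones_like(r)
    c = 1.0 - np.exp(-r * math.log(2.0 * Ne * s) / s)
    return np.clip(c, 0.0, 1.0)


_EPS = 1e-12


def _log_binom_pmf(k, n, q):
    """log C(n,k) q^k (1-q)^(n-k), broadcast over q; q clipped away from {0,1}."""
    q = np.clip(q, _EPS, 1.0 - _EPS)
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return coef + k * np.log(q) + (n - k) * np.log1p(-q)


@lru_cache(maxsize=8)
def _unit_quadrature(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped from (-1, 1) to (0, 1)."""
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    return 0.5 * (nodes + 1.0), 0.5 * weights


def _neutral_density_pieces(p1: np.ndarray, omega: float, n_quad: int):
    """s-independent pieces of the transition density, per SNP.

    Returns (x grid, weighted density matrix SNP x node, point masses at 0
    and 1).  The continuous part already carries the quadrature weights.
    """
    sigma = np.sqrt(omega * p1 * (1.0 - p1))
    if np.any(sigma <= 0):
        raise ValueError("reference frequencies must be strictly inside (0, 1)")
    x, w = _unit_quadrature(n_quad)
    mass0 = ndtr((0.0 - p1) / sigma)
    mass1 = 1.0 - ndtr((1.0 - p1) / sigma)
    dens = np.exp(-0.5 * ((x[None, :] - p1[:, None]) / sigma[:, None]) ** 2) / (
        sigma[:, None] * math.sqrt(2.0 * math.pi)
    )
    return x, w[None, :] * dens, mass0, mass1


def _logcl_given_pieces(k, n, c, x, wdens, mass0, mass1) -> float:
    """Summed per-SNP composite log-likelihood for one escape-probability vector."""
    q_grid = 1.0 - c[:, None] + c[:, None] * x[None, :]
    like_grid = np.exp(_log_binom_pmf(k[:, None], n[:, None], q_grid))
    integral = np.einsum("ij,ij->i", wdens, like_grid)
    like0 = np.exp(_log_binom_pmf(k, n, 1.0 - c))
    like1 = np.exp(_log_binom_pmf(k, n, np.ones_like(c)))
    total = mass0 * like0 + mass1 * like1 + integral
    return float(np.sum(np.log(np.maximum(total, 1e-300))))


def xpclr_site_logcl(p_ref, k, n, r, s: float, params: SweepModelParams) -> np.ndarray:
    """Per-SNP composite log-likelihood under selection coefficient ``s``.

    The neutral transition density f(p2|p1) is Normal(p1, omega*p1*(1-p1))
    truncated to (0,1), with the truncated tail mass placed as point masses at
    0 and 1.  Under selection, each lineage escapes the sweep with probability
    c(r, s) and otherwise is dragged to the selected background, so the
    post-sweep frequency is 1 - c + c*p2; the observed derived-allele count k
    of n is binomial given that frequency.  Integration over p2 uses
    Gauss-Legendre quadrature mapped to (0, 1).
    """
    p1 = np.atleast_1d(np.asarray(p_ref, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    r = np.atleast_1d(np.asarray(r, dtype=float))
    c = escape_probability(r, s, params.Ne)
    x, wdens, mass0, mass1 = _neutral_density_pieces(p1, params.omega, params.n_quad)
    q_grid = 1.0 - c[:, None] + c[:, None] * x[None, :]
    like_grid = np.exp(_log_binom_pmf(k[:, None], n[:, None], q_grid))
    integral = np.einsum("ij,ij->i", wdens, like_grid)
    like0 = np.exp(_log_binom_pmf(k, n, 1.0 - c))
    like1 = np.exp(_log_binom_pmf(k, n, np.ones_like(c)))
    total = mass0 * like0 + mass1 * like1 + integral
    return np.log(np.maximum(total, 1e-300))


def xpclr_window(
    positions: np.ndarray,
    p_ref: np.ndarray,
    k_obj: np.ndarray,
    n_obj: np.ndarray,
    params: SweepModelParams,
    putative_site: float,
) -> float:
    """Composite likelihood ratio score max_s 2*(logCL(s) - logCL(0)) >= 0.

    SNPs monomorphic in the reference population or without called object
    alleles are unusable; a window with fewer than three usable SNPs is
    missing (NaN).
    """
    positions = np.asarray(positions, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    k_obj = np.asarray(k_obj, dtype=float)
    n_obj = np.asarray(n_obj, dtype=float)
    use = (p_ref > 0.0) & (p_ref < 1.0) & (n_obj > 0)
    if int(use.sum()) < MIN_WINDOW_SITES:
        return math.nan
    pos = positions[use]
    p1 = p_ref[use]
    k = k_obj[use]
    n = n_obj[use]
    r = np.abs(pos - putative_site) * params.recomb_rate

    x, wdens, mass0, mass1 = _neutral_density_pieces(p1, params.omega, params.n_quad)
    log0 = _logcl_given_pieces(k, n, np.ones_like(r), x, wdens, mass0, mass1)
    best = 0.0
    for s in params.s_grid:
        if s == 0.0:
            continue
        c = escape_probability(r, float(s), params.Ne)
        logs = _logcl_given_pieces(k, n, c, x, wdens, mass0, mass1)
        best = max(best, 2.0 * (logs - log0))
    return best


# ---------------------------------------------------------------------------
# track builders


def _window_cols(gm: GenotypeMatrix, windows: list[Window]) -> list[np.ndarray]:
    cols = []
    pos0 = gm.positions - 1
    by_chrom = {c: np.nonzero(gm.chroms == c)[0] for c in np.unique(gm.chroms)}
    for w in windows:
        idx = by_chrom.get(w.chrom)
        if idx is None:
            cols.append(np.empty(0, dtype=int))
            continue
        p = pos0[idx]
        lo = np.searchsorted(p, w.start, side="left")
        hi = np.searchsorted(p, w.end, side="left")
        cols.append(idx[lo:hi])
    return cols


def scan_diversity(gm: GenotypeMatrix, windows: list[Window]) -> tuple[WindowTrack, WindowTrack]:
    """Per-window pi and Tajima's D tracks on a shared grid."""
    pis = np.full(len(windows), math.nan)
    ds = np.full(len(windows), math.nan)
    for i, cols in enumerate(_window_cols(gm, windows)):
        if cols.size < MIN_WINDOW_SITES:
            continue
        k, n = gm.allele_counts(cols)
        if np.all(n < 2):
            continue
        pis[i] = pi(k, n)
        ds[i] = tajimas_d(gm.dosages[:, cols])
    return (
        WindowTrack(name="pi", windows=windows, scores=pis),
        WindowTrack(name="tajimas_d", windows=windows, scores=ds),
    )


def scan_fst(
    gm1: GenotypeMatrix,
    gm2: GenotypeMatrix,
    windows: list[Window],
    estimator: str = "hudson",
) -> WindowTrack:
    if gm1.n_sites != gm2.n_sites or not np.array_equal(gm1.positions, gm2.positions):
        raise ValueError("populations must share the same site set")
    scores = np.full(len(windows), math.nan)
    for i, cols in enumerate(_window_cols(gm1, windows)):
        if cols.size < MIN_WINDOW_SITES:
            continue
        k1, n1 = gm1.allele_counts(cols)
        k2, n2 = gm2.allele_counts(cols)
        scores[i] = fst_window(k1, n1, k2, n2, estimator=estimator)
    return WindowTrack(name="fst", windows=windows, scores=scores)


def scan_xpclr(
    gm_ref: GenotypeMatrix,
    gm_obj: GenotypeMatrix,
    windows: list[Window],
    params: SweepModelParams | None = None,
) -> WindowTrack:
    """XP-CLR track; omega is estimated genome-wide when not supplied."""
    if not np.array_equal(gm_ref.positions, gm_obj.positions):
        raise ValueError("populations must share the same site set")
    k_r, n_r = gm_ref.allele_counts()
    k_o, n_o = gm_obj.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref = np.where(n_r > 0, k_r / np.maximum(n_r, 1), np.nan)
        p_obj = np.where(n_o > 0, k_o / np.maximum(n_o, 1), np.nan)
    if params is None:
        ok = (n_r > 0) & (n_o > 0) & (k_r > 0) & (k_r < n_r)
        omega = estimate_omega(p_ref[ok], p_obj[ok], min_sites=min(1000, max(50, int(ok.sum()))))
        params = SweepModelParams(omega=omega)
    scores = np.full(len(windows), math.nan)
    pos = gm_ref.positions.astype(float) - 1.0
    for i, (w, cols) in enumerate(zip(windows, _window_cols(gm_ref, windows))):
        if cols.size < MIN_WINDOW_SITES:
            continue
        mid = 0.5 * (w.start + w.end)
        scores[i] = xpclr_window(pos[cols], p_ref[cols], k_o[cols], n_o[cols], params, mid)
    return WindowTrack(name="xpclr", windows=windows, scores=scores)
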