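"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the data structure of a two/three-group pan-genome
cohort (wild ancestor, local landraces, improved breeding lines): divergent
SNP allele frequencies under the Balding-Nichols model with optionally
injected hard sweeps, occupancy matrices with prescribed class counts, SV
cohorts with group-shifted carrier frequencies and a rare-allele excess, and
tissue expression with SV-linked effects.

Balding-Nichols gives closed-form expectations (E[FST] ~= F,
Var(p_i | p) = F p (1-p)), which makes estimator consistency cheap to check;
sites are independent, so there is no linkage disequilibrium and sweep
signals come from the frequency transform alone (see docs/methods.md).
All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import GenotypeMatrix, escape_probability

__all__ = [
    "PopulationSpec",
    "SweepSpec",
    "SnpCohortConfig",
    "OccupancyConfig",
    "SvCohortConfig",
    "ExpressionConfig",
    "simulate_snp_cohort",
    "simulate_occupancy",
    "simulate_sv_cohort",
    "simulate_expression",
]


# ---------------------------------------------------------------------------
# SNP cohorts


@dataclass
class PopulationSpec:
    """One population: sample size and Balding-Nichols divergence F."""

    name: str
    n_diploid: int
    fst: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("F must lie in (0, 1)")
        if self.n_diploid < 1:
            raise ValueError("need at least one diploid")


@dataclass
class SweepSpec:
    """A hard sweep injected into the descendant population."""

    chrom: str
    position: int  # 1-based bp of the selected site
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class SnpCohortConfig:
    """Study conditions for the SNP cohort generator.

    Defaults are the desk-scale emulation used throughout: a few-hundred-kb
    chromosome, ~120 bp SNP spacing, Beta(0.5, 0.5) ancestral frequencies,
    wild (ancestral) and local (descendant) populations at F = 0.05 / 0.10,
    and a scaled-up recombination rate of 1e-6 per bp so that an s = 0.1
    sweep's footprint spans tens of kb of the scaled chromosome.
    """

    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 600_000})
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("wild", 25, 0.05),
            PopulationSpec("local", 25, 0.10),
        ]
    )
    descendant: str = "local"
    snp_spacing: float = 120.0
    beta_a: float = 0.5
    beta_b: float = 0.5
    sweeps: list[SweepSpec] = field(default_factory=list)
    Ne: float = 10_000.0
    recomb_rate: float = 1e-6


def _positions(rng: np.random.Generator, length: int, spacing: float) -> np.ndarray:
    n = int(length / spacing)
    pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n, length), replace=False))
    return pos


def simulate_snp_cohort(
    cfg: SnpCohortConfig, seed: int
) -> tuple[dict[str, GenotypeMatrix], dict]:
    """Balding-Nichols SNP cohort with optional hard sweeps.

    Ancestral frequency p ~ Beta(a, b) per site; each population draws
    p_i ~ Beta(p(1-F)/F, (1-p)(1-F)/F); the descendant population's
    frequencies are additionally pushed through the hitchhiking operator
    p -> 1 - c + c p with c = c(distance x recomb_rate, s, Ne) around each
    sweep site.  Genotypes are Binomial(2, p_i) per diploid.
    """
    rng = np.random.default_rng(seed)
    chroms_all, pos_all = [], []
    for chrom, length in cfg.chrom_lengths.items():
        pos = _positions(rng, int(length), cfg.snp_spacing)
        chroms_all.append(np.full(pos.size, chrom, dtype=object))
        pos_all.append(pos)
    chroms = np.concatenate(chroms_all)
    positions = np.concatenate(pos_all)
    n_sites = positions.size
    p_anc = rng.beta(cfg.beta_a, cfg.beta_b, size=n_sites)
    p_anc = np.clip(p_anc, 1e-6, 1.0 - 1e-6)

    cohort: dict[str, GenotypeMatrix] = {}
    truth: dict = {
        "seed": seed,
        "ancestral_freq": p_anc,
        "population_freqs": {},
        "sweeps": [(sw.chrom, sw.position, sw.s) for sw in cfg.sweeps],
    }
    for spec in cfg.populations:
        f = spec.fst
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_pop = rng.beta(a, b)
        if spec.name == cfg.descendant:
            for sw in cfg.sweeps:
                on = chroms == sw.chrom
                r = np.abs(positions[on] - sw.position) * cfg.recomb_rate
                c = escape_probability(r, sw.s, cfg.Ne)
                p_pop[on] = 1.0 - c + c * p_pop[on]
        truth["population_freqs"][spec.name] = p_pop
        dosages = rng.binomial(2, p_pop, size=(spec.n_diploid, n_sites)).astype(np.int8)
        samples = [f"{spec.name}{i + 1:03d}" for i in range(spec.n_diploid)]
        cohort[spec.name] = GenotypeMatrix(
            sample_ids=samples,
            chroms=chroms,
            positions=positions,
            dosages=dosages,
            populations={s: spec.name for s in samples},
        )
    return cohort, truth


# ---------------------------------------------------------------------------
# occupancy matrices


@dataclass
class OccupancyConfig:
    """Prescribed class counts for the occupancy generator.

    Defaults follow the empirical pan-genome class proportions (22% core,
    34% softcore, 44% dispensable, ~1% private) at a desk-scale orthogroup
    total.
    """

    n_genomes: int = 100
    n_core: int = 440
    n_softcore: int = 660
    n_dispensable: int = 880
    n_private: int = 20
    group_fractions: dict = field(
        default_factory=lambda: {"wild": 0.14, "local": 0.41, "improved": 0.15, "stock": 0.30}
    )

    @property
    def total(self) -> int:
        return self.n_core + self.n_softcore + self.n_dispensable + self.n_private


def simulate_occupancy(cfg: OccupancyConfig, seed: int) -> tuple[pd.DataFrame, dict, pd.Series]:
    """Occupancy matrix with exactly the requested class counts.

    Core rows are all-present; private rows carry one genome (round-robin);
    softcore occupancy is drawn uniformly from the integers in (0.9N, N);
    dispensable from [2, 0.9N].  Which genomes carry a row is a uniform
    draw.  Returns (matrix, group labels per genome, truth classes).
    """
    n = cfg.n_genomes
    if n < 2:
        raise ValueError("need at least two genomes")
    soft_lo = int(np.floor(0.9 * n)) + 1  # smallest count strictly above 0.9N
    disp_hi = int(np.floor(0.9 * n))  # largest count <= 0.9N
    if soft_lo >= n and cfg.n_softcore > 0:
        raise ValueError("no softcore occupancy exists for this N")
    if disp_hi < 2 and cfg.n_dispensable > 0:
        raise ValueError("no dispensable occupancy exists for this N")
    rng = np.random.default_rng(seed)
    genomes = [f"g{i + 1:03d}" for i in range(n)]
    rows, classes = [], []
    idx = []
    for i in range(cfg.n_core):
        rows.append(np.ones(n, dtype=bool))
        classes.append("core")
        idx.append(f"OG_core{i:05d}")
    for i in range(cfg.n_softcore):
        count = int(rng.integers(soft_lo, n))  # in [soft_lo, n-1]
        row = np.zeros(n, dtype=bool)
        row[rng.choice(n, size=count, replace=False)] = True
        rows.append(row)
        classes.append("softcore")
        idx.append(f"OG_soft{i:05d}")
    for i in range(cfg.n_dispensable):
        count = int(rng.integers(2, disp_hi + 1))
        row = np.zeros(n, dtype=bool)
        row[rng.choice(n, size=count, replace=False)] = True
        rows.append(row)
        classes.append("dispensable")
        idx.append(f"OG_disp{i:05d}")
    for i in range(cfg.n_private):
        row = np.zeros(n, dtype=bool)
        row[i % n] = True
        rows.append(row)
        classes.append("private")
        idx.append(f"OG_priv{i:05d}")
    occ = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n), bool), index=idx, columns=genomes)
    labels = []
    for name, frac in cfg.group_fractions.items():
        labels.extend([name] * int(round(frac * n)))
    labels = (labels + ["stock"] * n)[:n]
    groups = dict(zip(genomes, labels))
    return occ, groups, pd.Series(classes, index=idx)


# ---------------------------------------------------------------------------
# SV cohorts


@dataclass
class SvCohortConfig:
    """Study conditions for the SV cohort generator.

    Null sites draw their allele frequency from a mixture tuned so the
    realized cohort rare-allele fraction (AF < 0.05) hits ``rare_target``
    (default 0.81, the empirical pan-SV value).  ``n_shifted`` sites get a
    carrier-frequency shift between group A and group B.
    """

    n_sites: int = 5000
    samples_a: int = 40
    samples_b: int = 40
    group_a: str = "wild"
    group_b: str = "local"
    rare_target: float = 0.81
    n_shifted: int = 100
    base_af: float = 0.05
    shifted_af: float = 0.60
    rare_af_range: tuple = (0.002, 0.025)
    common_af_range: tuple = (0.10, 0.90)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rare_target <= 1.0):
            raise ValueError("rare_target must lie in [0, 1]")
        if self.n_shifted > self.n_sites:
            raise ValueError("more shifted sites than sites")
        for v in (self.base_af, self.shifted_af):
            if not (0.0 <= v <= 1.0):
                raise ValueError("allele frequencies must lie in [0, 1]")


def simulate_sv_cohort(cfg: SvCohortConfig, seed: int) -> tuple[pd.DataFrame, dict]:
    """Site x sample SV dosage matrix with truth labels.

    Genotypes are Hardy-Weinberg draws Binomial(2, AF) per sample; sites
    where no sample carries the variant are redrawn (an SV site exists only
    because somebody carries it).  Shifted sites use ``base_af`` in group A
    and ``shifted_af`` in group B (clipped to [0, 1]); null sites share one
    AF in both groups drawn from the rare/common mixture.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_sites
    shifted = np.zeros(n, dtype=bool)
    if cfg.n_shifted:
        shifted[rng.choice(n, size=cfg.n_shifted, replace=False)] = True
    is_rare_draw = rng.random(n) < cfg.rare_target
    af_null = np.where(
        is_rare_draw,
        rng.uniform(*cfg.rare_af_range, size=n),
        rng.uniform(*cfg.common_af_range, size=n),
    )
    af_a = np.where(shifted, cfg.base_af, af_null)
    af_b = np.where(shifted, np.clip(cfg.shifted_af, 0.0, 1.0), af_null)

    samples_a = [f"{cfg.group_a}{i + 1:03d}" for i in range(cfg.samples_a)]
    samples_b = [f"{cfg.group_b}{i + 1:03d}" for i in range(cfg.samples_b)]
    geno = np.empty((n, cfg.samples_a + cfg.samples_b), dtype=np.int8)
    for i in range(n):
        while True:
            ga = rng.binomial(2, af_a[i], size=cfg.samples_a)
            gb = rng.binomial(2, af_b[i], size=cfg.samples_b)
            if ga.sum() + gb.sum() > 0:
                break
        geno[i, : cfg.samples_a] = ga
        geno[i, cfg.samples_a :] = gb
    index = [f"sv{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame(geno, index=index, columns=samples_a + samples_b)
    truth = {
        "seed": seed,
        "shifted_sites": [index[i] for i in np.nonzero(shifted)[0]],
        "af_a": af_a,
        "af_b": af_b,
        "samples_a": samples_a,
        "samples_b": samples_b,
    }
    return df, truth


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionConfig:
    """Tissue expression with SV-linked log2 effects.

    log2 expression = baseline + delta * carrier + Normal(0, sigma) per
    strain x tissue x replicate, back-transformed so that
    log2(FPKM + 1) equals the simulated log2 value exactly.
    """

    tissues: tuple = ("cuticle", "fat_body", "head", "hemolymph", "midgut", "silk_gland")
    replicates: int = 2
    baseline_log2: float = 5.0
    delta: float = 1.0
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def simulate_expression(
    gene_carriers: dict[str, list[str]],
    strains: list[str],
    cfg: ExpressionConfig,
    seed: int,
    effect_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """FPKM matrix genes x (strain, tissue, replicate) with truth effects.

    ``gene_carriers`` maps gene id -> strains carrying the linked SV.  Genes
    listed in ``effect_genes`` (default: all) receive the ``delta`` carrier
    effect in every tissue; the rest are null.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(gene_carriers)
    affected = set(effect_genes if effect_genes is not None else genes)
    columns = pd.MultiIndex.from_tuples(
        [
            (s, t, f"rep{r + 1}")
            for s in strains
            for t in cfg.tissues
            for r in range(cfg.replicates)
        ],
        names=["strain", "tissue", "replicate"],
    )
    values = np.empty((len(genes), len(columns)))
    for gi, gene in enumerate(genes):
        carrier_set = set(gene_carriers[gene])
        for ci, (s, _t, _r) in enumerate(columns):
            mu = cfg.baseline_log2 + (cfg.delta if (gene in affected and s in carrier_set) else 0.0)
            values[gi, ci] = mu + (rng.normal(0.0, cfg.sigma) if cfg.sigma > 0 else 0.0)
    fpkm_vals = np.exp2(values) - 1.0
    expr = pd.DataFrame(fpkm_vals, index=genes, columns=columns)
    truth = {
        "seed": seed,
        "effect_genes": sorted(affected & set(genes)),
        "delta": cfg.delta,
        "sigma": cfg.sigma,
    }
    return expr, truth
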