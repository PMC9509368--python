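"""Pan-gene occupancy classification, accumulation curves, and plateau model.

An occupancy matrix is a boolean pandas DataFrame with orthogroups as rows
and genomes as columns.  Classes follow the standard pan-genome partition:
core (all genomes), softcore (>90% but not all), dispensable (more than one
but <=90%), private (exactly one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

CLASSES = ("core", "softcore", "dispensable", "private")

__all__ = [
    "CLASSES",
    "AccumulationModel",
    "classify_orthogroups",
    "accumulation_curves",
    "fit_exponential",
    "plateau_size",
    "gene_frequency_differentiation",
]


def classify_orthogroups(occ: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Occupancy class per orthogroup plus the class counts.

    With N genomes: count == N -> core; 0.9N < count < N -> softcore;
    2 <= count <= 0.9N -> dispensable; count == 1 -> private.
    """
    mat = occ.astype(bool)
    n = mat.shape[1]
    if n < 2:
        raise ValueError("need at least two genomes")
    counts = mat.sum(axis=1)
    if (counts == 0).any():
        bad = counts.index[counts == 0][:5].tolist()
        raise ValueError(f"all-absent orthogroup rows not allowed: {bad}")
    soft_floor = 0.9 * n
    cls = pd.Series("dispensable", index=mat.index, dtype=object)
    cls[counts == n] = "core"
    cls[(counts > soft_floor) & (counts < n)] = "softcore"
    cls[counts == 1] = "private"
    tallies = {c: int((cls == c).sum()) for c in CLASSES}
    return cls, tallies


def _curves_for_order(mat: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pan(x), core(x) for one genome addition order via first-hit indices."""
    n = order.size
    sub = mat[:, order]
    any_hit = sub.any(axis=1)
    first_present = np.where(any_hit, sub.argmax(axis=1), n)
    absent = ~sub
    any_absent = absent.any(axis=1)
    first_absent = np.where(any_absent, absent.argmax(axis=1), n)
    x = np.arange(1, n + 1)
    pan = np.searchsorted(np.sort(first_present), x, side="left")
    core = mat.shape[0] - np.searchsorted(np.sort(first_absent), x, side="left")
    return pan.astype(float), core.astype(float)


def accumulation_curves(
    occ: pd.DataFrame,
    n_permutations: int = 100,
    seed: int | None = None,
    order: list | None = None,
) -> pd.DataFrame:
    """Pan- and core-gene counts as genomes are added one at a time.

    Either averages over ``n_permutations`` random genome orders (seeded) or
    follows a single user-supplied fixed order (e.g. phylogeny-guided).
    Returns a DataFrame with columns x, pan, core (mean over orders).
    """
    mat = occ.astype(bool).to_numpy()
    n = mat.shape[1]
    if n < 2:
        raise ValueError("need at least two genomes")
    if order is not None:
        cols = list(occ.columns)
        orders = [np.asarray([cols.index(g) for g in order])]
        if orders[0].size != n:
            raise ValueError("fixed order must list every genome exactly once")
    elif n_permutations > 0:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_permutations)]
    else:
        raise ValueError("need a fixed order or at least one permutation")
    pans = np.zeros(n)
    cores = np.zeros(n)
    for o in orders:
        p, c = _curves_for_order(mat, o)
        pans += p
        cores += c
    k = len(orders)
    return pd.DataFrame({"x": np.arange(1, n + 1), "pan": pans / k, "core": cores / k})


@dataclass
class AccumulationModel:
    """Saturating exponential y = A + B*exp(C*x) fitted to a gene count curve."""

    A: float
    B: float
    C: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.A + self.B * np.exp(self.C * x)


def _init_params(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    increasing = y[-1] >= y[0]
    a0 = float(np.max(y)) if increasing else float(np.min(y))
    resid = y - a0
    mask = np.abs(resid) > 1e-9
    if mask.sum() >= 2:
        # log|y - A0| is linear in x with slope C and intercept log|B|
        slope, intercept = np.polyfit(x[mask], np.log(np.abs(resid[mask])), 1)
        c0 = float(slope)
        b0 = float(math.copysign(math.exp(intercept), resid[mask][0]))
    else:
        c0, b0 = -0.05, float(resid[0] if resid[0] != 0 else (y[0] - a0) or -1.0)
    if c0 >= 0 and increasing:
        c0 = -0.05
    return a0, b0, c0


def fit_exponential(x_values, y_values, seed: int = 0) -> AccumulationModel:
    """Least-squares fit of y = A + B*exp(C*x).

    Starts from a log-linear initialization plus five jittered restarts and
    keeps the best residual sum of squares.  Raises on non-convergence of all
    starts or on constant y.
    """
    from scipy.optimize import least_squares

    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least four (x, y) points")
    if np.ptp(y) == 0:
        raise ValueError("constant y: exponential model unidentifiable")

    a0, b0, c0 = _init_params(x, y)
    rng = np.random.default_rng(seed)
    starts = [(a0, b0, c0)]
    for _ in range(5):
        starts.append(
            (
                a0 * (1 + 0.05 * rng.standard_normal()),
                b0 * (1 + 0.2 * rng.standard_normal()),
                c0 * (1 + 0.2 * rng.standard_normal()),
            )
        )

    def resid(theta):
        a, b, c = theta
        return a + b * np.exp(np.clip(c * x, -700, 700)) - y

    best = None
    for theta0 in starts:
        try:
            sol = least_squares(resid, theta0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("exponential fit failed from every start")
    rss, sol = best
    init_rss = float(np.sum(resid(starts[0]) ** 2))
    model = AccumulationModel(
        A=float(sol.x[0]), B=float(sol.x[1]), C=float(sol.x[2]), rss=rss, converged=bool(sol.success)
    )
    if not sol.success or rss > init_rss + 1e-9:
        raise RuntimeError(
            f"exponential fit did not converge (status={sol.status}, rss={rss:.6g}, "
            f"initial rss={init_rss:.6g})"
        )
    return model


def plateau_size(model: AccumulationModel, epsilon_fraction: float = 0.001) -> int:
    """Smallest integer n with fitted y(n+1) - y(n) < epsilon_fraction * A.

    The increment B*e^(Cn)*(e^C - 1) decays geometrically for C < 0, so the
    crossing is solved in closed form and verified at the integer boundary.
    """
    if model.C >= 0:
        raise ValueError("no plateau: model is not saturating (C >= 0)")
    threshold = epsilon_fraction * model.A
    amp = abs(model.B * (math.exp(model.C) - 1.0))

    def increment(n: int) -> float:
        return amp * math.exp(model.C * n)

    if increment(1) < threshold:
        return 1
    n = max(1, math.floor(math.log(threshold / amp) / model.C))
    while increment(n) >= threshold:
        n += 1
    while n > 1 and increment(n - 1) < threshold:
        n -= 1
    return n


def gene_frequency_differentiation(
    occ: pd.DataFrame,
    groups: dict,
    group_a: str,
    group_b: str,
    fdr: float = 1e-4,
    fc: float = 2.0,
) -> pd.DataFrame:
    """Per-orthogroup presence-frequency contrast between two genome groups.

    Each orthogroup yields a 2x2 present/absent table tested with Fisher's
    exact test; Benjamini-Hochberg correction is applied across all tested
    orthogroups.  Significant means q < ``fdr`` and fold change > ``fc``;
    direction reports the change in ``group_b`` relative to ``group_a``.
    """
    mat = occ.astype(bool)
    samples_a = [g for g in mat.columns if groups.get(g) == group_a]
    samples_b = [g for g in mat.columns if groups.get(g) == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need at least two genomes")
    pres_a = mat[samples_a].sum(axis=1).to_numpy()
    pres_b = mat[samples_b].sum(axis=1).to_numpy()
    na, nb = len(samples_a), len(samples_b)
    freq_a = pres_a / na
    freq_b = pres_b / nb
    pvals = np.array(
        [
            stats.fisher_exact_two_sided([[ka, na - ka], [kb, nb - kb]])
            for ka, kb in zip(pres_a, pres_b)
        ]
    )
    qvals = stats.bh_fdr(pvals)
    fcs = np.array([stats.fold_change(fa, fb) for fa, fb in zip(freq_a, freq_b)])
    significant = (qvals < fdr) & (fcs > fc)
    direction = np.where(freq_b > freq_a, "increased", np.where(freq_b < freq_a, "reduced", "unchanged"))
    return pd.DataFrame(
        {
            "freq_a": freq_a,
            "freq_b": freq_b,
            "p": pvals,
            "q": qvals,
            "fold_change": fcs,
            "significant": significant,
            "direction": direction,
        },
        index=mat.index,
    )
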