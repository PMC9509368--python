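"""Candidate selective-sweep regions from statistic tracks.

A window is called as a sweep window when it simultaneously sits in the top
1% of FST, the top 5% of XP-CLR, the lowest 5% of the descendant population's
Tajima's D, and has descendant D below ancestral D.  Passing windows are then
merged into maximal regions and assigned overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgen import WindowTrack, Window

__all__ = ["SweepCallConfig", "SweepRegion", "select_quantile", "call_sweeps", "regions_to_genes"]


@dataclass
class SweepCallConfig:
    q_fst: float = 0.99  # top 1%
    q_xpclr: float = 0.95  # top 5%
    q_tajd: float = 0.05  # lowest 5%
    require_descendant_lower: bool = True

    def __post_init__(self) -> None:
        for q in (self.q_fst, self.q_xpclr, self.q_tajd):
            if not (0.0 < q < 1.0):
                raise ValueError("quantiles must lie in (0, 1)")


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    windows: list[Window] = field(default_factory=list)
    max_fst: float = float("nan")
    max_xpclr: float = float("nan")
    min_tajd: float = float("nan")
    genes: list[str] = field(default_factory=list)


def select_quantile(track: WindowTrack, q: float, tail: str) -> np.ndarray:
    """Boolean mask of windows at or beyond the empirical q-quantile.

    Quantiles are computed genome-wide over non-missing scores with linear
    interpolation; ties at the threshold are included.  ``tail='upper'``
    selects scores >= quantile(q); ``tail='lower'`` selects <= quantile(q).
    Missing windows are never selected.
    """
    scores = track.scores
    ok = np.isfinite(scores)
    if not np.any(ok):
        raise ValueError("track has no non-missing scores")
    thr = float(np.quantile(scores[ok], q))
    if tail == "upper":
        mask = scores >= thr
    elif tail == "lower":
        mask = scores <= thr
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return mask & ok


def _merge_windows(windows: list[Window]) -> list[tuple[str, int, int, list[Window]]]:
    """Merge half-open windows sharing >= 1 bp into maximal regions."""
    regions: list[tuple[str, int, int, list[Window]]] = []
    for w in sorted(windows, key=lambda w: (w.chrom, w.start, w.end)):
        if regions and regions[-1][0] == w.chrom and w.start < regions[-1][2]:
            chrom, start, end, members = regions[-1]
            regions[-1] = (chrom, start, max(end, w.end), members + [w])
        else:
            regions.append((w.chrom, w.start, w.end, [w]))
    return regions


def call_sweeps(
    fst: WindowTrack,
    xpclr: WindowTrack,
    d_descendant: WindowTrack,
    d_ancestral: WindowTrack,
    cfg: SweepCallConfig | None = None,
) -> list[SweepRegion]:
    """Intersect the four selection signatures and merge passing windows."""
    cfg = cfg or SweepCallConfig()
    for other in (xpclr, d_descendant, d_ancestral):
        if not fst.same_grid(other):
            raise ValueError("tracks must share an identical window grid")
    mask = (
        select_quantile(fst, cfg.q_fst, "upper")
        & select_quantile(xpclr, cfg.q_xpclr, "upper")
        & select_quantile(d_descendant, cfg.q_tajd, "lower")
    )
    if cfg.require_descendant_lower:
        both = np.isfinite(d_descendant.scores) & np.isfinite(d_ancestral.scores)
        mask &= both & (d_descendant.scores < d_ancestral.scores)

    chosen = [w for w, m in zip(fst.windows, mask) if m]
    idx = {(w.chrom, w.start, w.end): i for i, w in enumerate(fst.windows)}
    regions = []
    for chrom, start, end, members in _merge_windows(chosen):
        rows = [idx[(w.chrom, w.start, w.end)] for w in members]
        regions.append(
            SweepRegion(
                chrom=chrom,
                start=start,
                end=end,
                windows=members,
                max_fst=float(np.nanmax(fst.scores[rows])),
                max_xpclr=float(np.nanmax(xpclr.scores[rows])),
                min_tajd=float(np.nanmin(d_descendant.scores[rows])),
            )
        )
    return regions


def regions_to_genes(regions: list[SweepRegion], gene_models) -> tuple[list[SweepRegion], list[str]]:
    """Assign genes overlapping each region by >= 1 bp (half-open intervals).

    ``gene_models`` is an iterable of objects with chrom/start/end/gene_id
    attributes (e.g. :class:`silkpan.io.GeneModel`) or (gene_id, chrom,
    start, end) tuples.  Returns the regions (gene lists filled in) and the
    sorted union of assigned gene ids.
    """
    genes = []
    for g in gene_models:
        if hasattr(g, "gene_id"):
            genes.append((g.gene_id, g.chrom, g.start, g.end))
        else:
            genes.append(tuple(g))
    union: set[str] = set()
    for region in regions:
        hits = [
            gid
            for gid, chrom, start, end in genes
            if chrom == region.chrom and start < region.end and end > region.start
        ]
        region.genes = sorted(hits)
        union.update(hits)
    return regions, sorted(union)
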