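"""SV presence/absence association with gene expression.

Expression matrices are pandas DataFrames with genes as rows and a 3-level
column MultiIndex (strain, tissue, replicate) holding FPKM values.  Tests run
per tissue on log2(FPKM + 1), with replicates averaged per strain first and a
single Benjamini-Hochberg correction pooled over every pair x tissue test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

PAIR_RELATIONS = ("intron", "flank_up", "flank_down")

__all__ = ["SVGenePair", "fpkm", "strain_tissue_means", "build_pairs", "pair_differential_expression"]


@dataclass
class SVGenePair:
    sv_id: str
    gene_id: str
    relation: str
    carriers: list[str] = field(default_factory=list)
    non_carriers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.carriers) & set(self.non_carriers):
            raise ValueError("carrier and non-carrier strains must be disjoint")


def fpkm(counts, gene_length_bp, library_fragments):
    """Fragments per kilobase of transcript per million mapped fragments."""
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    lib = np.asarray(library_fragments, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    return counts / ((length / 1000.0) * (lib / 1e6))


def strain_tissue_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Average replicates: genes x (strain, tissue) mean FPKM."""
    if expr.columns.nlevels != 3:
        raise ValueError("expected (strain, tissue, replicate) column MultiIndex")
    return expr.T.groupby(level=[0, 1]).mean().T


def build_pairs(
    sv_relations: dict[str, list[tuple[str, str]]],
    carriers: dict[str, list[str]],
    strains: list[str],
    min_present: int = 3,
    min_absent: int = 3,
) -> list[SVGenePair]:
    """Testable SV-gene pairs from annotation relations and carrier strains.

    ``sv_relations`` maps SV id -> [(gene_id, relation)] as produced by
    :func:`silkpan.sv.annotate_sv_context`; only intron and +/- flank
    relations define a pair.  A pair is testable when, among ``strains`` (the
    samples with expression data), at least ``min_present`` carry the SV and
    at least ``min_absent`` do not.
    """
    pairs: list[SVGenePair] = []
    strain_set = list(strains)
    for sv_id, relations in sv_relations.items():
        with_sv = [s for s in strain_set if s in set(carriers.get(sv_id, []))]
        without_sv = [s for s in strain_set if s not in set(carriers.get(sv_id, []))]
        if len(with_sv) < min_present or len(without_sv) < min_absent:
            continue
        for gene_id, relation in relations:
            if relation not in PAIR_RELATIONS:
                continue
            pairs.append(
                SVGenePair(
                    sv_id=sv_id,
                    gene_id=gene_id,
                    relation=relation,
                    carriers=with_sv,
                    non_carriers=without_sv,
                )
            )
    return pairs


def pair_differential_expression(
    pairs: list[SVGenePair],
    expr: pd.DataFrame,
    fdr: float = 0.001,
    min_per_side: int = 3,
) -> pd.DataFrame:
    """Per-pair, per-tissue presence/absence expression tests.

    Student's t-test on log2(FPKM + 1) of carrier versus non-carrier strains
    within each tissue, Benjamini-Hochberg corrected across all pair x tissue
    hypotheses jointly.  A pair is significant when q < ``fdr`` in at least
    one tissue.  Tissues with fewer than ``min_per_side`` strains with
    expression on either side are skipped (recorded with a reason).
    """
    means = strain_tissue_means(expr)
    tissues = sorted(means.columns.get_level_values(1).unique())
    rows = []
    for pair in pairs:
        for tissue in tissues:
            cols = means.xs(tissue, axis=1, level=1)
            car = [s for s in pair.carriers if s in cols.columns]
            non = [s for s in pair.non_carriers if s in cols.columns]
            if pair.gene_id not in means.index or len(car) < min_per_side or len(non) < min_per_side:
                rows.append(
                    {
                        "sv_id": pair.sv_id,
                        "gene_id": pair.gene_id,
                        "tissue": tissue,
                        "p": math.nan,
                        "direction": "skipped",
                        "skip_reason": "insufficient strains or missing gene",
                    }
                )
                continue
            a = np.log2(cols.loc[pair.gene_id, car].to_numpy(dtype=float) + 1.0)
            b = np.log2(cols.loc[pair.gene_id, non].to_numpy(dtype=float) + 1.0)
            res = stats.two_sample_t(a, b)
            rows.append(
                {
                    "sv_id": pair.sv_id,
                    "gene_id": pair.gene_id,
                    "tissue": tissue,
                    "p": res.p_value,
                    "direction": "up_in_carriers" if np.mean(a) > np.mean(b) else "down_in_carriers",
                    "skip_reason": "",
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant_pair"] = []
        return out
    tested = out["p"].notna()
    q = np.full(len(out), math.nan)
    if tested.any():
        q[tested.to_numpy()] = stats.bh_fdr(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    sig_by_pair = (
        out.assign(hit=(out["q"] < fdr).fillna(False))
        .groupby(["sv_id", "gene_id"])["hit"]
        .transform("any")
    )
    out["significant_pair"] = sig_by_pair
    return out
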