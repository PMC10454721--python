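"""Comparison of iModulon gene sets with draft-TRN regulons.

For every (iModulon, regulator) pair the overlap is scored with a one-sided
hypergeometric test against the expression-matrix gene universe, corrected
with Benjamini–Hochberg across all pairs. Overlap quality is summarized by
regulon recall (RR = shared / regulon size) and iModulon recall
(MR = shared / iModulon size) and binned into four categories at a 0.6
threshold on both: well-matched (both high), regulon subset (iModulon lies
mostly inside the regulon), regulon discovery (iModulon covers the regulon
plus new genes), poorly-matched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imodulons import IModulon

CATEGORIES = ("well-matched", "regulon subset", "regulon discovery", "poorly-matched")


class TRNError(ValueError):
    """Raised for malformed regulon tables."""


@dataclass
class RegulonTable:
    """Draft TRN as a regulator → target edge list.

    Edges carry an optional effect ('+', '-', 'unknown') and evidence string.
    """

    edges: pd.DataFrame  # columns: regulator, target_gene, effect, evidence

    def __post_init__(self) -> None:
        required = {"regulator", "target_gene"}
        if not required <= set(self.edges.columns):
            raise TRNError("TRN table needs 'regulator' and 'target_gene' columns")
        for col, default in (("effect", "unknown"), ("evidence", "")):
            if col not in self.edges.columns:
                self.edges[col] = default
        dup = self.edges.duplicated(subset=["regulator", "target_gene"])
        if dup.any():
            pairs = self.edges.loc[dup, ["regulator", "target_gene"]].values.tolist()
            raise TRNError(f"duplicate (regulator, target) pairs: {pairs[:5]}")

    @classmethod
    def from_csv(cls, path) -> "RegulonTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)

    @property
    def regulons(self) -> dict[str, set[str]]:
        return {
            str(reg): set(sub["target_gene"])
            for reg, sub in self.edges.groupby("regulator")
        }

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.edges[["regulator", "target_gene"]].values))


def compute_rr_mr(imodulon_genes: set, regulon_genes: set) -> tuple[float, float]:
    """Regulon recall and iModulon recall of one overlap.

    RR = |shared| / |regulon|, MR = |shared| / |iModulon| (0 for an empty
    iModulon by convention).
    """
    if not regulon_genes:
        raise ValueError("regulon recall undefined for an empty regulon")
    shared = len(set(imodulon_genes) & set(regulon_genes))
    rr = shared / len(regulon_genes)
    mr = shared / len(imodulon_genes) if imodulon_genes else 0.0
    return rr, mr


def categorize_overlap(rr: float, mr: float, threshold: float = 0.6) -> str:
    """Map an (RR, MR) pair onto the four overlap categories."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not (0.0 <= rr <= 1.0 and 0.0 <= mr <= 1.0):
        raise ValueError("RR and MR must lie in [0, 1]")
    if rr >= threshold and mr >= threshold:
        return "well-matched"
    if rr < threshold and mr >= threshold:
        return "regulon subset"
    if rr >= threshold and mr < threshold:
        return "regulon discovery"
    return "poorly-matched"


def hypergeom_pvalue(universe: int, regulon: int, imodulon: int, shared: int) -> float:
    """One-sided P(X >= shared) for drawing an iModulon from the universe."""
    return float(stats.hypergeom.sf(shared - 1, universe, regulon, imodulon))


def enrich_regulons(
    imodulons: list[IModulon],
    trn: RegulonTable,
    universe: set,
    category_threshold: float = 0.6,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every iModulon against every regulon.

    Returns one row per (iModulon, regulator) pair with p-value, global BH
    FDR, RR/MR, category, and an `is_best` flag on each iModulon's strongest
    hit (lowest FDR; ties broken by larger overlap, then regulator name).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    regulons = trn.regulons
    for reg, targets in regulons.items():
        extra = targets - universe
        if extra:
            raise ValueError(
                f"regulon {reg!r} has targets outside the universe: {sorted(extra)[:5]}"
            )
    rows = []
    for im in imodulons:
        genes = set(im.member_genes) & universe
        for reg in sorted(regulons):
            targets = regulons[reg]
            shared = len(genes & targets)
            rr, mr = compute_rr_mr(genes, targets)
            rows.append(
                {
                    "imodulon": im.name,
                    "component_id": im.component_id,
                    "regulator": reg,
                    "shared": shared,
                    "imodulon_size": len(genes),
                    "regulon_size": len(targets),
                    "p_value": hypergeom_pvalue(len(universe), len(targets), len(genes), shared),
                    "rr": rr,
                    "mr": mr,
                    "category": categorize_overlap(rr, mr, category_threshold),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        result["fdr"] = []
        result["is_best"] = []
        return result
    result["fdr"] = multipletests(result["p_value"].values, method="fdr_bh")[1]
    result["is_best"] = False
    for _, idx in result.groupby("imodulon").groups.items():
        sub = result.loc[idx].sort_values(
            by=["fdr", "shared", "regulator"], ascending=[True, False, True]
        )
        result.loc[sub.index[0], "is_best"] = True
    return result.reset_index(drop=True)


def brute_force_hypergeom(universe: int, regulon: int, imodulon: int, shared: int) -> float:
    """Independent enumeration oracle for the hypergeometric tail (small universes).

    Sums C(K, x)·C(N−K, n−x)/C(N, n) over all x >= shared using exact integer
    binomials; used only for cross-checking the closed form.
    """
    from math import comb

    total = comb(universe, imodulon)
    acc = 0
    for x in range(shared, min(regulon, imodulon) + 1):
        if imodulon - x > universe - regulon:
            continue
        acc += comb(regulon, x) * comb(universe - regulon, imodulon - x)
    return acc / total
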