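"""Condition-specific active transcriptional regulatory networks.

An active-TRN for a target condition is the subgraph of the draft TRN induced
by the iModulons whose activity significantly increases versus a reference
condition (typically the free-living aerobic state). Significance is a
two-sample Kolmogorov–Smirnov test on the activity distributions, conjoined
with a higher target-group mean to operationalize "increase". A draft-TRN
edge enters the active network when its TARGET gene belongs to an activated
iModulon; regulator nodes can therefore appear without being active
themselves (grey nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import RegulonTable
from .imodulons import IModulon


def ks_activity_table(
    A: pd.DataFrame, reference_samples, target_samples
) -> pd.DataFrame:
    """Per-iModulon KS statistic/p-value and group means, reference vs target."""
    ref = list(reference_samples)
    tgt = list(target_samples)
    if not ref or not tgt:
        raise ValueError("reference and target sample sets must be non-empty")
    if len(ref) < 2 or len(tgt) < 2:
        raise ValueError("each sample set needs at least 2 samples")
    if set(ref) & set(tgt):
        raise ValueError("reference and target sample sets overlap")
    rows = []
    for im in A.index:
        r = A.loc[im, ref].values.astype(float)
        t = A.loc[im, tgt].values.astype(float)
        ks = stats.ks_2samp(r, t)
        rows.append(
            {
                "imodulon": im,
                "ks_statistic": float(ks.statistic),
                "p_value": float(ks.pvalue),
                "mean_reference": float(r.mean()),
                "mean_target": float(t.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("imodulon")


def ks_active_imodulons(
    A: pd.DataFrame,
    reference_samples,
    target_samples,
    alpha: float = 0.05,
    fdr: bool = False,
) -> set[str]:
    """iModulons whose activity significantly increases in the target condition.

    Selected iff the two-sample KS p-value (optionally BH-adjusted when
    `fdr=True`) is below `alpha` AND the target mean exceeds the reference
    mean.
    """
    table = ks_activity_table(A, reference_samples, target_samples)
    p = table["p_value"].values
    if fdr:
        p = multipletests(p, method="fdr_bh")[1]
    increased = table["mean_target"].values > table["mean_reference"].values
    return set(table.index[(p < alpha) & increased])


@dataclass
class ActiveTRN:
    """Condition-specific subgraph of the draft TRN."""

    condition_id: str
    nodes: pd.DataFrame  # columns: gene, role, active
    edges: pd.DataFrame  # columns: regulator, target, source_imodulons

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(map(tuple, self.edges[["regulator", "target"]].values))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(condition_id=self.condition_id)
        for _, row in self.nodes.iterrows():
            g.add_node(row["gene"], role=row["role"], active=bool(row["active"]))
        for _, row in self.edges.iterrows():
            g.add_edge(row["regulator"], row["target"],
                       source_imodulons=row["source_imodulons"])
        return g

    def write(self, edges_path, nodes_path, graphml_path=None) -> None:
        self.edges.to_csv(edges_path, index=False)
        self.nodes.to_csv(nodes_path, index=False)
        if graphml_path is not None:
            nx.write_graphml(self.to_networkx(), graphml_path)


def build_active_trn(
    active: set[str],
    imodulons: list[IModulon],
    trn: RegulonTable,
    condition_id: str,
) -> ActiveTRN:
    """Induce the active-TRN from the activated iModulon set.

    The active gene set is the union of member genes over activated iModulons;
    a draft edge is kept iff its target gene is active. Nodes are all genes
    incident to kept edges, flagged active iff they belong to the active gene
    set. Output ordering is deterministic (sorted by regulator, then target).
    """
    by_name = {im.name: im for im in imodulons}
    unknown = set(active) - set(by_name)
    if unknown:
        raise ValueError(f"unknown iModulon ids: {sorted(unknown)}")
    gene_sources: dict[str, list[str]] = {}
    for name in sorted(active):
        for g in by_name[name].member_genes:
            gene_sources.setdefault(g, []).append(name)
    active_genes = set(gene_sources)

    kept = []
    for reg, tgt in sorted(trn.edge_set):
        if tgt in active_genes:
            kept.append(
                {
                    "regulator": reg,
                    "target": tgt,
                    "source_imodulons": ";".join(sorted(gene_sources[tgt])),
                }
            )
    edges = pd.DataFrame(kept, columns=["regulator", "target", "source_imodulons"])

    regs = set(edges["regulator"]) if len(edges) else set()
    tgts = set(edges["target"]) if len(edges) else set()
    node_rows = []
    for gene in sorted(regs | tgts):
        role = "both" if gene in regs and gene in tgts else ("regulator" if gene in regs else "target")
        node_rows.append({"gene": gene, "role": role, "active": gene in active_genes})
    nodes = pd.DataFrame(node_rows, columns=["gene", "role", "active"])
    return ActiveTRN(condition_id=condition_id, nodes=nodes, edges=edges)
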