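"""iModulon definition: gene-weight thresholding, explained variance, naming.

An iModulon is one robust independent component together with the set of genes
whose |weight| exceeds a component-specific threshold. The threshold is found
by iterative outlier trimming: the largest-|weight| gene is removed until the
remaining weights look Gaussian under the D'Agostino–Pearson K² statistic.
Components where the full weight vector already looks Gaussian have no member
genes ("Null" iModulons); they are kept as first-class outputs because their
activities can still track conditions even without dominant genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ica import Decomposition

#: D'Agostino K² statistic cutoff below which a weight vector is "Gaussian
#: enough" to stop trimming. Under the null the statistic is ~chi²(2), so 50
#: makes a pure-noise component essentially never yield members while genuine
#: heavy-tailed module weights keep the statistic far above the cutoff until
#: all members are removed.
DEFAULT_K2_CUTOFF = 50.0

_MIN_TEST_N = 20  # normaltest needs n >= 20 for a calibrated statistic


@dataclass
class IModulon:
    name: str
    component_id: str
    weights: pd.Series  # indexed by gene id, unit norm
    threshold: float
    member_genes: set[str]
    explained_variance: float | None = None
    enrichment: dict | None = field(default=None)

    @property
    def is_null(self) -> bool:
        return len(self.member_genes) == 0

    @property
    def size(self) -> int:
        return len(self.member_genes)


def compute_gene_threshold(
    weights, k2_cutoff: float = DEFAULT_K2_CUTOFF
) -> float:
    """Membership threshold for one component's gene-weight vector.

    Genes are removed in order of decreasing |weight| until the remainder
    passes the K² normality check (statistic < `k2_cutoff`). The threshold is
    the midpoint between the last removed and the largest surviving |weight|;
    if nothing is removed it equals max|weight| so the member set is empty.
    Scale-equivariant: scaling the weights by c > 0 scales the threshold by c.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < _MIN_TEST_N:
        raise ValueError(f"need a 1-d weight vector of length >= {_MIN_TEST_N}")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    absw = np.abs(w)
    order = np.argsort(-absw, kind="stable")
    sorted_abs = absw[order]
    n = w.size

    n_removed = 0
    while True:
        rem = w[order[n_removed:]]
        if rem.size < _MIN_TEST_N:
            break  # everything above the test's minimum n is an outlier
        if np.std(rem) == 0:
            break  # constant remainder: no structure left
        stat, _ = stats.normaltest(rem)
        if stat < k2_cutoff:
            break
        n_removed += 1

    if n_removed == 0:
        return float(sorted_abs[0])
    last_removed = sorted_abs[n_removed - 1]
    top_survivor = sorted_abs[n_removed] if n_removed < n else 0.0
    return float((last_removed + top_survivor) / 2.0)


def define_imodulons(
    d: Decomposition,
    X=None,
    k2_cutoff: float = DEFAULT_K2_CUTOFF,
    rename_map: dict[str, str] | None = None,
) -> list[IModulon]:
    """One IModulon per robust component.

    Provisional names are ``IM_1..IM_k``; components with empty member sets
    are named ``Null_1..`` in order. When the centered matrix X is given,
    per-component explained variances are attached. `rename_map` maps
    component ids to curated names (e.g. a regulator name).
    """
    imodulons: list[IModulon] = []
    n_null = 0
    for i, cid in enumerate(d.M.columns):
        w = d.M[cid]
        thr = compute_gene_threshold(w.values, k2_cutoff=k2_cutoff)
        members = set(w.index[np.abs(w.values) > thr])
        if members:
            name = f"IM_{i + 1}"
        else:
            n_null += 1
            name = f"Null_{n_null}"
        if rename_map and cid in rename_map:
            name = rename_map[cid]
        ev = explained_variance(d, X, subset=[cid]) if X is not None else None
        imodulons.append(
            IModulon(
                name=name,
                component_id=str(cid),
                weights=w,
                threshold=thr,
                member_genes=members,
                explained_variance=ev,
            )
        )
    return imodulons


def explained_variance(d: Decomposition, X, subset=None) -> float:
    """Fraction of expression variation captured by a component subset.

    Computed as 1 − ‖X − M_S · A_S‖²_F / ‖X‖²_F, clipped below at 0.
    """
    Xa = X.values if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    denom = np.linalg.norm(Xa) ** 2
    if denom == 0:
        raise ValueError("explained variance undefined for an all-zero matrix")
    if subset is None:
        subset = list(d.M.columns)
    M = d.M[list(subset)].values
    A = d.A.loc[list(subset)].values
    resid = Xa - M @ A
    ev = 1.0 - (np.linalg.norm(resid) ** 2) / denom
    return float(max(ev, 0.0))


def membership_table(imodulons: list[IModulon]) -> pd.DataFrame:
    """Long-format (component, gene, weight) table of member genes."""
    rows = [
        {"component_id": im.component_id, "name": im.name,
         "gene": g, "weight": float(im.weights[g])}
        for im in imodulons
        for g in sorted(im.member_genes)
    ]
    return pd.DataFrame(rows, columns=["component_id", "name", "gene", "weight"])


def imodulon_table(imodulons: list[IModulon]) -> pd.DataFrame:
    rows = [
        {
            "component_id": im.component_id,
            "name": im.name,
            "threshold": im.threshold,
            "n_genes": im.size,
            "explained_variance": im.explained_variance,
        }
        for im in imodulons
    ]
    return pd.DataFrame(rows)
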