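"""Scan ICA dimensions and extract robust independent components.

Each candidate dimension is decomposed from repeated FastICA restarts and the
recurring components are clustered (DBSCAN, distance 1 − |ρ|, eps 0.1). The
working dimension is where the non-single-gene component count meets the
number of components reproduced at the largest scanned dimension; the final
robust decomposition X ≈ M·A is then computed at that dimension.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from modulome import decompose, select_dimension

import common

SCAN = dict(dim_min=10, dim_max=30, step=5)


def main() -> None:
    common.ensure_dirs()
    X = pd.read_csv(common.CENTERED, sep="\t", index_col=0)

    chosen, diagnostics = select_dimension(
        X, **SCAN, n_runs=10, min_cluster_seed=5, master_seed=common.MASTER_SEED,
    )
    diagnostics.to_csv(common.RESULTS / "dimension_scan.tsv", sep="\t", index=False)
    print("dimension scan:")
    print(diagnostics.to_string(index=False))
    print(f"chosen dimension: {chosen}")

    d = decompose(
        X, chosen, n_runs=common.N_RUNS, min_cluster_seed=common.MIN_CLUSTER_SEED,
        master_seed=common.MASTER_SEED,
    )
    M = d.M.copy()
    M.index.name = "gene_id"
    M.to_csv(common.M_MATRIX, sep="\t")
    d.A.to_csv(common.A_MATRIX, sep="\t")
    sizes = [c.cluster_size for c in d.components]
    print(f"robust components: {d.k_robust} "
          f"(cluster sizes {min(sizes)}..{max(sizes)} of {common.N_RUNS} restarts)")
    print(f"wrote {common.M_MATRIX} and {common.A_MATRIX}")


if __name__ == "__main__":
    main()
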