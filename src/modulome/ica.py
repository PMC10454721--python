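"""Robust independent component analysis of an expression compendium.

The centered matrix X (genes × samples) is decomposed many times with
fixed-point ICA (log-cosh contrast, full whitening) from different random
starts. Components recurring across restarts are found by density clustering
(DBSCAN) under the sign-invariant distance d(x, y) = 1 − |ρ(x, y)|, where ρ is
the Pearson correlation between gene-weight vectors. Cluster centroids are the
robust components: their weight vectors form M (unit-norm columns) and their
activities A are recomputed by least squares so that X ≈ M · A holds for the
final pair regardless of per-run scalings.

Gene weights are the ICA sources here (each gene is an observation, each
sample a mixed signal); sparse module structure makes the sources heavy-tailed
and hence identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning


@dataclass
class ComponentRun:
    """One ICA restart: weights (genes × k, unit-norm columns) and activities (k × samples)."""

    run_index: int
    seed: int
    weights: np.ndarray
    activities: np.ndarray
    converged: bool = True


@dataclass
class RobustComponent:
    """Centroid of one density cluster of run components."""

    centroid_weights: np.ndarray
    centroid_activities: np.ndarray
    cluster_size: int
    member_indices: list[tuple[int, int]]


@dataclass
class Decomposition:
    """Robust decomposition X ≈ M · A with its run parameters for provenance."""

    M: pd.DataFrame  # genes × robust components, unit-norm columns
    A: pd.DataFrame  # robust components × samples
    dimension: int
    n_runs: int
    tolerance: float
    epsilon: float
    min_cluster_seed: int
    master_seed: int
    components: list[RobustComponent] | None = None

    @property
    def k_robust(self) -> int:
        return self.M.shape[1]


def component_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sign-invariant dissimilarity 1 − |ρ(x, y)| between component vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance vector")
    rho = np.corrcoef(x, y)[0, 1]
    return float(np.clip(1.0 - abs(rho), 0.0, 1.0))


def _as_array(X) -> np.ndarray:
    return X.values if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def derive_run_seeds(master_seed: int, n_runs: int) -> np.ndarray:
    """Per-run seeds derived deterministically from one master seed."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=n_runs)


def run_ica_restarts(
    X,
    dimension: int,
    n_runs: int = 100,
    tolerance: float = 1e-7,
    master_seed: int = 0,
    max_iter: int = 1000,
) -> list[ComponentRun]:
    """Run FastICA `n_runs` times from seeds derived from `master_seed`.

    Each run's weight columns are rescaled to unit L2 norm with the activity
    rows scaled inversely, leaving the product unchanged. Runs that hit the
    iteration cap are recorded as unconverged and kept; the call fails only if
    more than half do.
    """
    Xa = _as_array(X)
    n_genes, n_samples = Xa.shape
    if dimension > min(n_genes, n_samples):
        raise ValueError(f"dimension {dimension} exceeds min(genes, samples)")
    seeds = derive_run_seeds(master_seed, n_runs)
    runs: list[ComponentRun] = []
    n_failed = 0
    for i, seed in enumerate(seeds):
        ica = FastICA(
            n_components=dimension,
            fun="logcosh",
            whiten="unit-variance",
            tol=tolerance,
            max_iter=max_iter,
            random_state=int(seed),
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                S = ica.fit_transform(Xa)  # genes × k
            if not np.all(np.isfinite(S)):
                raise ValueError("non-finite weights")
        except Exception:  # noqa: BLE001 - a broken run is recorded, not fatal
            n_failed += 1
            continue
        # hitting the iteration cap is recorded but the solution is kept:
        # above the true source count the surplus directions are Gaussian and
        # never reach a fixed point, yet the signal components are usable and
        # the robust-clustering stage discards the wandering ones
        converged = ica.n_iter_ < max_iter
        A = ica.mixing_.T  # k × samples
        norms = np.linalg.norm(S, axis=0)
        norms[norms == 0] = 1.0
        runs.append(
            ComponentRun(
                run_index=i,
                seed=int(seed),
                weights=S / norms,
                activities=A * norms[:, None],
                converged=converged,
            )
        )
    if n_failed > n_runs / 2:
        raise RuntimeError(f"{n_failed}/{n_runs} ICA runs failed to converge")
    return runs


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs 1 − |ρ| over columns of W."""
    corr = np.corrcoef(W.T)
    return np.clip(1.0 - np.abs(corr), 0.0, 1.0)


def cluster_components(
    runs: list[ComponentRun],
    X,
    epsilon: float = 0.1,
    min_cluster_seed: int = 50,
) -> list[RobustComponent]:
    """Density-cluster all run components; centroids of large clusters are robust.

    Clusters need at least `min_cluster_seed` member columns, so with the
    default 100 runs a component must recur in at least half the restarts.
    Members are sign-aligned to the cluster's first column (scan order) before
    averaging; centroids are re-normalized and oriented so their largest-|w|
    gene entry is positive. Activities are recomputed jointly by ordinary
    least squares of X on the centroid weight set.
    """
    if len(runs) < 1:
        raise ValueError("no runs to cluster")
    cols = []
    origins = []
    for run in runs:
        for j in range(run.weights.shape[1]):
            cols.append(run.weights[:, j])
            origins.append((run.run_index, j))
    W = np.column_stack(cols)
    D = _distance_matrix(W)
    labels = DBSCAN(eps=epsilon, min_samples=min_cluster_seed, metric="precomputed").fit(D).labels_

    components: list[RobustComponent] = []
    for label in [l for l in sorted(set(labels)) if l >= 0]:
        members = np.flatnonzero(labels == label)
        ref = W[:, members[0]]
        aligned = []
        for idx in members:
            col = W[:, idx]
            rho = np.corrcoef(ref, col)[0, 1]
            aligned.append(col if rho >= 0 else -col)
        centroid = np.mean(aligned, axis=0)
        norm = np.linalg.norm(centroid)
        if norm == 0:
            continue
        centroid = centroid / norm
        if centroid[np.argmax(np.abs(centroid))] < 0:
            centroid = -centroid
        components.append(
            RobustComponent(
                centroid_weights=centroid,
                centroid_activities=np.empty(0),
                cluster_size=len(members),
                member_indices=[origins[i] for i in members],
            )
        )
    if not components:
        warnings.warn("no robust components found", stacklevel=2)
        return []

    Xa = _as_array(X)
    M = np.column_stack([c.centroid_weights for c in components])
    A, *_ = np.linalg.lstsq(M, Xa, rcond=None)
    for i, c in enumerate(components):
        c.centroid_activities = A[i]
    return components


def decompose(
    X,
    dimension: int,
    n_runs: int = 100,
    tolerance: float = 1e-7,
    epsilon: float = 0.1,
    min_cluster_seed: int = 50,
    master_seed: int = 0,
    max_iter: int = 1000,
) -> Decomposition:
    """Full robust decomposition: restarts, clustering, centroid M/A assembly."""
    runs = run_ica_restarts(
        X, dimension, n_runs=n_runs, tolerance=tolerance,
        master_seed=master_seed, max_iter=max_iter,
    )
    components = cluster_components(
        runs, X, epsilon=epsilon, min_cluster_seed=min_cluster_seed
    )
    genes = list(X.index) if isinstance(X, pd.DataFrame) else list(range(_as_array(X).shape[0]))
    samples = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(_as_array(X).shape[1]))
    ids = [f"IC_{i + 1}" for i in range(len(components))]
    M = pd.DataFrame(
        np.column_stack([c.centroid_weights for c in components]) if components
        else np.empty((len(genes), 0)),
        index=genes,
        columns=ids,
    )
    A = pd.DataFrame(
        np.vstack([c.centroid_activities for c in components]) if components
        else np.empty((0, len(samples))),
        index=ids,
        columns=samples,
    )
    return Decomposition(
        M=M, A=A, dimension=dimension, n_runs=n_runs, tolerance=tolerance,
        epsilon=epsilon, min_cluster_seed=min_cluster_seed, master_seed=master_seed,
        components=components,
    )


def select_dimension(
    X,
    dim_min: int = 20,
    dim_max: int = 215,
    step: int = 5,
    n_runs: int = 100,
    tolerance: float = 1e-7,
    epsilon: float = 0.1,
    min_cluster_seed: int = 50,
    master_seed: int = 0,
    match_corr: float = 0.7,
) -> tuple[int, pd.DataFrame]:
    """Scan candidate ICA dimensions and pick the working one.

    For each dimension the scan records the number of robust components, the
    number whose thresholded gene set has more than one gene, and the number
    reproduced (|ρ| > `match_corr` between weight vectors) at the largest
    scanned dimension. The chosen dimension is the smallest at which the
    non-single-gene count equals the reproduced count; among such dimensions
    the one with the most reproduced components wins (ties go to the smallest
    dimension), because at low dimensions a handful of two-module mixtures can
    trivially satisfy the equality while reproducing only a fraction of the
    final structure. If no dimension satisfies the equality, the smallest
    dimension minimizing the gap is returned.
    """
    from .imodulons import compute_gene_threshold  # local import, avoids cycle

    dims = list(range(dim_min, dim_max + 1, step))
    if not dims:
        raise ValueError("empty dimension scan range")
    Xa = _as_array(X)
    if dims[-1] > min(Xa.shape) - 1:
        raise ValueError("dim_max must be < min(genes, samples)")

    decomps = {
        d: decompose(
            X, d, n_runs=n_runs, tolerance=tolerance, epsilon=epsilon,
            min_cluster_seed=min_cluster_seed, master_seed=master_seed,
        )
        for d in dims
    }
    M_final = decomps[dims[-1]].M.values

    rows = []
    for d in dims:
        M = decomps[d].M.values
        n_robust = M.shape[1]
        n_non_single = 0
        for j in range(n_robust):
            w = M[:, j]
            thr = compute_gene_threshold(w)
            if int(np.sum(np.abs(w) > thr)) > 1:
                n_non_single += 1
        if n_robust and M_final.shape[1]:
            corr = np.corrcoef(M.T, M_final.T)[:n_robust, n_robust:]
            n_matched = int(np.sum(np.max(np.abs(corr), axis=1) > match_corr))
        else:
            n_matched = 0
        rows.append(
            {
                "dimension": d,
                "n_robust": n_robust,
                "n_non_single_gene": n_non_single,
                "n_matched_final": n_matched,
            }
        )
    diagnostics = pd.DataFrame(rows)
    exact = diagnostics[
        (diagnostics.n_non_single_gene == diagnostics.n_matched_final)
        & (diagnostics.n_robust > 0)
    ]
    if len(exact):
        best = exact.sort_values(
            by=["n_matched_final", "dimension"], ascending=[False, True]
        )
        chosen = int(best.dimension.iloc[0])
    else:
        gap = (diagnostics.n_non_single_gene - diagnostics.n_matched_final).abs()
        chosen = int(diagnostics.dimension.iloc[int(np.argmin(gap.values))])
    return chosen, diagnostics
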