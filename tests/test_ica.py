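"""Robust ICA: distance metric, restarts, density clustering, dimension scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from modulome import (
    cluster_components,
    component_distance,
    decompose,
    run_ica_restarts,
    select_dimension,
)
from modulome.ica import ComponentRun, _distance_matrix


class TestComponentDistance:
    def test_self_and_sign_flip_are_zero(self):
        x = np.array([0.3, -1.2, 2.0, 0.1, -0.5])
        assert component_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert component_distance(x, -x) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_centered_vectors(self):
        x = np.array([1.0, 0.0, -1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert component_distance(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_reference_value(self):
        # rho = 9 / sqrt(84) ~ 0.98198 -> d ~ 0.01802
        d = component_distance(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert d == pytest.approx(1.0 - 9.0 / np.sqrt(84.0), abs=1e-9)
        assert d == pytest.approx(0.01802, abs=5e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            component_distance(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, 6, elements=st.floats(-5, 5)),
        hnp.arrays(np.float64, 6, elements=st.floats(-5, 5)),
    )
    def test_symmetric_and_bounded(self, x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return
        d_xy = component_distance(x, y)
        assert d_xy == pytest.approx(component_distance(y, x), abs=1e-12)
        assert 0.0 <= d_xy <= 1.0


def _planted_sources(n_genes=200, n_samples=24, k=3, seed=0):
    """Noiseless mix of k sparse heavy-tailed gene sources."""
    rng = np.random.default_rng(seed)
    M = np.zeros((n_genes, k))
    block = n_genes // (2 * k)
    for j in range(k):
        idx = np.arange(j * block, (j + 1) * block)
        M[idx, j] = rng.laplace(0, 1, size=block) + np.sign(rng.normal(size=block))
        M[:, j] /= np.linalg.norm(M[:, j])
    A = rng.normal(0, 10, size=(k, n_samples))
    X = M @ A
    X -= X.mean(axis=0, keepdims=True)
    return X, M, A


class TestRestarts:
    def test_recovers_planted_sources(self):
        X, M_true, _ = _planted_sources(seed=4)
        runs = run_ica_restarts(X, dimension=3, n_runs=5, master_seed=11)
        for run in runs:
            # greedy matching by |rho|
            corr = np.abs(np.corrcoef(run.weights.T, M_true.T)[:3, 3:])
            matched = []
            work = corr.copy()
            for _ in range(3):
                i, j = np.unravel_index(np.argmax(work), work.shape)
                matched.append(work[i, j])
                work[i, :] = -1
                work[:, j] = -1
            assert min(matched) >= 0.95

    def test_full_dimension_reconstructs(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 8))
        X -= X.mean(axis=0, keepdims=True)
        runs = run_ica_restarts(X, dimension=8, n_runs=2, master_seed=1)
        for run in runs:
            rec = run.weights @ run.activities
            rel = np.linalg.norm(X - rec) / np.linalg.norm(X)
            assert rel <= 1e-6

    def test_unit_norm_columns(self):
        X, _, _ = _planted_sources(seed=5)
        runs = run_ica_restarts(X, dimension=3, n_runs=2, master_seed=2)
        for run in runs:
            norms = np.linalg.norm(run.weights, axis=0)
            assert np.abs(norms - 1.0).max() < 1e-9

    def test_deterministic_under_master_seed(self):
        X, _, _ = _planted_sources(seed=6)
        r1 = run_ica_restarts(X, dimension=3, n_runs=3, master_seed=42)
        r2 = run_ica_restarts(X, dimension=3, n_runs=3, master_seed=42)
        for a, b in zip(r1, r2):
            assert (a.weights == b.weights).all()
            assert (a.activities == b.activities).all()


def _runs_from_columns(columns, n_genes):
    """Wrap bare weight columns as single-component runs."""
    return [
        ComponentRun(
            run_index=i,
            seed=i,
            weights=col.reshape(n_genes, 1),
            activities=np.zeros((1, 2)),
        )
        for i, col in enumerate(columns)
    ]


def _brute_force_dbscan(D, eps, min_samples):
    """Independent density-clustering oracle: BFS over the eps-graph from cores."""
    n = D.shape[0]
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = [-1] * n
    current = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = current
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for nb in neighbors[j]:
                if labels[nb] == -1:
                    labels[nb] = current
                    queue.append(nb)
        current += 1
    return labels


class TestClustering:
    def test_identical_columns_one_cluster(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        v /= np.linalg.norm(v)
        signs = rng.choice([-1.0, 1.0], size=100)
        runs = _runs_from_columns([s * v for s in signs], 50)
        X = np.outer(v, [1.0, 2.0])
        comps = cluster_components(runs, X, epsilon=0.1, min_cluster_seed=50)
        assert len(comps) == 1
        assert comps[0].cluster_size == 100
        assert abs(abs(comps[0].centroid_weights @ v) - 1.0) < 1e-9

    def test_small_cluster_discarded(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=80)
        w = rng.normal(size=80)
        v /= np.linalg.norm(v)
        w /= np.linalg.norm(w)
        cols = [v] * 60 + [w] * 40
        runs = _runs_from_columns(cols, 80)
        X = np.column_stack([v, w])
        comps = cluster_components(runs, X, epsilon=0.1, min_cluster_seed=50)
        assert len(comps) == 1
        assert comps[0].cluster_size == 60
        assert abs(abs(comps[0].centroid_weights @ v) - 1.0) < 1e-9

        # cross-check the clustering against a brute-force density oracle
        W = np.column_stack(cols)
        D = _distance_matrix(W)
        labels = _brute_force_dbscan(D, eps=0.1, min_samples=50)
        sizes = sorted(
            sum(1 for l in labels if l == lab) for lab in set(labels) if lab >= 0
        )
        assert sizes == [60]

    def test_all_orthogonal_columns_no_cluster(self):
        cols = [np.eye(60)[:, i] for i in range(10)]
        runs = _runs_from_columns(cols, 60)
        with pytest.warns(UserWarning, match="no robust components"):
            comps = cluster_components(
                runs, np.zeros((60, 2)), epsilon=0.1, min_cluster_seed=5
            )
        assert comps == []

    def test_member_sign_flips_leave_centroid_invariant(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=40)
        v /= np.linalg.norm(v)
        X = np.outer(v, [1.0, -1.0])
        runs_a = _runs_from_columns([v] * 10, 40)
        runs_b = _runs_from_columns([v * s for s in rng.choice([-1, 1], size=10)], 40)
        ca = cluster_components(runs_a, X, min_cluster_seed=5)[0]
        cb = cluster_components(runs_b, X, min_cluster_seed=5)[0]
        assert np.allclose(ca.centroid_weights, cb.centroid_weights)

    def test_sign_convention_largest_weight_positive(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=40)
        v /= np.linalg.norm(v)
        if v[np.argmax(np.abs(v))] > 0:
            v = -v  # feed a negatively oriented column
        runs = _runs_from_columns([v] * 10, 40)
        c = cluster_components(runs, np.outer(v, [1.0, 2.0]), min_cluster_seed=5)[0]
        w = c.centroid_weights
        assert w[np.argmax(np.abs(w))] > 0


class TestDecompose:
    def test_activities_reconstruct_by_least_squares(self, small_world):
        from modulome import center_to_reference

        compendium, _ = small_world
        X = center_to_reference(compendium).values
        d = decompose(X.iloc[:, :], dimension=6, n_runs=8, min_cluster_seed=4, master_seed=9)
        rec = d.M.values @ d.A.values
        rel = np.linalg.norm(X.values - rec) / np.linalg.norm(X.values)
        assert rel < 0.2  # noise floor only
        assert np.abs(np.linalg.norm(d.M.values, axis=0) - 1.0).max() < 1e-9
        assert d.k_robust <= d.dimension


class TestSelectDimension:
    def test_single_candidate_returned(self, small_world):
        from modulome import center_to_reference

        compendium, _ = small_world
        X = center_to_reference(compendium).values
        chosen, diag = select_dimension(
            X, dim_min=6, dim_max=6, step=5, n_runs=6, min_cluster_seed=3, master_seed=5
        )
        assert chosen == 6
        assert len(diag) == 1

    def test_scan_recovers_planted_modules(self):
        from modulome import (
            center_to_reference,
            define_imodulons,
            generate_compendium,
            score_recovery,
        )

        compendium, truth = generate_compendium(
            n_genes=800, n_conditions=25, replicates_per_condition=3,
            k_modules=10, genes_per_module=30, seed=321, planted_shifts={},
        )
        X = center_to_reference(compendium).values
        chosen, diag = select_dimension(
            X, dim_min=5, dim_max=30, step=5, n_runs=6, min_cluster_seed=3,
            master_seed=17,
        )
        assert len(diag) == 6  # one row per scanned dimension
        d = decompose(X, chosen, n_runs=8, min_cluster_seed=4, master_seed=18)
        ims = define_imodulons(d)
        rec = score_recovery(ims, truth)
        assert (rec.jaccard >= 0.7).sum() >= 9
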