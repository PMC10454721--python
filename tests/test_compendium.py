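"""Compendium loading, replicate QC, and reference centering."""

import numpy as np
import pandas as pd
import pytest

from modulome import (
    center_to_reference,
    filter_replicates,
    load_expression,
    replicate_correlation_summary,
)
from modulome.compendium import (
    CompendiumError,
    write_expression,
    write_metadata,
)

from conftest import correlated_pair, make_compendium, make_metadata


def _write_dataset(tmp_path, values: pd.DataFrame, metadata: pd.DataFrame):
    expr = tmp_path / "expr.tsv"
    meta = tmp_path / "meta.csv"
    out = values.copy()
    out.index.name = "gene_id"
    out.to_csv(expr, sep="\t")
    metadata.reset_index().to_csv(meta, index=False)
    return expr, meta


@pytest.fixture
def tiny_meta():
    return make_metadata(
        samples=["s1", "s2"],
        projects=["p1", "p1"],
        conditions=["c1", "c2"],
        references=["c1", "c1"],
    )


class TestLoad:
    def test_round_trip(self, tmp_path, tiny_meta):
        values = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["gA", "gB", "gC"],
            columns=["s1", "s2"],
        )
        expr, meta = _write_dataset(tmp_path, values, tiny_meta)
        c = load_expression(expr, meta)
        assert c.values.shape == (3, 2)
        assert np.allclose(c.values.values, values.values)
        assert c.genes == ["gA", "gB", "gC"]

        # write -> read reproduces values to full float precision
        out_expr = tmp_path / "out.tsv"
        out_meta = tmp_path / "out_meta.csv"
        write_expression(c, out_expr)
        write_metadata(c, out_meta)
        c2 = load_expression(out_expr, out_meta)
        assert (c2.values.values == c.values.values).all()

    def test_duplicate_gene_rejected(self, tmp_path, tiny_meta):
        expr = tmp_path / "expr.tsv"
        expr.write_text("gene_id\ts1\ts2\ngA\t1\t2\ngA\t3\t4\n")
        meta = tmp_path / "meta.csv"
        tiny_meta.reset_index().to_csv(meta, index=False)
        with pytest.raises(CompendiumError, match="gA"):
            load_expression(expr, meta)

    def test_metadata_sample_missing_from_matrix(self, tmp_path):
        values = pd.DataFrame([[1.0]], index=["gA"], columns=["s1"])
        meta = make_metadata(
            samples=["s1", "s_ghost"],
            projects=["p1", "p1"],
            conditions=["c1", "c1"],
            references=["c1", "c1"],
        )
        expr, meta_path = _write_dataset(tmp_path, values, meta)
        with pytest.raises(CompendiumError, match="s_ghost"):
            load_expression(expr, meta_path)

    def test_non_numeric_cell_names_coordinates(self, tmp_path, tiny_meta):
        expr = tmp_path / "expr.tsv"
        expr.write_text("gene_id\ts1\ts2\ngA\t1\tabc\ngB\t3\t4\n")
        meta = tmp_path / "meta.csv"
        tiny_meta.reset_index().to_csv(meta, index=False)
        with pytest.raises(CompendiumError, match="gA.*s2"):
            load_expression(expr, meta)


class TestFilterReplicates:
    def test_identical_replicates_retained(self):
        meta = make_metadata(
            ["s1", "s2"], ["p", "p"], ["c", "c"], ["c", "c"], ["r1", "r1"]
        )
        v = np.random.default_rng(0).normal(size=(50, 1))
        c = make_compendium(np.hstack([v, v]), meta)
        filtered, removed = filter_replicates(c)
        assert removed == []
        assert filtered.samples == ["s1", "s2"]

    def test_outlier_replicate_removed(self):
        # S1 == S2 (rho = 1); S3 independent noise (rho ~ 0)
        rng = np.random.default_rng(1)
        v = rng.normal(size=(200, 1))
        w = rng.normal(size=(200, 1))
        assert abs(np.corrcoef(v[:, 0], w[:, 0])[0, 1]) < 0.3
        meta = make_metadata(
            ["s1", "s2", "s3"], ["p"] * 3, ["c"] * 3, ["c"] * 3, ["r1"] * 3
        )
        c = make_compendium(np.hstack([v, v, w]), meta)
        filtered, removed = filter_replicates(c)
        assert removed == ["s3"]
        assert filtered.samples == ["s1", "s2"]

    def test_pair_just_below_cutoff_both_removed(self):
        x, y = correlated_pair(0.949, n=300, seed=2)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.949, abs=1e-12)
        meta = make_metadata(
            ["s1", "s2"], ["p", "p"], ["c", "c"], ["c", "c"], ["r1", "r1"]
        )
        c = make_compendium(np.column_stack([x, y]), meta)
        with pytest.warns(UserWarning, match="whole group"):
            filtered, removed = filter_replicates(c)
        assert sorted(removed) == ["s1", "s2"]
        assert filtered.samples == []

    def test_singleton_group_untouched(self):
        meta = make_metadata(
            ["s1", "s2"], ["p", "p"], ["c1", "c2"], ["c1", "c1"], ["r1", "r2"]
        )
        rng = np.random.default_rng(3)
        c = make_compendium(rng.normal(size=(30, 2)), meta)
        _, removed = filter_replicates(c)
        assert removed == []

    def test_rejects_centered_compendium(self):
        meta = make_metadata(
            ["s1", "s2"], ["p", "p"], ["c", "c"], ["c", "c"], ["r1", "r1"]
        )
        c = make_compendium(np.random.default_rng(0).normal(size=(30, 2)), meta)
        centered = center_to_reference(c)
        with pytest.raises(CompendiumError):
            filter_replicates(centered)


class TestCorrelationSummary:
    def test_median_of_known_pairs(self):
        # three 2-sample groups with pair correlations 0.9, 0.96, 1.0
        rhos = [0.9, 0.96, 1.0]
        cols, samples, groups = [], [], []
        for i, rho in enumerate(rhos):
            x, y = correlated_pair(rho, n=400, seed=10 + i)
            cols += [x, y]
            samples += [f"s{i}a", f"s{i}b"]
            groups += [f"r{i}", f"r{i}"]
        meta = make_metadata(samples, ["p"] * 6, groups, [groups[0]] * 6, groups)
        c = make_compendium(np.column_stack(cols), meta)
        summary = replicate_correlation_summary(c)
        assert summary["n_pairs"] == 3
        assert summary["median"] == pytest.approx(0.96, abs=1e-9)
        assert summary["min"] == pytest.approx(0.9, abs=1e-9)

    def test_no_groups_gives_empty_summary(self):
        meta = make_metadata(
            ["s1", "s2"], ["p", "p"], ["c1", "c2"], ["c1", "c1"], ["r1", "r2"]
        )
        c = make_compendium(np.random.default_rng(0).normal(size=(20, 2)), meta)
        summary = replicate_correlation_summary(c)
        assert summary["n_pairs"] == 0 and summary["median"] is None

    def test_synthetic_default_noise_median_high(self, small_world):
        compendium, _ = small_world
        summary = replicate_correlation_summary(compendium)
        assert summary["median"] >= 0.95


class TestCentering:
    def test_reference_mean_subtracted(self):
        # reference replicates (2, 4); test sample 5 -> 5 - mean(2,4) = 2
        meta = make_metadata(
            ["ref1", "ref2", "t1"],
            ["p"] * 3,
            ["c_ref", "c_ref", "c_t"],
            ["c_ref"] * 3,
            ["r1", "r1", "r2"],
        )
        c = make_compendium(np.array([[2.0, 4.0, 5.0]]), meta)
        centered = center_to_reference(c)
        assert centered.values.iloc[0].tolist() == [-1.0, 1.0, 2.0]
        assert centered.values["t1"].iloc[0] == pytest.approx(2.0)
        assert centered.centered

    def test_all_zero_reference_is_identity(self):
        meta = make_metadata(
            ["ref1", "t1"], ["p", "p"], ["c_ref", "c_t"], ["c_ref"] * 2, ["r1", "r2"]
        )
        c = make_compendium(np.array([[0.0, 7.0], [0.0, -3.0]]), meta)
        centered = center_to_reference(c)
        assert np.allclose(centered.values.values, c.values.values)

    def test_reference_means_zero_per_project(self, small_world):
        compendium, _ = small_world
        centered = center_to_reference(compendium)
        for _, sub in centered.metadata.groupby("project_id"):
            ref = sub["reference_condition_id"].iloc[0]
            ref_samples = sub.index[sub["condition_id"] == ref].tolist()
            means = centered.values[ref_samples].mean(axis=1)
            assert np.abs(means.values).max() < 1e-9

    def test_idempotent_in_effect(self, small_world):
        compendium, _ = small_world
        once = center_to_reference(compendium)
        twice = center_to_reference(once)
        assert np.abs(twice.values.values - once.values.values).max() <= 1e-9

    def test_missing_reference_samples_rejected(self):
        meta = make_metadata(
            ["t1", "t2"], ["p", "p"], ["c_t", "c_t"], ["c_ref", "c_ref"], ["r1", "r1"]
        )
        c = make_compendium(np.zeros((3, 2)), meta)
        with pytest.raises(CompendiumError, match="c_ref"):
            center_to_reference(c)
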