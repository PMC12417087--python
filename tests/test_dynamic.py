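import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stagewalk import (
    BackgroundNetwork,
    ExpressionMatrix,
    StagePartition,
    active_probabilities,
    build_dynamic_networks,
    gene_stats,
    reweight_sample,
    stage_adjacency,
)
from stagewalk.containers import ValidationError
from stagewalk.dynamic import ACTIVITY_LEVELS


def expr_from(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = np.vstack([values, np.zeros_like(values)])
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestGeneStats:
    def test_mean_and_unbiased_sd(self):
        stats = gene_stats(expr_from([1.0, 2.0, 3.0]))
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.sigma[0] == pytest.approx(1.0)

    def test_constant_gene_collapses_thresholds(self):
        stats = gene_stats(expr_from([5.0, 5.0, 5.0, 5.0]))
        assert stats.sigma[0] == 0.0
        assert np.allclose(stats.thresholds[:, 0], 5.0)

    def test_damped_thresholds_at_unit_sigma(self):
        # mean 2, sigma 1 -> damping 1/2 -> Th1 = 2.5, Th3 = 3.5
        stats = gene_stats(expr_from([1.0, 2.0, 3.0]))
        assert stats.thresholds[0, 0] == pytest.approx(2.5)
        assert stats.thresholds[1, 0] == pytest.approx(3.0)
        assert stats.thresholds[2, 0] == pytest.approx(3.5)

    @given(
        values=hnp.arrays(
            float,
            shape=st.tuples(st.integers(2, 6), st.integers(2, 10)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_threshold_monotonicity(self, values):
        """Th1 <= Th2 <= Th3 for every gene, any finite data."""
        stats = gene_stats(expr_from(values))
        assert (np.diff(stats.thresholds, axis=0) >= -1e-12).all()

    def test_large_sigma_limit(self):
        """As sigma -> inf the damping factor -> 1, so Th_k -> mean + k*sigma."""
        base = np.array([-1.0, 1.0]) * 1e3 * np.sqrt(2) / 2  # sigma ~ 1e3, mean 0
        stats = gene_stats(expr_from(base))
        sigma = stats.sigma[0]
        for k in range(1, 4):
            expected = stats.mean[0] + k * sigma
            assert stats.thresholds[k - 1, 0] == pytest.approx(expected, rel=1e-4)


def _one_sample():
    # bypass ExpressionMatrix's own M >= 2 check via direct construction attempt
    return ExpressionMatrix(["a", "b"], ["s0", "s1"], [[1.0, 2.0], [3.0, 4.0]])


def test_gene_stats_requires_two_samples():
    expr = _one_sample()
    expr.sample_ids = ["s0"]
    expr.values = expr.values[:, :1]
    with pytest.raises(ValidationError):
        gene_stats(expr)


class TestActiveProbabilities:
    def test_band_mapping_with_boundaries(self):
        expr = expr_from([1.0, 2.0, 3.0, 2.5, 3.0, 3.5, 0.0, 2.49])
        stats = gene_stats(expr)
        # gene 0: mean 2.1862..., recompute bands explicitly
        th1, th2, th3 = stats.thresholds[:, 0]
        ap = active_probabilities(expr, stats)[0]
        for value, prob in zip(expr.values[0], ap):
            if value >= th3:
                assert prob == 0.99
            elif value >= th2:
                assert prob == 0.95
            elif value >= th1:
                assert prob == 0.68
            else:
                assert prob == 0.0

    def test_exact_boundary_values_inclusive_below(self):
        """A value exactly at Th_k belongs to the upper band (>= rule)."""
        expr = expr_from([1.0, 2.0, 3.0])
        stats = gene_stats(expr)
        probe = ExpressionMatrix(
            expr.gene_ids,
            ["p1", "p2", "p3"],
            np.vstack([stats.thresholds[:, 0], np.zeros(3)]),
        )
        ap = active_probabilities(probe, stats)[0]
        assert list(ap) == [0.68, 0.95, 0.99]

    def test_values_are_band_constants(self):
        rng = np.random.default_rng(0)
        expr = expr_from(rng.normal(size=(4, 12)))
        ap = active_probabilities(expr, gene_stats(expr))
        assert set(np.unique(ap)) <= set(ACTIVITY_LEVELS)


class TestReweighting:
    def test_two_sided_product(self, toy_background):
        ap = np.array([0.99, 0.95, 1.0, 1.0, 1.0])
        net = reweight_sample(toy_background, ap)
        assert net.adjacency[0, 1] == pytest.approx(0.99 * 0.9 * 0.95)

    def test_inactive_gene_zeroes_row_and_column(self, toy_background):
        ap = np.ones(5)
        ap[2] = 0.0
        net = reweight_sample(toy_background, ap)
        A = net.adjacency.toarray()
        assert A[2].sum() == 0 and A[:, 2].sum() == 0

    def test_all_active_identity(self, toy_background):
        net = reweight_sample(toy_background, np.ones(5))
        assert abs(net.adjacency - toy_background.adjacency).max() == 0

    def test_length_mismatch(self, toy_background):
        with pytest.raises(ValidationError):
            reweight_sample(toy_background, np.ones(4))


class TestStageAdjacency:
    def test_mean_of_two(self, toy_background):
        a = reweight_sample(toy_background, np.full(5, np.sqrt(0.4 / 0.9)))
        b = reweight_sample(toy_background, np.full(5, np.sqrt(0.6 / 0.9)))
        stage = stage_adjacency([a, b], "s")
        assert stage.adjacency[0, 1] == pytest.approx(0.5 * (0.4 + 0.6))

    def test_single_sample_is_identity(self, toy_background):
        a = reweight_sample(toy_background, np.full(5, 0.7))
        stage = stage_adjacency([a], "s")
        assert abs(stage.adjacency - a.adjacency).max() == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            stage_adjacency([], "s")


class TestBuildDynamicNetworks:
    def test_constant_genes_hit_top_band(self, toy_background):
        """With sigma = 0 every value sits at Th3 = mean, so ap = 0.99 everywhere."""
        values = np.tile(np.array([[3.0], [1.0], [2.0], [5.0], [4.0]]), (1, 4))
        expr = ExpressionMatrix(toy_background.gene_ids, [f"s{j}" for j in range(4)], values)
        stages = StagePartition(
            ["a", "b"], {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        )
        nets = build_dynamic_networks(expr, stages, toy_background)
        expected = 0.99 * 0.99 * toy_background.adjacency.toarray()
        for net in nets:
            assert np.allclose(net.adjacency.toarray(), expected)

    def test_zero_background_gives_zero_stages(self, toy_expr, toy_stages):
        empty = BackgroundNetwork(toy_expr.gene_ids, sp.csr_matrix((5, 5)))
        nets = build_dynamic_networks(toy_expr, toy_stages, empty)
        assert all(net.adjacency.nnz == 0 for net in nets)

    def test_hand_composed_two_stage_fixture(self, toy_background):
        """Compose stats -> bands -> reweight -> mean by hand and compare."""
        rng = np.random.default_rng(5)
        values = rng.normal(4.0, 2.0, size=(5, 4))
        expr = ExpressionMatrix(toy_background.gene_ids, [f"s{j}" for j in range(4)], values)
        stages = StagePartition(["a", "b"], {"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
        nets = build_dynamic_networks(expr, stages, toy_background)

        mean = values.mean(axis=1)
        sigma = values.std(axis=1, ddof=1)
        damp = 1 - 1 / (1 + sigma**2)
        A = toy_background.adjacency.toarray()
        for stage, cols in [("a", [0, 1]), ("b", [2, 3])]:
            acc = np.zeros((5, 5))
            for m in cols:
                ap = np.zeros(5)
                for n in range(5):
                    v = values[n, m]
                    ths = [mean[n] + k * sigma[n] * damp[n] for k in (1, 2, 3)]
                    ap[n] = (
                        0.99 if v >= ths[2] else 0.95 if v >= ths[1] else 0.68 if v >= ths[0] else 0.0
                    )
                acc += np.outer(ap, ap) * A
            expected = acc / len(cols)
            got = [net for net in nets if net.stage == stage][0].adjacency.toarray()
            assert np.allclose(got, expected)

    def test_entrywise_bound(self, toy_background):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, size=(5, 6))
        expr = ExpressionMatrix(toy_background.gene_ids, [f"s{j}" for j in range(6)], values)
        stages = StagePartition(
            ["a", "b"], {f"s{j}": ("a" if j < 3 else "b") for j in range(6)}
        )
        nets = build_dynamic_networks(expr, stages, toy_background)
        A = toy_background.adjacency.toarray()
        for net in nets:
            D = net.adjacency.toarray()
            assert (D >= -1e-15).all()
            assert (D <= A + 1e-12).all()

    def test_sample_permutation_equivariance(self, toy_background):
        """Shuffling sample order within a stage leaves A[s] unchanged."""
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, size=(5, 6))
        genes = toy_background.gene_ids
        samples = [f"s{j}" for j in range(6)]
        expr = ExpressionMatrix(genes, samples, values)
        perm = [2, 0, 1, 5, 3, 4]  # permutes within each stage
        expr_p = ExpressionMatrix(genes, [samples[j] for j in perm], values[:, perm])
        stages = StagePartition(["a", "b"], {f"s{j}": ("a" if j < 3 else "b") for j in range(6)})
        nets = build_dynamic_networks(expr, stages, toy_background)
        nets_p = build_dynamic_networks(expr_p, stages, toy_background)
        for x, y in zip(nets, nets_p):
            assert np.allclose(x.adjacency.toarray(), y.adjacency.toarray())
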