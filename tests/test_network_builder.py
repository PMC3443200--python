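import numpy as np
import pandas as pd
import pytest

from cnsnet.io_formats import ExpressionMatrix
from cnsnet.network_builder import (
    InsufficientEigenvaluesError,
    RMTThresholdSelector,
    average_connectivity,
    build_network,
    nnsd_poisson_chi2,
    nnsd_spacings,
    pairwise_pcc,
    poisson_gof,
    round_half_up,
    select_rmt_threshold,
    summarize_network,
)
from conftest import graph_network, planted_correlation


def make_matrix(values, group="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        group,
    )


class TestPairwisePcc:
    def test_duplicated_row_correlates_to_one(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=50)
        corr = pairwise_pcc(make_matrix([row, row]), min_overlap=2)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_row_correlates_to_minus_one(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=50)
        corr = pairwise_pcc(make_matrix([row, -row]), min_overlap=2)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula_on_random_matrix(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 100))
        corr = pairwise_pcc(make_matrix(x), min_overlap=2).to_numpy()
        expected = np.corrcoef(x)
        np.testing.assert_allclose(corr, expected, atol=1e-12)

    def test_low_overlap_pairs_marked_invalid_not_zero(self):
        x = np.full((3, 40), np.nan)
        x[0, :20] = np.random.default_rng(3).normal(size=20)
        x[1, 20:] = np.random.default_rng(4).normal(size=20)
        x[2, :] = np.random.default_rng(5).normal(size=40)
        corr = pairwise_pcc(make_matrix(x), min_overlap=10)
        assert np.isnan(corr.iloc[0, 1])  # zero overlapping samples
        assert not np.isnan(corr.iloc[0, 2])

    def test_zero_variance_row_invalid(self):
        x = np.vstack([np.ones(30), np.random.default_rng(6).normal(size=30)])
        corr = pairwise_pcc(make_matrix(x), min_overlap=2)
        assert np.isnan(corr.iloc[0, 1])

    def test_single_gene_matrix_rejected(self):
        with pytest.raises(ValueError):
            pairwise_pcc(make_matrix(np.ones((1, 10))))


class TestBuildNetwork:
    def corr_frame(self, values):
        n = values.shape[0]
        ids = [f"g{i}" for i in range(n)]
        return pd.DataFrame(values, index=ids, columns=ids)

    def test_threshold_one_keeps_only_perfect_pair(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 1.0
        c[0, 2] = c[2, 0] = 0.99
        net = build_network(self.corr_frame(c), 1.0, "t")
        assert net.n_edges == 1 and net.nodes == {"g0", "g1"}

    def test_threshold_above_max_gives_empty_network(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.5
        with pytest.warns(UserWarning, match="no edges"):
            net = build_network(self.corr_frame(c), 0.9, "t")
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_edge_set_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 40))
        c = np.corrcoef(x)
        frame = self.corr_frame(c)
        prev = None
        for t in (0.2, 0.4, 0.6, 0.8):
            edges = build_network(frame, t, "t").edge_set()
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_negative_correlations_kept_under_signed_mode(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = -0.95
        assert build_network(self.corr_frame(c), 0.9, "t", signed=True).n_edges == 1
        with pytest.warns(UserWarning):
            assert build_network(self.corr_frame(c), 0.9, "t", signed=False).n_edges == 0

    def test_edge_set_invariant_to_gene_order(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 50))
        x[:5] += rng.normal(size=50) * 2  # correlated block
        mat = make_matrix(x)
        corr = pairwise_pcc(mat, min_overlap=2)
        net1 = build_network(corr, 0.5, "a")
        perm = rng.permutation(20)
        mat2 = ExpressionMatrix(
            [mat.gene_ids[i] for i in perm],
            mat.sample_ids,
            x[perm],
            "g",
        )
        net2 = build_network(pairwise_pcc(mat2, min_overlap=2), 0.5, "b")
        assert net1.edge_set() == net2.edge_set()


class TestSummary:
    def test_triangle_closed_form(self):
        net = graph_network([("a", "b"), ("b", "c"), ("a", "c")])
        s = summarize_network(net)
        assert (s.n_nodes, s.n_edges, s.avg_connectivity) == (3, 3, 2.0)

    def test_empty_network_has_undefined_connectivity(self):
        assert average_connectivity(0, 0) is None

    @pytest.mark.parametrize(
        "n,e,expected",
        [(2606, 95004, 72.9), (1735, 17111, 19.7), (972, 8043, 16.5)],
    )
    def test_average_connectivity_examples(self, n, e, expected):
        assert average_connectivity(n, e) == expected

    def test_round_half_up(self):
        assert round_half_up(16.55, 1) == 16.6
        assert round_half_up(16.549, 1) == 16.5
        assert round_half_up(12.6499, 1) == 12.6


class TestNNSD:
    def test_goe_rejected_poisson_accepted_single_replicate(self):
        rng = np.random.default_rng(0)
        n = 300
        a = rng.normal(size=(n, n))
        goe = (a + a.T) / 2
        _, p_goe = poisson_gof(nnsd_spacings(np.linalg.eigvalsh(goe)))
        assert p_goe < 0.001
        from scipy.linalg import block_diag

        blocks = [
            (lambda m: (m + m.T) / 2)(rng.normal(size=(5, 5))) for _ in range(60)
        ]
        _, p_block = poisson_gof(
            nnsd_spacings(np.linalg.eigvalsh(block_diag(*blocks)))
        )
        assert p_block >= 0.001

    def test_identical_call_identical_statistic(self):
        corr, _ = planted_correlation(150, 100, [20, 20, 20, 20, 20], 0.9, seed=0)
        a = nnsd_poisson_chi2(corr, 0.7, min_eigenvalues=50)
        b = nnsd_poisson_chi2(corr, 0.7, min_eigenvalues=50)
        assert a == b

    def test_too_few_eigenvalues_signalled(self):
        with pytest.raises(InsufficientEigenvaluesError):
            nnsd_spacings(np.arange(10), min_eigenvalues=100)


class TestThresholdSelection:
    def test_planted_scenario_threshold_separates_signal_from_noise(self):
        # ground-truth comparison across 5 seeds
        for seed in range(5):
            corr, truth = planted_correlation(350, 200, [20] * 10, 0.9, seed=seed)
            t = select_rmt_threshold(corr, start=0.70, step=0.01)
            assert t is not None
            values = corr.to_numpy()
            ids = list(corr.index)
            pos = {g: i for i, g in enumerate(ids)}
            planted = [
                (pos[a], pos[b])
                for m in truth.planted_modules
                for i, a in enumerate(m["genes"])
                for b in m["genes"][i + 1 :]
            ]
            surv = np.mean([abs(values[i, j]) >= t for i, j in planted])
            assert surv >= 0.95
            mask = np.zeros_like(values, dtype=bool)
            for m in truth.planted_modules:
                idx = [pos[g] for g in m["genes"]]
                mask[np.ix_(idx, idx)] = True
            iu = np.triu_indices(len(ids), 1)
            bg = ~mask[iu]
            bg_frac = np.mean(np.abs(values[iu][bg]) >= t)
            assert bg_frac <= 0.01

    def test_pure_noise_gives_no_threshold_or_near_empty_network(self):
        corr, _ = planted_correlation(200, 150, [], 0.0, seed=1)
        t = select_rmt_threshold(corr, start=0.70, step=0.05)
        if t is not None:
            values = corr.to_numpy()
            iu = np.triu_indices(len(corr), 1)
            assert np.mean(np.abs(values[iu]) >= t) < 0.001

    def test_returned_value_lies_on_scan_grid(self):
        corr, _ = planted_correlation(300, 200, [20] * 8, 0.9, seed=2)
        t = select_rmt_threshold(corr, start=0.80, step=0.01, min_eigenvalues=100)
        if t is not None:
            assert round(t * 100) == pytest.approx(t * 100, abs=1e-9)

    def test_estimator_params_round_trip(self):
        sel = RMTThresholdSelector(start=0.8, step=0.02)
        params = sel.get_params()
        sel2 = RMTThresholdSelector().set_params(**params)
        assert sel2.get_params() == params
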