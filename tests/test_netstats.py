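"""Network construction/centralities and the statistical utilities."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from damfretkit.netstats import (
    build_network,
    centralities,
    chi_square_2x2,
    cluster_interaction_matrix,
    cramers_v_from_chi2,
    loglog_powerlaw_fit,
    mann_whitney,
    protein_label_from_domains,
    spearman,
    wald_ci,
)
from oracles import betweenness_brute, mann_whitney_u_exact


def edges_df(rows):
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


class TestBuildNetwork:
    def test_score_threshold_inclusive(self):
        g = build_network(edges_df([("a", "b", 899), ("b", "c", 900)]))
        assert not g.has_edge("a", "b") and g.has_edge("b", "c")

    def test_duplicate_keeps_max_score_and_no_self_loops(self):
        g = build_network(
            edges_df([("a", "b", 910), ("b", "a", 950), ("a", "a", 999)])
        )
        assert g["a"]["b"]["score"] == 950
        assert g.number_of_edges() == 1

    def test_malformed_rows_skipped(self):
        df = edges_df([("a", "b", 950), ("c", "d", "not-a-score")])
        g = build_network(df)
        assert g.graph["skipped_rows"] == 1
        assert g.number_of_edges() == 1

    def test_multi_domain_protein_label(self):
        assert protein_label_from_domains(["continuous", "discontinuous"]) == "discontinuous"
        assert protein_label_from_domains(["continuous"]) == "continuous"


class TestCentralities:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(3)
        df = centralities(g).set_index("node")
        assert df.loc[1, "degree_centrality"] == pytest.approx(1.0)
        assert df.loc[1, "betweenness_centrality"] == pytest.approx(1.0)
        assert df.loc[0, "betweenness_centrality"] == 0.0

    def test_complete_graph_zero_betweenness(self):
        df = centralities(nx.complete_graph(4))
        assert (df["betweenness_raw"] == 0).all()

    def test_matches_bfs_path_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 10))
            p = rng.uniform(0.25, 0.7)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            df = centralities(g).set_index("node")
            oracle = betweenness_brute(g.nodes, g.edges)
            for v in g.nodes:
                assert df.loc[v, "betweenness_raw"] == pytest.approx(oracle[v], abs=1e-9)


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(50.0)  # n1*n2/2

    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res.statistic == 0.0  # U for x when x entirely below y

    def test_exact_small_sample_oracle(self):
        x, y = [1.2, 3.4, 0.5, 2.2], [4.1, 2.8, 5.0, 3.9]
        res = mann_whitney(x, y)
        u_oracle, p_oracle = mann_whitney_u_exact(x, y)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_printed_cramers_v(self):
        assert cramers_v_from_chi2(40.71, 83) == pytest.approx(0.700, abs=5e-4)

    def test_independent_table(self):
        res = chi_square_2x2([[25, 25], [25, 25]])
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_perfect_association(self):
        res = chi_square_2x2([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.effect_size == pytest.approx(1.0)

    def test_zero_margin(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_rho_matches_rank_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=6), rng.normal(size=6)
        res = spearman(x, y)
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(rho_oracle, abs=1e-12)
        # two-tailed p within MC distance of the exhaustive permutation law
        from itertools import permutations

        perm_rhos = [
            abs(np.corrcoef(rx, np.array(p, float))[0, 1]) for p in permutations(ry)
        ]
        p_exact = np.mean(np.asarray(perm_rhos) >= abs(res.statistic) - 1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=0.06)

    def test_constant_input(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


class TestWaldCI:
    def test_printed_intervals(self):
        lo, hi = wald_ci(3423 - 16, 3423)
        assert round(100 * lo, 2) == 99.30 and round(100 * hi, 2) == 99.76
        lo, hi = wald_ci(3478 - 17, 3478)
        assert round(100 * lo, 2) == 99.28 and round(100 * hi, 2) == 99.74

    def test_degenerate(self):
        assert wald_ci(50, 50) == (1.0, 1.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(5, 4)


class TestPowerLaw:
    def test_exact_power_law(self):
        x = np.geomspace(1, 100, 30)
        fit = loglog_powerlaw_fit(x, 3 * x**-2.0)
        assert fit.slope == pytest.approx(-2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(np.log10(3), abs=1e-10)

    def test_slope_ci_coverage(self):
        rng = np.random.default_rng(3)
        x = np.geomspace(1, 1000, 25)
        cover = 0
        n_rep = 400
        for _ in range(n_rep):
            y = 2.0 * x**-1.5 * 10 ** rng.normal(0, 0.1, x.size)
            fit = loglog_powerlaw_fit(x, y)
            cover += fit.slope_ci[0] <= -1.5 <= fit.slope_ci[1]
        assert cover / n_rep == pytest.approx(0.95, abs=0.035)

    def test_minimal_input_and_errors(self):
        fit = loglog_powerlaw_fit([1, 10, 100], [1.0, 0.5, 0.1])
        assert np.isfinite(fit.slope)
        with pytest.raises(ValueError):
            loglog_powerlaw_fit([0, 1, 2], [1, 1, 1])


class TestClustering:
    def test_planted_blocks_contiguous(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 0.1, (8, 8))
        m[:4, :4] += 5.0
        m[4:, 4:] += 5.0
        perm = rng.permutation(8)
        rows, cols = cluster_interaction_matrix(pd.DataFrame(m[perm][:, perm]))
        labels = (perm < 4)[rows]
        # members of each planted block are adjacent in the leaf order
        assert np.abs(np.diff(labels.astype(int))).sum() == 1

    def test_small_and_degenerate(self):
        rows, cols = cluster_interaction_matrix(pd.DataFrame([[1.0, 2.0], [3.0, 4.0]]))
        assert sorted(rows) == [0, 1] and sorted(cols) == [0, 1]
        with pytest.raises(ValueError):
            cluster_interaction_matrix(pd.DataFrame(np.ones((3, 3))))
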