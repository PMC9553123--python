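import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scpfates.container import CountContainer
from scpfates.fate import (
    absorption_probabilities,
    combine_kernels,
    differentiation_potential,
    root_probabilities,
    select_terminal_states,
    tip_markers,
)
from scpfates.graph import build_graph


def _row_norm(m):
    m = np.asarray(m, dtype=float)
    return m / m.sum(axis=1, keepdims=True)


class TestCombineKernels:
    @pytest.fixture()
    def setup(self, small_norm):
        g = build_graph(small_norm, n_pcs=10, k=5, seed=0)
        n = g.n_cells
        rng = np.random.default_rng(0)
        t_vel = sp.csr_matrix(_row_norm(rng.random((n, n)) * (g.connectivities > 0).toarray()
                                        + np.eye(n) * 1e-12))
        return t_vel, g

    def test_w0_returns_velocity_kernel(self, setup):
        t_vel, g = setup
        t = combine_kernels(t_vel, g, w=0.0)
        tv = _row_norm(t_vel.toarray())
        assert np.allclose(t.toarray(), tv, atol=1e-12)

    def test_w1_returns_connectivity_kernel(self, setup):
        t_vel, g = setup
        t = combine_kernels(t_vel, g, w=1.0)
        tc = _row_norm(g.connectivities.toarray())
        assert np.allclose(t.toarray(), tc, atol=1e-12)

    @pytest.mark.parametrize("w", [0.0, 0.3, 0.7, 1.0])
    def test_rows_sum_to_one(self, setup, w):
        t_vel, g = setup
        t = combine_kernels(t_vel, g, w=w)
        assert np.allclose(np.asarray(t.sum(axis=1)).ravel(), 1.0, atol=1e-10)

    def test_w_out_of_range_rejected(self, setup):
        t_vel, g = setup
        with pytest.raises(ValueError):
            combine_kernels(t_vel, g, w=1.5)


def _block_chain(eps=0.02, block=10, n_blocks=6, seed=0):
    """Blocks 0-2 nearly absorbing, blocks 3-5 transient feeding into them."""
    rng = np.random.default_rng(seed)
    n = block * n_blocks
    t = np.zeros((n, n))
    labels = np.repeat(np.arange(n_blocks), block)
    for b in range(n_blocks):
        rows = np.where(labels == b)[0]
        inner = rng.random((block, block)) + 0.1
        t[np.ix_(rows, rows)] = inner
        if b >= 3:  # transient blocks leak towards absorbing block b-3
            target = np.where(labels == b - 3)[0]
            t[np.ix_(rows, target)] = rng.random((block, block)) * 2.0
        else:
            others = np.where(labels != b)[0]
            t[np.ix_(rows, others)] *= 0.0
            t[np.ix_(rows, rows)] = inner * (1 - eps)
            # tiny leak keeps the chain irreducible enough for ranking
            t[rows, (rows + block) % n] += eps
    return _row_norm(t), labels


class TestSelectTerminalStates:
    def test_absorbing_blocks_rank_top3_by_metastability(self):
        t, labels = _block_chain()
        terminal = select_terminal_states(sp.csr_matrix(t), labels,
                                          n_macrostates=6, n_terminal=3)
        assert sorted(terminal) == ["0", "1", "2"]
        for name, members in terminal.items():
            assert np.array_equal(members, np.where(labels == int(name))[0])

    def test_user_selection_returned_verbatim(self):
        t, labels = _block_chain()
        terminal = select_terminal_states(sp.csr_matrix(t), labels,
                                          terminal_names=[4, 1])
        assert sorted(terminal) == ["1", "4"]

    def test_missing_user_cluster_rejected(self):
        t, labels = _block_chain()
        with pytest.raises(ValueError, match="absent"):
            select_terminal_states(sp.csr_matrix(t), labels,
                                   terminal_names=[99])

    def test_uniform_chain_tie_breaks_by_cluster_id(self):
        n = 30
        t = np.full((n, n), 1.0 / n)
        labels = np.repeat(np.arange(3), 10)
        terminal = select_terminal_states(sp.csr_matrix(t), labels,
                                          n_macrostates=3, n_terminal=2)
        assert sorted(terminal) == ["0", "1"]


class TestAbsorption:
    def test_terminal_cell_rows_are_indicators(self):
        t, labels = _block_chain()
        terminal = {"a": np.where(labels == 0)[0], "b": np.where(labels == 1)[0]}
        a = absorption_probabilities(sp.csr_matrix(t), terminal)
        assert np.allclose(a.iloc[terminal["a"]]["a"], 1.0)
        assert np.allclose(a.iloc[terminal["a"]]["b"], 0.0)

    def test_symmetric_1d_chain_splits_half_half(self):
        # 0 and 4 absorbing ends of a symmetric random walk on 5 states
        t = np.zeros((5, 5))
        t[0, 0] = t[4, 4] = 1.0
        for i in (1, 2, 3):
            t[i, i - 1] = t[i, i + 1] = 0.5
        a = absorption_probabilities(
            sp.csr_matrix(t), {"L": np.array([0]), "R": np.array([4])}
        )
        assert a.loc[2, "L"] == pytest.approx(0.5, abs=1e-12)
        assert a.loc[2, "R"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_monte_carlo_on_10_state_chain(self, rng):
        n = 10
        t = _row_norm(rng.random((n, n)) + 0.05)
        term = {"x": np.array([8]), "y": np.array([9])}
        t[8] = 0; t[8, 8] = 1.0
        t[9] = 0; t[9, 9] = 1.0
        a = absorption_probabilities(sp.csr_matrix(t), term)
        # random-walk oracle
        n_walks = 100_000
        cum = np.cumsum(t, axis=1)
        hits = np.zeros((n, 2))
        state = np.repeat(np.arange(n), n_walks // n)
        walkers = state.copy()
        active = np.ones(walkers.size, dtype=bool)
        origin = state.copy()
        for _ in range(500):
            if not active.any():
                break
            u = rng.random(active.sum())
            nxt = (cum[walkers[active]] > u[:, None]).argmax(axis=1)
            walkers[active] = nxt
            done = np.isin(walkers, [8, 9]) & active
            for s_, col in ((8, 0), (9, 1)):
                sel = done & (walkers == s_)
                np.add.at(hits, (origin[sel], col), 1)
            active &= ~done
        est = hits / (n_walks // n)
        assert np.abs(est[:8] - a.iloc[:8][["x", "y"]].to_numpy()).max() <= 0.01

    def test_unreachable_cell_is_reported(self):
        t = np.eye(4)
        t[1, 1] = 0; t[1, 0] = 1.0
        with pytest.raises(ValueError, match="cell index"):
            absorption_probabilities(
                sp.csr_matrix(t), {"a": np.array([0])}
            )

    def test_overlapping_terminal_sets_rejected(self):
        t = _row_norm(np.ones((4, 4)))
        with pytest.raises(ValueError, match="disjoint"):
            absorption_probabilities(
                sp.csr_matrix(t), {"a": np.array([0, 1]), "b": np.array([1])}
            )


class TestRootProbabilities:
    def test_directed_line_peaks_at_source(self):
        # a -> b -> c with high forward probability; the reversed chain's
        # stationary distribution piles onto a
        t = np.array([
            [0.1, 0.9, 0.0],
            [0.0, 0.1, 0.9],
            [0.05, 0.05, 0.9],
        ])
        rp = root_probabilities(sp.csr_matrix(_row_norm(t)), eps=1e-6)
        # explicit eigenvector oracle for the backward chain
        b = _row_norm(t.T)
        w, v = np.linalg.eig(b.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        assert rp.argmax() == pi.argmax()
        assert np.allclose(rp, pi / pi.max(), atol=1e-4)

    def test_symmetric_walk_is_uniform(self):
        n = 8
        t = np.full((n, n), 1.0 / n)
        rp = root_probabilities(sp.csr_matrix(t), eps=1e-8)
        assert np.allclose(rp, 1.0, atol=1e-6)

    def test_range_and_max(self):
        t = _row_norm(np.random.default_rng(0).random((20, 20)))
        rp = root_probabilities(sp.csr_matrix(t), eps=1e-8)
        assert rp.max() == pytest.approx(1.0)
        assert rp.min() >= 0


class TestDifferentiationPotential:
    def test_score_spans_unit_interval_and_ranks_by_gene_count(self):
        rng = np.random.default_rng(5)
        n, m = 40, 300
        counts = np.zeros((n, m), dtype=int)
        # staggered: cell i expresses the first 50 + 6*i genes
        for i in range(n):
            k = 50 + 6 * i
            counts[i, :k] = rng.integers(1, 20, size=k)
        c = CountContainer(
            cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
            gene_ids=np.array([f"g{j}" for j in range(m)], dtype=object),
            layers={"total": sp.csr_matrix(counts)},
            ercc=np.zeros(m, dtype=bool),
        )
        norm = pd.DataFrame(np.log10(counts + 1.0), index=c.cell_ids,
                            columns=c.gene_ids)
        g = build_graph(norm, n_pcs=5, k=4, seed=0)
        dp = differentiation_potential(c, g, n_top=50)
        assert dp.min() == 0.0 and dp.max() == 1.0
        # gene-count order should be preserved overall
        from scipy.stats import spearmanr

        assert spearmanr(dp, np.arange(n)).statistic > 0.9

    def test_progenitors_score_high_on_simulation(self, small_sim, small_norm):
        from scipy.stats import spearmanr

        container, gt = small_sim
        g = build_graph(small_norm, n_pcs=10, k=15, seed=0)
        dp = differentiation_potential(container, g)
        rho = spearmanr(dp, -gt.cells["true_time"]).statistic
        assert rho >= 0.7

    def test_n_top_bound(self, small_sim, small_norm):
        container, _ = small_sim
        g = build_graph(small_norm, n_pcs=5, k=5, seed=0)
        with pytest.raises(ValueError, match="n_top"):
            differentiation_potential(container, g, n_top=10**6)


class TestTipMarkers:
    def test_planted_marker_tops_its_fate(self, small_sim, small_norm,
                                          small_spec):
        container, gt = small_sim
        segs = gt.cells["segment"].to_numpy()
        terminal = {
            "glial": np.where(segs == "glial")[0],
            "chA": np.where(segs == "ChC-A")[0],
        }
        absorption = pd.DataFrame(
            {k: (segs == {"glial": "glial", "chA": "ChC-A"}[k]).astype(float)
             for k in terminal}
        )
        table = tip_markers(small_norm, absorption, terminal, n_tip=15).table
        kin = small_spec.genes.set_index("gene")
        glial_rows = table[table.fate == "glial"]
        top = glial_rows.nsmallest(30, "q")
        top_kinds = kin.loc[[g for g in top.gene if g in kin.index], "kind"]
        assert (top_kinds == "program").sum() + (top_kinds == "module_glial").sum() > 0
        # planted glial program genes are significant for the glial tip
        prog = kin.query("kind == 'program' and segment == 'glial'").index
        sub = glial_rows[glial_rows.gene.isin(prog)]
        assert (sub.q < 0.05).mean() > 0.5

    def test_constant_gene_reports_p_one(self, small_sim, small_norm):
        container, gt = small_sim
        segs = gt.cells["segment"].to_numpy()
        terminal = {"glial": np.where(segs == "glial")[0]}
        absorption = pd.DataFrame({"glial": np.ones(len(segs))})
        norm = small_norm.copy()
        norm["flatgene"] = 3.14
        table = tip_markers(norm, absorption, terminal, n_tip=15).table
        row = table[table.gene == "flatgene"].iloc[0]
        assert row.p == 1.0

    def test_tip_size_respected_and_too_small_rejected(self, small_sim,
                                                       small_norm):
        container, gt = small_sim
        segs = gt.cells["segment"].to_numpy()
        terminal = {"glial": np.where(segs == "glial")[0]}
        absorption = pd.DataFrame({"glial": np.ones(len(segs))})
        table = tip_markers(small_norm, absorption, terminal, n_tip=15).table
        tips = table["tip_cells"].iloc[0].split(",")
        assert len(tips) == 15
        with pytest.raises(ValueError, match="n_tip"):
            tip_markers(small_norm, absorption,
                        {"tiny": np.arange(3)}, n_tip=15)
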