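"""Network matrix assembly, SVD projection, and core extraction."""

import numpy as np
import pytest

import gencore as gc
from gencore.errors import NumericalError, ValidationError
from gencore.pnp import (
    NetworkMatrix,
    assemble_delta,
    eigen_fractions,
    projection_values,
    run_pnp,
    select_M,
    select_core,
)
from gencore.types import Node, RealGEN


def _real(nodes, ppi=(), reg=(), basal=()):
    real = RealGEN({n: Node(n, k) for n, k in nodes})
    for t, p, a in ppi:
        real.add_ppi(t, p, a)
    for r, t, c, a in reg:
        real.add_reg(r, t, c, a)
    for n, b, v in basal:
        real.set_basal(n, b, v)
    return real


class TestAssembleDelta:
    def test_single_ppi_entry(self):
        real = _real(
            [("P1", "protein"), ("P2", "protein")],
            ppi=[("P1", "P2", 0.5)],
            basal=[("P1", "ppin", 1.0), ("P2", "ppin", 1.0)],
        )
        m = assemble_delta(real)
        assert m.values.shape == (2, 1)
        assert m.values[m.row_of("P1", "ppin"), m.col_of("P2", "tf")] == 0.5
        assert np.count_nonzero(m.values) == 1

    def test_mirna_block_entry_negated(self):
        real = _real(
            [("g", "receptor"), ("mi", "miRNA")],
            reg=[("mi", "g", "mirna", 0.3)],
            basal=[("g", "grn", 1.0), ("mi", "mrn", 0.2)],
        )
        m = assemble_delta(real)
        assert m.values[m.row_of("g", "grn"), m.col_of("mi", "mirna")] == -0.3

    def test_pruned_edges_are_exact_zeros(self, small_gt):
        real = gc.true_real_gen(small_gt)
        removed = next(iter(real.reg))
        del real.reg[removed]
        m = assemble_delta(real)
        reg, tgt, cls = removed
        row = next(rb for rb in m.row_index if rb[0] == tgt and rb[1] != "ppin")
        assert m.values[m.row_index.index(row), m.col_of(reg, cls)] == 0.0

    def test_shared_column_for_ppi_partner_and_tf(self):
        """A protein acting as PPI partner and TF regulator gets one column."""
        real = _real(
            [("P1", "protein"), ("P2", "protein"), ("g", "receptor")],
            ppi=[("P1", "P2", 0.4)],
            reg=[("P2", "g", "tf", 0.7)],
            basal=[("P1", "ppin", 1.0), ("g", "grn", 1.0)],
        )
        m = assemble_delta(real)
        assert sum(1 for c, _ in m.col_index if c == "P2") == 1

    def test_regulation_of_unfitted_node_rejected(self):
        real = _real(
            [("g", "receptor"), ("tf", "TF")],
            reg=[("tf", "g", "tf", 0.5)],
            basal=[],
        )
        with pytest.raises(ValidationError):
            assemble_delta(real)

    def test_miRNA_column_entries_nonpositive(self, small_gt):
        m = assemble_delta(gc.true_real_gen(small_gt))
        for j, (_, cls) in enumerate(m.col_index):
            if cls == "mirna":
                assert np.all(m.values[:, j] <= 0)


def _matrix(values):
    values = np.asarray(values, float)
    rows = [(f"n{i}", "grn") for i in range(values.shape[0])]
    cols = [(f"c{j}", "tf") for j in range(values.shape[1])]
    return NetworkMatrix(values, rows, cols)


class TestEigenFractions:
    def test_known_spectrum(self):
        _, s, _, frac = eigen_fractions(_matrix(np.diag([4.0, 3.0])))
        np.testing.assert_allclose(s, [4.0, 3.0])
        np.testing.assert_allclose(frac, [0.64, 0.36])

    def test_identity_splits_evenly(self):
        _, _, _, frac = eigen_fractions(_matrix(np.eye(2)))
        np.testing.assert_allclose(frac, [0.5, 0.5])

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        _, _, _, frac = eigen_fractions(_matrix(rng.normal(size=(8, 5))))
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(NumericalError):
            eigen_fractions(_matrix(np.zeros((3, 2))))

    def test_reconstruction(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.normal(size=(6, 4)))
        pi, s, psit, _ = eigen_fractions(m)
        sigma = np.zeros((6, 4))
        np.fill_diagonal(sigma, s)
        rebuilt = pi @ sigma @ psit
        rel = np.linalg.norm(rebuilt - m.values) / np.linalg.norm(m.values)
        assert rel < 1e-9

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(size=(5, 5)))
        _, _, psit_a, _ = eigen_fractions(m)
        _, _, psit_b, _ = eigen_fractions(m)
        np.testing.assert_array_equal(psit_a, psit_b)
        for row in psit_a:
            nz = row[np.abs(row) > 1e-12]
            assert nz[0] > 0


class TestSelectM:
    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [([0.64, 0.36], 0.85, 2), ([0.9, 0.1], 0.85, 1), ([0.5, 0.5], 0.5, 1)],
    )
    def test_minimum_cumulative_rule(self, fractions, threshold, expected):
        assert select_M(np.array(fractions), threshold) == expected

    def test_threshold_one_takes_all_nonzero(self):
        assert select_M(np.array([0.6, 0.4, 0.0]), 1.0) == 2

    @pytest.mark.parametrize("threshold", [0.0, -0.1, 1.5])
    def test_invalid_threshold_rejected(self, threshold):
        with pytest.raises(ValidationError):
            select_M(np.array([1.0]), threshold)


class TestProjectionValues:
    def test_identity_orthonormal_projection(self):
        m = _matrix(np.eye(2))
        _, _, psit, _ = eigen_fractions(m)
        _, d = projection_values(m, psit, 2)
        np.testing.assert_allclose(d, [1.0, 1.0])

    def test_full_projection_equals_row_norm(self):
        m = _matrix([[3.0, 4.0], [1.0, 0.0]])
        _, _, psit, _ = eigen_fractions(m)
        _, d = projection_values(m, psit, 2)
        np.testing.assert_allclose(d, [5.0, 1.0], atol=1e-12)

    def test_zero_components_give_zero(self):
        m = _matrix([[1.0, 2.0]])
        _, _, psit, _ = eigen_fractions(m)
        _, d = projection_values(m, psit, 0)
        np.testing.assert_array_equal(d, [0.0])

    def test_full_rank_d_equals_row_norms_random(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(size=(10, 6)))
        _, _, psit, _ = eigen_fractions(m)
        _, d = projection_values(m, psit, 6)
        np.testing.assert_allclose(
            d, np.linalg.norm(m.values, axis=1), atol=1e-9
        )

    def test_d_invariant_to_column_permutation(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(7, 5))
        m1 = _matrix(vals)
        perm = rng.permutation(5)
        m2 = NetworkMatrix(vals[:, perm], m1.row_index,
                           [m1.col_index[j] for j in perm])
        for m in (m1, m2):
            _, _, psit, frac = eigen_fractions(m)
            m.d = projection_values(m, psit, select_M(frac))[1]
        np.testing.assert_allclose(m1.d, m2.d, atol=1e-9)


class TestCore:
    def test_run_pnp_deterministic_and_positive(self, small_gt):
        real = gc.true_real_gen(small_gt)
        a, b = run_pnp(real), run_pnp(real)
        assert a.ranking == b.ranking
        assert all(v >= 0 for v in a.D.values())
        assert a.eigen_fractions[: a.M].sum() >= 0.85 - 1e-9

    def test_top_k_selection(self, small_gt):
        real = gc.true_real_gen(small_gt)
        res = run_pnp(real)
        core = select_core(real, res, k=3)
        expected = sorted(res.D, key=lambda n: (-res.D[n], n))[:3]
        assert core.core_nodes == expected

    def test_k_capped_at_node_count(self, small_gt):
        real = gc.true_real_gen(small_gt)
        res = run_pnp(real)
        core = select_core(real, res, k=10_000)
        assert len(core.core_nodes) == len(res.ranking)

    def test_tie_broken_lexicographically(self):
        real = _real(
            [("b", "receptor"), ("a", "receptor"), ("tf", "TF")],
            reg=[("tf", "a", "tf", 0.5), ("tf", "b", "tf", 0.5)],
            basal=[("a", "grn", 1.0), ("b", "grn", 1.0)],
        )
        res = run_pnp(real, threshold=1.0)
        assert res.D["a"] == pytest.approx(res.D["b"])
        core = select_core(real, res, k=1)
        assert core.core_nodes == ["a"]

    def test_invalid_k_rejected(self, small_gt):
        real = gc.true_real_gen(small_gt)
        res = run_pnp(real)
        with pytest.raises(ValidationError):
            select_core(real, res, k=0)

    def test_core_network_is_induced_subgraph(self, small_gt):
        real = gc.true_real_gen(small_gt)
        res = run_pnp(real)
        core = select_core(real, res, k=5)
        keep = set(core.core_nodes)
        assert set(core.network.nodes) == keep
        for (t, p) in core.network.ppi:
            assert t in keep and p in keep
        for (r, t, _) in core.network.reg:
            assert r in keep and t in keep
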