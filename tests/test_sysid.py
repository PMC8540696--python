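"""Regression construction and constrained least-squares estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gencore as gc
from _oracles import constrained_lsq_oracle
from gencore.errors import NumericalError, ValidationError
from gencore.types import CandidateGEN, ExpressionMatrix, Node, RegressionProblem


@pytest.fixture
def tiny_world():
    nodes = [
        Node("P1", "protein"), Node("P2", "protein"), Node("P3", "protein"),
        Node("TF1", "TF"), Node("LNC1", "lncRNA"), Node("MIR1", "miRNA"),
        Node("G1", "receptor"),
    ]
    gen = CandidateGEN(
        nodes,
        ppi_edges=[("P1", "P2"), ("P1", "P3")],
        reg_edges=[("TF1", "G1"), ("LNC1", "G1"), ("MIR1", "G1"),
                   ("TF1", "LNC1"), ("MIR1", "MIR1")],
    )
    rng = np.random.default_rng(0)
    ids = [n.node_id for n in nodes]
    expr = ExpressionMatrix(ids, [f"s{k}" for k in range(5)],
                            rng.lognormal(0, 0.5, (len(ids), 5)))
    return gen, expr


class TestBuildProtein:
    def test_shape_two_partners(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_protein_regression("P1", gen, expr, expr.sample_ids)
        assert prob.regressors.shape == (5, 3)
        assert prob.column_meta == [("P2", "tf"), ("P3", "tf")]
        assert prob.sign_constraints == ["free", "free"]

    def test_product_column_is_elementwise_product(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_protein_regression(
            "P1", gen, expr, expr.sample_ids, ppi_term="product"
        )
        np.testing.assert_allclose(
            prob.regressors[:, 0], expr.row("P1") * expr.row("P2")
        )

    def test_linear_column_is_partner_expression(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_protein_regression("P1", gen, expr, expr.sample_ids)
        np.testing.assert_allclose(prob.regressors[:, 0], expr.row("P2"))

    def test_zero_partners_gives_intercept_only(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_protein_regression("P2", gen, expr, expr.sample_ids)
        # P2's only candidate partner is P1
        assert prob.column_meta == [("P1", "tf")]
        prob3 = gc.build_protein_regression("TF1", gen, expr, expr.sample_ids)
        assert prob3.regressors.shape == (5, 1)
        np.testing.assert_array_equal(prob3.regressors[:, 0], 1.0)

    def test_non_protein_target_rejected(self, tiny_world):
        gen, expr = tiny_world
        with pytest.raises(ValidationError):
            gc.build_protein_regression("MIR1", gen, expr, expr.sample_ids)


class TestBuildGene:
    def test_blocks_and_constraints(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_gene_regression("G1", gen, expr, expr.sample_ids)
        assert prob.regressors.shape == (5, 4)
        assert prob.column_meta == [
            ("TF1", "tf"), ("LNC1", "lncrna"), ("MIR1", "mirna")
        ]
        assert prob.sign_constraints == ["free", "free", "nonpositive"]

    def test_mirna_column_is_raw_expression(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_gene_regression("G1", gen, expr, expr.sample_ids)
        np.testing.assert_allclose(prob.regressors[:, 2], expr.row("MIR1"))

    def test_no_regulators_intercept_only(self, tiny_world):
        gen, expr = tiny_world
        prob = gc.build_gene_regression("P3", gen, expr, expr.sample_ids)
        assert prob.regressors.shape == (5, 1)

    def test_lncrna_and_mirna_targets(self, tiny_world):
        gen, expr = tiny_world
        lnc = gc.build_lncrna_regression("LNC1", gen, expr, expr.sample_ids)
        assert lnc.block == "lrn" and lnc.regressors.shape == (5, 2)
        mir = gc.build_mirna_regression("MIR1", gen, expr, expr.sample_ids)
        assert mir.block == "mrn"
        # miRNA self-regulation column carries the nonpositive constraint
        assert mir.sign_constraints == ["nonpositive"]
        with pytest.raises(ValidationError):
            gc.build_lncrna_regression("P1", gen, expr, expr.sample_ids)


def _problem(phi, p, constraints):
    phi = np.asarray(phi, float)
    meta = [(f"r{k}", "mirna" if c == "nonpositive" else "tf")
            for k, c in enumerate(constraints)]
    return RegressionProblem(
        target="g", block="grn", response=np.asarray(p, float),
        regressors=np.column_stack([phi, np.ones(len(p))]),
        column_meta=meta, sign_constraints=list(constraints),
    )


class TestSolve:
    def test_exact_interpolation(self):
        fit = gc.solve_constrained_lsq(_problem([[1.0], [2.0]], [2.0, 4.0], ["free"]))
        assert fit.theta[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.basal == pytest.approx(0.0, abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_active_constraint_clips_to_boundary(self):
        # unconstrained optimum has positive slope; constrained optimum is the
        # boundary (coef 0, basal = mean), confirmed by the active-set oracle
        fit = gc.solve_constrained_lsq(
            _problem([[1.0], [2.0]], [1.0, 2.0], ["nonpositive"])
        )
        assert fit.theta[0] == 0.0
        assert fit.basal == pytest.approx(1.5)
        assert fit.sse == pytest.approx(0.5)
        theta_o, sse_o = constrained_lsq_oracle(
            np.array([[1.0, 1.0], [2.0, 1.0]]), np.array([1.0, 2.0]), [True, False]
        )
        assert fit.sse == pytest.approx(sse_o)

    def test_intercept_only_closed_form(self):
        p = np.array([1.0, 2.0, 6.0])
        prob = RegressionProblem("g", "grn", p, np.ones((3, 1)), [], [])
        fit = gc.solve_constrained_lsq(prob)
        assert fit.basal == pytest.approx(p.mean())
        assert fit.sse == pytest.approx(np.sum((p - p.mean()) ** 2))

    def test_nonfinite_rejected(self):
        with pytest.raises(NumericalError):
            gc.solve_constrained_lsq(
                _problem([[np.inf], [1.0]], [1.0, 2.0], ["free"])
            )

    def test_rank_deficiency_warned_not_fatal(self, caplog):
        phi = [[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]
        with caplog.at_level("WARNING"):
            fit = gc.solve_constrained_lsq(
                _problem(phi, [1.0, 2.0, 3.0], ["free", "free"])
            )
        assert fit.rank_deficient
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_mirna_ability_reported_nonnegative(self):
        rng = np.random.default_rng(4)
        r = rng.lognormal(0, 0.5, 40)
        p = 1.0 - 0.6 * r + rng.normal(0, 0.01, 40)
        fit = gc.solve_constrained_lsq(_problem(r[:, None], p, ["nonpositive"]))
        assert fit.theta[0] <= 1e-10
        assert fit.ability(0) == pytest.approx(0.6, abs=0.05)


@st.composite
def random_problems(draw):
    n = draw(st.integers(8, 25))
    k = draw(st.integers(1, 5))
    seed = draw(st.integers(0, 2**20))
    rng = np.random.default_rng(seed)
    phi = rng.normal(0, 1, (n, k))
    p = rng.normal(0, 1, n)
    constraints = [draw(st.sampled_from(["free", "nonpositive"])) for _ in range(k)]
    return _problem(phi, p, constraints)


@given(random_problems())
def test_solver_matches_active_set_oracle(prob):
    """The bounded solver attains the global constrained optimum."""
    fit = gc.solve_constrained_lsq(prob)
    nonpos = [c == "nonpositive" for c in prob.sign_constraints] + [False]
    _, sse_oracle = constrained_lsq_oracle(prob.regressors, prob.response, nonpos)
    assert fit.sse == pytest.approx(sse_oracle, abs=1e-8)
    for j, c in enumerate(prob.sign_constraints):
        if c == "nonpositive":
            assert fit.theta[j] <= 1e-10


@given(random_problems())
def test_residual_orthogonality_and_constraint_cost(prob):
    """Normal equations hold when no constraint binds; constraints cost sse."""
    fit = gc.solve_constrained_lsq(prob)
    free_prob = RegressionProblem(
        prob.target, prob.block, prob.response, prob.regressors,
        prob.column_meta, ["free"] * len(prob.sign_constraints),
    )
    free_fit = gc.solve_constrained_lsq(free_prob)
    resid = free_prob.response - free_prob.regressors @ np.append(
        free_fit.theta, free_fit.basal
    )
    np.testing.assert_allclose(free_prob.regressors.T @ resid, 0, atol=1e-8)
    assert fit.sse >= free_fit.sse - 1e-10


def test_parameter_recovery_noiseless(small_config):
    """Forward/inverse consistency: noiseless simulation, exact recovery."""
    import dataclasses

    cfg = dataclasses.replace(small_config, noise_sd=0.0, decoy_rate=0.0)
    gt = gc.generate_ground_truth(cfg)
    expr = gc.simulate_expression(gt, cfg, "early")
    cand = gc.corrupt_candidate(gt, 0.0, seed=0)
    problems = gc.sysid.build_all_problems(cand, expr, expr.sample_ids)
    fits = gc.sysid.fit_all(problems)
    for (t, p), a in gt.ppi_edges.items():
        fit = fits[(t, "ppin")]
        k = [m for m, _ in fit.column_meta].index(p)
        assert fit.theta[k] == pytest.approx(a, abs=1e-6)
    for (r, t, c), a in gt.reg_edges.items():
        fit = fits[(t, gt.target_block[t])]
        k = fit.column_meta.index((r, c))
        assert fit.ability(k) == pytest.approx(a, abs=1e-6)
        assert fits[(t, gt.target_block[t])].basal == pytest.approx(
            gt.basal[t], abs=1e-6
        )
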