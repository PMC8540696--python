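"""System identification: per-node regressions and constrained least squares.

Each node of the candidate GEN defines a static cross-sample regression:

* PPIN model (protein-like target i): the response p_i is explained by
  interaction terms over candidate partners m != i plus a basal level.  The
  default ``linear`` regressor for partner m is the partner expression p_m
  (the form the estimation is actually set up on); the ``product`` variant
  uses the per-sample product p_i * p_m.  The product form is available for
  completeness but cannot prune false-positive interactions: the response
  appears inside every product column, so a spurious partner column always
  explains p_i and survives AIC selection.
* GRN model (gene target j): additive TF/protein terms b_js * p_s, lncRNA
  terms c_jt * x_t, repressive miRNA terms -d_ju * r_u, plus basal level.
  miRNA columns carry raw miRNA expression and a nonpositive coefficient
  constraint, so the reported repression ability d = -coefficient is >= 0.
* lncRNA and miRNA targets use the same additive form with their own
  regulator classes (TF/protein and miRNA).

All problems carry a trailing all-ones intercept column whose coefficient is
the basal level; it is never constrained.  Estimation minimizes
||Phi @ theta - P||^2 subject to the per-column sign constraints.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import lsq_linear

from .errors import NumericalError, ValidationError
from .types import (
    PROTEIN_LIKE,
    CandidateGEN,
    ExpressionMatrix,
    NodeModelFit,
    RegressionProblem,
)

logger = logging.getLogger(__name__)


def _with_intercept(columns: list[np.ndarray], n: int) -> np.ndarray:
    return np.column_stack(columns + [np.ones(n)]) if columns else np.ones((n, 1))


def build_protein_regression(
    i: str,
    gen: CandidateGEN,
    expr: ExpressionMatrix,
    samples: list[str],
    ppi_term: str = "linear",
) -> RegressionProblem:
    """PPIN regression for protein-like node ``i`` over its candidate partners."""
    if gen.kind(i) not in PROTEIN_LIKE:
        raise ValidationError(f"{i!r} is not protein-like; no PPIN model applies")
    if ppi_term not in ("product", "linear"):
        raise ValidationError(f"unknown ppi_term {ppi_term!r}")
    p_i = expr.row(i, samples)
    partners = gen.ppi_partners(i)
    cols = []
    for m in partners:
        p_m = expr.row(m, samples)
        cols.append(p_i * p_m if ppi_term == "product" else p_m)
    return RegressionProblem(
        target=i,
        block="ppin",
        response=p_i,
        regressors=_with_intercept(cols, len(p_i)),
        column_meta=[(m, "tf") for m in partners],
        sign_constraints=["free"] * len(partners),
    )


def _block_for_target(kind: str) -> str:
    if kind in PROTEIN_LIKE:
        return "grn"
    if kind == "lncRNA":
        return "lrn"
    if kind == "miRNA":
        return "mrn"
    raise ValidationError(f"unknown node kind {kind!r}")


def build_gene_regression(
    j: str, gen: CandidateGEN, expr: ExpressionMatrix, samples: list[str]
) -> RegressionProblem:
    """Regulatory regression for target ``j``: TF/protein, lncRNA, miRNA blocks.

    Columns are ordered by class block then regulator id.  miRNA columns hold
    the miRNA's raw expression; repression enters through the nonpositive
    coefficient constraint.
    """
    response = expr.row(j, samples)
    meta = gen.regulators(j)
    cols = [expr.row(r, samples) for r, _ in meta]
    return RegressionProblem(
        target=j,
        block=_block_for_target(gen.kind(j)),
        response=response,
        regressors=_with_intercept(cols, len(response)),
        column_meta=meta,
        sign_constraints=["nonpositive" if c == "mirna" else "free" for _, c in meta],
    )


def build_lncrna_regression(
    k: str, gen: CandidateGEN, expr: ExpressionMatrix, samples: list[str]
) -> RegressionProblem:
    if gen.kind(k) != "lncRNA":
        raise ValidationError(f"{k!r} is not an lncRNA")
    return build_gene_regression(k, gen, expr, samples)


def build_mirna_regression(
    l: str, gen: CandidateGEN, expr: ExpressionMatrix, samples: list[str]
) -> RegressionProblem:
    if gen.kind(l) != "miRNA":
        raise ValidationError(f"{l!r} is not a miRNA")
    return build_gene_regression(l, gen, expr, samples)


def solve_constrained_lsq(problem: RegressionProblem) -> NodeModelFit:
    """Minimize ||Phi theta - P||_2^2 subject to per-column sign constraints.

    Unconstrained problems go through the minimum-norm least-squares solver;
    constrained ones through a bounded-variable solver.  Rank deficiency is
    tolerated with a logged warning (minimum-norm behaviour), never silently
    regularized.
    """
    phi, p = problem.regressors, problem.response
    if not (np.isfinite(phi).all() and np.isfinite(p).all()):
        raise NumericalError(f"non-finite values in regression for {problem.target!r}")
    if problem.n_samples < 1:
        raise ValidationError("at least one sample is required")

    nonpos = np.array(
        [c == "nonpositive" for c in problem.sign_constraints] + [False]
    )
    rank = int(np.linalg.matrix_rank(phi)) if phi.size else 0
    deficient = rank < phi.shape[1]
    if deficient:
        logger.warning(
            "rank-deficient regression for %s (%s): rank %d < %d columns; "
            "minimum-norm solution used",
            problem.target, problem.block, rank, phi.shape[1],
        )

    if not nonpos.any():
        theta, *_ = np.linalg.lstsq(phi, p, rcond=None)
    else:
        ub = np.where(nonpos, 0.0, np.inf)
        lb = np.full(phi.shape[1], -np.inf)
        method = "bvls" if (not deficient and phi.shape[0] >= phi.shape[1]) else "trf"
        res = lsq_linear(phi, p, bounds=(lb, ub), method=method, tol=1e-14)
        theta = res.x
        # bounded solvers may stop a hair inside the boundary
        theta = np.where(nonpos & (theta > -1e-12), 0.0, theta)

    resid = p - phi @ theta
    sse = float(resid @ resid)
    return NodeModelFit(
        target=problem.target,
        block=problem.block,
        theta=np.asarray(theta[:-1], dtype=float),
        basal=float(theta[-1]),
        sse=sse,
        n=problem.n_samples,
        column_meta=list(problem.column_meta),
        rank_deficient=deficient,
    )


def build_all_problems(
    gen: CandidateGEN,
    expr: ExpressionMatrix,
    samples: list[str],
    ppi_term: str = "linear",
) -> dict[tuple[str, str], RegressionProblem]:
    """All per-node regression problems of one group, keyed by (node, block).

    Every protein-like node gets a PPIN problem (intercept-only when it has
    no candidate partners) and, when it has incoming regulations, a separate
    GRN problem; every lncRNA/miRNA node gets its regulatory problem.  The
    PPIN and regulatory fits of the same node stay separate and meet only in
    the network matrix.
    """
    problems: dict[tuple[str, str], RegressionProblem] = {}
    for nid in gen.node_ids():
        kind = gen.kind(nid)
        if kind in PROTEIN_LIKE:
            problems[(nid, "ppin")] = build_protein_regression(
                nid, gen, expr, samples, ppi_term
            )
            if gen.regulators(nid):
                problems[(nid, "grn")] = build_gene_regression(nid, gen, expr, samples)
        elif kind == "lncRNA":
            problems[(nid, "lrn")] = build_lncrna_regression(nid, gen, expr, samples)
        elif kind == "miRNA":
            problems[(nid, "mrn")] = build_mirna_regression(nid, gen, expr, samples)
    return problems


def fit_all(
    problems: dict[tuple[str, str], RegressionProblem]
) -> dict[tuple[str, str], NodeModelFit]:
    return {key: solve_constrained_lsq(p) for key, p in problems.items()}
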