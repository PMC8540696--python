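"""AIC-based system order detection and false-positive edge pruning.

The candidate network over-specifies each node model; the real system order
is the regressor count minimizing the Akaike information criterion

    AIC(k) = log(SSE / N) + 2 (k + 1) / N

(natural log; the +1 counts the basal-level intercept).  Candidate subsets
are searched over magnitude-ranked nested prefixes of the full fit, each
prefix refitted under the sign constraints; the AIC depends on a subset only
through its size and residual, so a single ranking serves all regulator
classes jointly.  An exhaustive mode enumerating every subset is available
for small problems and serves as the verification oracle for the nested
heuristic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .errors import ValidationError
from .sysid import solve_constrained_lsq
from .types import AICTrace, CandidateGEN, NodeModelFit, RealGEN, RegressionProblem

#: SSE floor keeping AIC finite on exact (noiseless) fits
_SSE_FLOOR = 1e-300

#: exhaustive search is exponential; refuse beyond this many regressors
MAX_EXHAUSTIVE = 12


def aic(sse: float, n: int, k: int) -> float:
    """Akaike information criterion for a k-regressor fit on n samples."""
    if n < 1:
        raise ValidationError("AIC requires at least one sample")
    if sse < 0:
        raise ValidationError("sse must be >= 0")
    return float(np.log(max(sse, _SSE_FLOOR) / n) + 2.0 * (k + 1) / n)


def _magnitude_ranking(full_fit: NodeModelFit) -> list[int]:
    """Column indices sorted by |theta| descending, ties by column order."""
    mags = np.abs(full_fit.theta)
    return sorted(range(len(mags)), key=lambda c: (-mags[c], c))


def detect_order(
    problem: RegressionProblem,
    full_fit: NodeModelFit | None = None,
    mode: str = "nested",
) -> AICTrace:
    """Select the AIC-minimizing regressor subset for one node model.

    ``nested`` refits the nested prefixes {}, {top-1}, {top-1,2}, ... of the
    magnitude ranking from the full fit (linear number of refits);
    ``exhaustive`` enumerates every subset (<= MAX_EXHAUSTIVE regressors).
    Ties are broken toward the smaller order.
    """
    if mode not in ("nested", "exhaustive"):
        raise ValidationError(f"unknown search mode {mode!r}")
    if full_fit is None:
        full_fit = solve_constrained_lsq(problem)
    k_max = problem.n_regressors

    if mode == "exhaustive":
        if k_max > MAX_EXHAUSTIVE:
            raise ValidationError(
                f"exhaustive search limited to {MAX_EXHAUSTIVE} regressors, got {k_max}"
            )
        best_by_size: list[tuple[float, tuple[int, ...], NodeModelFit]] = []
        for k in range(k_max + 1):
            best = None
            for subset in combinations(range(k_max), k):
                fit = solve_constrained_lsq(problem.subproblem(list(subset)))
                value = aic(fit.sse, fit.n, k)
                if best is None or value < best[0] - 1e-15:
                    best = (value, subset, fit)
            best_by_size.append(best)
        aic_values = [b[0] for b in best_by_size]
        sel = int(np.argmin(aic_values))  # first minimum = smallest order
        _, subset, fit = best_by_size[sel]
        meta = [problem.column_meta[c] for c in subset]
    else:
        ranking = _magnitude_ranking(full_fit)
        aic_values = []
        fits: list[tuple[NodeModelFit, list[int]]] = []
        for k in range(k_max + 1):
            cols = sorted(ranking[:k])  # keep original class-block column order
            fit = (
                solve_constrained_lsq(problem.subproblem(cols))
                if k < k_max
                else full_fit
            )
            aic_values.append(aic(fit.sse, fit.n, k))
            fits.append((fit, cols))
        sel = int(np.argmin(aic_values))
        fit, cols = fits[sel]
        meta = [problem.column_meta[c] for c in cols]

    fit.aic = aic_values[sel]
    return AICTrace(
        target=problem.target,
        block=problem.block,
        orders=list(range(k_max + 1)),
        aic_values=aic_values,
        selected_order=sel,
        selected_edges=meta,
        selected_fit=fit,
    )


def detect_all(
    problems: dict[tuple[str, str], RegressionProblem],
    fits: dict[tuple[str, str], NodeModelFit] | None = None,
    mode: str = "nested",
) -> dict[tuple[str, str], AICTrace]:
    fits = fits or {}
    return {
        key: detect_order(p, fits.get(key), mode=mode) for key, p in problems.items()
    }


def prune_network(
    gen: CandidateGEN, traces: dict[tuple[str, str], AICTrace]
) -> RealGEN:
    """Assemble the real GEN from per-node AIC selections.

    Keeps exactly the union of selected edges with their selected-order refit
    abilities; basal levels come from the selected-order fits.  Pruning is
    per target: a PPI pair may survive on one endpoint's row only.
    """
    modeled = _modeled_keys(gen)
    missing = [key for key in modeled if key not in traces]
    if missing:
        raise ValidationError(f"missing AIC traces for modeled nodes: {missing}")

    real = RealGEN(gen.nodes)
    for (node, block), trace in traces.items():
        fit = trace.selected_fit
        real.set_basal(node, block, fit.basal)
        for k, (reg, cls) in enumerate(fit.column_meta):
            if block == "ppin":
                real.add_ppi(node, reg, float(fit.theta[k]))
            else:
                real.add_reg(reg, node, cls, fit.ability(k))
    return real


def _modeled_keys(gen: CandidateGEN) -> list[tuple[str, str]]:
    from .types import PROTEIN_LIKE

    keys = []
    for nid in gen.node_ids():
        kind = gen.kind(nid)
        if kind in PROTEIN_LIKE:
            keys.append((nid, "ppin"))
            if gen.regulators(nid):
                keys.append((nid, "grn"))
        elif kind == "lncRNA":
            keys.append((nid, "lrn"))
        elif kind == "miRNA":
            keys.append((nid, "mrn"))
    return keys


def export_traces(traces: dict[tuple[str, str], AICTrace], path) -> None:
    """Per-node AIC audit trail as TSV."""
    import pandas as pd

    rows = []
    for (node, block), tr in sorted(traces.items()):
        for order, value in zip(tr.orders, tr.aic_values):
            rows.append(
                {
                    "node_id": node,
                    "block": block,
                    "order": order,
                    "aic": value,
                    "selected": order == tr.selected_order,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
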