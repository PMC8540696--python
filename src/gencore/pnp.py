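"""Principal network projection (PNP): core-network extraction by SVD.

The identified abilities of a real GEN are arranged into a network matrix
Delta whose rows are the fitted node models (PPIN rows, then gene rows, then
lncRNA rows, then miRNA rows) and whose columns are the regulators (one
shared partition: TF/protein columns, lncRNA columns, miRNA columns).
Entries absent from the pruned network are exactly zero; miRNA-class entries
are stored negated (-d) so repression keeps its sign.  Basal levels do not
enter the matrix.

From the SVD Delta = Pi Sigma Psi^T, the eigen-expression fraction of the
m-th singular value is E_m = sigma_m^2 / sum sigma^2; the smallest M with
cumulative fraction >= 0.85 (default) defines the principal subspace.  Each
row's projection value is the 2-norm of its inner products with the top M
right singular vectors; nodes are ranked by projection value and the top k
(default 2000) induce the core GEN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ValidationError
from .types import MODEL_BLOCKS, REG_CLASSES, RealGEN

_BLOCK_POS = {b: k for k, b in enumerate(MODEL_BLOCKS)}
_CLS_POS = {c: k for k, c in enumerate(REG_CLASSES)}


@dataclass
class NetworkMatrix:
    """The ability matrix Delta with its row/column index maps."""

    values: np.ndarray
    row_index: list[tuple[str, str]]  # (node_id, model block)
    col_index: list[tuple[str, str]]  # (regulator_id, class block)

    def row_of(self, node: str, block: str) -> int:
        return self.row_index.index((node, block))

    def col_of(self, regulator: str, cls: str) -> int:
        return self.col_index.index((regulator, cls))


@dataclass
class PNPResult:
    singular_values: np.ndarray
    eigen_fractions: np.ndarray
    M: int
    B: np.ndarray  # rows x M projections onto the principal subspace
    D_rows: np.ndarray  # per-row projection values
    D: dict[str, float]  # per-node projection values (rows of a node combined)
    ranking: list[str]  # node ids by D descending, ties lexicographic
    matrix: NetworkMatrix
    threshold: float


@dataclass
class CoreGEN:
    core_nodes: list[str]
    D: dict[str, float]
    rank: dict[str, int]
    network: RealGEN  # induced subnetwork of the real GEN
    k: int


def assemble_delta(real_gen: RealGEN) -> NetworkMatrix:
    """Build Delta from a pruned real GEN.

    One row per fitted node model (every (node, block) with a recorded basal
    level, so order-0 models contribute all-zero rows); one column per
    regulator appearing in the surviving edges.  A protein that is both a
    PPI partner and a TF-class regulator occupies a single column.
    """
    rows = sorted(real_gen.basal, key=lambda nb: (_BLOCK_POS[nb[1]], nb[0]))
    if not rows:
        raise ValidationError("real GEN has no fitted node models")

    cols: set[tuple[str, str]] = set()
    for (_t, partner) in real_gen.ppi:
        cols.add((partner, "tf"))
    for (reg, _t, cls) in real_gen.reg:
        cols.add((reg, cls))
    col_index = sorted(cols, key=lambda rc: (_CLS_POS[rc[1]], rc[0]))

    row_pos = {rb: k for k, rb in enumerate(rows)}
    col_pos = {rc: k for k, rc in enumerate(col_index)}
    # regulatory rows: the target's non-PPIN model row
    target_row: dict[str, tuple[str, str]] = {
        node: (node, block) for (node, block) in rows if block != "ppin"
    }

    delta = np.zeros((len(rows), max(len(col_index), 1)))
    if not col_index:
        return NetworkMatrix(delta, rows, col_index)

    for (t, partner), a in real_gen.ppi.items():
        if (t, "ppin") not in row_pos:
            raise ValidationError(f"PPI ability for unfitted node {t!r}")
        delta[row_pos[(t, "ppin")], col_pos[(partner, "tf")]] = a
    for (reg, t, cls), ability in real_gen.reg.items():
        if t not in target_row:
            raise ValidationError(f"regulation targets unfitted node {t!r}")
        value = -ability if cls == "mirna" else ability
        delta[row_pos[target_row[t]], col_pos[(reg, cls)]] = value
    return NetworkMatrix(delta, rows, col_index)


def eigen_fractions(matrix: NetworkMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Full SVD of Delta and the eigen-expression fractions E_m.

    Returns (Pi, sigma, Psi^T, E).  Right singular vectors follow a
    deterministic sign convention: first nonzero component positive.
    """
    delta = matrix.values
    if delta.size == 0 or not np.any(delta):
        raise NumericalError("all-zero network matrix: eigen fractions undefined")
    pi, s, psit = np.linalg.svd(delta, full_matrices=True)
    for m in range(psit.shape[0]):
        nz = np.nonzero(np.abs(psit[m]) > 1e-12)[0]
        if nz.size and psit[m, nz[0]] < 0:
            psit[m] = -psit[m]
            if m < pi.shape[1]:
                pi[:, m] = -pi[:, m]
    fractions = s**2 / np.sum(s**2)
    return pi, s, psit, fractions


def select_M(fractions: np.ndarray, threshold: float = 0.85) -> int:
    """Smallest M whose cumulative eigen-expression fraction reaches threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    cum = np.cumsum(fractions)
    hit = np.nonzero(cum >= threshold - 1e-9)[0]
    if hit.size == 0:
        raise NumericalError("cumulative eigen fractions never reach the threshold")
    return int(hit[0]) + 1


def projection_values(
    matrix: NetworkMatrix, psit: np.ndarray, M: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row projections B onto the top-M right singular vectors and their 2-norms."""
    if M < 0 or M > psit.shape[0]:
        raise ValidationError(f"M={M} outside [0, {psit.shape[0]}]")
    b = matrix.values @ psit[:M].T if M else np.zeros((matrix.values.shape[0], 0))
    d = np.sqrt(np.sum(b**2, axis=1))
    return b, d


def run_pnp(real_gen: RealGEN, threshold: float = 0.85) -> PNPResult:
    """Assemble Delta, decompose, and rank nodes by projection value.

    A node fitted in two blocks (PPIN and gene model) owns two rows; its
    projection value combines them as the root-sum-square over its rows.
    """
    matrix = assemble_delta(real_gen)
    _, s, psit, fractions = eigen_fractions(matrix)
    m_sel = select_M(fractions, threshold)
    b, d_rows = projection_values(matrix, psit, m_sel)

    d_nodes: dict[str, float] = {}
    for (node, _block), d in zip(matrix.row_index, d_rows**2):
        d_nodes[node] = d_nodes.get(node, 0.0) + float(d)
    d_nodes = {node: float(np.sqrt(v)) for node, v in d_nodes.items()}
    ranking = sorted(d_nodes, key=lambda n: (-d_nodes[n], n))

    return PNPResult(
        singular_values=s,
        eigen_fractions=fractions,
        M=m_sel,
        B=b,
        D_rows=d_rows,
        D=d_nodes,
        ranking=ranking,
        matrix=matrix,
        threshold=threshold,
    )


def select_core(real_gen: RealGEN, result: PNPResult, k: int = 2000) -> CoreGEN:
    """Top-k nodes by projection value and the induced core subnetwork.

    Ties at the cut are broken toward the lexicographically smaller node id;
    k is capped at the number of ranked nodes.
    """
    if k <= 0:
        raise ValidationError(f"core size k must be positive, got {k}")
    k_eff = min(k, len(result.ranking))
    core = result.ranking[:k_eff]
    rank = {node: r + 1 for r, node in enumerate(result.ranking)}
    network = real_gen.induced(set(core))
    return CoreGEN(
        core_nodes=core,
        D={n: result.D[n] for n in core},
        rank={n: rank[n] for n in core},
        network=network,
        k=k_eff,
    )


def export_projection(result: PNPResult, real_gen: RealGEN, core: CoreGEN, path) -> None:
    """Node-level PNP table: node_id, kind, D, rank, in_core."""
    import pandas as pd

    core_set = set(core.core_nodes)
    rows = [
        {
            "node_id": node,
            "kind": real_gen.nodes[node].kind,
            "D": result.D[node],
            "rank": r + 1,
            "in_core": node in core_set,
        }
        for r, node in enumerate(result.ranking)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_spectrum(result: PNPResult, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "m": np.arange(1, len(result.singular_values) + 1),
            "sigma": result.singular_values,
            "eigen_fraction": result.eigen_fractions,
            "cumulative": np.cumsum(result.eigen_fractions),
        }
    ).to_csv(path, sep="\t", index=False)
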