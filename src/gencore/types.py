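"""Core domain containers for genetic-and-epigenetic networks (GENs).

A GEN is the union of a protein-protein interaction network (PPIN) and a
gene regulatory network (GRN) over five node kinds: receptors, proteins,
transcription factors (TFs), miRNAs and lncRNAs.  Receptors, proteins and
TFs are all "protein-like" for modeling purposes: they can interact in the
PPIN and act as TF/protein-class regulators in the GRN; the finer kind is
retained for reporting only.

Regulatory edges carry a class derived from the regulator's kind:

* ``tf``     — TF/protein-class regulation (free-signed ability),
* ``lncrna`` — lncRNA regulation (free-signed ability),
* ``mirna``  — miRNA repression (ability d >= 0, entering the model as -d).

The candidate GEN is a binary structure (edges present/absent, no
abilities); the real GEN, produced by system identification plus AIC
pruning, attaches an estimated ability to every surviving edge and a basal
level to every fitted node model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: the five node kinds
NODE_KINDS = ("receptor", "protein", "TF", "miRNA", "lncRNA")

#: kinds that behave as proteins in the models (PPIN members, TF-class regulators)
PROTEIN_LIKE = frozenset({"receptor", "protein", "TF"})

#: regulation classes, in the column-block order of the network matrix
REG_CLASSES = ("tf", "lncrna", "mirna")

#: model blocks: PPIN fit, gene (GRN) fit, lncRNA fit, miRNA fit
MODEL_BLOCKS = ("ppin", "grn", "lrn", "mrn")


def reg_class_for(kind: str) -> str:
    """Regulation class implied by a regulator's node kind."""
    if kind == "miRNA":
        return "mirna"
    if kind == "lncRNA":
        return "lncrna"
    if kind in PROTEIN_LIKE:
        return "tf"
    raise ValidationError(f"unknown node kind {kind!r}")


@dataclass(frozen=True)
class Node:
    node_id: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValidationError(
                f"node {self.node_id!r}: unknown kind {self.kind!r} "
                f"(expected one of {NODE_KINDS})"
            )


class CandidateGEN:
    """Binary candidate network: typed nodes plus unweighted edges.

    Parameters
    ----------
    nodes
        Iterable of :class:`Node`; ids must be unique.
    ppi_edges
        Iterable of unordered protein-like pairs ``(i, m)``, ``i != m``.
    reg_edges
        Iterable of ``(regulator, target)`` or ``(regulator, target, cls)``
        triples; when given, ``cls`` must match the regulator's kind.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        ppi_edges: Iterable[tuple[str, str]] = (),
        reg_edges: Iterable[tuple] = (),
    ) -> None:
        self.nodes: dict[str, Node] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise ValidationError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node

        self.ppi_edges: set[tuple[str, str]] = set()
        for i, m in ppi_edges:
            self.add_ppi(i, m)

        self.reg_edges: set[tuple[str, str, str]] = set()
        for edge in reg_edges:
            if len(edge) == 2:
                reg, tgt = edge
                cls = None
            else:
                reg, tgt, cls = edge
            self.add_reg(reg, tgt, cls)

    # -- construction -----------------------------------------------------

    def _require(self, node_id: str, context: str) -> Node:
        node = self.nodes.get(node_id)
        if node is None:
            raise ValidationError(f"{context}: unknown node {node_id!r}")
        return node

    def add_ppi(self, i: str, m: str) -> None:
        ni = self._require(i, f"PPI edge ({i}, {m})")
        nm = self._require(m, f"PPI edge ({i}, {m})")
        if i == m:
            raise ValidationError(f"PPI self-edge ({i}, {m}) is not allowed")
        for n in (ni, nm):
            if n.kind not in PROTEIN_LIKE:
                raise ValidationError(
                    f"PPI edge ({i}, {m}): {n.node_id!r} has kind {n.kind!r}, "
                    "expected a protein-like node"
                )
        self.ppi_edges.add((min(i, m), max(i, m)))

    def add_reg(self, regulator: str, target: str, cls: str | None = None) -> None:
        nr = self._require(regulator, f"regulation ({regulator} -> {target})")
        self._require(target, f"regulation ({regulator} -> {target})")
        implied = reg_class_for(nr.kind)
        if cls is None:
            cls = implied
        elif cls != implied:
            raise ValidationError(
                f"regulation ({regulator} -> {target}): class {cls!r} is "
                f"inconsistent with regulator kind {nr.kind!r} (implies {implied!r})"
            )
        # GRN self-regulation is permitted (a TF may regulate its own gene).
        self.reg_edges.add((regulator, target, cls))

    # -- queries ----------------------------------------------------------

    def kind(self, node_id: str) -> str:
        return self._require(node_id, "kind lookup").kind

    def ppi_partners(self, node_id: str) -> list[str]:
        """Sorted PPI partners of a protein-like node."""
        out = set()
        for i, m in self.ppi_edges:
            if i == node_id:
                out.add(m)
            elif m == node_id:
                out.add(i)
        return sorted(out)

    def regulators(self, target: str) -> list[tuple[str, str]]:
        """Incoming regulators of ``target`` as ``(regulator, cls)``.

        Ordered by class block (tf, lncrna, mirna) then regulator id, the
        column order used throughout identification and the network matrix.
        """
        hits = [(r, c) for (r, t, c) in self.reg_edges if t == target]
        order = {c: k for k, c in enumerate(REG_CLASSES)}
        return sorted(hits, key=lambda rc: (order[rc[1]], rc[0]))

    @property
    def n_edges(self) -> int:
        return len(self.ppi_edges) + len(self.reg_edges)

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def adjacency(self) -> pd.DataFrame:
        """Binary node x node adjacency (PPI symmetric, regulation directed)."""
        ids = self.node_ids()
        pos = {n: k for k, n in enumerate(ids)}
        a = np.zeros((len(ids), len(ids)), dtype=int)
        for i, m in self.ppi_edges:
            a[pos[i], pos[m]] = a[pos[m], pos[i]] = 1
        for r, t, _ in self.reg_edges:
            a[pos[r], pos[t]] = 1
        return pd.DataFrame(a, index=ids, columns=ids)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CandidateGEN({len(self.nodes)} nodes, {len(self.ppi_edges)} PPI, "
            f"{len(self.reg_edges)} regulatory edges)"
        )


@dataclass
class ExpressionMatrix:
    """Node x sample expression values with aligned index lists."""

    node_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.node_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.node_ids)} nodes x {len(self.sample_ids)} samples"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids in expression matrix")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        self._row = {n: k for k, n in enumerate(self.node_ids)}

    def row(self, node_id: str, samples: list[str] | None = None) -> np.ndarray:
        if node_id not in self._row:
            raise ValidationError(f"node {node_id!r} has no expression row")
        vals = self.values[self._row[node_id]]
        if samples is None:
            return vals
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in samples]
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from exc
        return vals[idx]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))


@dataclass
class SampleGroups:
    """Early/later stage assignment derived from Braak scores."""

    group: dict[str, str]  # sample_id -> "early" | "later"
    braak: dict[str, str]  # sample_id -> raw score string

    def samples(self, group: str) -> list[str]:
        if group not in ("early", "later"):
            raise ValidationError(f"unknown group {group!r} (expected 'early' or 'later')")
        return [s for s, g in self.group.items() if g == group]


@dataclass
class RegressionProblem:
    """One node's linear regression: response = regressors @ theta + noise.

    The last column of ``regressors`` is always the all-ones intercept whose
    coefficient is the basal level; it is never constrained and never counted
    in ``column_meta``.  miRNA-class columns carry a ``nonpositive``
    coefficient constraint: the fitted coefficient is -d with repression
    ability d >= 0.
    """

    target: str
    block: str  # one of MODEL_BLOCKS
    response: np.ndarray
    regressors: np.ndarray
    column_meta: list[tuple[str, str]]  # (regulator_id, class), excludes intercept
    sign_constraints: list[str]  # per column_meta entry: "free" | "nonpositive"

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.regressors = np.asarray(self.regressors, dtype=float)
        n, p = self.regressors.shape
        if self.response.shape != (n,):
            raise ValidationError("response length does not match regressor rows")
        if p != len(self.column_meta) + 1:
            raise ValidationError("regressors must hold one column per regulator plus intercept")
        if len(self.sign_constraints) != len(self.column_meta):
            raise ValidationError("one sign constraint per regressor column required")
        if not np.allclose(self.regressors[:, -1], 1.0):
            raise ValidationError("last regressor column must be the all-ones intercept")
        if self.block not in MODEL_BLOCKS:
            raise ValidationError(f"unknown model block {self.block!r}")

    @property
    def n_samples(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_regressors(self) -> int:
        return len(self.column_meta)

    def subproblem(self, columns: list[int]) -> "RegressionProblem":
        """Problem restricted to the given regressor columns (intercept kept)."""
        cols = list(columns)
        keep = cols + [self.regressors.shape[1] - 1]
        return RegressionProblem(
            target=self.target,
            block=self.block,
            response=self.response,
            regressors=self.regressors[:, keep],
            column_meta=[self.column_meta[c] for c in cols],
            sign_constraints=[self.sign_constraints[c] for c in cols],
        )


@dataclass
class NodeModelFit:
    """Estimated parameters of one node model.

    ``theta`` holds one coefficient per ``column_meta`` entry of the problem
    it was fitted on (raw regression scale: miRNA columns are <= 0, the
    repression ability is the negated coefficient); ``basal`` is the
    intercept coefficient.
    """

    target: str
    block: str
    theta: np.ndarray
    basal: float
    sse: float
    n: int
    column_meta: list[tuple[str, str]]
    rank_deficient: bool = False
    aic: float | None = None

    def ability(self, k: int) -> float:
        """Signed ability of the k-th column (miRNA reported as d >= 0)."""
        _, cls = self.column_meta[k]
        coef = float(self.theta[k])
        return -coef if cls == "mirna" else coef

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in REG_CLASSES}
        for _, cls in self.column_meta:
            out[cls] += 1
        return out


@dataclass
class AICTrace:
    """AIC values along the nested order search for one node model."""

    target: str
    block: str
    orders: list[int]
    aic_values: list[float]
    selected_order: int
    selected_edges: list[tuple[str, str]]  # (regulator_id, class)
    selected_fit: NodeModelFit

    def __post_init__(self) -> None:
        sel = self.aic_values[self.orders.index(self.selected_order)]
        if sel > min(self.aic_values) + 1e-12:
            raise ValidationError("selected order does not minimize AIC")


class RealGEN:
    """Pruned network with estimated abilities and basal levels.

    Edges are per-target: a candidate PPI pair ``(i, m)`` may survive AIC
    selection in node ``i``'s model but not in node ``m``'s, in which case
    only the ``(target=i, partner=m)`` entry exists.
    """

    def __init__(self, nodes: Mapping[str, Node]) -> None:
        self.nodes: dict[str, Node] = dict(nodes)
        # (target, partner) -> interaction ability a_hat
        self.ppi: dict[tuple[str, str], float] = {}
        # (regulator, target, cls) -> ability (mirna abilities stored >= 0)
        self.reg: dict[tuple[str, str, str], float] = {}
        # (node, block) -> basal level
        self.basal: dict[tuple[str, str], float] = {}

    def add_ppi(self, target: str, partner: str, ability: float) -> None:
        for n in (target, partner):
            if n not in self.nodes:
                raise ValidationError(f"PPI ability references unknown node {n!r}")
        self.ppi[(target, partner)] = float(ability)

    def add_reg(self, regulator: str, target: str, cls: str, ability: float) -> None:
        for n in (regulator, target):
            if n not in self.nodes:
                raise ValidationError(f"regulation references unknown node {n!r}")
        if cls == "mirna" and ability < -1e-10:
            raise ValidationError(
                f"miRNA ability for ({regulator} -> {target}) must be >= 0, got {ability}"
            )
        self.reg[(regulator, target, cls)] = float(ability)

    def set_basal(self, node: str, block: str, value: float) -> None:
        if node not in self.nodes:
            raise ValidationError(f"basal level references unknown node {node!r}")
        self.basal[(node, block)] = float(value)

    def node_basal(self, node: str) -> float | None:
        """Basal level of a node, preferring its gene-level (regulatory) fit."""
        for block in ("grn", "lrn", "mrn", "ppin"):
            if (node, block) in self.basal:
                return self.basal[(node, block)]
        return None

    @property
    def n_edges(self) -> int:
        return len(self.ppi) + len(self.reg)

    def edge_iter(self) -> Iterator[tuple[str, str, str, float]]:
        """All edges as (source, target, class, ability); PPI class is 'ppi'."""
        for (t, p), a in sorted(self.ppi.items()):
            yield p, t, "ppi", a
        for (r, t, c), a in sorted(self.reg.items()):
            yield r, t, c, a

    def induced(self, keep: set[str]) -> "RealGEN":
        """Subnetwork on ``keep``: edges with every endpoint retained."""
        sub = RealGEN({n: v for n, v in self.nodes.items() if n in keep})
        for (t, p), a in self.ppi.items():
            if t in keep and p in keep:
                sub.ppi[(t, p)] = a
        for (r, t, c), a in self.reg.items():
            if r in keep and t in keep:
                sub.reg[(r, t, c)] = a
        for (n, b), v in self.basal.items():
            if n in keep:
                sub.basal[(n, b)] = v
        return sub

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RealGEN({len(self.nodes)} nodes, {len(self.ppi)} PPI entries, "
            f"{len(self.reg)} regulations)"
        )
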