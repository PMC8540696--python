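"""File-based assembly of the candidate GEN and sample groups.

Formats
-------
* node table (TSV): columns ``node_id``, ``kind``
* edge table (TSV): columns ``source``, ``target``, ``edge_type`` in
  {ppi, tf, lncrna, mirna}
* expression (TSV): first column ``node_id``, remaining columns sample ids
* sample metadata (TSV): columns ``sample_id``, ``braak_score``

Braak neurofibrillary scores I-III map to the early stage and IV-VI to the
later stage; integer scores 1-6 are accepted as synonyms.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .types import CandidateGEN, ExpressionMatrix, Node, RealGEN, SampleGroups

logger = logging.getLogger(__name__)

_BRAAK_EARLY = {"I", "II", "III", "1", "2", "3"}
_BRAAK_LATER = {"IV", "V", "VI", "4", "5", "6"}


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def read_candidate(node_table, edge_table) -> CandidateGEN:
    """Read and validate a binary candidate GEN from node/edge TSVs.

    Unknown kinds, dangling edge endpoints and PPI self-edges are rejected
    with the offending row named; duplicate edges are deduplicated with a
    warning.
    """
    nodes_df = _read_tsv(node_table, ("node_id", "kind"))
    edges_df = _read_tsv(edge_table, ("source", "target", "edge_type"))

    nodes = []
    for row in nodes_df.itertuples(index=False):
        try:
            nodes.append(Node(str(row.node_id), str(row.kind)))
        except ValidationError as exc:
            raise ValidationError(f"{node_table}: {exc}") from exc

    gen = CandidateGEN(nodes)
    seen: set[tuple] = set()
    for k, row in enumerate(edges_df.itertuples(index=False)):
        src, tgt, etype = str(row.source), str(row.target), str(row.edge_type)
        key = (
            ("ppi", min(src, tgt), max(src, tgt))
            if etype == "ppi"
            else ("reg", src, tgt, etype)
        )
        if key in seen:
            logger.warning("%s row %d: duplicate edge %s, ignored", edge_table, k, key)
            continue
        seen.add(key)
        try:
            if etype == "ppi":
                gen.add_ppi(src, tgt)
            elif etype in ("tf", "lncrna", "mirna"):
                gen.add_reg(src, tgt, etype)
            else:
                raise ValidationError(f"unknown edge_type {etype!r}")
        except ValidationError as exc:
            raise ValidationError(f"{edge_table} row {k}: {exc}") from exc
    return gen


def write_candidate(gen: CandidateGEN, node_table, edge_table) -> None:
    nodes = pd.DataFrame(
        [(n.node_id, n.kind) for n in gen.nodes.values()], columns=["node_id", "kind"]
    ).sort_values("node_id")
    rows = [(i, m, "ppi") for i, m in sorted(gen.ppi_edges)]
    rows += [(r, t, c) for r, t, c in sorted(gen.reg_edges)]
    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type"])
    nodes.to_csv(node_table, sep="\t", index=False)
    edges.to_csv(edge_table, sep="\t", index=False)


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "node_id":
        raise ValidationError(f"{path}: first column must be named 'node_id'")
    try:
        return ExpressionMatrix.from_frame(df)
    except (ValidationError, ValueError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.to_frame()
    df.index.name = "node_id"
    df.to_csv(path, sep="\t")


def assign_groups(metadata) -> SampleGroups:
    """Partition samples into early (Braak I-III) and later (IV-VI) stages."""
    df = _read_tsv(metadata, ("sample_id", "braak_score"))
    group: dict[str, str] = {}
    braak: dict[str, str] = {}
    bad: list[str] = []
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        score = str(row.braak_score).strip().upper()
        braak[sid] = score
        if score in _BRAAK_EARLY:
            group[sid] = "early"
        elif score in _BRAAK_LATER:
            group[sid] = "later"
        else:
            bad.append(sid)
    if bad:
        raise ValidationError(
            f"unparseable or out-of-range Braak scores for samples: {bad}"
        )
    return SampleGroups(group=group, braak=braak)


def align(
    gen: CandidateGEN, expr: ExpressionMatrix
) -> tuple[CandidateGEN, ExpressionMatrix]:
    """Restrict the network and the expression matrix to their shared nodes.

    Network nodes without an expression row are dropped together with their
    incident edges (logged); expression rows are reordered to the surviving
    node order.  Nodes whose every candidate partner is dropped are retained
    with zero candidate edges.
    """
    keep = [n for n in gen.nodes if n in expr]
    if not keep:
        raise ValidationError("no overlap between network nodes and expression rows")
    dropped = sorted(set(gen.nodes) - set(keep))
    if dropped:
        logger.info("align: dropping %d nodes without expression: %s", len(dropped), dropped)

    keep_set = set(keep)
    sub = CandidateGEN(
        [gen.nodes[n] for n in keep],
        [(i, m) for i, m in gen.ppi_edges if i in keep_set and m in keep_set],
        [(r, t, c) for r, t, c in gen.reg_edges if r in keep_set and t in keep_set],
    )
    mat = expr.to_frame().loc[keep]
    return sub, ExpressionMatrix.from_frame(mat)


def zscore(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Optional per-node z-scoring (off by default; raw values are the norm)."""
    df = expr.to_frame()
    sd = df.std(axis=1, ddof=0).replace(0.0, 1.0)
    out = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix.from_frame(out)


def _to_graph(network: CandidateGEN | RealGEN) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in network.nodes.values():
        g.add_node(n.node_id, kind=n.kind)
    if isinstance(network, CandidateGEN):
        for i, m in sorted(network.ppi_edges):
            g.add_edge(i, m, edge_type="ppi")
        for r, t, c in sorted(network.reg_edges):
            g.add_edge(r, t, edge_type=c)
    else:
        for src, tgt, cls, ability in network.edge_iter():
            g.add_edge(src, tgt, edge_type=cls, ability=float(ability))
    return g


def write_graphml(network: CandidateGEN | RealGEN, path) -> None:
    nx.write_graphml(_to_graph(network), path)


def write_real_gen(real: RealGEN, path) -> None:
    """Export a real GEN as edge TSV with abilities plus per-node basal levels."""
    rows = [
        {"source": s, "target": t, "edge_type": c, "ability": a}
        for s, t, c, a in real.edge_iter()
    ]
    pd.DataFrame(rows, columns=["source", "target", "edge_type", "ability"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_real_gen(node_table, edge_table, basal_table) -> RealGEN:
    """Read a real GEN back from its exported edge and basal TSVs."""
    nodes_df = _read_tsv(node_table, ("node_id", "kind"))
    edges_df = pd.read_csv(
        edge_table, sep="\t", dtype={"ability": float}, float_precision="round_trip"
    )
    basal_df = pd.read_csv(
        basal_table, sep="\t", dtype={"basal": float}, float_precision="round_trip"
    )
    real = RealGEN(
        {str(r.node_id): Node(str(r.node_id), str(r.kind))
         for r in nodes_df.itertuples(index=False)}
    )
    for row in edges_df.itertuples(index=False):
        if row.edge_type == "ppi":
            real.add_ppi(str(row.target), str(row.source), float(row.ability))
        else:
            real.add_reg(str(row.source), str(row.target), str(row.edge_type),
                         float(row.ability))
    for row in basal_df.itertuples(index=False):
        real.set_basal(str(row.node_id), str(row.block), float(row.basal))
    return real


def write_basal_levels(real: RealGEN, path) -> None:
    rows = [
        {"node_id": n, "block": b, "basal": v}
        for (n, b), v in sorted(real.basal.items())
    ]
    pd.DataFrame(rows, columns=["node_id", "block", "basal"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
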