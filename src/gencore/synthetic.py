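"""Ground-truth GEN simulator.

Generates networks with known interaction/regulatory abilities and simulates
stage-stratified expression data obeying the identification models, so that
parameter estimation, AIC pruning and principal network projection can be
tested end-to-end without any external download.

Design of the simulated world
-----------------------------
Nodes are layered: *exogenous* nodes (all TFs, half of the proteins, half of
the lncRNAs and miRNAs) have expression drawn i.i.d. from a lognormal
distribution, mimicking positive microarray intensities.  *Modeled* nodes are
computed in one pass from the exogenous draws — the models are static
per-node regressions, so no feedback/equilibrium solving is needed:

* PPIN targets (the remaining proteins) follow the interaction model in the
  form matching the identification regressors (``ppi_term``).  The default
  ``linear`` form is p_i = sum_m a_im p_m + beta_i + eps with free-signed
  abilities.  The ``product`` form p_i = sum_m a_im p_i p_m + beta_i + eps
  is solved in closed form as p_i = (beta_i + eps) / (1 - sum_m a_im p_m);
  its abilities are drawn negative (magnitude uniform on [0.2, 1.0]) so the
  denominator stays >= 1 and the model is well-posed for every draw.
* GRN targets (receptors) follow the additive regulation model
  g_j = sum_s b_js p_s + sum_t c_jt x_t - sum_u d_ju r_u + beta_j + eps
  with TF/protein and lncRNA abilities of random sign and miRNA repression
  abilities d >= 0.
* lncRNA and miRNA targets follow the same additive form with their own
  regulator classes.

Epigenetic modification is realized as a between-group basal-level shift:
flagged nodes use beta + epi_shift in the later group.  Candidate networks
are corrupted with false-positive decoy edges that respect kind constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .types import CandidateGEN, ExpressionMatrix, Node, RealGEN, reg_class_for

_GROUP_INDEX = {"early": 0, "later": 1}


@dataclass
class SimulationConfig:
    """Knobs of the simulated world.

    ``noise_sd`` defaults to 0.05: exogenous intensities are lognormal(0, 0.5)
    with mean ~1.13, so this is ~5% of the typical signal level.
    """

    n_receptor: int = 6
    n_protein: int = 30
    n_tf: int = 10
    n_mirna: int = 8
    n_lncrna: int = 8
    n_samples: int = 120  # per group
    noise_sd: float = 0.05
    decoy_rate: float = 0.5
    basal_shift: float = 1.0
    epi_fraction: float = 0.2
    seed: int = 0
    reg_mu: float = 0.0  # lognormal location of exogenous intensities
    reg_sigma: float = 0.5  # lognormal scale of exogenous intensities
    max_ppi_partners: int = 3
    max_tf_regs: int = 2
    max_lncrna_regs: int = 1
    max_mirna_regs: int = 1
    ppi_term: str = "linear"  # linear | product interaction form

    def __post_init__(self) -> None:
        if self.ppi_term not in ("linear", "product"):
            raise ValidationError(f"unknown ppi_term {self.ppi_term!r}")
        counts = (
            self.n_receptor, self.n_protein, self.n_tf,
            self.n_mirna, self.n_lncrna, self.n_samples,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("node and sample counts must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValidationError("decoy_rate must lie in [0, 1]")
        if not 0.0 <= self.epi_fraction <= 1.0:
            raise ValidationError("epi_fraction must lie in [0, 1]")
        if self.reg_sigma < 0:
            raise ValidationError("reg_sigma must be >= 0")


@dataclass
class GroundTruthGEN:
    """A GEN with known parameters.

    ``ppi_edges`` is target-centric: ``(target, partner) -> a`` records that
    the *target* protein's model contains the interaction term; the candidate
    network derived from it is undirected.  miRNA-class regulation abilities
    are stored as d >= 0 (they enter the models as -d * r).
    """

    nodes: dict[str, Node]
    ppi_edges: dict[tuple[str, str], float]
    reg_edges: dict[tuple[str, str, str], float]
    basal: dict[str, float]
    epi_flags: dict[str, bool]
    epi_shift: float
    exogenous: set[str]
    target_block: dict[str, str]  # modeled node -> ppin|grn|lrn|mrn

    def __post_init__(self) -> None:
        for (t, p) in self.ppi_edges:
            if t == p:
                raise ValidationError(f"PPI self-edge on {t!r}")
            for n in (t, p):
                if n not in self.nodes:
                    raise ValidationError(f"PPI edge endpoint {n!r} missing")
        for (r, t, c), ability in self.reg_edges.items():
            for n in (r, t):
                if n not in self.nodes:
                    raise ValidationError(f"regulation endpoint {n!r} missing")
            if c == "mirna" and ability < 0:
                raise ValidationError("miRNA abilities must be >= 0")

    @property
    def n_true_edges(self) -> int:
        return len(self.ppi_edges) + len(self.reg_edges)

    def modeled_nodes(self) -> list[str]:
        return list(self.target_block)


def _node_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{k:04d}" for k in range(n)]


def _signed_ability(rng: np.random.Generator) -> float:
    mag = rng.uniform(0.2, 1.0)
    return float(mag if rng.random() < 0.5 else -mag)


def generate_ground_truth(config: SimulationConfig) -> GroundTruthGEN:
    """Draw a ground-truth GEN with abilities of magnitude uniform [0.2, 1.0].

    Reproducible: identical configs (including seed) give identical networks.
    """
    rng = np.random.default_rng(config.seed)

    receptors = _node_ids("R", config.n_receptor)
    proteins = _node_ids("P", config.n_protein)
    tfs = _node_ids("TF", config.n_tf)
    mirnas = _node_ids("MIR", config.n_mirna)
    lncrnas = _node_ids("LNC", config.n_lncrna)

    nodes: dict[str, Node] = {}
    for nid in receptors:
        nodes[nid] = Node(nid, "receptor")
    for nid in proteins:
        nodes[nid] = Node(nid, "protein")
    for nid in tfs:
        nodes[nid] = Node(nid, "TF")
    for nid in mirnas:
        nodes[nid] = Node(nid, "miRNA")
    for nid in lncrnas:
        nodes[nid] = Node(nid, "lncRNA")

    # layering: sources are exogenous, the rest are modeled targets
    n_src_p = math.ceil(config.n_protein / 2)
    src_proteins = proteins[:n_src_p]
    tgt_proteins = proteins[n_src_p:]
    src_mirnas = mirnas[: math.ceil(config.n_mirna / 2)]
    tgt_mirnas = mirnas[math.ceil(config.n_mirna / 2):]
    src_lncrnas = lncrnas[: math.ceil(config.n_lncrna / 2)]
    tgt_lncrnas = lncrnas[math.ceil(config.n_lncrna / 2):]
    tf_class_pool = tfs + src_proteins  # TF/protein-class regulators

    target_block: dict[str, str] = {}
    ppi_edges: dict[tuple[str, str], float] = {}
    reg_edges: dict[tuple[str, str, str], float] = {}

    for t in tgt_proteins:
        target_block[t] = "ppin"
        if not src_proteins:
            continue
        k = int(rng.integers(1, config.max_ppi_partners + 1))
        k = min(k, len(src_proteins))
        partners = rng.choice(src_proteins, size=k, replace=False)
        for m in sorted(partners):
            if config.ppi_term == "product":
                # negative ability keeps 1 - sum(a * p_m) >= 1 for positive p_m
                ppi_edges[(t, m)] = float(-rng.uniform(0.2, 1.0))
            else:
                ppi_edges[(t, m)] = _signed_ability(rng)

    def _add_regs(target: str, pool: list[str], cls: str, lo: int, hi: int) -> None:
        if not pool or hi == 0:
            return
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(pool))
        if k == 0:
            return
        regs = rng.choice(pool, size=k, replace=False)
        for r in sorted(regs):
            if cls == "mirna":
                reg_edges[(r, target, cls)] = float(rng.uniform(0.2, 1.0))
            else:
                reg_edges[(r, target, cls)] = _signed_ability(rng)

    for t in receptors:
        target_block[t] = "grn"
        _add_regs(t, tf_class_pool, "tf", 1, config.max_tf_regs)
        _add_regs(t, src_lncrnas, "lncrna", 0, config.max_lncrna_regs)
        _add_regs(t, src_mirnas, "mirna", 0, config.max_mirna_regs)

    for t in tgt_lncrnas:
        target_block[t] = "lrn"
        _add_regs(t, tf_class_pool, "tf", 1, config.max_tf_regs)
        _add_regs(t, src_mirnas, "mirna", 0, config.max_mirna_regs)

    for t in tgt_mirnas:
        target_block[t] = "mrn"
        _add_regs(t, tf_class_pool, "tf", 1, config.max_tf_regs)
        _add_regs(t, src_mirnas, "mirna", 0, config.max_mirna_regs)

    basal = {nid: float(rng.uniform(0.5, 1.5)) for nid in nodes}

    modeled = list(target_block)
    n_epi = round(config.epi_fraction * len(modeled))
    epi_nodes = set(rng.choice(modeled, size=n_epi, replace=False)) if n_epi else set()
    epi_flags = {nid: nid in epi_nodes for nid in nodes}

    exogenous = set(nodes) - set(target_block)
    return GroundTruthGEN(
        nodes=nodes,
        ppi_edges=ppi_edges,
        reg_edges=reg_edges,
        basal=basal,
        epi_flags=epi_flags,
        epi_shift=config.basal_shift,
        exogenous=exogenous,
        target_block=target_block,
    )


def simulate_expression(
    gt: GroundTruthGEN, config: SimulationConfig, group: str
) -> ExpressionMatrix:
    """Simulate one group's expression matrix from the ground truth.

    Exogenous nodes are lognormal(reg_mu, reg_sigma) i.i.d. per sample;
    modeled nodes equal their model right-hand side plus group-appropriate
    basal level plus Gaussian(0, noise_sd) noise.  Deterministic per
    (config.seed, group); the two groups use independent draws.
    """
    if group not in _GROUP_INDEX:
        raise ValidationError(f"unknown group {group!r} (expected 'early' or 'later')")
    rng = np.random.default_rng([config.seed, _GROUP_INDEX[group]])

    node_order = list(gt.nodes)
    n = config.n_samples
    sample_ids = [f"{group}_{k:03d}" for k in range(n)]
    values = np.zeros((len(node_order), n))
    pos = {nid: k for k, nid in enumerate(node_order)}

    # exogenous layer first, in fixed node order
    for nid in node_order:
        if nid in gt.exogenous:
            values[pos[nid]] = rng.lognormal(config.reg_mu, config.reg_sigma, n)

    # modeled layer: one pass, all regulators already drawn
    reg_by_target: dict[str, list[tuple[str, str, float]]] = {}
    for (r, t, c), a in sorted(gt.reg_edges.items()):
        reg_by_target.setdefault(t, []).append((r, c, a))
    ppi_by_target: dict[str, list[tuple[str, float]]] = {}
    for (t, m), a in sorted(gt.ppi_edges.items()):
        ppi_by_target.setdefault(t, []).append((m, a))

    for nid in node_order:
        block = gt.target_block.get(nid)
        if block is None:
            continue
        beta = gt.basal[nid]
        if group == "later" and gt.epi_flags.get(nid, False):
            beta += gt.epi_shift
        eps = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
        if block == "ppin" and config.ppi_term == "product":
            denom = np.ones(n)
            for m, a in ppi_by_target.get(nid, []):
                denom -= a * values[pos[m]]
            values[pos[nid]] = (beta + eps) / denom
        elif block == "ppin":
            rhs = np.full(n, beta) + eps
            for m, a in ppi_by_target.get(nid, []):
                rhs += a * values[pos[m]]
            values[pos[nid]] = rhs
        else:
            rhs = np.full(n, beta) + eps
            for r, c, a in reg_by_target.get(nid, []):
                sign = -1.0 if c == "mirna" else 1.0
                rhs += sign * a * values[pos[r]]
            values[pos[nid]] = rhs

    return ExpressionMatrix(node_order, sample_ids, values)


def corrupt_candidate(
    gt: GroundTruthGEN, decoy_rate: float, seed: int
) -> CandidateGEN:
    """Binary candidate network: all true edges plus kind-consistent decoys.

    The decoy count is round(decoy_rate * number of true edges); decoys are
    drawn without replacement from edges absent in the ground truth, attached
    to modeled targets so that pruning is observable.  True abilities are not
    carried over — the candidate is binary.
    """
    if not 0.0 <= decoy_rate <= 1.0:
        raise ValidationError("decoy_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    true_pairs = {(min(t, p), max(t, p)) for (t, p) in gt.ppi_edges}
    true_regs = set(gt.reg_edges)
    n_decoys = round(decoy_rate * gt.n_true_edges)

    pool: list[tuple] = []
    src_proteins = sorted(
        n for n, node in gt.nodes.items()
        if node.kind in ("protein", "TF") and n in gt.exogenous
    )
    src_lncrnas = sorted(
        n for n, node in gt.nodes.items() if node.kind == "lncRNA" and n in gt.exogenous
    )
    src_mirnas = sorted(
        n for n, node in gt.nodes.items() if node.kind == "miRNA" and n in gt.exogenous
    )
    for tgt, block in sorted(gt.target_block.items()):
        if block == "ppin":
            for m in src_proteins:
                if m != tgt and (min(tgt, m), max(tgt, m)) not in true_pairs:
                    pool.append(("ppi", tgt, m))
        else:
            pools = {"tf": src_proteins, "lncrna": src_lncrnas, "mirna": src_mirnas}
            if block in ("lrn", "mrn"):
                pools["lncrna"] = []  # lncRNA/miRNA targets: TF + miRNA regulators
            for cls, regs in pools.items():
                for r in regs:
                    if r != tgt and (r, tgt, cls) not in true_regs:
                        pool.append(("reg", r, tgt, cls))

    if n_decoys > len(pool):
        raise ValidationError(
            f"cannot place {n_decoys} decoys: only {len(pool)} kind-consistent "
            "candidate edges are available"
        )
    idx = rng.choice(len(pool), size=n_decoys, replace=False) if n_decoys else []

    gen = CandidateGEN(gt.nodes.values())
    for (t, p) in true_pairs:
        gen.add_ppi(t, p)
    for (r, t, c) in true_regs:
        gen.add_reg(r, t, c)
    for k in idx:
        entry = pool[k]
        if entry[0] == "ppi":
            gen.add_ppi(entry[1], entry[2])
        else:
            gen.add_reg(entry[1], entry[2], entry[3])
    return gen


def true_real_gen(gt: GroundTruthGEN, group: str = "early") -> RealGEN:
    """The ground truth expressed as a RealGEN (true abilities, true basal).

    Useful as the ideal pruning outcome and as a synthetic real GEN for
    projection-stage tests that do not require identification.
    """
    if group not in _GROUP_INDEX:
        raise ValidationError(f"unknown group {group!r}")
    real = RealGEN(gt.nodes)
    for (t, p), a in gt.ppi_edges.items():
        real.add_ppi(t, p, a)
    for (r, t, c), a in gt.reg_edges.items():
        real.add_reg(r, t, c, a)
    for nid, block in gt.target_block.items():
        beta = gt.basal[nid]
        if group == "later" and gt.epi_flags.get(nid, False):
            beta += gt.epi_shift
        real.set_basal(nid, block, beta)
    return real


def write_dataset(gt: GroundTruthGEN, config: SimulationConfig, outdir) -> dict:
    """Write node/edge/expression/metadata TSVs readable by the assembly layer.

    Simulates both groups, concatenates their samples into one expression
    table, assigns Braak scores (cycling I-III for early, IV-VI for later)
    and writes the candidate network produced by ``corrupt_candidate``.
    Returns the written paths.
    """
    from pathlib import Path

    import pandas as pd

    from . import assembly

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    candidate = corrupt_candidate(gt, config.decoy_rate, config.seed)
    paths = {
        "nodes": outdir / "nodes.tsv",
        "edges": outdir / "edges.tsv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
    }
    assembly.write_candidate(candidate, paths["nodes"], paths["edges"])

    early = simulate_expression(gt, config, "early")
    later = simulate_expression(gt, config, "later")
    expr = pd.concat([early.to_frame(), later.to_frame()], axis=1)
    assembly.write_expression(ExpressionMatrix.from_frame(expr), paths["expression"])

    early_scores = ["I", "II", "III"]
    later_scores = ["IV", "V", "VI"]
    meta = pd.DataFrame(
        {
            "sample_id": early.sample_ids + later.sample_ids,
            "braak_score": [early_scores[k % 3] for k in range(len(early.sample_ids))]
            + [later_scores[k % 3] for k in range(len(later.sample_ids))],
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths
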