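"""End-to-end orchestration: files in, real/core GENs and reports out.

One *stage* (early or later Braak group) runs assembly -> system
identification -> AIC order detection -> pruning -> principal network
projection -> core extraction, writing every export under
``outdir/<group>/``.  A full run processes both stages independently, then
compares basal levels for the epigenetic report and, when drug tables are
configured, ranks candidate drugs per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from . import assembly, epidrug, order, pnp, sysid
from .errors import GencoreError
from .types import CandidateGEN, ExpressionMatrix, RealGEN, SampleGroups

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    node_table: str
    edge_table: str
    expression: str
    metadata: str
    outdir: str = "gencore_run"
    ppi_term: str = "linear"  # linear | product interaction regressors
    aic_mode: str = "nested"  # nested | exhaustive
    pnp_threshold: float = 0.85
    core_size: int = 2000
    epi_threshold: float | str = "auto"
    zscore: bool = False
    seed: int = 0
    # optional drug-matching inputs ("bundled" uses the packaged fixtures)
    drug_table_early: str | None = None
    drug_table_later: str | None = None
    biomarkers_early: str | None = None
    biomarkers_later: str | None = None
    top_n_drugs: int = 3


@dataclass
class StageResult:
    group: str
    real_gen: RealGEN
    traces: dict
    pnp_result: pnp.PNPResult
    core: pnp.CoreGEN


@dataclass
class FullResult:
    stages: dict[str, StageResult]
    epi_report: epidrug.EpiFlagReport
    drug_scores: dict[str, list[epidrug.DrugScore]] = field(default_factory=dict)


def _stage(name: str):
    """Context that prefixes package errors with the failing stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, GencoreError):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def identify_group(
    gen: CandidateGEN,
    expr: ExpressionMatrix,
    samples: list[str],
    ppi_term: str = "linear",
    aic_mode: str = "nested",
) -> tuple[RealGEN, dict]:
    """Fit, order-detect and prune one group's candidate GEN."""
    problems = sysid.build_all_problems(gen, expr, samples, ppi_term)
    fits = sysid.fit_all(problems)
    traces = order.detect_all(problems, fits, mode=aic_mode)
    real = order.prune_network(gen, traces)
    return real, traces


def run_stage(config: PipelineConfig, group: str) -> StageResult:
    """Run one group end-to-end and write its exports."""
    outdir = Path(config.outdir) / group

    with _stage("assembly"):
        gen = assembly.read_candidate(config.node_table, config.edge_table)
        expr = assembly.read_expression(config.expression)
        groups = assembly.assign_groups(config.metadata)
        gen, expr = assembly.align(gen, expr)
        if config.zscore:
            expr = assembly.zscore(expr)
        samples = [s for s in groups.samples(group) if s in expr.sample_ids]
        if not samples:
            raise GencoreError(f"no {group}-group samples present in expression data")

    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("sysid/order_detect"):
        real, traces = identify_group(
            gen, expr, samples, config.ppi_term, config.aic_mode
        )
        assembly.write_real_gen(real, outdir / "real_edges.tsv")
        assembly.write_basal_levels(real, outdir / "basal_levels.tsv")
        assembly.write_graphml(real, outdir / "real_gen.graphml")
        order.export_traces(traces, outdir / "aic_traces.tsv")
        logger.info(
            "%s: pruned %d candidate edges to %d real edges",
            group, gen.n_edges, real.n_edges,
        )

    with _stage("pnp_core"):
        result = pnp.run_pnp(real, config.pnp_threshold)
        core = pnp.select_core(real, result, config.core_size)
        pnp.export_projection(result, real, core, outdir / "pnp_nodes.tsv")
        pnp.export_spectrum(result, outdir / "singular_spectrum.tsv")
        assembly.write_real_gen(core.network, outdir / "core_edges.tsv")
        assembly.write_graphml(core.network, outdir / "core_gen.graphml")

    return StageResult(group=group, real_gen=real, traces=traces,
                       pnp_result=result, core=core)


def _drug_inputs(config: PipelineConfig, stage: str):
    table_path = getattr(config, f"drug_table_{stage}")
    marker_path = getattr(config, f"biomarkers_{stage}")
    if table_path is None:
        return None
    if table_path == "bundled":
        table = epidrug.bundled_drug_table(stage)
    else:
        table = epidrug.load_drug_table(table_path)
    if marker_path in (None, "bundled"):
        markers = epidrug.bundled_biomarkers(stage)
    else:
        markers = epidrug.load_biomarkers(marker_path)
    return markers, table


def run_full(config: PipelineConfig) -> FullResult:
    """Both stages, the epigenetic report, and (optionally) drug rankings."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_manifest(config, outdir / "run_manifest.json")

    stages = {g: run_stage(config, g) for g in ("early", "later")}

    with _stage("epi_flag"):
        report = epidrug.flag_epigenetic(
            stages["early"].real_gen, stages["later"].real_gen, config.epi_threshold
        )
        report.to_frame().to_csv(outdir / "epi_flags.tsv", sep="\t", index=False)

    drug_scores: dict[str, list[epidrug.DrugScore]] = {}
    for stage in ("early", "later"):
        inputs = _drug_inputs(config, stage)
        if inputs is None:
            logger.info("%s: no drug table supplied, drug matching skipped", stage)
            continue
        with _stage("match_drugs"):
            markers, table = inputs
            scores = epidrug.match_drugs(markers, table, config.top_n_drugs)
            drug_scores[stage] = scores
            _write_drug_ranking(scores, outdir / f"drug_ranking_{stage}.tsv")

    return FullResult(stages=stages, epi_report=report, drug_scores=drug_scores)


def _write_drug_ranking(scores: list[epidrug.DrugScore], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "rank": s.rank,
                "drug": s.drug,
                "n_targets": s.count,
                "matched_targets": ";".join(s.matched),
            }
            for s in scores
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_manifest(config: PipelineConfig, path) -> None:
    import numpy
    import scipy

    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "config": cfg,
        "config_hash": digest,
        "seed": config.seed,
        "versions": {
            "gencore": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
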