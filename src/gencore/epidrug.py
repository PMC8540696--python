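"""Epigenetic-modification flagging and multi-target drug matching.

Epigenetic effects (methylation, acetylation, ubiquitination,
phosphorylation) are absorbed into each node model's basal level; a node
whose basal level changes between the early and later stage fits by more
than a threshold is flagged as epigenetically modified.  The threshold is
not dictated by the method: the default is the 95th percentile of the
|delta| distribution across nodes (scale-free), overridable by an absolute
value.

Drug matching scores each drug by how many identified biomarkers it affects
in the desired direction (targets to be inhibited vs enhanced); the top
scorers form a candidate multiple-molecule drug.  Fixture tables transcribed
from published early- and later-stage Alzheimer's drug screens ship with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import RealGEN

_ACTIONS = ("inhibit", "enhance")


@dataclass
class EpiRecord:
    node_id: str
    basal_early: float
    basal_later: float
    delta: float
    flagged: bool


@dataclass
class EpiFlagReport:
    records: list[EpiRecord]
    threshold: float

    def flagged_nodes(self) -> list[str]:
        return [r.node_id for r in self.records if r.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_id": r.node_id,
                    "basal_early": r.basal_early,
                    "basal_later": r.basal_later,
                    "delta": r.delta,
                    "flagged": r.flagged,
                }
                for r in self.records
            ]
        )


def _basal_map(fits) -> dict[str, float]:
    if isinstance(fits, RealGEN):
        out = {}
        for node in fits.nodes:
            b = fits.node_basal(node)
            if b is not None:
                out[node] = b
        return out
    if isinstance(fits, Mapping):
        return {str(k): float(v) for k, v in fits.items()}
    raise ValidationError("expected a RealGEN or a node -> basal mapping")


def flag_epigenetic(
    fits_early, fits_later, threshold: float | str = "auto"
) -> EpiFlagReport:
    """Flag nodes whose basal level shifts between stages beyond a threshold.

    ``threshold`` is an absolute value >= 0 or ``"auto"`` (95th percentile of
    the between-stage |delta| distribution).  Flagging is strict: a node is
    flagged when |delta| > threshold.
    """
    early = _basal_map(fits_early)
    later = _basal_map(fits_later)
    shared = sorted(set(early) & set(later))
    if not shared:
        raise ValidationError("no shared fitted nodes between the two stages")

    deltas = np.array([abs(early[n] - later[n]) for n in shared])
    if threshold == "auto":
        thr = float(np.percentile(deltas, 95))
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValidationError("threshold must be >= 0")

    records = [
        EpiRecord(
            node_id=n,
            basal_early=early[n],
            basal_later=later[n],
            delta=float(d),
            flagged=bool(d > thr),
        )
        for n, d in zip(shared, deltas)
    ]
    return EpiFlagReport(records=records, threshold=thr)


@dataclass
class BiomarkerSpec:
    """Desired drug action per biomarker node."""

    actions: dict[str, str]  # node_id -> inhibit | enhance

    def __post_init__(self) -> None:
        for node, action in self.actions.items():
            if action not in _ACTIONS:
                raise ValidationError(
                    f"biomarker {node!r}: unknown action {action!r} "
                    f"(expected one of {_ACTIONS})"
                )


@dataclass
class DrugTargetTable:
    """Rows of (drug, target, effect) with unique (drug, target) pairs."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"drug", "target", "effect"}
        if not required.issubset(self.rows.columns):
            raise ValidationError(f"drug table must have columns {sorted(required)}")
        bad = set(self.rows["effect"]) - set(_ACTIONS)
        if bad:
            raise ValidationError(f"unknown effect labels in drug table: {sorted(bad)}")
        if self.rows.duplicated(subset=["drug", "target"]).any():
            raise ValidationError("duplicate (drug, target) pairs in drug table")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.rows["drug"].unique())


@dataclass
class DrugScore:
    drug: str
    matched: list[str]
    count: int
    rank: int


def score_drugs(biomarkers: BiomarkerSpec, table: DrugTargetTable) -> list[DrugScore]:
    """Rank every drug by biomarker-direction coverage (count desc, name asc)."""
    if table.rows.empty:
        raise ValidationError("drug-target table is empty")
    scored = []
    for drug in table.drugs:
        sub = table.rows[table.rows["drug"] == drug]
        matched = sorted(
            t
            for t, e in zip(sub["target"], sub["effect"])
            if biomarkers.actions.get(t) == e
        )
        scored.append((drug, matched))
    scored.sort(key=lambda dm: (-len(dm[1]), dm[0]))
    return [
        DrugScore(drug=d, matched=m, count=len(m), rank=r + 1)
        for r, (d, m) in enumerate(scored)
    ]


def match_drugs(
    biomarkers: BiomarkerSpec, table: DrugTargetTable, top_n: int = 3
) -> list[DrugScore]:
    """The top-n drugs by matched-biomarker count (the multiple-molecule drug)."""
    if top_n <= 0:
        raise ValidationError("top_n must be positive")
    return score_drugs(biomarkers, table)[:top_n]


# -- file and fixture access ----------------------------------------------


def load_biomarkers(path) -> BiomarkerSpec:
    df = pd.read_csv(path, dtype=str)
    if not {"node_id", "action"}.issubset(df.columns):
        raise ValidationError(f"{path}: biomarker spec needs columns node_id, action")
    if df["node_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate biomarker node ids")
    return BiomarkerSpec(dict(zip(df["node_id"], df["action"])))


def load_drug_table(path) -> DrugTargetTable:
    return DrugTargetTable(pd.read_csv(path, dtype=str))


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("gencore.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str)


def bundled_biomarkers(stage: str) -> BiomarkerSpec:
    """Bundled early/later-stage biomarker direction lists."""
    if stage not in ("early", "later"):
        raise ValidationError(f"unknown stage {stage!r}")
    df = _fixture(f"{stage}_biomarkers.csv")
    return BiomarkerSpec(dict(zip(df["node_id"], df["action"])))


def bundled_drug_table(stage: str) -> DrugTargetTable:
    """Bundled early/later-stage drug -> target-effect tables."""
    if stage not in ("early", "later"):
        raise ValidationError(f"unknown stage {stage!r}")
    return DrugTargetTable(_fixture(f"{stage}_drug_targets.csv"))
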