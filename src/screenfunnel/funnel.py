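"""The screening funnel: ordered filter stages with per-stage reporting.

Default configuration mirrors a docking-score stage (strict < 5.0), a
redocking-score stage (strict < 3.0), a cross-program pose-consistency
stage (symmetry-corrected in-place RMSD < 2.0 Å) and a five-criterion
top-decile consensus vote selecting a 5,000-compound shortlist.  The
RMSD computed by the consistency stage doubles as the fifth voting
criterion by default; a four-criterion vote is available by disabling
``vote_criterion``.

Thresholds are applied to raw stored score values — no sign convention
is imposed on docking scores; direction semantics live entirely in
``CriterionSpec`` and comparator semantics in the stage definition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import yaml

from .consensus_vote import DEFAULT_TOP_FRACTION, build_vote_table, select_top_voted
from .pose_rmsd import (
    DEFAULT_AUTOMORPHISM_CAP,
    NotComparableError,
    Pose,
    pose_consistency,
)
from .score_io import (
    HIGHER_BETTER,
    LOWER_BETTER,
    CriterionSpec,
    HitList,
    ScoreTable,
)

__all__ = [
    "ScoreThresholdStage",
    "RmsdConsistencyStage",
    "VoteStage",
    "FunnelConfig",
    "StageRecord",
    "StageReport",
    "default_criteria",
    "default_config",
    "apply_score_stage",
    "apply_rmsd_stage",
    "run_funnel",
    "load_config",
]

logger = logging.getLogger(__name__)

DEFAULT_RMSD_CUTOFF = 2.0
DEFAULT_SHORTLIST = 5000
RMSD_CRITERION = CriterionSpec("rmsd", LOWER_BETTER)


def default_criteria() -> tuple[CriterionSpec, ...]:
    """The four score-table criteria of the default screen (the fifth,
    pose RMSD, is produced by the consistency stage)."""
    return (
        CriterionSpec("glide", LOWER_BETTER),
        CriterionSpec("ehits", LOWER_BETTER),
        CriterionSpec("ligx", LOWER_BETTER),
        CriterionSpec("pki", HIGHER_BETTER),
    )


@dataclass(frozen=True)
class ScoreThresholdStage:
    criterion: str
    threshold: float
    comparator: str = "lt"  # "lt" (strict, default) or "le"

    def __post_init__(self) -> None:
        if self.comparator not in ("lt", "le"):
            raise ValueError("comparator must be 'lt' or 'le'")
        if not float("-inf") < self.threshold < float("inf"):
            raise ValueError("threshold must be finite")

    @property
    def name(self) -> str:
        return f"score[{self.criterion} {self.comparator} {self.threshold}]"


@dataclass(frozen=True)
class RmsdConsistencyStage:
    cutoff: float = DEFAULT_RMSD_CUTOFF
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP
    vote_criterion: str | None = "rmsd"  # None → RMSD is a filter only

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")

    @property
    def name(self) -> str:
        return f"rmsd[<{self.cutoff} Å]"


@dataclass(frozen=True)
class VoteStage:
    criteria: tuple[str, ...]
    f: float = DEFAULT_TOP_FRACTION
    shortlist: int = DEFAULT_SHORTLIST

    @property
    def name(self) -> str:
        return f"vote[K={len(self.criteria)}, f={self.f}, top {self.shortlist}]"


Stage = Union[ScoreThresholdStage, RmsdConsistencyStage, VoteStage]


@dataclass(frozen=True)
class FunnelConfig:
    stages: tuple[Stage, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("funnel needs at least one stage")


def default_config(
    include_rmsd_vote: bool = True,
    shortlist: int = DEFAULT_SHORTLIST,
) -> FunnelConfig:
    """Score stage (<5.0) → redock stage (<3.0) → RMSD (<2.0 Å) → vote."""
    vote_names = tuple(c.name for c in default_criteria())
    if include_rmsd_vote:
        vote_names = vote_names + (RMSD_CRITERION.name,)
    return FunnelConfig(stages=(
        ScoreThresholdStage("glide", 5.0, "lt"),
        ScoreThresholdStage("ehits", 3.0, "lt"),
        RmsdConsistencyStage(
            vote_criterion=RMSD_CRITERION.name if include_rmsd_vote else None
        ),
        VoteStage(criteria=vote_names, shortlist=shortlist),
    ))


@dataclass(frozen=True)
class StageRecord:
    name: str
    n_in: int
    n_out: int
    params: dict
    dropped: dict  # reason -> count

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("stage cannot create compounds")


@dataclass
class StageReport:
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        if self.stages and record.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {record.name!r} input count {record.n_in} != previous "
                f"survivor count {self.stages[-1].n_out}"
            )
        self.stages.append(record)

    def counts(self) -> list[int]:
        if not self.stages:
            return []
        return [self.stages[0].n_in] + [s.n_out for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input": s.n_in,
                    "surviving": s.n_out,
                    "params": s.params,
                    "dropped": s.dropped,
                }
                for s in self.stages
            ]
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def apply_score_stage(
    table: ScoreTable, stage: ScoreThresholdStage
) -> tuple[ScoreTable, StageRecord]:
    """Keep compounds whose raw value satisfies the comparator; compounds
    with a missing value on the stage criterion are dropped and counted
    separately."""
    col = table.column(stage.criterion)
    present = col.notna()
    if stage.comparator == "lt":
        ok = col < stage.threshold
    else:
        ok = col <= stage.threshold
    keep = present & ok
    survivors = table.subset(col.index[keep])
    record = StageRecord(
        name=stage.name,
        n_in=len(table),
        n_out=len(survivors),
        params={
            "criterion": stage.criterion,
            "threshold": stage.threshold,
            "comparator": stage.comparator,
        },
        dropped={
            "missing_score": int((~present).sum()),
            "threshold": int((present & ~ok).sum()),
        },
    )
    return survivors, record


def apply_rmsd_stage(
    poses_a: Mapping[str, Pose],
    poses_b: Mapping[str, Pose],
    cutoff: float = DEFAULT_RMSD_CUTOFF,
    automorphism_cap: int = DEFAULT_AUTOMORPHISM_CAP,
    ids: list[str] | None = None,
) -> tuple[list[str], dict[str, float], dict[str, int]]:
    """Pose-consistency filter over compounds present in both pose sets.

    Returns (survivor ids, per-compound RMSD for every compared pair,
    drop tallies by reason).  Pose errors demote to "not comparable" per
    compound; nothing passes silently.
    """
    candidates = ids if ids is not None else sorted(set(poses_a) | set(poses_b))
    survivors: list[str] = []
    rmsds: dict[str, float] = {}
    drops = {"unpaired": 0, "not_comparable": 0, "cutoff": 0}
    for cid in candidates:
        if cid not in poses_a or cid not in poses_b:
            drops["unpaired"] += 1
            continue
        try:
            ok, value = pose_consistency(
                poses_a[cid], poses_b[cid], cutoff, cap=automorphism_cap
            )
        except (NotComparableError, ValueError) as exc:
            logger.debug("compound %s not comparable: %s", cid, exc)
            drops["not_comparable"] += 1
            continue
        rmsds[cid] = value
        if ok:
            survivors.append(cid)
        else:
            drops["cutoff"] += 1
    return survivors, rmsds, drops


def run_funnel(
    config: FunnelConfig,
    table: ScoreTable,
    poses_a: Mapping[str, Pose] | None = None,
    poses_b: Mapping[str, Pose] | None = None,
) -> tuple[HitList, StageReport]:
    """Apply the configured stages in order.

    Deterministic given inputs and config.  A stage that eliminates every
    compound yields an empty hit list and a warning, not a crash.
    """
    report = StageReport()
    hits: HitList | None = None
    for stage in config.stages:
        if isinstance(stage, ScoreThresholdStage):
            table, record = apply_score_stage(table, stage)
        elif isinstance(stage, RmsdConsistencyStage):
            if poses_a is None or poses_b is None:
                raise ValueError("RMSD stage configured but pose sets not provided")
            survivors, rmsds, drops = apply_rmsd_stage(
                poses_a, poses_b, stage.cutoff, stage.automorphism_cap,
                ids=table.compounds,
            )
            n_in = len(table)
            table = table.subset(survivors)
            if stage.vote_criterion is not None:
                table = table.with_column(
                    CriterionSpec(stage.vote_criterion, LOWER_BETTER),
                    {cid: rmsds[cid] for cid in survivors},
                )
            record = StageRecord(
                name=stage.name,
                n_in=n_in,
                n_out=len(table),
                params={
                    "cutoff": stage.cutoff,
                    "automorphism_cap": stage.automorphism_cap,
                    "vote_criterion": stage.vote_criterion,
                },
                dropped=drops,
            )
        elif isinstance(stage, VoteStage):
            n_in = len(table)
            if n_in == 0:
                hits = HitList(stage.criteria, ())
                record = StageRecord(stage.name, 0, 0,
                                     params={"f": stage.f, "shortlist": stage.shortlist},
                                     dropped={})
            else:
                vt = build_vote_table(table, criteria=stage.criteria, f=stage.f)
                hits = select_top_voted(vt, stage.shortlist)
                record = StageRecord(
                    name=stage.name,
                    n_in=n_in,
                    n_out=len(hits),
                    params={"f": stage.f, "shortlist": stage.shortlist,
                            "criteria": list(stage.criteria)},
                    dropped={
                        "missing_score": len(vt.excluded),
                        "vote": n_in - len(vt.excluded) - len(hits),
                    },
                )
            table = table.subset(hits.ids())
        else:  # pragma: no cover
            raise TypeError(f"unknown stage type {type(stage).__name__}")
        report.add(record)
        logger.info("%s: %d -> %d", record.name, record.n_in, record.n_out)
        if record.n_out == 0:
            logger.warning("stage %s eliminated every compound", record.name)
    if hits is None:
        # no voting stage configured: emit survivors as a vote-0 hit list
        names = tuple(c.name for c in table.criteria)
        hits = HitList((), tuple())
        logger.warning("funnel has no voting stage; returning empty hit list "
                       "(survivors: %d over criteria %s)", len(table), names)
    return hits, report


# ---------------------------------------------------------------------------
# YAML configuration (schema_version 1)


def load_config(path: str | Path) -> tuple[FunnelConfig, tuple[CriterionSpec, ...]]:
    """Read a funnel config.  Returns (config, score-table criteria)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("schema_version") != 1:
        raise ValueError(f"{path}: expected mapping with schema_version: 1")
    criteria = tuple(
        CriterionSpec(c["name"], c["direction"], c.get("source_tag"))
        for c in doc.get("criteria", [])
    ) or default_criteria()
    stages: list[Stage] = []
    for s in doc["stages"]:
        kind = s["kind"]
        if kind == "score_threshold":
            stages.append(ScoreThresholdStage(
                s["criterion"], float(s["threshold"]), s.get("comparator", "lt")))
        elif kind == "rmsd_consistency":
            stages.append(RmsdConsistencyStage(
                float(s.get("cutoff", DEFAULT_RMSD_CUTOFF)),
                int(s.get("automorphism_cap", DEFAULT_AUTOMORPHISM_CAP)),
                s.get("vote_criterion", "rmsd"),
            ))
        elif kind == "consensus_vote":
            stages.append(VoteStage(
                tuple(s["criteria"]),
                float(s.get("f", DEFAULT_TOP_FRACTION)),
                int(s.get("shortlist", DEFAULT_SHORTLIST)),
            ))
        else:
            raise ValueError(f"{path}: unknown stage kind {kind!r}")
    return FunnelConfig(tuple(stages), seed=int(doc.get("seed", 0))), criteria
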