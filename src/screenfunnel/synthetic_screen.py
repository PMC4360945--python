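"""Synthetic screening libraries: correlated criterion scores with
planted binders, and pose pairs with controlled perturbation.

Scores follow a one-factor model: a latent affinity per compound, a
standardised shift of −δ for binders (lower raw score = more
favourable), and per-criterion noise giving pairwise inter-criterion
correlation ρ.  Higher-is-better criteria are emulated by negating the
column, keeping a single internal code path.

Pose pairs reuse hard-coded templates (no chemistry toolkit): pose A is
the reference; pose B adds per-atom Gaussian noise, relabels atoms by a
random graph automorphism, and with probability ``p_inconsistent``
suffers a gross rigid displacement that must exceed the consistency
cutoff.

All randomness flows from one ``numpy.random.default_rng(seed)``; the
same config regenerates a bit-identical library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .funnel import DEFAULT_RMSD_CUTOFF, default_criteria
from .pose_rmsd import AtomMapping, MolecularGraph, Pose, enumerate_automorphisms
from .score_io import (
    HIGHER_BETTER,
    CriterionSpec,
    PoseRecord,
    ScoreTable,
    write_score_csv,
    write_sdf_poses,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticLibrary",
    "TEMPLATES",
    "generate_scores",
    "generate_pose_pair",
    "generate_library",
    "write_library",
    "expected_vote_distribution",
]

# Built-in pose templates: fixed heavy-atom graphs + reference coordinates (Å).
# linear_c4: zig-zag butane backbone; ring_c6: regular hexagon, 1.4 Å sides;
# branched_c5: neopentane-like star; hetero_oc2: O-C-C chain with distinct ends.
TEMPLATES: dict[str, tuple[MolecularGraph, np.ndarray]] = {
    "linear_c4": (
        MolecularGraph(("C", "C", "C", "C"), ((0, 1, 1), (1, 2, 1), (2, 3, 1))),
        np.array([[0.0, 0.0, 0.0], [1.54, 0.0, 0.0],
                  [2.31, 1.33, 0.0], [3.85, 1.33, 0.0]]),
    ),
    "ring_c6": (
        MolecularGraph(
            ("C",) * 6,
            ((0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (0, 5, 1)),
        ),
        1.4 * np.array(
            [[np.cos(k * np.pi / 3.0), np.sin(k * np.pi / 3.0), 0.0] for k in range(6)]
        ),
    ),
    "branched_c5": (
        MolecularGraph(("C",) * 5, ((0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1))),
        np.array([[0.0, 0.0, 0.0],
                  [0.89, 0.89, 0.89], [-0.89, -0.89, 0.89],
                  [-0.89, 0.89, -0.89], [0.89, -0.89, -0.89]]),
    ),
    "hetero_oc2": (
        MolecularGraph(("O", "C", "C"), ((0, 1, 1), (1, 2, 1))),
        np.array([[0.0, 0.0, 0.0], [1.43, 0.0, 0.0], [2.20, 1.33, 0.0]]),
    ),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; see module docstring for the score model."""

    n: int = 1000
    k: int = 4
    rho: float = 0.3
    prevalence: float = 0.05
    delta: float = 1.0
    sigma_pose: float = 0.1
    p_inconsistent: float = 0.1
    gross_shift: float = 5.0
    seed: int = 0
    criteria: tuple[CriterionSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("library size n must be >= 1")
        if self.k < 1:
            raise ValueError("need at least one criterion")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.sigma_pose < 0.0:
            raise ValueError("sigma_pose must be >= 0")
        if not 0.0 <= self.p_inconsistent <= 1.0:
            raise ValueError("p_inconsistent must lie in [0, 1]")
        if self.p_inconsistent > 0 and self.gross_shift <= DEFAULT_RMSD_CUTOFF:
            raise ValueError(
                f"gross_shift must exceed the consistency cutoff "
                f"({DEFAULT_RMSD_CUTOFF} Å) when p_inconsistent > 0"
            )
        if self.criteria is not None and len(self.criteria) != self.k:
            raise ValueError("len(criteria) must equal k")

    def effective_criteria(self) -> tuple[CriterionSpec, ...]:
        if self.criteria is not None:
            return self.criteria
        return tuple(
            CriterionSpec(f"crit{i + 1}", "lower_better") for i in range(self.k)
        )

    def to_dict(self) -> dict:
        d = {
            "n": self.n, "k": self.k, "rho": self.rho,
            "prevalence": self.prevalence, "delta": self.delta,
            "sigma_pose": self.sigma_pose, "p_inconsistent": self.p_inconsistent,
            "gross_shift": self.gross_shift, "seed": self.seed,
            "criteria": [
                {"name": c.name, "direction": c.direction}
                for c in self.effective_criteria()
            ],
        }
        return d


def _compound_ids(n: int) -> list[str]:
    width = max(6, len(str(n)))
    return [f"CPD-{i + 1:0{width}d}" for i in range(n)]


def generate_scores(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ScoreTable, pd.Series]:
    """Score table plus ground-truth binder labels.

    Latent affinity a_i ~ N(0,1), shifted by −δ for binders; criterion k
    value is sqrt(ρ)·a_i + sqrt(1−ρ)·ε_ik.  Higher-better criteria are
    negated so that favourable stays favourable.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    specs = cfg.effective_criteria()
    ids = _compound_ids(cfg.n)
    labels = rng.random(cfg.n) < cfg.prevalence
    latent = rng.standard_normal(cfg.n) - cfg.delta * labels
    eps = rng.standard_normal((cfg.n, cfg.k))
    scores = np.sqrt(cfg.rho) * latent[:, None] + np.sqrt(1.0 - cfg.rho) * eps
    for j, spec in enumerate(specs):
        if spec.direction == HIGHER_BETTER:
            scores[:, j] = -scores[:, j]
    df = pd.DataFrame(scores, index=pd.Index(ids, name="id"),
                      columns=[c.name for c in specs])
    table = ScoreTable(df, specs)
    return table, pd.Series(labels, index=df.index, name="is_binder")


# automorphism lists are template-fixed; memoised for determinism + speed
_AUTO_CACHE: dict[str, list[AtomMapping]] = {}


def _template_automorphisms(name: str) -> list[AtomMapping]:
    if name not in _AUTO_CACHE:
        _AUTO_CACHE[name] = enumerate_automorphisms(TEMPLATES[name][0])
    return _AUTO_CACHE[name]


def generate_pose_pair(
    template: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Pose, Pose]:
    """A reference pose and a perturbed, automorphism-relabelled copy."""
    if template not in TEMPLATES:
        raise KeyError(
            f"unknown template {template!r}; available: {sorted(TEMPLATES)}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    graph, ref = TEMPLATES[template]
    noisy = ref + rng.normal(0.0, cfg.sigma_pose, size=ref.shape)
    if rng.random() < cfg.p_inconsistent:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        noisy = noisy + cfg.gross_shift * direction
    autos = _template_automorphisms(template)
    alpha = autos[rng.integers(len(autos))]
    # relabel by the automorphism: atom i of pose B is template atom alpha(i)
    scrambled = noisy[list(alpha.perm)]
    return Pose(graph, ref.copy()), Pose(graph, scrambled)


@dataclass(frozen=True)
class SyntheticLibrary:
    config: SyntheticConfig
    score_table: ScoreTable
    labels: pd.Series
    poses_a: dict[str, Pose]
    poses_b: dict[str, Pose]
    templates: dict[str, str]  # compound id -> template name


def generate_library(cfg: SyntheticConfig) -> SyntheticLibrary:
    """Scores, labels and pose pairs for every compound, one seeded RNG."""
    rng = np.random.default_rng(cfg.seed)
    table, labels = generate_scores(cfg, rng)
    names = sorted(TEMPLATES)
    poses_a: dict[str, Pose] = {}
    poses_b: dict[str, Pose] = {}
    templates: dict[str, str] = {}
    for i, cid in enumerate(table.compounds):
        tname = names[i % len(names)]
        a, b = generate_pose_pair(tname, cfg, rng)
        poses_a[cid], poses_b[cid] = a, b
        templates[cid] = tname
    return SyntheticLibrary(cfg, table, labels, poses_a, poses_b, templates)


def write_library(lib: SyntheticLibrary, out_dir: str | Path) -> None:
    """scores.csv, poses_a.sdf, poses_b.sdf, labels.csv, log.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_score_csv(lib.score_table, out / "scores.csv")
    for fname, poses in (("poses_a.sdf", lib.poses_a), ("poses_b.sdf", lib.poses_b)):
        records = [
            PoseRecord(cid, pose, {}, record_index=i)
            for i, (cid, pose) in enumerate(poses.items())
        ]
        write_sdf_poses(records, out / fname)
    lib.labels.astype(int).to_csv(out / "labels.csv", index_label="id")
    (out / "log.json").write_text(
        json.dumps({"config": lib.config.to_dict()}, indent=2) + "\n"
    )


def expected_vote_distribution(k: int, f: float) -> np.ndarray:
    """Binomial(K, f) mass function over votes 0..K — the analytic null
    for independent continuous criteria without boundary ties."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < f < 1.0:
        raise ValueError("f must lie in (0, 1)")
    return binom.pmf(np.arange(k + 1), k, f)
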