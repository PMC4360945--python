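"""Tabular and structural I/O for the screening funnel.

Score tables are CSV with a mandatory ``id`` column and one column per
scoring criterion.  Poses travel as multi-record SDF V2000 with scores
in SD tags.  Hit lists round-trip through CSV.

Hydrogens are stripped at SDF read time: the two docking programs may
protonate differently, so cross-program comparisons are heavy-atom only.
Missing score cells are recorded as missing, never imputed — downstream
policy lives in the voting and funnel layers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pose_rmsd import MolecularGraph, Pose

__all__ = [
    "CriterionSpec",
    "ScoreTable",
    "PoseRecord",
    "HitEntry",
    "HitList",
    "ScoreTableError",
    "DuplicateCompoundError",
    "SdfFormatError",
    "read_score_csv",
    "write_score_csv",
    "read_sdf_poses",
    "write_sdf_poses",
    "poses_by_id",
    "write_hitlist",
    "read_hitlist",
]

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"


class ScoreTableError(ValueError):
    pass


class DuplicateCompoundError(ScoreTableError):
    pass


class SdfFormatError(ValueError):
    pass


@dataclass(frozen=True)
class CriterionSpec:
    """A named scoring criterion with an explicit favourable direction."""

    name: str
    direction: str
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("criterion name must be non-empty")
        if self.direction not in (LOWER_BETTER, HIGHER_BETTER):
            raise ValueError(
                f"direction must be '{LOWER_BETTER}' or '{HIGHER_BETTER}', "
                f"got {self.direction!r}"
            )

    @property
    def column(self) -> str:
        """Column / SD-tag name carrying this criterion's values."""
        return self.source_tag or self.name


class ScoreTable:
    """Per-compound values for a fixed set of criteria.

    Backed by a float DataFrame indexed by compound id; NaN marks a
    missing value.  Compound ids are unique, order is preserved.
    """

    def __init__(self, values: pd.DataFrame, criteria: Sequence[CriterionSpec]):
        criteria = tuple(criteria)
        if not criteria:
            raise ScoreTableError("criteria list must be non-empty")
        names = [c.name for c in criteria]
        if len(set(names)) != len(names):
            raise ScoreTableError("duplicate criterion names")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise DuplicateCompoundError(f"duplicate compound id {dup!r}")
        missing = [n for n in names if n not in values.columns]
        if missing:
            raise ScoreTableError(f"values lack criterion column(s) {missing}")
        values = values.loc[:, names].astype(float)
        with np.errstate(invalid="ignore"):
            if np.isinf(values.to_numpy()).any():
                raise ScoreTableError("score values must be finite")
        self._values = values
        self._criteria = criteria

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def criteria(self) -> tuple[CriterionSpec, ...]:
        return self._criteria

    @property
    def compounds(self) -> list[str]:
        return list(self._values.index)

    def criterion(self, name: str) -> CriterionSpec:
        for c in self._criteria:
            if c.name == name:
                return c
        raise KeyError(f"unknown criterion {name!r}")

    def column(self, name: str) -> pd.Series:
        self.criterion(name)
        return self._values[name]

    def subset(self, ids: Iterable[str]) -> "ScoreTable":
        keep = set(ids)
        mask = [c in keep for c in self._values.index]
        return ScoreTable(self._values.loc[mask], self._criteria)

    def with_column(self, spec: CriterionSpec, values: Mapping[str, float]) -> "ScoreTable":
        """New table with an extra criterion column (e.g. pose RMSD)."""
        if any(c.name == spec.name for c in self._criteria):
            raise ScoreTableError(f"criterion {spec.name!r} already present")
        df = self._values.copy()
        df[spec.name] = pd.Series(values, dtype=float).reindex(df.index)
        return ScoreTable(df, self._criteria + (spec,))

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._values.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return self._criteria == other._criteria and self._values.equals(other._values)


def read_score_csv(path: str | Path, criteria: Sequence[CriterionSpec]) -> ScoreTable:
    """Load a score table from CSV.

    The header must contain ``id`` plus one column per criterion source
    name.  Empty cells become missing values; non-numeric cells are a
    hard error carrying the offending line number.
    """
    criteria = tuple(criteria)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ScoreTableError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if "id" not in header:
            raise ScoreTableError(f"{path}: no 'id' column in header")
        id_col = header.index("id")
        col_idx: dict[str, int] = {}
        for spec in criteria:
            if spec.column not in header:
                raise ScoreTableError(
                    f"{path}: criterion column {spec.column!r} missing from header"
                )
            col_idx[spec.name] = header.index(spec.column)

        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            cid = row[id_col].strip()
            if cid in seen:
                raise DuplicateCompoundError(
                    f"{path}:{lineno}: duplicate compound id {cid!r}"
                )
            seen.add(cid)
            ids.append(cid)
            vals: list[float] = []
            for spec in criteria:
                cell = row[col_idx[spec.name]].strip() if col_idx[spec.name] < len(row) else ""
                if not cell:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ScoreTableError(
                        f"{path}:{lineno}: non-numeric score {cell!r} "
                        f"for criterion {spec.name!r}"
                    ) from None
            rows.append(vals)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"),
                      columns=[c.name for c in criteria], dtype=float)
    return ScoreTable(df, criteria)


def write_score_csv(table: ScoreTable, path: str | Path) -> None:
    df = table.values.copy()
    df.columns = [c.column for c in table.criteria]
    df.to_csv(path, index_label="id", float_format="%.10g")


# ---------------------------------------------------------------------------
# SDF V2000


@dataclass(frozen=True)
class PoseRecord:
    """One docking pose for one compound from one program (heavy atoms only)."""

    compound_id: str
    pose: Pose
    scores: dict[str, float] = field(default_factory=dict)
    record_index: int = 0

    @property
    def n_atoms(self) -> int:
        return self.pose.n_atoms


_TAG_RE = re.compile(r">\s*<([^>]+)>")
_HYDROGENS = {"H", "D", "T"}


def _parse_record(lines: list[str], idx: int, score_tags: Sequence[str]) -> PoseRecord:
    if len(lines) < 4:
        raise SdfFormatError(f"record {idx}: truncated (no counts line)")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise SdfFormatError(f"record {idx}: V3000 records are not supported")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise SdfFormatError(f"record {idx}: malformed counts line {counts!r}") from None
    atom_end = 4 + n_atoms
    bond_end = atom_end + n_bonds
    if len(lines) < bond_end:
        raise SdfFormatError(
            f"record {idx}: truncated (expected {n_atoms} atoms, {n_bonds} bonds)"
        )

    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for ln in lines[4:atom_end]:
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            el = ln[31:34].strip()
        except (ValueError, IndexError):
            raise SdfFormatError(f"record {idx}: malformed atom line {ln!r}") from None
        if not el:
            raise SdfFormatError(f"record {idx}: atom line without element symbol")
        elements.append(el)
        coords.append((x, y, z))

    bonds: list[tuple[int, int, int]] = []
    for ln in lines[atom_end:bond_end]:
        try:
            i, j, order = int(ln[0:3]), int(ln[3:6]), int(ln[6:9])
        except (ValueError, IndexError):
            raise SdfFormatError(f"record {idx}: malformed bond line {ln!r}") from None
        if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
            raise SdfFormatError(
                f"record {idx}: bond references atom {min(i, j)} outside 1..{n_atoms}"
            )
        bonds.append((i - 1, j - 1, order))

    # heavy-atom filter with index remap
    keep = [k for k, el in enumerate(elements) if el not in _HYDROGENS]
    if not keep:
        raise SdfFormatError(f"record {idx}: zero heavy atoms")
    remap = {old: new for new, old in enumerate(keep)}
    heavy_bonds = tuple(
        (remap[i], remap[j], order)
        for i, j, order in bonds
        if i in remap and j in remap
    )
    graph = MolecularGraph(tuple(elements[k] for k in keep), heavy_bonds)
    pose = Pose(graph, np.array([coords[k] for k in keep], dtype=float))

    wanted = set(score_tags)
    scores: dict[str, float] = {}
    k = bond_end
    while k < len(lines):
        m = _TAG_RE.match(lines[k])
        if m and m.group(1) in wanted:
            tag = m.group(1)
            if k + 1 >= len(lines):
                raise SdfFormatError(f"record {idx}: tag <{tag}> has no value line")
            raw = lines[k + 1].strip()
            try:
                scores[tag] = float(raw)
            except ValueError:
                raise SdfFormatError(
                    f"record {idx}: tag <{tag}> value {raw!r} is not numeric"
                ) from None
        k += 1
    return PoseRecord(title, pose, scores, record_index=idx)


def read_sdf_poses(path: str | Path, score_tags: Sequence[str] = ()) -> list[PoseRecord]:
    """Parse a multi-record SDF V2000 file into heavy-atom pose records.

    The compound id is the (whitespace-stripped) title line.  Multiple
    records may share a title; duplicates are surfaced as-is for the
    caller to resolve (see :func:`poses_by_id`).
    """
    text = Path(path).read_text()
    records: list[PoseRecord] = []
    chunk: list[str] = []
    idx = 0
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if chunk:
                records.append(_parse_record(chunk, idx, score_tags))
                idx += 1
            chunk = []
        else:
            chunk.append(line)
    if any(ln.strip() for ln in chunk):
        raise SdfFormatError(f"record {idx}: truncated record (missing '$$$$')")
    return records


def write_sdf_poses(records: Iterable[PoseRecord], path: str | Path) -> None:
    """Write pose records as SDF V2000 with score tags."""
    out: list[str] = []
    for rec in records:
        g, xyz = rec.pose.graph, rec.pose.coords
        out.append(rec.compound_id)
        out.append("  screenfnl")
        out.append("")
        out.append(f"{g.n_atoms:3d}{len(g.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        for k in range(g.n_atoms):
            x, y, z = xyz[k]
            out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {g.elements[k]:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for i, j, order in g.bonds:
            out.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0  0  0  0")
        out.append("M  END")
        for tag, val in rec.scores.items():
            out.append(f"> <{tag}>")
            out.append(f"{val:.10g}")
            out.append("")
        out.append("$$$$")
    Path(path).write_text("\n".join(out) + "\n")


def poses_by_id(records: Iterable[PoseRecord], on_duplicate: str = "error") -> dict[str, Pose]:
    """Key poses by compound id.  ``on_duplicate``: 'error' or 'first'."""
    if on_duplicate not in ("error", "first"):
        raise ValueError("on_duplicate must be 'error' or 'first'")
    out: dict[str, Pose] = {}
    for rec in records:
        if rec.compound_id in out:
            if on_duplicate == "error":
                raise DuplicateCompoundError(
                    f"multiple poses for compound {rec.compound_id!r}"
                )
            continue
        out[rec.compound_id] = rec.pose
    return out


# ---------------------------------------------------------------------------
# Hit lists


@dataclass(frozen=True)
class HitEntry:
    compound_id: str
    vote: int
    ranks: tuple[int, ...]  # aligned with HitList.criteria; -1 marks "unranked"
    tie_break_key: float


@dataclass(frozen=True)
class HitList:
    """Ordered shortlist: vote desc, then tie-break key asc, then id."""

    criteria: tuple[str, ...]
    entries: tuple[HitEntry, ...]

    def __post_init__(self) -> None:
        for e in self.entries:
            if not 0 <= e.vote <= len(self.criteria):
                raise ValueError(
                    f"vote {e.vote} for {e.compound_id!r} outside [0, {len(self.criteria)}]"
                )
            if len(e.ranks) != len(self.criteria):
                raise ValueError(f"rank vector length mismatch for {e.compound_id!r}")
        keys = [(-e.vote, e.tie_break_key, e.compound_id) for e in self.entries]
        if keys != sorted(keys):
            raise ValueError("hit list entries are not in ranking order")

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return [e.compound_id for e in self.entries]


def write_hitlist(hits: HitList, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "cumulative_vote"]
                   + [f"rank_{c}" for c in hits.criteria] + ["tie_break_key"])
        for e in hits.entries:
            w.writerow([e.compound_id, e.vote, *e.ranks, f"{e.tie_break_key:.12g}"])


def read_hitlist(path: str | Path) -> HitList:
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["id", "cumulative_vote"] or header[-1] != "tie_break_key":
            raise ScoreTableError(f"{path}: not a hit-list CSV")
        criteria = tuple(h.removeprefix("rank_") for h in header[2:-1])
        entries = []
        for row in reader:
            entries.append(HitEntry(
                compound_id=row[0],
                vote=int(row[1]),
                ranks=tuple(int(v) for v in row[2:-1]),
                tie_break_key=float(row[-1]),
            ))
    return HitList(criteria, tuple(entries))
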