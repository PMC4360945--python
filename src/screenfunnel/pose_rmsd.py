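"""Symmetry-corrected, in-place heavy-atom RMSD between docking poses.

Two docking programs produce poses of the same molecule in a common
receptor frame, generally with different atom orderings.  A meaningful
pose-consistency RMSD therefore needs (a) an element- and
adjacency-preserving atom correspondence between the two records and
(b) minimisation over the molecular graph's automorphism group, so that
chemically equivalent atoms (ring symmetry, equivalent methyls) do not
inflate the value.

All RMSD here is *in place* by default: the poses already share the
receptor frame, so no superposition is applied.  A Kabsch-superposed
variant is available behind the ``superpose`` flag but is not part of
the default consistency filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "MolecularGraph",
    "Pose",
    "AtomMapping",
    "NotComparableError",
    "FormulaMismatchError",
    "ConnectivityMismatchError",
    "AutomorphismCapError",
    "find_correspondence",
    "enumerate_automorphisms",
    "in_place_rmsd",
    "superposed_rmsd",
    "symmetry_min_rmsd",
    "pose_consistency",
]

DEFAULT_AUTOMORPHISM_CAP = 10_000


class NotComparableError(ValueError):
    """The two molecular graphs cannot be put in correspondence."""


class FormulaMismatchError(NotComparableError):
    """Heavy-atom element multisets differ."""


class ConnectivityMismatchError(NotComparableError):
    """Same formula but no bond-preserving isomorphism exists."""


class AutomorphismCapError(RuntimeError):
    """More automorphisms than the configured cap."""


@dataclass(frozen=True)
class MolecularGraph:
    """Simple undirected molecular graph over heavy atoms.

    Atoms are indexed 0..n-1 internally (file formats use 1-based
    indices; I/O layers translate).  Bonds are (i, j, order) with i < j.
    """

    elements: tuple[str, ...]
    bonds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.elements)
        if n == 0:
            raise ValueError("molecular graph must contain at least one atom")
        norm = []
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references atom outside 0..{n - 1}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {key[0]} and {key[1]}")
            seen.add(key)
            norm.append((key[0], key[1], order))
        object.__setattr__(self, "bonds", tuple(sorted(norm)))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def formula(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for el in self.elements:
            out[el] = out.get(el, 0) + 1
        return out

    def to_networkx(self, with_order: bool = False) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el)
        for i, j, order in self.bonds:
            if with_order:
                g.add_edge(i, j, order=order)
            else:
                g.add_edge(i, j)
        return g


@dataclass(frozen=True)
class Pose:
    """A molecular graph with 3-D heavy-atom coordinates (Å, receptor frame)."""

    graph: MolecularGraph
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (self.graph.n_atoms, 3):
            raise ValueError(
                f"coordinate array has shape {coords.shape}, "
                f"expected ({self.graph.n_atoms}, 3)"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("pose contains non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.graph.n_atoms


@dataclass(frozen=True)
class AtomMapping:
    """Bijection atoms(A) -> atoms(B), stored as perm[i] = σ(i)."""

    perm: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.perm) != list(range(len(self.perm))):
            raise ValueError("mapping is not a permutation")

    def __len__(self) -> int:
        return len(self.perm)

    def inverse(self) -> "AtomMapping":
        inv = [0] * len(self.perm)
        for i, j in enumerate(self.perm):
            inv[j] = i
        return AtomMapping(tuple(inv))

    def compose(self, inner: "AtomMapping") -> "AtomMapping":
        """self ∘ inner: i -> self(inner(i))."""
        return AtomMapping(tuple(self.perm[j] for j in inner.perm))


def _matcher(a: MolecularGraph, b: MolecularGraph, match_order: bool) -> nx.isomorphism.GraphMatcher:
    nm = nx.isomorphism.categorical_node_match("element", None)
    em = nx.isomorphism.categorical_edge_match("order", None) if match_order else None
    return nx.isomorphism.GraphMatcher(
        a.to_networkx(match_order), b.to_networkx(match_order),
        node_match=nm, edge_match=em,
    )


def find_correspondence(
    a: MolecularGraph, b: MolecularGraph, match_order: bool = False
) -> AtomMapping:
    """One element- and adjacency-preserving isomorphism a -> b.

    Bond orders are ignored unless ``match_order``: docking exports
    frequently disagree on aromatic-bond encoding.

    Raises
    ------
    FormulaMismatchError
        If the heavy-atom element counts differ.
    ConnectivityMismatchError
        If the formulas agree but no isomorphism exists.
    """
    if a.formula() != b.formula():
        raise FormulaMismatchError(
            f"element counts differ: {a.formula()} vs {b.formula()}"
        )
    gm = _matcher(a, b, match_order)
    if not gm.is_isomorphic():
        raise ConnectivityMismatchError(
            "graphs share a formula but are not isomorphic "
            "(connectivity or bond-order divergence)"
        )
    return AtomMapping(tuple(gm.mapping[i] for i in range(a.n_atoms)))


def enumerate_automorphisms(
    g: MolecularGraph,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
    match_order: bool = False,
) -> list[AtomMapping]:
    """All element-preserving automorphisms of ``g``, up to ``cap``."""
    if cap < 1:
        raise ValueError("cap must be a positive integer")
    gm = _matcher(g, g, match_order)
    out: list[AtomMapping] = []
    for mapping in gm.isomorphisms_iter():
        if len(out) >= cap:
            raise AutomorphismCapError(
                f"graph has more than {cap} automorphisms; raise the cap"
            )
        out.append(AtomMapping(tuple(mapping[i] for i in range(g.n_atoms))))
    return out


def in_place_rmsd(a: Pose, b: Pose, m: AtomMapping) -> float:
    """sqrt((1/n) Σ ||x_i − y_σ(i)||²) with NO superposition."""
    if len(m) != a.n_atoms or a.n_atoms != b.n_atoms:
        raise ValueError(
            f"mapping length {len(m)} does not fit poses of "
            f"{a.n_atoms} and {b.n_atoms} atoms"
        )
    diff = a.coords - b.coords[list(m.perm)]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def superposed_rmsd(a: Pose, b: Pose, m: AtomMapping) -> float:
    """Kabsch-superposed RMSD (NOT used by the default consistency filter)."""
    if len(m) != a.n_atoms or a.n_atoms != b.n_atoms:
        raise ValueError("mapping length does not fit the poses")
    x = a.coords - a.coords.mean(axis=0)
    y = b.coords[list(m.perm)]
    y = y - y.mean(axis=0)
    h = y.T @ x
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = x - y @ rot
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def symmetry_min_rmsd(
    a: Pose,
    b: Pose,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
    match_order: bool = False,
    superpose: bool = False,
) -> float:
    """Minimum RMSD over the found correspondence composed with every
    automorphism of ``a``'s graph."""
    sigma = find_correspondence(a.graph, b.graph, match_order=match_order)
    autos = enumerate_automorphisms(a.graph, cap=cap, match_order=match_order)
    metric = superposed_rmsd if superpose else in_place_rmsd
    return min(metric(a, b, sigma.compose(alpha)) for alpha in autos)


def pose_consistency(
    a: Pose,
    b: Pose,
    cutoff: float,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
    match_order: bool = False,
) -> tuple[bool, float]:
    """Strict pose-consistency test: passes iff RMSD < cutoff.

    Boundary equality fails; non-isomorphic pairs raise
    :class:`NotComparableError` and must be handled by the caller,
    never silently passed.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    value = symmetry_min_rmsd(a, b, cap=cap, match_order=match_order)
    return value < cutoff, value


def brute_force_min_rmsd(a: Pose, b: Pose) -> float:
    """Full-factorial oracle: minimum in-place RMSD over ALL element- and
    adjacency-preserving permutations.  Exponential; intended for tests
    on graphs of ≤ 8 heavy atoms only."""
    ga, gb = a.graph, b.graph
    if ga.formula() != gb.formula():
        raise FormulaMismatchError("element counts differ")
    edges_b = {(min(i, j), max(i, j)) for i, j, _ in gb.bonds}
    best = None
    for perm in itertools.permutations(range(gb.n_atoms)):
        if any(ga.elements[i] != gb.elements[perm[i]] for i in range(ga.n_atoms)):
            continue
        mapped = {
            (min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j, _ in ga.bonds
        }
        if mapped != edges_b:
            continue
        val = in_place_rmsd(a, b, AtomMapping(perm))
        best = val if best is None else min(best, val)
    if best is None:
        raise ConnectivityMismatchError("no adjacency-preserving permutation")
    return best
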