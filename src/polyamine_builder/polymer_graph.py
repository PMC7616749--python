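"""Typed monomer trees for branched polyethylenimine (PEI).

Branched PEI is modelled as an acyclic graph of monomer units classified by
their amine chemistry: terminal units (T, primary amines, valence 1), linear
units (L, secondary amines, valence 2) and dendritic units (D, tertiary
amines, valence 3).  During growth a node may carry unused valences ("open
ends"); a *complete* polymer has none.  On any complete tree built from these
valences the handshake lemma fixes ``count(T) = count(D) + 2``.

The degree of branching follows the Hölter definition

    DB = 2 D / (2 D + L)

which is 0 for a linear chain and 1 for a perfect dendrimer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Union

import networkx as nx

__all__ = [
    "UnitKind",
    "PolymerGraph",
    "BondType",
    "AngleType",
    "FragmentSpec",
    "MONOMER_MASS",
    "KIND_MASSES",
    "degree_of_branching",
    "molecular_weight",
    "enumerate_bond_types",
    "enumerate_angle_types",
    "build_capped_fragment",
    "to_smiles",
    "linear_backbone_tree",
]

#: Nominal mass of one ethylenimine repeat unit (Da); commercial MW specs
#: quote nominal repeat-unit masses, so this is the default for all kinds.
MONOMER_MASS = 43.07


class UnitKind(Enum):
    """Monomer unit classes of branched PEI."""

    T = "T"
    L = "L"
    D = "D"

    @property
    def valence(self) -> int:
        return {UnitKind.T: 1, UnitKind.L: 2, UnitKind.D: 3}[self]

    @property
    def amine_class(self) -> str:
        return {
            UnitKind.T: "primary",
            UnitKind.L: "secondary",
            UnitKind.D: "tertiary",
        }[self]

    def __lt__(self, other: "UnitKind") -> bool:
        order = {"T": 0, "L": 1, "D": 2}
        return order[self.value] < order[other.value]

    def __str__(self) -> str:
        return self.value


#: Exact per-kind monomer masses (Da): NH2-CH2 / CH2-NH-CH2 / CH2-N(CH2)-CH2
#: repeat-unit shares, selectable instead of the nominal mass.
KIND_MASSES = {UnitKind.T: 44.08, UnitKind.L: 43.07, UnitKind.D: 42.06}


def _as_kind(k: Union[UnitKind, str]) -> UnitKind:
    return k if isinstance(k, UnitKind) else UnitKind(str(k).upper())


@dataclass(frozen=True)
class BondType:
    """Unordered pair of unit kinds joined by a bond, e.g. L-D."""

    pair: tuple[UnitKind, UnitKind]

    def __init__(self, a: Union[UnitKind, str], b: Union[UnitKind, str]):
        a, b = sorted((_as_kind(a), _as_kind(b)))
        object.__setattr__(self, "pair", (a, b))

    @property
    def is_complete_molecule(self) -> bool:
        """T-T occurs only as the complete ethylenediamine dimer."""
        return self.pair == (UnitKind.T, UnitKind.T)

    def __str__(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"

    @classmethod
    def from_string(cls, s: str) -> "BondType":
        parts = s.strip().split("-")
        if len(parts) != 2:
            raise ValueError(f"not a bond type string: {s!r}")
        return cls(*parts)


@dataclass(frozen=True)
class AngleType:
    """Angle defined by a centre unit (valence >= 2) and two flanking units."""

    center: UnitKind
    flanks: tuple[UnitKind, UnitKind]

    def __init__(
        self,
        flank_a: Union[UnitKind, str],
        center: Union[UnitKind, str],
        flank_b: Union[UnitKind, str],
    ):
        center = _as_kind(center)
        if center.valence < 2:
            raise ValueError("angle centre must have valence >= 2 (L or D)")
        fa, fb = sorted((_as_kind(flank_a), _as_kind(flank_b)))
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "flanks", (fa, fb))

    @property
    def is_complete_molecule(self) -> bool:
        """T-L-T occurs only as the complete diethylenetriamine trimer."""
        return self.center == UnitKind.L and self.flanks == (
            UnitKind.T,
            UnitKind.T,
        )

    def __str__(self) -> str:
        return f"{self.flanks[0]}-{self.center}-{self.flanks[1]}"

    @classmethod
    def from_string(cls, s: str) -> "AngleType":
        parts = s.strip().split("-")
        if len(parts) != 3:
            raise ValueError(f"not an angle type string: {s!r}")
        return cls(parts[0], parts[1], parts[2])


class PolymerGraph:
    """Acyclic graph of typed monomer units with explicit open valences.

    Nodes are integer ids carrying a :class:`UnitKind`; edges are chemical
    bonds.  ``free_valence(n) = valence(kind(n)) - degree(n)`` counts the open
    ends still available for growth at node ``n``.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    def add_node(self, kind: Union[UnitKind, str]) -> int:
        node = self._g.number_of_nodes()
        self._g.add_node(node, kind=_as_kind(kind))
        return node

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-bond not allowed")
        for n in (a, b):
            if n not in self._g:
                raise KeyError(f"unknown node {n}")
            if self.free_valence(n) < 1:
                raise ValueError(
                    f"node {n} ({self.kind(n)}) has no free valence"
                )
        if self._g.has_edge(a, b):
            raise ValueError(f"duplicate bond {a}-{b}")
        self._g.add_edge(a, b)
        if not nx.is_forest(self._g):  # pragma: no cover - guarded by valences
            self._g.remove_edge(a, b)
            raise ValueError(f"bond {a}-{b} would create a cycle")

    def add_child(self, parent: int, kind: Union[UnitKind, str]) -> int:
        """Attach a new unit to an open end of ``parent``."""
        node = self.add_node(kind)
        self.add_edge(parent, node)
        return node

    def copy(self) -> "PolymerGraph":
        other = PolymerGraph()
        other._g = self._g.copy()
        return other

    # -- inspection ----------------------------------------------------

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def nodes(self) -> list[int]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def kind(self, node: int) -> UnitKind:
        return self._g.nodes[node]["kind"]

    def degree(self, node: int) -> int:
        return self._g.degree[node]

    def neighbors(self, node: int) -> list[int]:
        return sorted(self._g.neighbors(node))

    def free_valence(self, node: int) -> int:
        return self.kind(node).valence - self._g.degree[node]

    @property
    def open_ends(self) -> list[tuple[int, int]]:
        """(node_id, free valence count) for every node with open valences."""
        return [
            (n, fv)
            for n in self.nodes
            if (fv := self.free_valence(n)) > 0
        ]

    @property
    def is_complete(self) -> bool:
        return len(self) > 0 and not self.open_ends

    def counts(self) -> dict[UnitKind, int]:
        c = {UnitKind.T: 0, UnitKind.L: 0, UnitKind.D: 0}
        for n in self._g.nodes:
            c[self.kind(n)] += 1
        return c

    def count(self, kind: Union[UnitKind, str]) -> int:
        return self.counts()[_as_kind(kind)]

    def validate(self) -> None:
        """Raise if the graph is not a connected tree of valid valences."""
        if len(self) == 0:
            raise ValueError("empty polymer graph")
        if not nx.is_tree(self._g):
            raise ValueError("polymer graph must be a connected tree")
        for n in self._g.nodes:
            if self.free_valence(n) < 0:
                raise ValueError(f"node {n} exceeds valence of {self.kind(n)}")

    def bond_types(self) -> Iterator[BondType]:
        for a, b in self.edges:
            yield BondType(self.kind(a), self.kind(b))

    def angles(self) -> Iterator[tuple[int, int, int]]:
        """All (i, center, k) angle triples, flanks ordered i < k."""
        for c in self.nodes:
            nbrs = self.neighbors(c)
            for i in range(len(nbrs)):
                for k in range(i + 1, len(nbrs)):
                    yield (nbrs[i], c, nbrs[k])

    def angle_types(self) -> Iterator[AngleType]:
        for i, c, k in self.angles():
            yield AngleType(self.kind(i), self.kind(c), self.kind(k))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [[n, str(self.kind(n))] for n in self.nodes],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PolymerGraph":
        g = cls()
        ids = {}
        for node_id, kind in doc["nodes"]:
            ids[node_id] = g.add_node(kind)
        for a, b in doc["edges"]:
            g.add_edge(ids[a], ids[b])
        return g

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PolymerGraph":
        try:
            doc = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                doc = json.load(fh)
        return cls.from_dict(doc)


@dataclass(frozen=True)
class FragmentSpec:
    """A bond or angle realized as a minimal T-capped complete polymer."""

    target: Union[BondType, AngleType]
    graph: PolymerGraph = field(compare=False)
    core: tuple[int, ...] = ()


# ----------------------------------------------------------------------
# operations


def degree_of_branching(graph: PolymerGraph) -> float:
    """Hölter degree of branching DB = 2D / (2D + L) of a complete polymer.

    Returns 0 for purely linear polymers (D = 0).  Raises for degenerate
    molecules containing only terminal units (the ethylenediamine dimer),
    where no branching measure is defined.
    """
    graph.validate()
    if not graph.is_complete:
        raise ValueError("degree of branching requires a complete polymer")
    c = graph.counts()
    d, l = c[UnitKind.D], c[UnitKind.L]
    if d == 0 and l == 0:
        raise ValueError(
            "degenerate molecule of terminal units only: DB undefined"
        )
    if d == 0:
        return 0.0
    return 2.0 * d / (2.0 * d + l)


def molecular_weight(graph: PolymerGraph, per_kind_masses: bool = False) -> float:
    """Molecular weight in Da.

    By default every monomer contributes the nominal ethylenimine repeat mass
    (43.07 Da); with ``per_kind_masses`` the exact per-kind masses are summed.
    """
    if len(graph) == 0:
        raise ValueError("empty polymer graph")
    if per_kind_masses:
        return sum(KIND_MASSES[graph.kind(n)] for n in graph.nodes)
    return len(graph) * MONOMER_MASS


def enumerate_bond_types(
    allow_complete_molecules: bool = False,
) -> set[BondType]:
    """All bond types over {T, L, D}.

    Inside a polymer of four or more monomers a T-T bond cannot occur (it is
    the complete dimer); it is included only with ``allow_complete_molecules``.
    """
    kinds = list(UnitKind)
    out = set()
    for i, a in enumerate(kinds):
        for b in kinds[i:]:
            bt = BondType(a, b)
            if bt.is_complete_molecule and not allow_complete_molecules:
                continue
            out.add(bt)
    return out


def enumerate_angle_types(
    allow_complete_molecules: bool = False,
) -> set[AngleType]:
    """All angle types: centre in {L, D}, unordered flank pairs.

    The T-L-T angle occurs only as the complete trimer and is excluded unless
    ``allow_complete_molecules`` is set.
    """
    kinds = list(UnitKind)
    out = set()
    for center in (UnitKind.L, UnitKind.D):
        for i, fa in enumerate(kinds):
            for fb in kinds[i:]:
                at = AngleType(fa, center, fb)
                if at.is_complete_molecule and not allow_complete_molecules:
                    continue
                out.add(at)
    return out


def build_capped_fragment(target: Union[BondType, AngleType]) -> FragmentSpec:
    """Realize a bond or angle as its minimal complete polymer.

    The core units are placed and every residual valence is saturated with a
    terminal (T) cap, mirroring how representative fragments are cut out of a
    larger model molecule for atomistic reference simulations.
    """
    if target.is_complete_molecule:
        raise ValueError(
            f"{target} is a complete molecule, not a fragment target"
        )
    g = PolymerGraph()
    if isinstance(target, BondType):
        a = g.add_node(target.pair[0])
        b = g.add_node(target.pair[1])
        g.add_edge(a, b)
        core = (a, b)
    elif isinstance(target, AngleType):
        c = g.add_node(target.center)
        fa = g.add_child(c, target.flanks[0])
        fb = g.add_child(c, target.flanks[1])
        core = (fa, c, fb)
    else:
        raise TypeError(f"unsupported fragment target: {target!r}")
    for node, fv in list(g.open_ends):
        for _ in range(fv):
            g.add_child(node, UnitKind.T)
    assert g.is_complete
    return FragmentSpec(target=target, graph=g, core=core)


def to_smiles(graph: PolymerGraph) -> str:
    """Connectivity SMILES of a complete polymer.

    Each monomer contributes one nitrogen and each bond an ethylene (CC)
    bridge, so the string has exactly one N per monomer and two C per edge.
    Traversal is depth-first from the lowest-numbered leaf (a terminal unit
    in any complete polymer of three or more monomers, so linear chains come
    out unparenthesized), branches in node-id order; the string is valid
    SMILES but not canonicalized.
    """
    graph.validate()
    if not graph.is_complete:
        raise ValueError("SMILES requires a complete polymer (no open ends)")

    leaves = [n for n in graph.nodes if graph.degree(n) <= 1]
    root = leaves[0] if leaves else graph.nodes[0]

    def emit(node: int, parent: int | None) -> str:
        children = [n for n in graph.neighbors(node) if n != parent]
        s = "N"
        for child in children[:-1]:
            s += f"(CC{emit(child, node)})"
        if children:
            s += f"CC{emit(children[-1], node)}"
        return s

    return emit(root, None)


def linear_backbone_tree(n_dendritic: int, n_linear: int) -> PolymerGraph:
    """Deterministic complete polymer with given D and L counts.

    Builds a backbone chain with linear units at both ends and all dendritic
    units in the interior, then caps every residual valence with terminal
    units (adding exactly ``n_dendritic + 2`` of them).  Useful for
    constructing worked molecules of a prescribed composition.
    """
    if n_dendritic < 0 or n_linear < 0:
        raise ValueError("unit counts must be non-negative")
    g = PolymerGraph()
    if n_dendritic + n_linear == 0:
        # ethylenediamine: the only all-T complete polymer
        a = g.add_node(UnitKind.T)
        g.add_child(a, UnitKind.T)
        return g
    if n_dendritic > 0 and n_linear < 2:
        raise ValueError(
            "backbone construction needs >= 2 linear units to host interior "
            "dendritic units"
        )
    backbone: list[UnitKind] = []
    if n_linear >= 2:
        interior = [UnitKind.D] * n_dendritic + [UnitKind.L] * (n_linear - 2)
        backbone = [UnitKind.L] + interior + [UnitKind.L]
    else:
        backbone = [UnitKind.L] * n_linear
    prev = g.add_node(backbone[0])
    for kind in backbone[1:]:
        prev = g.add_child(prev, kind)
    for node, fv in list(g.open_ends):
        for _ in range(fv):
            g.add_child(node, UnitKind.T)
    assert g.is_complete
    return g
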