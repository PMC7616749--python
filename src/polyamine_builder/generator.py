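"""Stochastic growth of branched PEI to target molecular weight and branching.

Growth starts from an initiator — a secondary amine (L) with two open ends —
and proceeds breadth-first over all open ends, mimicking chemical
polymerization growing on every branch in parallel.  At each open end a
termination draw (probability ``p_term``) may cap the branch with a terminal
unit; otherwise a dendritic unit is added with probability

    p_D = DB / (2 - DB)

(derived from the Hölter relation DB = 2D/(2D+L): additions in the ratio
D:L = p_D : 1-p_D give the requested DB in expectation) and a linear unit
otherwise.  Once the projected mass reaches the target, all remaining open
ends are capped with terminal units.  Because a high termination probability
can end polymerization prematurely, multiple attempts are made before giving
up.

Coordinates are embedded by breadth-first placement at the bonded-parameter
equilibrium distances; bead overlaps are permitted — relaxing them is the MD
engine's soft-core minimization job, not ours.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .parametrize import ParamTable
from .polymer_graph import (
    MONOMER_MASS,
    PolymerGraph,
    UnitKind,
    degree_of_branching,
    molecular_weight,
)

__all__ = [
    "GrowthConfig",
    "EmbeddedPolymer",
    "EnsembleSummary",
    "GrowthError",
    "branching_probability",
    "grow_polymer",
    "generate_ensemble",
    "embed_coordinates",
]

PH_PRESETS = (5.5, 7.4)


class GrowthError(RuntimeError):
    """Target mass not reached; carries the best attempt's mass."""

    def __init__(self, message: str, best_mass: float | None = None):
        super().__init__(message)
        self.best_mass = best_mass


@dataclass
class GrowthConfig:
    """User configuration for one polymer build.

    ``mw_tolerance`` defaults to two monomer masses: the stopping rule can
    overshoot the target by at most two monomers (a dendritic addition), so
    that is the tightest tolerance every attempt can satisfy.
    """

    target_mw: float
    target_db: float
    p_term: float = 0.05
    max_attempts: int = 100
    mw_tolerance: float = 2 * MONOMER_MASS
    seed: int = 0
    ph_preset: Optional[float] = None

    def __post_init__(self) -> None:
        if self.target_mw <= 0:
            raise ValueError("target_mw must be positive")
        if not 0.0 <= self.target_db <= 1.0:
            raise ValueError("target_db must lie in [0, 1]")
        if not 0.0 <= self.p_term <= 1.0:
            raise ValueError("p_term must lie in [0, 1]")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if self.mw_tolerance < MONOMER_MASS:
            raise ValueError("mw_tolerance must be at least one monomer mass")
        if self.ph_preset is not None and self.ph_preset not in PH_PRESETS:
            raise ValueError(
                f"ph_preset must be one of {PH_PRESETS}, got {self.ph_preset}"
            )


@dataclass
class EmbeddedPolymer:
    """A polymer graph with per-node 3D coordinates (nm) in a cubic box."""

    graph: PolymerGraph
    coordinates: np.ndarray  # (n, 3), row i -> node id graph.nodes[i]
    box: np.ndarray  # (3,) box vectors in nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if len(self.graph) == 0:
            raise ValueError("empty polymer cannot be embedded")
        if self.coordinates.shape != (len(self.graph), 3):
            raise ValueError("coordinates must be (n_nodes, 3)")
        if self.box.shape != (3,):
            raise ValueError("box must be a 3-vector")


def branching_probability(target_db: float) -> float:
    """Per-addition probability of a dendritic unit for a target DB."""
    if not 0.0 <= target_db <= 1.0:
        raise ValueError("target_db must lie in [0, 1]")
    return target_db / (2.0 - target_db)


def _grow_once(config: GrowthConfig, rng: np.random.Generator) -> PolymerGraph:
    p_branch = branching_probability(config.target_db)
    g = PolymerGraph()
    initiator = g.add_node(UnitKind.L)
    # FIFO queue of open valences, one entry per free slot
    queue: deque[int] = deque([initiator, initiator])

    def projected_mass() -> float:
        # mass if growth stopped now and every open end were T-capped
        return (len(g) + len(queue)) * MONOMER_MASS

    while queue and projected_mass() < config.target_mw:
        node = queue.popleft()
        if rng.random() < config.p_term:
            g.add_child(node, UnitKind.T)
            continue
        if rng.random() < p_branch:
            child = g.add_child(node, UnitKind.D)
            queue.append(child)
            queue.append(child)
        else:
            child = g.add_child(node, UnitKind.L)
            queue.append(child)
    while queue:
        g.add_child(queue.popleft(), UnitKind.T)
    return g


def grow_polymer(config: GrowthConfig) -> PolymerGraph:
    """Grow one complete branched polymer matching the configured target mass.

    Deterministic for a given config and seed.  Raises :class:`GrowthError`
    reporting the best attempt's mass when the termination probability ends
    polymerization prematurely in every attempt.
    """
    rng = np.random.default_rng(config.seed)
    best_mass = None
    for _ in range(config.max_attempts):
        g = _grow_once(config, rng)
        mass = molecular_weight(g)
        if abs(mass - config.target_mw) <= config.mw_tolerance:
            return g
        if best_mass is None or abs(mass - config.target_mw) < abs(
            best_mass - config.target_mw
        ):
            best_mass = mass
    raise GrowthError(
        f"target MW {config.target_mw:.1f} Da not reached within "
        f"{config.mw_tolerance:.1f} Da after {config.max_attempts} attempts; "
        f"best attempt: {best_mass:.1f} Da",
        best_mass=best_mass,
    )


@dataclass
class EnsembleSummary:
    n: int
    mean_db: float
    sd_db: float
    mean_mw: float
    sd_mw: float


def generate_ensemble(
    config: GrowthConfig, n: int
) -> tuple[list[PolymerGraph], EnsembleSummary]:
    """Grow ``n`` independent polymers from sequential sub-seeds.

    Member ``i`` uses seed ``config.seed + i``; summary statistics cover the
    realized degrees of branching and molecular weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    graphs = []
    for i in range(n):
        member = GrowthConfig(
            target_mw=config.target_mw,
            target_db=config.target_db,
            p_term=config.p_term,
            max_attempts=config.max_attempts,
            mw_tolerance=config.mw_tolerance,
            seed=config.seed + i,
            ph_preset=config.ph_preset,
        )
        graphs.append(grow_polymer(member))
    dbs = np.array([degree_of_branching(g) for g in graphs])
    mws = np.array([molecular_weight(g) for g in graphs])
    summary = EnsembleSummary(
        n=n,
        mean_db=float(dbs.mean()),
        sd_db=float(dbs.std(ddof=1)) if n > 1 else 0.0,
        mean_mw=float(mws.mean()),
        sd_mw=float(mws.std(ddof=1)) if n > 1 else 0.0,
    )
    return graphs, summary


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - essentially impossible
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


_MIN_BOND_ANGLE_DEG = 30.0


def embed_coordinates(
    graph: PolymerGraph, params: ParamTable, seed: int = 0
) -> EmbeddedPolymer:
    """Place beads breadth-first at bonded equilibrium distances.

    Each child sits exactly at its bond type's equilibrium distance from its
    parent, in a random (seeded) direction kept more than 30 degrees away
    from the incoming bond — a geometric sanity constraint, not an energy
    minimization; overlapping beads are allowed.  The cubic box edge is the
    maximum coordinate extent plus a 2 nm margin and all beads are shifted
    inside it.
    """
    graph.validate()
    if not graph.is_complete:
        raise ValueError("embedding requires a complete polymer")
    for bt in sorted(set(graph.bond_types()), key=str):
        params.get(bt)  # raises KeyError naming the missing type

    rng = np.random.default_rng(seed)
    nodes = graph.nodes
    index = {n: i for i, n in enumerate(nodes)}
    pos = np.zeros((len(nodes), 3))
    root = nodes[0]
    parent_of: dict[int, int] = {root: -1}
    queue = deque([root])
    visited = {root}
    while queue:
        node = queue.popleft()
        for child in graph.neighbors(node):
            if child in visited:
                continue
            visited.add(child)
            parent_of[child] = node
            r_eq = params.get(_bond_type(graph, node, child)).equilibrium
            grand = parent_of[node]
            incoming = None
            if grand >= 0:
                incoming = pos[index[node]] - pos[index[grand]]
                incoming = incoming / np.linalg.norm(incoming)
            for _ in range(1000):
                direction = _random_unit_vector(rng)
                if incoming is None:
                    break
                # angle at the parent between grandparent and the new child
                cos_angle = float(np.dot(-incoming, direction))
                angle = np.degrees(np.arccos(np.clip(cos_angle, -1.0, 1.0)))
                if angle > _MIN_BOND_ANGLE_DEG:
                    break
            pos[index[child]] = pos[index[node]] + r_eq * direction
            queue.append(child)

    margin = 2.0
    extent = float(np.max(pos.max(axis=0) - pos.min(axis=0))) if len(nodes) > 1 else 0.0
    edge = extent + margin
    shift = -pos.min(axis=0) + margin / 2.0
    pos = pos + shift
    box = np.array([edge, edge, edge])
    return EmbeddedPolymer(graph=graph, coordinates=pos, box=box)


def _bond_type(graph: PolymerGraph, a: int, b: int):
    from .polymer_graph import BondType

    return BondType(graph.kind(a), graph.kind(b))
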