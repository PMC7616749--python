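"""pH-preset protonation: bead swaps, charge bookkeeping, pKa annotation.

Each monomer maps to one Martini 3 bead; protonation swaps the neutral bead
for its +1 charged variant:

    terminal  (primary amine)   TN6d -> TQ5d   (tiny)
    linear    (secondary amine) SN4  -> SQ4p   (small)
    dendritic (tertiary amine)  SN3a -> SQ3p   (small)

Two pH presets fix the protonated fraction per amine class — at pH 7.4, 66%
of primary and 33% of secondary amines are charged; at the endolysosomal
pH 5.5, 100% of primary, 66% of secondary and 33% of tertiary amines.
Which individual amines are protonated is chosen uniformly at random with a
stated seed; counts are rounded half-up.  For downstream titratable-bead
tooling each amine also carries a pKa: 10.6 for primary amines, 10.2 for
secondary and tertiary ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .polymer_graph import PolymerGraph, UnitKind

__all__ = [
    "BeadSpec",
    "BEAD_SPECS",
    "ChargeState",
    "PH_FRACTIONS",
    "PKA_BY_KIND",
    "apply_ph_preset",
    "uncharged_state",
    "total_charge",
    "annotate_titratable",
]


@dataclass(frozen=True)
class BeadSpec:
    kind: UnitKind
    uncharged: str
    charged: str
    size_class: str  # "tiny" | "small"

    @property
    def mass(self) -> float:
        """Martini bead mass by size class (Da): tiny 36, small 54."""
        return {"tiny": 36.0, "small": 54.0}[self.size_class]


BEAD_SPECS: dict[UnitKind, BeadSpec] = {
    UnitKind.T: BeadSpec(UnitKind.T, "TN6d", "TQ5d", "tiny"),
    UnitKind.L: BeadSpec(UnitKind.L, "SN4", "SQ4p", "small"),
    UnitKind.D: BeadSpec(UnitKind.D, "SN3a", "SQ3p", "small"),
}

#: Protonated fraction per amine class at each preset pH.
PH_FRACTIONS: dict[float, dict[str, float]] = {
    7.4: {"primary": 0.66, "secondary": 0.33, "tertiary": 0.0},
    5.5: {"primary": 1.0, "secondary": 0.66, "tertiary": 0.33},
}

PKA_BY_KIND: dict[UnitKind, float] = {
    UnitKind.T: 10.6,
    UnitKind.L: 10.2,
    UnitKind.D: 10.2,
}


@dataclass
class ChargeState:
    """Per-node bead assignment after (optionally) applying a pH preset."""

    beads: dict[int, str]
    charges: dict[int, int]
    preset: Optional[float] = None
    seed: Optional[int] = None

    def bead(self, node: int) -> str:
        return self.beads[node]

    def charge(self, node: int) -> int:
        return self.charges[node]

    @property
    def charged_nodes(self) -> list[int]:
        return sorted(n for n, q in self.charges.items() if q != 0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def uncharged_state(graph: PolymerGraph) -> ChargeState:
    """All-neutral bead assignment (no pH preset applied)."""
    graph.validate()
    beads = {n: BEAD_SPECS[graph.kind(n)].uncharged for n in graph.nodes}
    charges = {n: 0 for n in graph.nodes}
    return ChargeState(beads=beads, charges=charges, preset=None, seed=None)


def apply_ph_preset(
    graph: PolymerGraph, ph: float, seed: int = 0
) -> ChargeState:
    """Assign charged beads per the pH preset's class fractions.

    Per amine class, ``round_half_up(fraction * class_size)`` sites are
    protonated, chosen uniformly at random with the given seed; their bead
    names switch to the charged variant.  Identical (graph, ph, seed) inputs
    yield identical assignments.
    """
    graph.validate()
    if not graph.is_complete:
        raise ValueError("protonation requires a complete polymer")
    if ph not in PH_FRACTIONS:
        supported = sorted(PH_FRACTIONS)
        raise ValueError(f"unsupported pH preset {ph}; supported: {supported}")
    fractions = PH_FRACTIONS[ph]
    rng = np.random.default_rng(seed)
    state = uncharged_state(graph)
    state.preset = ph
    state.seed = seed
    for kind in (UnitKind.T, UnitKind.L, UnitKind.D):
        members = [n for n in graph.nodes if graph.kind(n) == kind]
        if not members:
            continue
        f = fractions[kind.amine_class]
        n_charged = _round_half_up(f * len(members))
        n_charged = min(n_charged, len(members))
        chosen = rng.choice(len(members), size=n_charged, replace=False)
        for i in sorted(chosen):
            node = members[i]
            state.beads[node] = BEAD_SPECS[kind].charged
            state.charges[node] = 1
    return state


def total_charge(state: ChargeState) -> int:
    """Net charge in elementary units: the count of +1 charged beads."""
    return sum(state.charges.values())


def annotate_titratable(graph: PolymerGraph) -> dict[int, float]:
    """Per-node pKa for titratable-bead tooling (10.6 primary, 10.2 else)."""
    graph.validate()
    if not graph.is_complete:
        raise ValueError("annotation requires a complete polymer")
    return {n: PKA_BY_KIND[graph.kind(n)] for n in graph.nodes}
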