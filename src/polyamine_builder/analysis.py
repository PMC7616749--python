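"""Polyplex bookkeeping and post-simulation numerics.

Covers N/P stoichiometry (amine nitrogens of the polycation over phosphates
of the nucleic acid), radius of gyration, free-energy extraction from
potential-of-mean-force curves, and ensemble summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .generator import EmbeddedPolymer
from .polymer_graph import (
    PolymerGraph,
    UnitKind,
    degree_of_branching,
    molecular_weight,
)
from .protonation import BEAD_SPECS, ChargeState, total_charge

__all__ = [
    "NPContext",
    "PMFCurve",
    "np_ratio",
    "duplex_phosphate_count",
    "radius_of_gyration",
    "pmf_delta_g",
    "read_pmf",
    "ensemble_summary",
]


@dataclass
class NPContext:
    """Stoichiometry context for an N/P ratio.

    ``nitrogens_per_molecule`` is the amine nitrogen count of one polymer
    molecule (one per monomer for PEI); ``phosphates`` counts the nucleic
    acid's phosphodiester groups.
    """

    nitrogens_per_molecule: int
    copies: int
    phosphates: int

    def __post_init__(self) -> None:
        if self.nitrogens_per_molecule < 0 or self.copies < 0 or self.phosphates < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_graph(
        cls, graph: PolymerGraph, copies: int, phosphates: int
    ) -> "NPContext":
        return cls(
            nitrogens_per_molecule=len(graph), copies=copies, phosphates=phosphates
        )


def duplex_phosphate_count(strand_lengths: Sequence[int] = (25, 27)) -> int:
    """Internal phosphodiester linkages of a duplex: (nt - 1) per strand.

    The default is the asymmetric 25/27-mer Dicer-substrate siRNA duplex,
    giving 50 phosphates.
    """
    return sum(int(n) - 1 for n in strand_lengths)


def np_ratio(
    ctx: NPContext,
    charged_only: bool = False,
    charge_state: Optional[ChargeState] = None,
) -> float:
    """N/P ratio: (copies x nitrogens per molecule) / phosphates.

    All nitrogens count by default (the conventional definition); with
    ``charged_only`` the protonated amines of ``charge_state`` count instead.
    Exactly linear in copy number.
    """
    if ctx.phosphates <= 0:
        raise ValueError("phosphate count must be positive for an N/P ratio")
    n_per_mol = ctx.nitrogens_per_molecule
    if charged_only:
        if charge_state is None:
            raise ValueError("charged_only requires a charge_state")
        n_per_mol = total_charge(charge_state)
    # copies * (N/P): keeps linearity in copy number exact in floating point
    return ctx.copies * (n_per_mol / ctx.phosphates)


def radius_of_gyration(
    embedded: Union[EmbeddedPolymer, np.ndarray],
    mass_weighted: bool = False,
    masses: Optional[np.ndarray] = None,
) -> float:
    """Radius of gyration sqrt(sum m_i |r_i - r_cm|^2 / sum m_i) in nm.

    Accepts an embedded polymer (bead masses by Martini size class when
    ``mass_weighted``) or a bare (n, 3) coordinate array with optional
    explicit masses.  Unweighted, all masses are equal.
    """
    if isinstance(embedded, EmbeddedPolymer):
        coords = embedded.coordinates
        if mass_weighted and masses is None:
            masses = np.array(
                [BEAD_SPECS[embedded.graph.kind(n)].mass for n in embedded.graph.nodes]
            )
    else:
        coords = np.asarray(embedded, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coordinates must be (n, 3) with n >= 1")
    if not mass_weighted or masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


@dataclass
class PMFCurve:
    """Potential of mean force vs separation, with an unbound-plateau window.

    ``plateau_window`` is a (lo, hi) distance range treated as the unbound
    reference; by default the final 20% of the distance range.
    """

    distance: np.ndarray  # nm, increasing
    energy: np.ndarray  # kJ/mol
    plateau_window: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.distance.shape != self.energy.shape or self.distance.size < 3:
            raise ValueError("distance and energy must be equal-length series, n >= 3")
        if np.any(np.diff(self.distance) <= 0):
            raise ValueError("distance series must be strictly increasing")
        if self.plateau_window is None:
            lo = self.distance[0] + 0.8 * (self.distance[-1] - self.distance[0])
            self.plateau_window = (float(lo), float(self.distance[-1]))
        lo, hi = self.plateau_window
        if lo < self.distance[0] or hi > self.distance[-1] or lo >= hi:
            raise ValueError("plateau window must lie inside the distance range")

    @property
    def plateau_mask(self) -> np.ndarray:
        lo, hi = self.plateau_window
        return (self.distance >= lo) & (self.distance <= hi)


def pmf_delta_g(curve: PMFCurve) -> float:
    """Binding free energy from a PMF: well depth below the unbound plateau.

    The curve is referenced to the plateau mean (invariant under vertical
    shifts); the returned value min(G) - mean(G_plateau) is <= 0, more
    negative meaning more favorable binding.  A global minimum lying inside
    the plateau window (and genuinely below it) makes the reference ill-posed
    and raises.
    """
    mask = curve.plateau_mask
    if not np.any(mask):
        raise ValueError("plateau window contains no samples")
    plateau_mean = float(curve.energy[mask].mean())
    shifted = curve.energy - plateau_mean
    i_min = int(np.argmin(shifted))
    g_min = float(shifted[i_min])
    scale = max(float(np.ptp(curve.energy)), 1.0)
    if mask[i_min] and g_min < -1e-12 * scale:
        raise ValueError(
            "global PMF minimum lies inside the plateau window: "
            "ill-posed unbound reference"
        )
    return min(g_min, 0.0)


def read_pmf(path: Union[str, Path], **kwargs) -> PMFCurve:
    """Read a two-column xvg-style PMF file ('#'/'@' comment lines ignored)."""
    dist, ener = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        fields = line.split()
        dist.append(float(fields[0]))
        ener.append(float(fields[1]))
    return PMFCurve(distance=np.array(dist), energy=np.array(ener), **kwargs)


def ensemble_summary(
    graphs: Sequence[PolymerGraph],
    charge_states: Optional[Sequence[Optional[ChargeState]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-molecule and aggregate statistics of a polymer ensemble.

    Returns a DataFrame with one row per molecule (MW, DB, unit counts,
    total charge) and an aggregate dict; the aggregate DB is the mean of the
    per-molecule DB values.
    """
    if len(graphs) == 0:
        raise ValueError("need at least one graph")
    if charge_states is None:
        charge_states = [None] * len(graphs)
    rows = []
    for g, cs in zip(graphs, charge_states):
        c = g.counts()
        rows.append(
            {
                "monomers": len(g),
                "mw": molecular_weight(g),
                "db": degree_of_branching(g),
                "n_T": c[UnitKind.T],
                "n_L": c[UnitKind.L],
                "n_D": c[UnitKind.D],
                "charge": total_charge(cs) if cs is not None else 0,
            }
        )
    df = pd.DataFrame(rows)
    aggregate = {
        "n": len(df),
        "mean_mw": float(df["mw"].mean()),
        "sd_mw": float(df["mw"].std(ddof=1)) if len(df) > 1 else 0.0,
        "mean_db": float(df["db"].mean()),
        "sd_db": float(df["db"].std(ddof=1)) if len(df) > 1 else 0.0,
        "mean_charge": float(df["charge"].mean()),
    }
    return df, aggregate
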