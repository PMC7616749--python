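"""Writers for simulation-ready files and the bonded-parameter table reader.

Emits fixed-column GRO coordinates, an include topology (ITP) with
``[moleculetype]/[atoms]/[bonds]/[angles]`` sections, a per-bead atomistic
mapping table for backmapping, a SMILES sidecar, and a titratable-pKa
sidecar.  Bonds use GROMACS function type 1 (harmonic); angles use function
type 2, the cosine-harmonic form matching the model potential
1/2 K (cos theta - cos theta_0)^2.  Nonbonded parameters are never emitted —
they live in the published Martini 3 force-field files, referenced by an
include path in the optional ``.top`` wrapper.

All outputs are byte-identical across runs for fixed inputs: titles carry a
content hash, never a timestamp.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np

from .generator import EmbeddedPolymer
from .parametrize import BondedParam, ParamTable
from .polymer_graph import AngleType, BondType, PolymerGraph, UnitKind, to_smiles
from .protonation import (
    BEAD_SPECS,
    PKA_BY_KIND,
    ChargeState,
    total_charge,
    uncharged_state,
)

__all__ = [
    "write_gro",
    "read_gro",
    "write_itp",
    "read_itp",
    "write_top",
    "write_mapping",
    "write_smiles",
    "write_charge_sidecar",
    "write_param_table",
    "read_param_table",
    "atom_name",
]

_GRO_MAX_ATOMS = 99999

#: Heavy atoms represented by each bead (Martini mapping): terminal H2N-CH2,
#: linear H2C-NH-CH2, dendritic H2C-N(CH2)-CH2.
MAPPING_ATOMS: dict[UnitKind, tuple[str, ...]] = {
    UnitKind.T: ("N", "C"),
    UnitKind.L: ("C", "N", "C"),
    UnitKind.D: ("C", "N", "C", "C"),
}


def atom_name(graph: PolymerGraph, node: int) -> str:
    """Atom name: bead kind letter + 1-based atom index (e.g. T1, L2)."""
    return f"{graph.kind(node)}{graph.nodes.index(node) + 1}"


def _content_hash(*chunks: str) -> str:
    h = hashlib.sha1()
    for c in chunks:
        h.update(c.encode())
    return h.hexdigest()[:12]


# ----------------------------------------------------------------------
# GRO coordinates


def write_gro(
    embedded: EmbeddedPolymer,
    path: Union[str, Path],
    title: Optional[str] = None,
) -> Path:
    """Write fixed-column GRO coordinates (nm), one residue "PEI"."""
    graph = embedded.graph
    n = len(graph)
    if n == 0:
        raise ValueError("empty polymer: nothing to write")
    if n > _GRO_MAX_ATOMS:
        raise ValueError(f"GRO format limit: at most {_GRO_MAX_ATOMS} atoms")
    path = Path(path)
    coords = embedded.coordinates
    if title is None:
        tag = _content_hash(
            repr(graph.to_dict()), np.array2string(coords, precision=6)
        )
        title = f"PEI {n} beads; build {tag}"
    lines = [title, f"{n:5d}"]
    for i, node in enumerate(graph.nodes):
        name = atom_name(graph, node)
        x, y, z = coords[i]
        lines.append(
            f"{1:5d}{'PEI':<5s}{name:>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    bx, by, bz = embedded.box
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gro(path: Union[str, Path]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a GRO file -> (atom names, coordinates (n,3) nm, box (3,))."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError("truncated GRO file")
    n = int(lines[1])
    names = []
    coords = np.zeros((n, 3))
    for i in range(n):
        line = lines[2 + i]
        names.append(line[10:15].strip())
        coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
    box = np.array([float(v) for v in lines[2 + n].split()[:3]])
    return names, coords, box


# ----------------------------------------------------------------------
# ITP topology


def write_itp(
    graph: PolymerGraph,
    params: ParamTable,
    charge_state: Optional[ChargeState] = None,
    path: Union[str, Path] = "molecule.itp",
    molecule_name: str = "PEI",
) -> Path:
    """Write an include topology: [moleculetype], [atoms], [bonds], [angles].

    Bead names and charges come from the charge state (all-neutral if none is
    given); bead masses follow the Martini size classes.  Raises ``KeyError``
    naming the first bond/angle type missing from the parameter table.
    """
    graph.validate()
    if not graph.is_complete:
        raise ValueError("topology requires a complete polymer")
    params.covers(graph)
    if charge_state is None:
        charge_state = uncharged_state(graph)

    nodes = graph.nodes
    index = {node: i + 1 for i, node in enumerate(nodes)}  # 1-based
    lines = [
        f"; polyamine-builder topology for {molecule_name}",
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        f"{molecule_name}  1",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    for node in nodes:
        kind = graph.kind(node)
        bead = charge_state.bead(node)
        q = charge_state.charge(node)
        mass = BEAD_SPECS[kind].mass
        i = index[node]
        lines.append(
            f"{i:5d}  {bead:<5s}  {1:4d}  {'PEI':<7s}  {atom_name(graph, node):<5s}"
            f"  {i:4d}  {q:6.3f}  {mass:7.3f}"
        )
    lines += ["", "[ bonds ]", ";  i  j  funct  r0(nm)  k(kJ/mol/nm2)"]
    for a, b in graph.edges:
        p = params.get(BondType(graph.kind(a), graph.kind(b)))
        lines.append(
            f"{index[a]:5d} {index[b]:5d}  1  {p.equilibrium:8.4f}  "
            f"{p.force_constant:10.2f}"
        )
    lines += ["", "[ angles ]", ";  i  j  k  funct  theta0(deg)  k(kJ/mol)"]
    for i_n, c_n, k_n in graph.angles():
        p = params.get(AngleType(graph.kind(i_n), graph.kind(c_n), graph.kind(k_n)))
        lines.append(
            f"{index[i_n]:5d} {index[c_n]:5d} {index[k_n]:5d}  2  "
            f"{p.equilibrium:8.2f}  {p.force_constant:10.2f}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_itp(path: Union[str, Path]) -> dict:
    """Parse the sections this package writes (for round-trip checks).

    Returns a dict with ``name``, ``atoms`` (list of dicts), ``bonds`` and
    ``angles`` (lists of tuples with indices, function type, parameters).
    """
    section = None
    out: dict = {"name": None, "atoms": [], "bonds": [], "angles": []}
    for raw in Path(path).read_text().splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        fields = line.split()
        if section == "moleculetype":
            out["name"] = fields[0]
        elif section == "atoms":
            out["atoms"].append(
                {
                    "nr": int(fields[0]),
                    "type": fields[1],
                    "residue": fields[3],
                    "atom": fields[4],
                    "charge": float(fields[6]),
                    "mass": float(fields[7]),
                }
            )
        elif section == "bonds":
            out["bonds"].append(
                (
                    int(fields[0]),
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                    float(fields[4]),
                )
            )
        elif section == "angles":
            out["angles"].append(
                (
                    int(fields[0]),
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[3]),
                    float(fields[4]),
                    float(fields[5]),
                )
            )
    return out


def write_top(
    path: Union[str, Path],
    itp_path: Union[str, Path],
    molecule_name: str = "PEI",
    n_molecules: int = 1,
    forcefield_include: str = "martini_v3.0.0.itp",
) -> Path:
    """Write a minimal system topology referencing the published force field."""
    lines = [
        f'#include "{forcefield_include}"',
        f'#include "{Path(itp_path).name}"',
        "",
        "[ system ]",
        f"{molecule_name} in vacuum",
        "",
        "[ molecules ]",
        f"{molecule_name}  {n_molecules}",
    ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ----------------------------------------------------------------------
# mapping / sidecars


def write_mapping(graph: PolymerGraph, path: Union[str, Path]) -> Path:
    """Per-bead heavy-atom mapping table for backmapping.

    One row per bead: index, kind, bead-local heavy atoms (element symbols)
    the bead represents.
    """
    graph.validate()
    if not graph.is_complete:
        raise ValueError("mapping requires a complete polymer")
    lines = ["; bead  kind  heavy_atoms"]
    for i, node in enumerate(graph.nodes, start=1):
        kind = graph.kind(node)
        atoms = ",".join(MAPPING_ATOMS[kind])
        lines.append(f"{i:5d}  {kind}  {atoms}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_smiles(graph: PolymerGraph, path: Union[str, Path]) -> Path:
    """SMILES sidecar for reconstructing the all-atom structure."""
    path = Path(path)
    path.write_text(to_smiles(graph) + "\n")
    return path


def write_charge_sidecar(
    graph: PolymerGraph, state: ChargeState, path: Union[str, Path]
) -> Path:
    """Tabular sidecar: node id, bead, charge, pKa (titratable annotation)."""
    lines = ["; node  bead  charge  pKa"]
    for node in graph.nodes:
        lines.append(
            f"{node:5d}  {state.bead(node):<5s}  {state.charge(node):2d}"
            f"  {PKA_BY_KIND[graph.kind(node)]:4.1f}"
        )
    lines.append(f"; total_charge {total_charge(state)}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ----------------------------------------------------------------------
# parameter tables


def write_param_table(table: ParamTable, path: Union[str, Path]) -> Path:
    """Write a bonded-parameter table as whitespace-delimited text.

    Columns: kind (bond|angle), type (e.g. L-D or T-L-D), equilibrium (nm or
    deg), force constant (kJ/mol/nm^2 or kJ/mol), retained peak count.
    """
    lines = ["# kind  type  equilibrium  force_constant  n_peaks"]
    for p in table:
        lines.append(
            f"{p.kind:<5s}  {str(p.type):<6s}  {p.equilibrium:12.6f}  "
            f"{p.force_constant:14.6f}  {len(p.peaks)}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_param_table(path: Union[str, Path]) -> ParamTable:
    """Read a bonded-parameter table, validating units and uniqueness."""
    table = ParamTable()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
        kind, type_str, eq_s, k_s = fields[:4]
        eq, k = float(eq_s), float(k_s)
        if k <= 0:
            raise ValueError(f"{path}:{lineno}: force constant must be positive")
        if kind == "bond":
            t: Union[BondType, AngleType] = BondType.from_string(type_str)
            if eq <= 0:
                raise ValueError(f"{path}:{lineno}: bond equilibrium must be > 0 nm")
        elif kind == "angle":
            t = AngleType.from_string(type_str)
            if not 0.0 < eq <= 180.0:
                raise ValueError(
                    f"{path}:{lineno}: angle equilibrium must be in (0, 180] deg"
                )
        else:
            raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
        try:
            table.add(BondedParam(type=t, kind=kind, equilibrium=eq, force_constant=k))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return table
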