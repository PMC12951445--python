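"""Readers/writers for PDB, PQR, XYZ and OpenDX grids, plus van der Waals radii.

Conventions
-----------
* PDB records are parsed fixed-width with a hybrid-36 fallback for serial and
  residue-id fields (the overflow dialect used by large structures).
* PQR records are whitespace-delimited, the dialect emitted by PDB→PQR
  converters feeding Poisson–Boltzmann solvers; every atom carries a partial
  charge (e) and a van der Waals radius (Å).
* OpenDX scalar grids use the "gridpositions counts" dialect with z-fastest
  value ordering, as written by common PB solvers; the actual serialization is
  delegated to :mod:`gridData`.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from gridData import Grid as _DXGrid

__all__ = [
    "Atom",
    "LabeledMolecule",
    "Trajectory",
    "PotentialGrid",
    "read_pdb",
    "write_pdb",
    "read_pqr",
    "write_pqr",
    "read_xyz",
    "write_xyz",
    "read_dx",
    "write_dx",
    "vdw_radius",
    "load_radius_table",
    "DEFAULT_VDW_TABLE",
]

RING_VOCABULARY = frozenset({"xylene", "central", "pyrimidine", "substituent"})

#: Amber-style van der Waals radii (Rmin/2, Å) with a config override hook.
DEFAULT_VDW_TABLE: dict[str, float] = {
    "H": 1.487,
    "D": 1.487,
    "C": 1.908,
    "N": 1.824,
    "O": 1.6612,
    "S": 2.0,
    "P": 2.1,
    "F": 1.75,
    "CL": 1.948,
    "BR": 2.22,
    "I": 2.35,
    "NA": 1.868,
    "K": 2.658,
    "MG": 0.787,
    "CA": 1.7131,
    "ZN": 1.10,
    "FE": 1.2,
}


def vdw_radius(element: str, table: Mapping[str, float] | None = None) -> float:
    """Van der Waals radius (Å) for an element symbol.

    Parameters
    ----------
    element
        Element symbol, case-insensitive ("C", "Cl", ...).
    table
        Optional override table mapping upper-case symbols to radii.
    """
    tab = DEFAULT_VDW_TABLE if table is None else table
    key = element.strip().upper()
    if key not in tab:
        known = ", ".join(sorted(tab))
        raise KeyError(f"unknown element {element!r}; known symbols: {known}")
    r = float(tab[key])
    if r <= 0:
        raise ValueError(f"radius for {element!r} must be positive, got {r}")
    return r


def load_radius_table(path: str | Path) -> dict[str, float]:
    """Load a radius table from JSON ({"C": 1.9, ...}) or two-column text."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        raw = json.loads(text)
        return {str(k).upper(): float(v) for k, v in raw.items()}
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sym, val = line.split()[:2]
        table[sym.upper()] = float(val)
    return table


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom: identity, position (Å) and, when known, charge (e) and radius (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    charge: float | None = None
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class LabeledMolecule:
    """An ordered atom list with optional chromophore site and ring labels.

    ``site_labels`` maps atom index → site name ("N5", "C4", ...); site names
    must be unique.  ``ring_labels`` maps atom index → one of
    xylene / central / pyrimidine / substituent.
    """

    atoms: list[Atom]
    site_labels: dict[int, str] = field(default_factory=dict)
    ring_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sites = list(self.site_labels.values())
        if len(sites) != len(set(sites)):
            raise ValueError("site names must be unique")
        bad = set(self.ring_labels.values()) - RING_VOCABULARY
        if bad:
            raise ValueError(f"ring labels {sorted(bad)} outside {sorted(RING_VOCABULARY)}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def heavy_atoms(self) -> "LabeledMolecule":
        idx = self.heavy_indices()
        remap = {int(old): new for new, old in enumerate(idx)}
        return LabeledMolecule(
            atoms=[self.atoms[i] for i in idx],
            site_labels={remap[i]: s for i, s in self.site_labels.items() if i in remap},
            ring_labels={remap[i]: r for i, r in self.ring_labels.items() if i in remap},
        )

    def total_charge(self) -> float:
        missing = [a.serial for a in self.atoms if a.charge is None]
        if missing:
            raise ValueError(f"atoms without charges: serials {missing[:5]}...")
        return float(sum(a.charge for a in self.atoms))

    def site_index(self, site: str) -> int:
        for i, s in self.site_labels.items():
            if s == site:
                return i
        raise KeyError(f"no atom labeled {site!r}")

    def with_positions(self, positions: np.ndarray) -> "LabeledMolecule":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValueError("position array shape mismatch")
        atoms = [dataclasses.replace(a, position=p.copy()) for a, p in zip(self.atoms, positions)]
        return LabeledMolecule(atoms, dict(self.site_labels), dict(self.ring_labels))


@dataclass
class Trajectory:
    """A topology plus per-frame coordinates (Å) and strictly increasing times (ps)."""

    topology: LabeledMolecule
    frames: list[np.ndarray]
    times: list[float]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {k}: shape {f.shape} != ({n}, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times/frames length mismatch")
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times else 0.0


@dataclass
class PotentialGrid:
    """Regular 3D scalar field (kT/e) on a node-centered grid."""

    origin: np.ndarray
    spacing: np.ndarray
    counts: tuple[int, int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.counts = tuple(int(c) for c in self.counts)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != int(np.prod(self.counts)):
            raise ValueError(
                f"value count {self.values.size} != product of counts {np.prod(self.counts)}"
            )
        self.values = self.values.reshape(self.counts)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.counts))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.counts[d]) for d in range(3)
        )

    def node_coordinates(self) -> np.ndarray:
        """All node positions, (n_nodes, 3), z-fastest ordering."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        hi = self.origin + self.spacing * (np.array(self.counts) - 1)
        return self.origin.copy(), hi


# ---------------------------------------------------------------------------
# hybrid-36 (overflow dialect for PDB serial / residue-id columns)
# ---------------------------------------------------------------------------

_DIGITS36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _decode_hybrid36(s: str, width: int) -> int:
    s = s.strip()
    if not s:
        raise ValueError("empty numeric field")
    try:
        return int(s)
    except ValueError:
        pass
    if len(s) != width:
        raise ValueError(f"hybrid-36 field {s!r} must fill its {width}-column width")
    first = s[0]
    if first in _DIGITS36[10:]:  # uppercase block
        return int(s, 36) - 10 * 36 ** (width - 1) + 10**width
    if first in _DIGITS36[10:].lower():  # lowercase block
        return int(s.upper(), 36) + 16 * 36 ** (width - 1) + 10**width
    raise ValueError(f"cannot decode numeric field {s!r}")


def _guess_element(name: str) -> str:
    name = name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return name[:2].capitalize()
    return name[0].upper()


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _parse_pdb_atom(line: str, lineno: int) -> Atom:
    try:
        serial = _decode_hybrid36(line[6:11], 5)
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21:22].strip() or " "
        res_id = _decode_hybrid36(line[22:26], 4)
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed PDB record at line {lineno}: {exc}") from exc
    return Atom(
        serial=serial,
        name=name,
        element=element or _guess_element(name),
        residue_name=res_name,
        residue_id=res_id,
        chain=chain,
        position=np.array([x, y, z]),
    )


def read_pdb(path: str | Path, multi_model: bool = False):
    """Read a PDB file into a LabeledMolecule, or a Trajectory when ``multi_model``.

    Charges and radii are absent (plain PDB carries neither).  Model indices
    serve as frame times (ps) for multi-model files.
    """
    path = Path(path)
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current and not in_model:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_pdb_atom(line, lineno))
    if current:
        models.append(current)
    if not models or not models[0]:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    if not multi_model:
        return LabeledMolecule(atoms=models[0])
    n = len(models[0])
    for k, m in enumerate(models):
        if len(m) != n:
            raise ValueError(f"{path}: model {k + 1} has {len(m)} atoms, expected {n}")
    topo = LabeledMolecule(atoms=models[0])
    frames = [np.array([a.position for a in m]) for m in models]
    return Trajectory(topology=topo, frames=frames, times=[float(k) for k in range(len(models))])


def _format_pdb_atom(a: Atom, bfactor: float, occupancy: float = 1.00) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial:>5d} {name:<4.4s} {a.residue_name:<3.3s} "
        f"{a.chain:1.1s}{a.residue_id:>4d}    "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}          {a.element:>2.2s}"
    )


def write_pdb(
    mol: LabeledMolecule,
    path: str | Path,
    bfactors: Sequence[float] | None = None,
    frames: Iterable[np.ndarray] | None = None,
) -> Path:
    """Write a PDB file; ``frames`` produces a multi-model file (MODEL/ENDMDL)."""
    path = Path(path)
    b = np.zeros(mol.n_atoms) if bfactors is None else np.asarray(bfactors, dtype=float)
    if b.shape != (mol.n_atoms,):
        raise ValueError("bfactors length mismatch")
    buf = io.StringIO()
    if frames is None:
        for a, bf in zip(mol.atoms, b):
            buf.write(_format_pdb_atom(a, bf) + "\n")
    else:
        for k, coords in enumerate(frames, start=1):
            buf.write(f"MODEL     {k:>4d}\n")
            for a, p, bf in zip(mol.atoms, np.asarray(coords), b):
                buf.write(_format_pdb_atom(dataclasses.replace(a, position=p), bf) + "\n")
            buf.write("ENDMDL\n")
    buf.write("END\n")
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# PQR (whitespace-delimited; per-atom charge and radius)
# ---------------------------------------------------------------------------


def read_pqr(path: str | Path) -> LabeledMolecule:
    """Read a whitespace-delimited PQR file; every atom carries charge and radius."""
    path = Path(path)
    atoms: list[Atom] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0] not in ("ATOM", "HETATM"):
                continue
            # chain column is optional: 10 fields without it, 11 with
            if len(parts) == 11:
                _, serial, name, res_name, chain, res_id, x, y, z, q, r = parts
            elif len(parts) == 10:
                _, serial, name, res_name, res_id, x, y, z, q, r = parts
                chain = " "
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 10 or 11 whitespace-delimited "
                    f"fields (incl. charge and radius), got {len(parts)}"
                )
            try:
                atoms.append(
                    Atom(
                        serial=int(serial),
                        name=name,
                        element=_guess_element(name),
                        residue_name=res_name,
                        residue_id=int(res_id),
                        chain=chain,
                        position=np.array([float(x), float(y), float(z)]),
                        charge=float(q),
                        vdw_radius=float(r),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return LabeledMolecule(atoms=atoms)


def write_pqr(mol: LabeledMolecule, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for a in mol.atoms:
        if a.charge is None or a.vdw_radius is None:
            raise ValueError(f"atom serial {a.serial}: PQR requires charge and radius")
        lines.append(
            f"ATOM {a.serial} {a.name} {a.residue_name} {a.chain.strip() or 'A'} "
            f"{a.residue_id} {a.position[0]:.6f} {a.position[1]:.6f} "
            f"{a.position[2]:.6f} {a.charge:.6f} {a.vdw_radius:.6f}"
        )
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


# ---------------------------------------------------------------------------
# XYZ (single- and multi-frame)
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path, multi_frame: bool = False):
    """Read XYZ; ``multi_frame`` stacks consecutive blocks into a Trajectory."""
    path = Path(path)
    lines = path.read_text().splitlines()
    blocks: list[tuple[list[str], np.ndarray]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: expected atom count") from exc
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        elems, coords = [], []
        for ln in body:
            parts = ln.split()
            elems.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        blocks.append((elems, np.array(coords)))
        i += 2 + n
    if not blocks:
        raise ValueError(f"{path}: empty XYZ file")
    elems, coords = blocks[0]
    atoms = [
        Atom(serial=k + 1, name=e, element=e, residue_name="MOL", residue_id=1,
             chain="A", position=p)
        for k, (e, p) in enumerate(zip(elems, coords))
    ]
    mol = LabeledMolecule(atoms=atoms)
    if not multi_frame:
        return mol
    frames = [c for _, c in blocks]
    return Trajectory(topology=mol, frames=frames, times=[float(k) for k in range(len(frames))])


def write_xyz(
    mol: LabeledMolecule,
    path: str | Path,
    frames: Iterable[np.ndarray] | None = None,
    comment: str = "",
) -> Path:
    path = Path(path)
    frames_list = [mol.positions] if frames is None else [np.asarray(f) for f in frames]
    out = []
    for coords in frames_list:
        out.append(str(mol.n_atoms))
        out.append(comment)
        for a, p in zip(mol.atoms, coords):
            out.append(f"{a.element:<2s} {p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# OpenDX
# ---------------------------------------------------------------------------


def write_dx(grid: PotentialGrid, path: str | Path) -> Path:
    """Write an OpenDX scalar grid ("gridpositions counts", z-fastest)."""
    path = Path(path)
    g = _DXGrid(grid.values, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="dx")
    return path


def read_dx(path: str | Path) -> PotentialGrid:
    path = Path(path)
    try:
        g = _DXGrid(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable OpenDX scalar grid: {exc}") from exc
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    return PotentialGrid(
        origin=np.asarray(g.origin, dtype=float),
        spacing=delta,
        counts=tuple(g.grid.shape),
        values=np.asarray(g.grid, dtype=float),
    )
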