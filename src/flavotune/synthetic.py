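"""Synthetic fixtures: toy chromophore, difference charges, environments, trajectories.

Everything the pipeline needs can be generated here with explicit seeds:

* a planar, tricyclic, flavin-like heavy-atom chromophore with the canonical
  isoalloxazine site labels (N1, C2, N3, C4, C4a, N5, N10, O2, O4) and ring
  membership (xylene / central / pyrimidine);
* zero-sum per-atom state difference charges whose spatial structure encodes
  the qualitative tuning behavior of the bright singlet (π,π*) and the
  N5-lone-pair triplet (n,π*): a positive charge below the N5/C4 face
  red-shifts the singlet and blue-shifts the triplet;
* "LOV1-like" (positive potential at the N5/C4 face) and "LOV2-like"
  (negative there, plus a diffuse negative shell over the xylene ring)
  point-charge environments;
* mini-protein trajectories with prescribed per-residue fluctuation
  amplitudes for flexibility analysis.

These are qualitative stand-ins for quantum-chemistry and MD outputs — the
difference-charge magnitudes are chosen so that map extrema with a +0.1e
probe at 2 VdW radii land in the 0.01–0.05 eV range typical of flavin
tuning maps, but no value is fitted to any reference calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .estm import StateDeltaCharges
from .potential_field import ChargeSet
from .structures_io import Atom, LabeledMolecule, Trajectory, vdw_radius

__all__ = [
    "GeneratorConfig",
    "make_toy_flavin",
    "make_delta_charges",
    "make_environment",
    "make_mini_protein",
    "make_residue_shell",
    "make_trajectory",
]

_BOND = 1.4  # Å, idealized aromatic ring bond length
_H = _BOND * np.sqrt(3.0) / 2.0  # hex-lattice half-width

# Planar fused-tricycle layout: ring centers at x = 0, 2h, 4h; each hexagon
# has vertical shared edges.  Name → (x, y, element, ring).
_TOY_ATOMS: list[tuple[str, float, float, str, str]] = [
    ("C8", -_H, 0.7, "C", "xylene"),
    ("C7", -_H, -0.7, "C", "xylene"),
    ("C9", 0.0, _BOND, "C", "xylene"),
    ("C6", 0.0, -_BOND, "C", "xylene"),
    ("C9A", _H, 0.7, "C", "central"),
    ("C5A", _H, -0.7, "C", "central"),
    ("N10", 2 * _H, _BOND, "N", "central"),
    ("N5", 2 * _H, -_BOND, "N", "central"),
    ("C10A", 3 * _H, 0.7, "C", "central"),
    ("C4A", 3 * _H, -0.7, "C", "central"),
    ("N1", 4 * _H, _BOND, "N", "pyrimidine"),
    ("C4", 4 * _H, -_BOND, "C", "pyrimidine"),
    ("C2", 5 * _H, 0.7, "C", "pyrimidine"),
    ("N3", 5 * _H, -0.7, "N", "pyrimidine"),
    ("O2", 5 * _H + 1.0664, 0.7 + 0.615, "O", "substituent"),
    ("O4", 4 * _H, -_BOND - 1.23, "O", "substituent"),
    ("C10M", 2 * _H, _BOND + 1.45, "C", "substituent"),
]

_SITES = ("N1", "C2", "N3", "C4", "C4A", "N5", "N10", "O2", "O4")
_SITE_NAME = {"C4A": "C4a"}  # canonical mixed-case site names

# Zero-sum state difference charges (e), chosen once for the qualitative
# sign structure described in the module docstring.
_DELTA_S1 = {
    "N5": -0.09, "C4": -0.07, "C4A": -0.05, "N3": -0.03, "C5A": -0.03,
    "C6": -0.02, "O4": -0.01,
    "N10": 0.07, "N1": 0.05, "C2": 0.04, "C10A": 0.05, "C9A": 0.04,
    "C9": 0.02, "O2": 0.02, "C10M": 0.01,
}
_DELTA_TN = {
    "N5": 0.20,
    "C4A": -0.04, "C10A": -0.03, "N10": -0.03, "C4": -0.02, "C2": -0.02,
    "N1": -0.02, "O4": -0.02, "C9A": -0.01, "C5A": -0.01,
}


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic trajectory generator."""

    seed: int = 0
    n_residues: int = 10
    frame_count: int = 500
    dt_ps: float = 10.0
    per_residue_sigma: dict[int, float] | float = 0.3  # Å, per-axis
    rigid_jitter: bool = False
    environment_motif: str = "neutral"
    chromophore_variant: str = "toy_flavin"


def make_toy_flavin() -> LabeledMolecule:
    """Planar tricyclic flavin-like chromophore (17 heavy atoms), deterministic.

    Idealized 1.4 Å ring bonds in the z = 0 plane; sites N1…O4 labeled and
    every atom assigned a ring label.
    """
    atoms, site_labels, ring_labels = [], {}, {}
    for k, (name, x, y, elem, ring) in enumerate(_TOY_ATOMS):
        atoms.append(
            Atom(
                serial=k + 1,
                name=name,
                element=elem,
                residue_name="LFN",
                residue_id=1,
                chain="X",
                position=np.array([x, y, 0.0]),
                charge=0.0,
                vdw_radius=vdw_radius(elem),
            )
        )
        ring_labels[k] = ring
        if name in _SITES:
            site_labels[k] = _SITE_NAME.get(name, name)
    return LabeledMolecule(atoms=atoms, site_labels=site_labels, ring_labels=ring_labels)


def make_delta_charges(state: str, mol: LabeledMolecule | None = None) -> StateDeltaCharges:
    """Packaged synthetic difference-charge set for "S1_pipi" or "Tn_npi".

    Both sets sum to zero exactly.  The singlet set is negative along the
    lower (N5-side) edge of the central and pyrimidine rings, so a positive
    probe there red-shifts the state; the triplet set is dominated by a
    large positive Δq on N5 (lone-pair depletion), so the same probe
    blue-shifts it.
    """
    mol = make_toy_flavin() if mol is None else mol
    if state == "S1_pipi":
        table = _DELTA_S1
    elif state == "Tn_npi":
        table = _DELTA_TN
    else:
        raise ValueError(f"unknown state {state!r}; expected 'S1_pipi' or 'Tn_npi'")
    dq = np.array([table.get(a.name, 0.0) for a in mol.atoms])
    return StateDeltaCharges(state=state, delta_q=dq)


def _n5_c4_face_point(mol: LabeledMolecule, distance: float) -> np.ndarray:
    n5 = mol.atoms[mol.site_index("N5")].position
    c4 = mol.atoms[mol.site_index("C4")].position
    return (n5 + c4) / 2.0 + np.array([0.0, 0.0, -distance])


def make_environment(
    motif: str,
    mol: LabeledMolecule | None = None,
    distance: float = 3.0,
    magnitude: float = 0.5,
) -> ChargeSet:
    """Point-charge environment around the toy chromophore.

    ``LOV1_like``: +magnitude below the N5/C4 face (positive potential
    there); ``LOV2_like``: −magnitude at the same site plus a diffuse
    negative shell (8 × −0.05 e) 4 Å above and below the xylene ring;
    ``neutral``: empty set.
    """
    mol = make_toy_flavin() if mol is None else mol
    if motif == "neutral":
        return ChargeSet(positions=np.empty((0, 3)), charges=np.empty(0), label="neutral")
    face = _n5_c4_face_point(mol, distance)
    if motif == "LOV1_like":
        return ChargeSet(positions=face[None, :], charges=np.array([magnitude]),
                         label="LOV1_like")
    if motif == "LOV2_like":
        positions = [face]
        charges = [-magnitude]
        xyl = [i for i, r in mol.ring_labels.items() if r == "xylene"]
        for i in xyl:
            for dz in (4.0, -4.0):
                positions.append(mol.atoms[i].position + np.array([0.0, 0.0, dz]))
                charges.append(-0.05)
        return ChargeSet(
            positions=np.array(positions), charges=np.array(charges), label="LOV2_like"
        )
    raise ValueError(f"unknown motif {motif!r}; expected LOV1_like, LOV2_like or neutral")


def make_mini_protein(n_residues: int = 10, origin: np.ndarray | None = None) -> LabeledMolecule:
    """Deterministic helical mini-protein: N, CA, C, O per residue."""
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    atoms = []
    serial = 1
    offsets = {
        "N": np.array([-1.0, 0.5, -0.4]),
        "CA": np.zeros(3),
        "C": np.array([1.1, 0.4, 0.3]),
        "O": np.array([1.5, 1.4, 0.5]),
    }
    for r in range(n_residues):
        theta = np.deg2rad(100.0) * r
        ca = origin + np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * r])
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=name[0],
                    residue_name="ALA",
                    residue_id=r + 1,
                    chain="A",
                    position=ca + offsets[name],
                    charge=0.0,
                    vdw_radius=vdw_radius(name[0]),
                )
            )
            serial += 1
    return LabeledMolecule(atoms=atoms)


def make_residue_shell(
    distances: list[float], mol: LabeledMolecule | None = None, seed: int = 0
) -> LabeledMolecule:
    """Single-heavy-atom residues at prescribed distances from the chromophore.

    Residue i is one carbon placed ``distances[i]`` Å from the nearest
    chromophore heavy atom, along a deterministic pseudo-random direction —
    a controlled fixture for proximity-selection checks.
    """
    mol = make_toy_flavin() if mol is None else mol
    rng = np.random.default_rng(seed)
    heavy = mol.positions[mol.heavy_indices()]
    atoms = []
    for r, dist in enumerate(distances):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        anchor = heavy[r % len(heavy)]

        # root-find the ray parameter where the nearest chromophore atom is
        # exactly `dist` away (the anchor need not be the nearest atom along
        # an arbitrary direction)
        def _excess(s: float) -> float:
            return np.linalg.norm(heavy - (anchor + s * u), axis=1).min() - dist

        hi = dist
        while _excess(hi) < 0:
            hi *= 2.0
        s_star = brentq(_excess, 0.0, hi, xtol=1e-12)
        pos = anchor + s_star * u
        atoms.append(
            Atom(
                serial=r + 1,
                name="CB",
                element="C",
                residue_name="GLY",
                residue_id=r + 1,
                chain="P",
                position=pos,
                charge=0.0,
                vdw_radius=vdw_radius("C"),
            )
        )
    return LabeledMolecule(atoms=atoms)


def make_trajectory(config: GeneratorConfig) -> Trajectory:
    """Synthetic trajectory: base structure + per-residue Gaussian jitter.

    Each atom of residue r is displaced independently per frame by
    N(0, σ_r²) per axis; optional global rigid motion (random rotation ≤ 10°
    and translation ≤ 1 Å per frame) exercises the superposition step.
    Deterministic for a fixed seed.
    """
    topo = make_mini_protein(config.n_residues)
    rng = np.random.default_rng(config.seed)
    sigma = config.per_residue_sigma
    if not isinstance(sigma, dict):
        sigma = {r + 1: float(sigma) for r in range(config.n_residues)}
    per_atom_sigma = np.array([sigma.get(a.residue_id, 0.0) for a in topo.atoms])
    base = topo.positions
    frames = []
    for _ in range(config.frame_count):
        noise = rng.normal(size=base.shape) * per_atom_sigma[:, None]
        coords = base + noise
        if config.rigid_jitter:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-np.deg2rad(10), np.deg2rad(10))
            k = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
            coords = coords @ rot.T + rng.uniform(-1.0, 1.0, size=3)
        frames.append(coords)
    times = [config.dt_ps * (k + 1) for k in range(config.frame_count)]
    return Trajectory(topology=topo, frames=frames, times=times)
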