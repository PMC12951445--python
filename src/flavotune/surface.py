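"""Scaled van der Waals surface point clouds.

Probe positions for spectral tuning maps sit on a surface two VdW radii from
each heavy atom of the chromophore; potential projections use one VdW radius.
Both are generated here: a deterministic golden-angle (Fibonacci) lattice is
placed on each heavy atom's k-scaled sphere and candidates strictly inside any
other heavy atom's k-scaled sphere are pruned, leaving the exposed union
surface.  Hydrogens neither seed nor prune.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structures_io import Atom, LabeledMolecule, write_pdb

__all__ = [
    "SurfaceCloud",
    "generate_surface",
    "fibonacci_sphere",
    "assign_point_regions",
    "region_masks",
    "export_cloud_csv",
    "export_cloud_pdb",
]

PRUNE_TOL = 1e-9  # Å; points exactly on two spheres' intersection are kept


def fibonacci_sphere(n: int) -> np.ndarray:
    """n points on the unit sphere by the golden-angle lattice; deterministic."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


@dataclass
class SurfaceCloud:
    """Points on a k×VdW surface, each tied to its parent atom index."""

    points: np.ndarray  # (m, 3), Å
    parent: np.ndarray  # (m,) indices into source.atoms
    scale: float
    source: LabeledMolecule
    density: float  # target points per Å²

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.parent = np.asarray(self.parent, dtype=int).reshape(-1)
        if len(self.points) != len(self.parent):
            raise ValueError("points/parent length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.points)


def generate_surface(
    mol: LabeledMolecule, scale: float = 1.0, density: float = 1.0
) -> SurfaceCloud:
    """Generate the pruned k×VdW surface cloud of a molecule's heavy atoms.

    Per atom, ``round(4π(k·r)²·density)`` lattice points are placed at radius
    k·r; a candidate survives unless it lies strictly inside another heavy
    atom's k-scaled sphere (strictly: distance < k·r_other − 1e−9 Å).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    heavy = mol.heavy_indices()
    if len(heavy) == 0:
        raise ValueError("molecule has no heavy atoms")
    radii = []
    for i in heavy:
        a = mol.atoms[i]
        if a.vdw_radius is None:
            raise ValueError(f"atom serial {a.serial} has no vdw_radius")
        radii.append(a.vdw_radius)
    radii = np.asarray(radii, dtype=float)
    centers = np.array([mol.atoms[i].position for i in heavy])

    pts_list, parent_list = [], []
    for j, (c, r) in enumerate(zip(centers, radii)):
        rk = scale * r
        n = max(1, int(round(4.0 * np.pi * rk * rk * density)))
        cand = c + rk * fibonacci_sphere(n)
        # prune against all other heavy atoms' k-spheres
        keep = np.ones(n, dtype=bool)
        for jj, (c2, r2) in enumerate(zip(centers, radii)):
            if jj == j:
                continue
            d = np.linalg.norm(cand - c2, axis=1)
            keep &= d >= scale * r2 - PRUNE_TOL
        pts_list.append(cand[keep])
        parent_list.append(np.full(int(keep.sum()), heavy[j], dtype=int))

    points = np.concatenate(pts_list, axis=0)
    parent = np.concatenate(parent_list, axis=0)
    return SurfaceCloud(points=points, parent=parent, scale=scale, source=mol, density=density)


# ---------------------------------------------------------------------------
# region labeling
# ---------------------------------------------------------------------------

_COMPOSITE_REGIONS = {"N5/C4": ("N5", "C4"), "C2/N3": ("C2", "N3")}


def assign_point_regions(
    cloud: SurfaceCloud, mol: LabeledMolecule | None = None
) -> list[frozenset[str]]:
    """Per-point region sets: parent ring label, parent site, composite regions.

    Points whose parent carries no ring label fall in "substituent".
    """
    mol = cloud.source if mol is None else mol
    regions: list[frozenset[str]] = []
    for p in cloud.parent:
        tags = {mol.ring_labels.get(int(p), "substituent")}
        site = mol.site_labels.get(int(p))
        if site is not None:
            tags.add(site)
            for comp, members in _COMPOSITE_REGIONS.items():
                if site in members:
                    tags.add(comp)
        regions.append(frozenset(tags))
    return regions


def region_masks(cloud: SurfaceCloud, mol: LabeledMolecule | None = None) -> dict[str, np.ndarray]:
    """Boolean point masks for every region tag present in the cloud."""
    regions = assign_point_regions(cloud, mol)
    names = sorted(set().union(*regions)) if regions else []
    return {
        name: np.array([name in tags for tags in regions], dtype=bool) for name in names
    }


def _primary_region(tags: frozenset[str]) -> str:
    for r in ("xylene", "central", "pyrimidine", "substituent"):
        if r in tags:
            return r
    return "substituent"


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_cloud_csv(
    cloud: SurfaceCloud, path: str | Path, values: np.ndarray | None = None
) -> Path:
    """CSV export: x, y, z, parent_serial, region (+ optional value column)."""
    regions = assign_point_regions(cloud)
    df = pd.DataFrame(
        {
            "x": cloud.points[:, 0],
            "y": cloud.points[:, 1],
            "z": cloud.points[:, 2],
            "parent_serial": [cloud.source.atoms[int(p)].serial for p in cloud.parent],
            "region": [_primary_region(t) for t in regions],
        }
    )
    if values is not None:
        df["value"] = np.asarray(values, dtype=float)
    df.to_csv(path, index=False)
    return Path(path)


def export_cloud_pdb(
    cloud: SurfaceCloud, path: str | Path, values: np.ndarray | None = None
) -> Path:
    """Pseudo-atom PDB export with the per-point value in the B-factor column."""
    vals = np.zeros(cloud.n_points) if values is None else np.asarray(values, dtype=float)
    atoms = [
        Atom(
            serial=(k % 99999) + 1,
            name="PS",
            element="He",  # chemically inert marker for renderers
            residue_name="SRF",
            residue_id=(k % 9999) + 1,
            chain="S",
            position=p,
        )
        for k, p in enumerate(cloud.points)
    ]
    return write_pdb(LabeledMolecule(atoms=atoms), path, bfactors=vals)
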