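"""Linear interpolation/extrapolation Cartesian reaction paths (LIIC).

A one-dimensional path between two optimized geometries: Cartesian
coordinates are interpolated on an equally spaced ladder and the same step is
continued beyond both endpoints, giving (by default) 15 interpolated + 2×3
extrapolated = 21 geometries for external single-point energy engines.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structures_io import LabeledMolecule, write_xyz

__all__ = ["LIICPath", "build_path", "path_metrics", "write_path"]


@dataclass
class LIICPath:
    """Ordered geometries along the interpolation coordinate (step units)."""

    geometries: list[np.ndarray]
    coordinate: list[float]  # ..., -1, 0, 1, ... with endpoints at 0 and n_interp-1
    endpoints: tuple[int, int]  # indices of the two input geometries

    @property
    def n_geometries(self) -> int:
        return len(self.geometries)


def _maybe_align(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ r.T + tc


def build_path(
    geom_a: np.ndarray,
    geom_b: np.ndarray,
    n_interp: int = 15,
    n_extrap_each: int = 3,
    pre_align: bool = False,
) -> LIICPath:
    """Build the equally spaced Cartesian path A → B with two-sided extrapolation.

    G_t = A + t·(B−A)/(n_interp−1) for t = −n_extrap_each … n_interp−1+n_extrap_each;
    total geometries = n_interp + 2·n_extrap_each (21 with the defaults).
    ``pre_align`` rigid-body superposes B onto A first (for free molecules;
    QM/MM frames already share the protein frame).
    """
    a = np.asarray(geom_a, dtype=float)
    b = np.asarray(geom_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(
            f"geometry shapes {a.shape} vs {b.shape} must match as (n_atoms, 3); "
            "if the atom orderings differ, reorder by atom serial first"
        )
    if n_interp < 2:
        raise ValueError("n_interp must be ≥ 2")
    if n_extrap_each < 0:
        raise ValueError("n_extrap_each must be ≥ 0")
    if pre_align:
        b = _maybe_align(b, a)
    step = (b - a) / (n_interp - 1)
    ts = list(range(-n_extrap_each, n_interp + n_extrap_each))
    geoms = [a + t * step for t in ts]
    # endpoints bit-identical to the inputs
    geoms[n_extrap_each] = a.copy()
    geoms[n_extrap_each + n_interp - 1] = b.copy() if not pre_align else geoms[
        n_extrap_each + n_interp - 1
    ]
    return LIICPath(
        geometries=geoms,
        coordinate=[float(t) for t in ts],
        endpoints=(n_extrap_each, n_extrap_each + n_interp - 1),
    )


def path_metrics(path: LIICPath, tol: float = 1e-9) -> dict:
    """Per-step RMS displacement (Å), constant along the path by construction."""
    diffs = [
        path.geometries[i + 1] - path.geometries[i]
        for i in range(path.n_geometries - 1)
    ]
    rms = [float(np.sqrt((d**2).mean())) for d in diffs]
    max_dev = max(
        float(np.abs(d - diffs[0]).max()) for d in diffs
    ) if diffs else 0.0
    if max_dev > tol:
        raise ValueError(f"unequal step vectors: max deviation {max_dev:.2e} Å > {tol:g}")
    per_atom_max = float(np.linalg.norm(diffs[0], axis=1).max()) if diffs else 0.0
    return {
        "per_step_rms": rms[0] if rms else 0.0,
        "per_step_max_atom": per_atom_max,
        "n_steps": len(diffs),
        "equal_spacing_max_dev": max_dev,
    }


def write_path(path: LIICPath, mol: LabeledMolecule, out_dir: str | Path) -> Path:
    """One XYZ per geometry plus a manifest CSV (index, coordinate, filename)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (geom, coord) in enumerate(zip(path.geometries, path.coordinate)):
        fname = f"liic_{k:03d}.xyz"
        write_xyz(mol.with_positions(geom), out / fname, comment=f"coordinate {coord:g}")
        rows.append((k, coord, fname))
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "coordinate", "filename"])
        w.writerows(rows)
    return manifest
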