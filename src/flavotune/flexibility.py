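"""Per-residue flexibility and chromophore-proximity analysis.

RMSF of Cα atoms about their trajectory mean, after least-squares rigid-body
superposition of every frame onto the iterated mean structure; the profile is
min–max normalized to [0, 1] for B-factor coloring, residues above the mean
normalized value are selected as "flexible", and active-site residues are
those with any heavy atom within a cutoff (4 Å by default) of the
chromophore's heavy atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures_io import LabeledMolecule, Trajectory, write_pdb

__all__ = [
    "RMSFProfile",
    "ca_indices",
    "superpose_to_mean",
    "rmsf",
    "normalize",
    "select_above_average",
    "residues_within",
    "write_bfactor_pdb",
]


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) with an optional min–max normalized companion."""

    values: dict[int, float]
    normalized: dict[int, float] | None = None
    excluded_residues: list[int] = field(default_factory=list)
    degenerate: bool = False

    @property
    def mean_rmsf(self) -> float:
        return float(np.mean(list(self.values.values())))


def ca_indices(mol: LabeledMolecule) -> np.ndarray:
    """Indices of Cα atoms (name CA, element C)."""
    return np.array(
        [
            i
            for i, a in enumerate(mol.atoms)
            if a.name.strip().upper() == "CA" and a.element.upper() == "C"
        ],
        dtype=int,
    )


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile → target (both centered)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise ValueError("degenerate (collinear) selection: superposition is ambiguous")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


def superpose_to_mean(
    traj: Trajectory, selection: np.ndarray | None = None, refinement_passes: int = 2
) -> Trajectory:
    """Rigid-body superpose every frame onto the iterated mean structure.

    The fit uses the Cα selection (all atoms if the topology has no Cα);
    the resulting transforms are applied to all atoms.  Two refinement passes
    re-estimate the mean from the aligned frames.
    """
    if traj.n_frames < 2:
        raise ValueError("superposition needs at least 2 frames")
    sel = ca_indices(traj.topology) if selection is None else np.asarray(selection, int)
    if len(sel) == 0:
        sel = np.arange(traj.topology.n_atoms)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    frames = [f.copy() for f in traj.frames]
    reference = frames[0][sel]
    for _ in range(1 + refinement_passes):
        aligned = []
        for f in frames:
            r, t = _kabsch(f[sel], reference)
            aligned.append(f @ r.T + t)
        frames = aligned
        reference = np.mean([f[sel] for f in frames], axis=0)
    return Trajectory(topology=traj.topology, frames=frames, times=list(traj.times))


def rmsf(traj: Trajectory, selection: np.ndarray | None = None) -> RMSFProfile:
    """Per-residue Cα RMSF (Å) of an aligned trajectory.

    rmsf_r = sqrt(⟨|x_r(t) − ⟨x_r⟩|²⟩_t) over each residue's Cα atom;
    residues without a Cα are excluded and reported.
    """
    sel = ca_indices(traj.topology) if selection is None else np.asarray(selection, int)
    coords = np.stack(traj.frames)  # (n_frames, n_atoms, 3)
    values: dict[int, float] = {}
    covered: set[int] = set()
    for i in sel:
        res = traj.topology.atoms[int(i)].residue_id
        x = coords[:, int(i), :]
        dev = x - x.mean(axis=0)
        values[res] = float(np.sqrt((dev**2).sum(axis=1).mean()))
        covered.add(res)
    excluded = sorted(
        {a.residue_id for a in traj.topology.atoms} - covered
    )
    return RMSFProfile(values=values, excluded_residues=excluded)


def normalize(profile: RMSFProfile) -> RMSFProfile:
    """Min–max normalize to [0, 1]; a constant profile maps to zeros, flagged."""
    vals = np.array(list(profile.values.values()))
    keys = list(profile.values.keys())
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        norm = {k: 0.0 for k in keys}
        degenerate = True
    else:
        norm = {k: (v - lo) / (hi - lo) for k, v in profile.values.items()}
        degenerate = False
    return RMSFProfile(
        values=dict(profile.values),
        normalized=norm,
        excluded_residues=list(profile.excluded_residues),
        degenerate=degenerate,
    )


def select_above_average(profile: RMSFProfile) -> list[int]:
    """Residue ids whose normalized RMSF is strictly above the mean normalized value."""
    prof = profile if profile.normalized is not None else normalize(profile)
    norm = prof.normalized
    mean = float(np.mean(list(norm.values())))
    return sorted(r for r, v in norm.items() if v > mean)


def residues_within(
    protein: LabeledMolecule, chromophore: LabeledMolecule, cutoff: float = 4.0
) -> tuple[list[int], int]:
    """Residues with any heavy atom within ``cutoff`` Å of a chromophore heavy atom.

    The cutoff is inclusive (≤).  Returns (sorted residue ids, count).
    """
    chrom_idx = chromophore.heavy_indices()
    if len(chrom_idx) == 0:
        raise ValueError("chromophore has no heavy atoms")
    chrom_pos = chromophore.positions[chrom_idx]
    tree = cKDTree(chrom_pos)
    hits: set[int] = set()
    for i, a in enumerate(protein.atoms):
        if not a.is_heavy:
            continue
        d, _ = tree.query(a.position)
        if d <= cutoff:
            hits.add(a.residue_id)
    ids = sorted(hits)
    return ids, len(ids)


def write_bfactor_pdb(
    structure: LabeledMolecule, profile: RMSFProfile, path: str | Path
) -> Path:
    """Write a PDB with each residue's (normalized) profile value as B-factor.

    Residues absent from the profile get B = 0.00 with a warning.
    """
    source = profile.normalized if profile.normalized is not None else profile.values
    missing = sorted(
        {a.residue_id for a in structure.atoms} - set(source.keys())
    )
    if missing:
        warnings.warn(f"residues without profile values set to B=0.00: {missing}")
    b = [float(source.get(a.residue_id, 0.0)) for a in structure.atoms]
    return write_pdb(structure, path, bfactors=b)


def profile_to_csv(profile: RMSFProfile, path: str | Path) -> Path:
    df = pd.DataFrame(
        {
            "residue_id": list(profile.values.keys()),
            "rmsf": list(profile.values.values()),
            "normalized": [
                (profile.normalized or {}).get(k, np.nan) for k in profile.values
            ],
        }
    )
    df.to_csv(path, index=False)
    return Path(path)
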