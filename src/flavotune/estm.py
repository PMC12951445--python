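"""Electrostatic spectral tuning maps (ESTMs) and gap-shift estimators.

A tuning map records, for each probe position on the 2×VdW surface, the
first-order shift of a state's vertical excitation energy caused by a small
point probe charge.  With per-atom state difference charges Δq_i (excited
minus ground) the frozen-density first-order shift of a probe q at p is

    Δε(p) = k_C · q · Σ_i Δq_i / |p − r_i|      [eV]

Sign convention (load-bearing): positive shift = blue-shift (the probe raises
the excitation energy), negative = red-shift.  The same bilinear form,
contracted against a protein potential φ sampled at the chromophore atoms,
gives the environment-induced state shift

    ΔE_state = Σ_i φ_i(kT/e) · Δq_i · kT(eV)

and the singlet–triplet gap shift Δ(gap) = ΔE_T − ΔE_S1 (positive = the gap
widens, the LOV1-like direction; negative = it narrows, LOV2-like).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import K_COULOMB_EV, T_DEFAULT, kt_ev
from .structures_io import LabeledMolecule
from .surface import SurfaceCloud, generate_surface, region_masks

__all__ = [
    "StateDeltaCharges",
    "TuningMap",
    "GapReport",
    "estm_map",
    "shift_from_environment",
    "gap_shift",
    "gap_report",
    "read_delta_charges",
    "write_delta_charges",
]

CHARGE_SUM_TOL = 1e-6  # e; excitation conserves total charge


@dataclass
class StateDeltaCharges:
    """Per-atom difference charges (e) for one electronic state, zero-sum."""

    state: str
    delta_q: np.ndarray

    def __post_init__(self) -> None:
        self.delta_q = np.asarray(self.delta_q, dtype=float).reshape(-1)
        s = float(self.delta_q.sum())
        if abs(s) > CHARGE_SUM_TOL:
            raise ValueError(
                f"state {self.state!r}: delta charges must sum to 0 "
                f"(excitation conserves charge); got {s:.3e} e"
            )

    def __len__(self) -> int:
        return len(self.delta_q)


@dataclass
class TuningMap:
    """Per-surface-point excitation-energy shifts (eV) for one state."""

    cloud: SurfaceCloud
    state: str
    shifts: np.ndarray
    probe_charge: float

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float).reshape(-1)
        if len(self.shifts) != self.cloud.n_points:
            raise ValueError("one shift per surface point required")

    @property
    def max_redshift(self) -> float:
        return float(self.shifts.min())

    @property
    def max_blueshift(self) -> float:
        return float(self.shifts.max())


@dataclass
class GapReport:
    """Combined tuning capacity of a singlet/triplet map pair."""

    max_redshift_S1: float  # eV, ≤ 0 when present
    max_blueshift_Tn: float  # eV, ≥ 0 when present
    combined_capacity: float  # eV
    degenerate: bool
    region_gap_means: dict[str, float]


def estm_map(
    mol: LabeledMolecule,
    dq: StateDeltaCharges,
    probe: float = 0.1,
    scale: float = 2.0,
    density: float = 1.0,
    cloud: SurfaceCloud | None = None,
) -> TuningMap:
    """Tuning map of one state over the k×VdW surface (k = 2 by default)."""
    if probe == 0:
        raise ValueError("probe charge must be nonzero")
    if len(dq) != mol.n_atoms:
        raise ValueError(
            f"delta-charge set has {len(dq)} entries for a {mol.n_atoms}-atom molecule"
        )
    if cloud is None:
        cloud = generate_surface(mol, scale=scale, density=density)
    d = np.linalg.norm(
        cloud.points[:, None, :] - mol.positions[None, :, :], axis=2
    )
    if d.min() <= 1e-6:
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        raise ValueError(f"surface point {i} coincides with atom index {j}")
    shifts = K_COULOMB_EV * probe * (1.0 / d) @ dq.delta_q
    return TuningMap(cloud=cloud, state=dq.state, shifts=shifts, probe_charge=probe)


def shift_from_environment(
    mol: LabeledMolecule,
    dq: StateDeltaCharges,
    phi_at_atoms: np.ndarray,
    temperature: float = T_DEFAULT,
) -> float:
    """First-order state shift (eV) from a potential φ (kT/e) at each atom."""
    phi = np.asarray(phi_at_atoms, dtype=float).reshape(-1)
    if len(phi) != mol.n_atoms or len(dq) != mol.n_atoms:
        raise ValueError(
            f"need one φ and one Δq per atom ({mol.n_atoms}); "
            f"got {len(phi)} and {len(dq)}"
        )
    return float(np.dot(phi, dq.delta_q) * kt_ev(temperature))


def gap_shift(
    mol: LabeledMolecule,
    dq_s1: StateDeltaCharges,
    dq_tn: StateDeltaCharges,
    phi_at_atoms: np.ndarray,
    temperature: float = T_DEFAULT,
) -> float:
    """Singlet–triplet gap shift (eV); positive = gap widening."""
    return shift_from_environment(mol, dq_tn, phi_at_atoms, temperature) - (
        shift_from_environment(mol, dq_s1, phi_at_atoms, temperature)
    )


def gap_report(map_s1: TuningMap, map_tn: TuningMap) -> GapReport:
    """Extrema of a singlet/triplet map pair and their combined capacity.

    Combined capacity = |max red-shift of S1| + max blue-shift of Tn when the
    S1 map has a red-shifted region and the Tn map a blue-shifted one;
    otherwise only the available one-sided extremum contributes and the
    report is flagged degenerate.
    """
    if map_s1.cloud is not map_tn.cloud and not (
        map_s1.cloud.n_points == map_tn.cloud.n_points
        and np.allclose(map_s1.cloud.points, map_tn.cloud.points)
    ):
        raise ValueError("tuning maps must share one surface cloud")
    red = map_s1.max_redshift
    blue = map_tn.max_blueshift
    degenerate = not (red < 0 and blue > 0)
    capacity = (abs(red) if red < 0 else 0.0) + (blue if blue > 0 else 0.0)
    masks = region_masks(map_s1.cloud)
    gaps = map_tn.shifts - map_s1.shifts
    region_means = {
        name: float(gaps[mask].mean()) for name, mask in masks.items() if mask.any()
    }
    return GapReport(
        max_redshift_S1=red,
        max_blueshift_Tn=blue,
        combined_capacity=capacity,
        degenerate=degenerate,
        region_gap_means=region_means,
    )


def read_delta_charges(path: str | Path, mol: LabeledMolecule, state: str) -> StateDeltaCharges:
    """Read a two-column (atom serial, Δq) text file aligned to a molecule."""
    by_serial: dict[int, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 'serial delta_q'")
        by_serial[int(parts[0])] = float(parts[1])
    dq = np.zeros(mol.n_atoms)
    for i, a in enumerate(mol.atoms):
        if a.serial not in by_serial:
            raise ValueError(f"{path}: no delta charge for atom serial {a.serial}")
        dq[i] = by_serial[a.serial]
    return StateDeltaCharges(state=state, delta_q=dq)


def write_delta_charges(dq: StateDeltaCharges, mol: LabeledMolecule, path: str | Path) -> Path:
    lines = [f"# state {dq.state}: atom_serial delta_q(e)"]
    lines += [f"{a.serial} {v:.6f}" for a, v in zip(mol.atoms, dq.delta_q)]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
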