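"""Average solvent electrostatic configuration (ASEC) environments.

An ASEC environment is built by extracting snapshots from an MD trajectory
at a fixed interval and merging them into one point-charge cloud whose
charges are scaled by 1/N, so the merged cloud's potential equals the
frame-averaged potential at every external point.  QM/MM boundary handling
zeroes the charges of MM atoms near the link atom and redistributes their
total onto neighboring atoms, conserving the global charge.  The iterative
QM-optimize / re-sample loop is exposed as a driver with a pluggable energy
callback; convergence means the last ``window`` excitation energies lie
within ``tol`` of one another (max − min spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .potential_field import ChargeSet
from .structures_io import LabeledMolecule, Trajectory

__all__ = [
    "ASECEnvironment",
    "BoundarySpec",
    "ConvergenceResult",
    "extract_frames",
    "merge_asec",
    "redistribute_boundary",
    "boundary_spec_from_bonds",
    "check_convergence",
    "asec_loop",
    "combine_frame_sets",
    "write_point_charges",
]


@dataclass
class ASECEnvironment:
    """Merged multi-frame point-charge cloud with 1/N-scaled charges."""

    charge_set: ChargeSet
    n_frames: int
    frame_times: list[float]  # ps, provenance
    lj_epsilon: np.ndarray | None = None  # kcal/mol, scaled by 1/N when present
    lj_sigma: np.ndarray | None = None  # Å, unscaled

    @property
    def scale(self) -> float:
        return 1.0 / self.n_frames

    @property
    def total_charge(self) -> float:
        return self.charge_set.total_charge


@dataclass
class BoundarySpec:
    """QM/MM boundary charge handling: which MM atoms are zeroed and who receives."""

    link_atom_host: int
    zeroed_atoms: tuple[int, ...]
    recipient_atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        self.zeroed_atoms = tuple(int(i) for i in self.zeroed_atoms)
        self.recipient_atoms = tuple(int(i) for i in self.recipient_atoms)
        if set(self.zeroed_atoms) & set(self.recipient_atoms):
            raise ValueError("zeroed and recipient atom sets must be disjoint")


@dataclass
class ConvergenceResult:
    converged: bool
    spread: float | None
    window_values: list[float]
    reason: str = ""


def extract_frames(traj: Trajectory, interval: float, count: int) -> list[int]:
    """Indices of ``count`` frames at times interval, 2·interval, … (nearest stored).

    Target times are absolute multiples of the interval (a production run's
    clock starts at zero); on a tie the earlier frame wins.  Raises when the
    trajectory is too short, stating the achievable count.
    """
    if interval <= 0 or count < 1:
        raise ValueError("interval must be positive and count ≥ 1")
    end = float(traj.times[-1])
    if end + 1e-9 < interval * count:
        achievable = int(end // interval)
        raise ValueError(
            f"trajectory ends at {end:g} ps; {count} frames at "
            f"{interval:g} ps intervals need {interval * count:g} ps "
            f"(achievable count: {achievable})"
        )
    t = np.asarray(traj.times, dtype=float)
    picks = []
    for k in range(1, count + 1):
        target = k * interval
        picks.append(int(np.argmin(np.abs(t - target))))  # argmin ties → lower index
    return picks


def merge_asec(
    frames: Sequence[np.ndarray],
    topology: LabeledMolecule,
    frame_times: Sequence[float] | None = None,
    lj_epsilon: np.ndarray | None = None,
    lj_sigma: np.ndarray | None = None,
    scale_lj: bool = True,
) -> ASECEnvironment:
    """Merge frames into one environment with charges (and optionally ε) / N."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    q = np.array(
        [a.charge if a.charge is not None else np.nan for a in topology.atoms]
    )
    if np.isnan(q).any():
        missing = [topology.atoms[i].serial for i in np.where(np.isnan(q))[0][:5]]
        raise ValueError(f"topology atoms without charges: serials {missing}")
    n = len(frames)
    for k, f in enumerate(frames):
        if np.asarray(f).shape != (topology.n_atoms, 3):
            raise ValueError(f"frame {k}: atom count mismatch with topology")
    positions = np.vstack([np.asarray(f, dtype=float) for f in frames])
    charges = np.tile(q / n, n)
    eps = sig = None
    if lj_epsilon is not None:
        eps = np.tile(np.asarray(lj_epsilon, float) / n if scale_lj else lj_epsilon, n)
    if lj_sigma is not None:
        sig = np.tile(np.asarray(lj_sigma, dtype=float), n)
    return ASECEnvironment(
        charge_set=ChargeSet(positions=positions, charges=charges, label="ASEC"),
        n_frames=n,
        frame_times=list(frame_times) if frame_times is not None else list(range(n)),
        lj_epsilon=eps,
        lj_sigma=sig,
    )


def redistribute_boundary(charges: np.ndarray, spec: BoundarySpec) -> np.ndarray:
    """Zero the boundary-shell charges and split their total equally among recipients.

    The global total charge is conserved exactly.
    """
    q = np.asarray(charges, dtype=float).copy()
    for i in list(spec.zeroed_atoms) + list(spec.recipient_atoms):
        if not 0 <= i < len(q):
            raise IndexError(f"atom index {i} out of range for {len(q)} charges")
    removed = float(q[list(spec.zeroed_atoms)].sum()) if spec.zeroed_atoms else 0.0
    if removed != 0.0 and not spec.recipient_atoms:
        raise ValueError(
            f"removed charge {removed:g} e has no recipient atoms to absorb it"
        )
    if spec.zeroed_atoms:
        q[list(spec.zeroed_atoms)] = 0.0
    if spec.recipient_atoms and removed != 0.0:
        q[list(spec.recipient_atoms)] += removed / len(spec.recipient_atoms)
    return q


def boundary_spec_from_bonds(
    bonds: Sequence[tuple[int, int]], link_atom_host: int
) -> BoundarySpec:
    """Derive a boundary spec from bond topology.

    MM atoms within 2 bonds of the link-atom host are zeroed; atoms exactly
    3 bonds away receive the redistributed charge (equal split).
    """
    adj: dict[int, set[int]] = {}
    for a, b in bonds:
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    dist = {int(link_atom_host): 0}
    frontier = [int(link_atom_host)]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    zeroed = tuple(sorted(i for i, d in dist.items() if 1 <= d <= 2))
    recipients = tuple(sorted(i for i, d in dist.items() if d == 3))
    return BoundarySpec(
        link_atom_host=int(link_atom_host),
        zeroed_atoms=zeroed,
        recipient_atoms=recipients,
    )


def check_convergence(
    energies: Sequence[float], tol: float = 0.02, window: int = 4
) -> ConvergenceResult:
    """Converged iff the last ``window`` energies span ≤ ``tol`` eV (max − min)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    if window < 2:
        raise ValueError("window must be ≥ 2")
    vals = [float(e) for e in energies]
    if len(vals) < window:
        return ConvergenceResult(
            converged=False,
            spread=None,
            window_values=vals,
            reason=f"only {len(vals)} iterations; need {window}",
        )
    tail = vals[-window:]
    spread = max(tail) - min(tail)
    return ConvergenceResult(
        converged=spread <= tol,
        spread=spread,
        window_values=tail,
        reason="" if spread <= tol else f"spread {spread:.4f} eV > tol {tol:g} eV",
    )


def asec_loop(
    energy_callback: Callable[[int], float],
    tol: float = 0.02,
    window: int = 4,
    max_iterations: int = 20,
) -> tuple[list[float], ConvergenceResult]:
    """Run the iterative refinement loop until the excitation energy converges.

    ``energy_callback(iteration)`` supplies the excitation energy (eV) of the
    monitored state for each iteration (in the full protocol this wraps a QM
    optimization inside the current environment followed by re-sampling).
    """
    energies: list[float] = []
    result = check_convergence(energies, tol, window)
    for it in range(max_iterations):
        energies.append(float(energy_callback(it)))
        result = check_convergence(energies, tol, window)
        if result.converged:
            break
    return energies, result


def combine_frame_sets(
    frame_sets: Sequence[Sequence[np.ndarray]],
    topology: LabeledMolecule,
    dt: float = 1.0,
) -> Trajectory:
    """Concatenate frames from successive iterations into one analysis trajectory.

    Frames are re-timed at a uniform ``dt`` (ps); used to pool the snapshots
    of several refinement iterations for flexibility analysis.
    """
    frames = [np.asarray(f, dtype=float) for fs in frame_sets for f in fs]
    if not frames:
        raise ValueError("no frames to combine")
    times = [dt * (k + 1) for k in range(len(frames))]
    return Trajectory(topology=topology, frames=frames, times=times)


def write_point_charges(env: ASECEnvironment, path: str | Path) -> Path:
    """Plain point-charge table: x y z q per line."""
    cs = env.charge_set
    lines = [f"# ASEC environment: {env.n_frames} frames, charges scaled by 1/N"]
    lines += [
        f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {q:.8f}"
        for p, q in zip(cs.positions, cs.charges)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
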