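"""Classical point-charge electrostatics: potentials at points and on grids.

The protein's field is modelled as a (optionally Debye-screened) Coulomb sum
over fixed partial charges in a uniform dielectric,

    φ(p) = (k_C / (ε·kT)) · Σ_i q_i · exp(−κ·d_i) / d_i      [kT/e]

with k_C the Coulomb constant in kcal·Å·mol⁻¹·e⁻², kT = RT in kcal/mol.
κ = 0, ε = 1 reduces to the vacuum Coulomb potential.  Grids evaluated here
are node-centered with inclusive boundaries, so a 64 Å box at 0.5 Å spacing
has 129 nodes per axis (2,146,689 total).  Potential maps from an external
Poisson–Boltzmann solver can be substituted via the OpenDX reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EV_TO_KCAL, K_COULOMB_KCAL, T_DEFAULT, kt_kcal
from .structures_io import LabeledMolecule, PotentialGrid

__all__ = ["ChargeSet", "FieldModel", "potential_at", "evaluate_grid", "convert_energy"]

MIN_SEPARATION = 1e-6  # Å


@dataclass
class ChargeSet:
    """Point charges: positions (n×3, Å) and charges (n, e)."""

    positions: np.ndarray
    charges: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if len(self.positions) != len(self.charges):
            raise ValueError("positions/charges length mismatch")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise ValueError("charge set contains non-finite values")

    @classmethod
    def from_molecule(cls, mol: LabeledMolecule, label: str = "") -> "ChargeSet":
        charges = []
        for a in mol.atoms:
            if a.charge is None:
                raise ValueError(f"atom serial {a.serial} has no charge")
            charges.append(a.charge)
        return cls(positions=mol.positions, charges=np.array(charges), label=label)

    def __len__(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def __add__(self, other: "ChargeSet") -> "ChargeSet":
        return ChargeSet(
            positions=np.vstack([self.positions, other.positions]),
            charges=np.concatenate([self.charges, other.charges]),
            label=f"{self.label}+{other.label}",
        )


@dataclass
class FieldModel:
    """Uniform-dielectric screened-Coulomb field parameters."""

    relative_dielectric: float = 1.0
    debye_kappa: float = 0.0  # Å⁻¹
    temperature: float = T_DEFAULT  # K

    def __post_init__(self) -> None:
        if self.relative_dielectric < 1:
            raise ValueError("relative_dielectric must be ≥ 1")
        if self.debye_kappa < 0:
            raise ValueError("debye_kappa must be ≥ 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def potential_at(
    points: np.ndarray, charges: ChargeSet, model: FieldModel | None = None
) -> np.ndarray:
    """Electrostatic potential (kT/e) at each evaluation point.

    Raises if any evaluation point lies within 1e−6 Å of a charge.
    """
    model = model or FieldModel()
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(charges) == 0:
        return np.zeros(len(pts))
    pref = K_COULOMB_KCAL / (model.relative_dielectric * kt_kcal(model.temperature))
    kappa = model.debye_kappa
    out = np.empty(len(pts))
    chunk = max(1, int(2_000_000 // max(1, len(charges))))
    for s in range(0, len(pts), chunk):
        block = pts[s : s + chunk]
        d = np.linalg.norm(block[:, None, :] - charges.positions[None, :, :], axis=2)
        if d.min() <= MIN_SEPARATION:
            i, j = np.unravel_index(int(d.argmin()), d.shape)
            raise ValueError(
                f"evaluation point {s + i} coincides with charge {j} "
                f"(separation {d[i, j]:.2e} Å ≤ {MIN_SEPARATION} Å)"
            )
        kern = np.exp(-kappa * d) / d if kappa > 0 else 1.0 / d
        out[s : s + chunk] = pref * kern @ charges.charges
    return out


def evaluate_grid(
    charges: ChargeSet,
    box_edge: float,
    spacing: float,
    center: np.ndarray | None = None,
    model: FieldModel | None = None,
) -> PotentialGrid:
    """Evaluate the potential on a node-centered cubic grid (kT/e).

    Counts per axis = box_edge/spacing + 1 (both boundary planes included);
    spacing must divide box_edge exactly.
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    ratio = box_edge / spacing
    n = round(ratio)
    if abs(ratio - n) > 1e-9:
        raise ValueError(f"spacing {spacing} does not divide box edge {box_edge} exactly")
    counts = (n + 1, n + 1, n + 1)
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float).reshape(3)
    origin = center - box_edge / 2.0
    ax = [origin[d] + spacing * np.arange(counts[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    values = potential_at(nodes, charges, model)
    return PotentialGrid(
        origin=origin, spacing=np.full(3, float(spacing)), counts=counts, values=values
    )


_UNIT_ALIASES = {
    "ev": "eV",
    "kcal/mol": "kcal/mol",
    "kcal": "kcal/mol",
    "kt": "kT",
}


def convert_energy(
    value: float, from_unit: str, to_unit: str, temperature: float = T_DEFAULT
) -> float:
    """Convert an energy among eV, kcal/mol and kT(T).

    1 eV = 23.060548 kcal/mol; 1 kT = RT kcal/mol.  Round-trips are exact to
    floating-point precision.
    """

    def canon(u: str) -> str:
        key = u.strip().lower()
        if key not in _UNIT_ALIASES:
            raise ValueError(f"unknown unit {u!r}; supported: eV, kcal/mol, kT")
        return _UNIT_ALIASES[key]

    f, t = canon(from_unit), canon(to_unit)
    to_kcal = {"eV": EV_TO_KCAL, "kcal/mol": 1.0, "kT": kt_kcal(temperature)}
    return float(value) * to_kcal[f] / to_kcal[t]
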