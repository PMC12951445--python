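"""Electrostatic projection maps: grid → chromophore-surface sampling.

The projection rule is the unweighted mean of the 8 grid nodes nearest to
each surface point (true nearest nodes by Euclidean distance, found with a
KD-tree and tie-broken by node index) — note this differs from trilinear
cell-corner interpolation when a point sits near a node, so trilinear is
offered only as an alternative method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .structures_io import PotentialGrid
from .surface import SurfaceCloud, export_cloud_pdb, region_masks

__all__ = ["ProjectionMap", "project", "summarize_regions", "export_colored"]

DEFAULT_CLIP = (-0.25, 0.25)  # kT/e, the conventional rendering range


@dataclass
class ProjectionMap:
    """Per-surface-point potential values (kT/e) with a rendering clip range."""

    cloud: SurfaceCloud
    values: np.ndarray
    color_clip: tuple[float, float] = DEFAULT_CLIP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) != self.cloud.n_points:
            raise ValueError("one value per surface point required")
        if not self.color_clip[0] < self.color_clip[1]:
            raise ValueError("clip low must be < clip high")

    @property
    def clipped_values(self) -> np.ndarray:
        return np.clip(self.values, *self.color_clip)


def _nearest_mean(grid: PotentialGrid, points: np.ndarray, m: int) -> np.ndarray:
    nodes = grid.node_coordinates()
    flat = grid.values.ravel()  # z-fastest, matching node_coordinates ordering
    tree = cKDTree(nodes)
    k = min(m + 8, len(nodes))  # headroom so distance ties can be re-sorted
    dist, idx = tree.query(points, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = np.empty(len(points))
    for i in range(len(points)):
        # deterministic tie-break: sort by (quantized distance, node index)
        order = np.lexsort((idx[i], np.round(dist[i] / 1e-9).astype(np.int64)))
        out[i] = flat[idx[i][order[:m]]].mean()
    return out


def project(
    grid: PotentialGrid,
    cloud: SurfaceCloud,
    m_neighbors: int = 8,
    method: str = "nearest",
    color_clip: tuple[float, float] = DEFAULT_CLIP,
) -> ProjectionMap:
    """Sample a potential grid onto a surface cloud.

    ``method="nearest"`` averages the ``m_neighbors`` nearest grid nodes;
    ``method="trilinear"`` interpolates within the enclosing cell.  Every
    surface point must lie inside the grid bounds.
    """
    if m_neighbors < 1:
        raise ValueError("m_neighbors must be ≥ 1")
    lo, hi = grid.bounds()
    outside = np.any((cloud.points < lo - 1e-12) | (cloud.points > hi + 1e-12), axis=1)
    if outside.any():
        i = int(np.argmax(outside))
        raise ValueError(
            f"surface point {i} at {cloud.points[i]} lies outside grid bounds "
            f"[{lo}, {hi}]"
        )
    if method == "nearest":
        values = _nearest_mean(grid, cloud.points, m_neighbors)
    elif method == "trilinear":
        interp = RegularGridInterpolator(grid.axes(), grid.values)
        values = interp(cloud.points)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ProjectionMap(cloud=cloud, values=values, color_clip=color_clip)


def summarize_regions(pmap: ProjectionMap) -> dict[str, dict]:
    """Per-region potential statistics (mean/min/max/n_points/sign).

    Regions include ring labels, labeled sites and the composite N5/C4 and
    C2/N3 faces; sign is "positive" iff the region minimum is > 0, "negative"
    iff its maximum is < 0, else "mixed".
    """
    masks = region_masks(pmap.cloud)
    summary: dict[str, dict] = {}
    for name, mask in masks.items():
        if not mask.any():
            continue
        v = pmap.values[mask]
        vmin, vmax = float(v.min()), float(v.max())
        sign = "positive" if vmin > 0 else "negative" if vmax < 0 else "mixed"
        summary[name] = {
            "mean": float(v.mean()),
            "min": vmin,
            "max": vmax,
            "n_points": int(mask.sum()),
            "sign": sign,
        }
    return summary


def export_colored(pmap: ProjectionMap, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` and a pseudo-atom ``<prefix>.pdb``.

    The CSV carries raw and clipped values; the PDB stores the clipped value
    in the B-factor column for external rendering.
    """
    prefix = Path(path_prefix)
    cloud = pmap.cloud
    masks = region_masks(cloud)
    primary = np.full(cloud.n_points, "substituent", dtype=object)
    for ring in ("xylene", "central", "pyrimidine"):
        if ring in masks:
            primary[masks[ring]] = ring
    df = pd.DataFrame(
        {
            "x": cloud.points[:, 0],
            "y": cloud.points[:, 1],
            "z": cloud.points[:, 2],
            "parent_serial": [cloud.source.atoms[int(p)].serial for p in cloud.parent],
            "region": primary,
            "value": pmap.values,
            "clipped_value": pmap.clipped_values,
        }
    )
    csv_path = prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    pdb_path = prefix.with_suffix(".pdb")
    export_cloud_pdb(cloud, pdb_path, values=pmap.clipped_values)
    return csv_path, pdb_path
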