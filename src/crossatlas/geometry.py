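"""Embryo geometry: surface area, local nuclear density, cylindrical
projection, inter-atlas spatial alignment and density-grid averaging.

Conventions: the anterior–posterior (AP) axis is the first coordinate axis
(anterior at low x), dorsal is the +y direction.  The cylindrical angle is
0 on the dorsal midline and increases toward the embryo's left side, in
radians on [-pi, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .atlas import Atlas
from .errors import IntegrityError


@dataclass
class DensityMap:
    """Per-cell surface nuclear densities (nuclei / µm²) for one cohort."""

    values: np.ndarray  # (n_cells,)
    cohort: int
    radius: float       # µm


@dataclass
class DensityGrid:
    """Densities resampled on a regular axial × angle grid, averaged over maps.

    ``samples`` retains the per-map resampled values (n_maps, n_axial, n_angle)
    so downstream statistics (e.g. per-node t-tests) can be computed.
    """

    axial_centers: np.ndarray   # (n_axial,) in [0, 1]
    angle_centers: np.ndarray   # (n_angle,) in [-pi, pi)
    mean: np.ndarray            # (n_axial, n_angle)
    sd: np.ndarray
    n: int
    samples: np.ndarray


@dataclass
class ProjectionCoords:
    """Cylindrical coordinates per cell: axial egg-length fraction and angle."""

    axial: np.ndarray  # (n_cells,) in [0, 1]
    angle: np.ndarray  # (n_cells,) in [-pi, pi)


# ------------------------------------------------------------- triangulation

def triangles_from_edges(edges: np.ndarray, n_cells: int) -> np.ndarray:
    """Enumerate the triangular faces of the surface neighbor graph.

    Faces are recovered as 3-cliques.  For a triangulated closed (or open)
    surface every edge must belong to one or two triangles; any edge in
    zero or more than two indicates non-triangular faces and is rejected.
    """
    adj = [set() for _ in range(n_cells)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    tris = []
    edge_cover = {}
    for a, b in np.sort(edges, axis=1):
        a, b = int(a), int(b)
        for c in adj[a] & adj[b]:
            if c > b:
                tris.append((a, b, c))
    for tri in tris:
        a, b, c = tri
        for e in ((a, b), (a, c), (b, c)):
            edge_cover[e] = edge_cover.get(e, 0) + 1
    for a, b in np.sort(edges, axis=1):
        cnt = edge_cover.get((int(a), int(b)), 0)
        if cnt == 0 or cnt > 2:
            raise IntegrityError(
                f"edge ({a}, {b}) lies in {cnt} triangles; "
                "neighbor graph is not a triangulated surface"
            )
    return np.array(tris, dtype=np.int64)


def surface_area(atlas: Atlas, t: int) -> float:
    """Total surface area (µm²) at cohort ``t``: sum of triangle areas
    defined by the neighbor relation.  Degenerate triangles contribute 0.
    """
    tris = triangles_from_edges(atlas.edges, atlas.n_cells)
    p = atlas.positions[:, t - 1, :]
    v1 = p[tris[:, 1]] - p[tris[:, 0]]
    v2 = p[tris[:, 2]] - p[tris[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=1)
    return float(areas.sum())


# ------------------------------------------------------------------- density

def local_density(atlas: Atlas, t: int, radius: float = 15.0) -> DensityMap:
    """Per-nucleus density: nuclei within ``radius`` µm (3D chord distance,
    the focal nucleus included) divided by the disk area pi r².
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = atlas.positions[:, t - 1, :]
    tree = cKDTree(p)
    counts = np.array(tree.query_ball_point(p, r=radius, return_length=True))
    return DensityMap(values=counts / (np.pi * radius**2), cohort=t, radius=radius)


def mean_internuclear_spacing(atlas: Atlas, t: int) -> float:
    """Mean distance to the spatially nearest other nucleus, in µm."""
    p = atlas.positions[:, t - 1, :]
    tree = cKDTree(p)
    d, _ = tree.query(p, k=2)
    return float(d[:, 1].mean())


# ---------------------------------------------------------------- projection

def cylindrical_projection(atlas: Atlas, t: int) -> ProjectionCoords:
    """Unroll the embryo surface: axial egg-length fraction vs angle.

    Requires the atlas in standard orientation (AP along x, dorsal +y).
    """
    p = atlas.positions[:, t - 1, :]
    x = p[:, 0]
    extent = x.max() - x.min()
    if extent <= 0:
        raise IntegrityError("zero AP extent; cannot project")
    axial = (x - x.min()) / extent
    angle = np.arctan2(p[:, 2], p[:, 1])
    angle = np.where(angle >= np.pi, angle - 2 * np.pi, angle)  # [-pi, pi)
    return ProjectionCoords(axial=axial, angle=angle)


def align_atlases(query: Atlas, target: Atlas, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Put both atlases in a common scaled frame at cohort ``t``.

    Each atlas is isotropically scaled to unit egg length (AP extent 1) and
    translated so its nuclear center of mass sits at the origin.  Returns
    the two (n_cells, 3) position arrays.
    """
    return _align_one(query, t), _align_one(target, t)


def _align_one(atlas: Atlas, t: int) -> np.ndarray:
    p = atlas.positions[:, t - 1, :]
    extent = p[:, 0].max() - p[:, 0].min()
    if extent <= 0:
        raise IntegrityError("zero AP extent; cannot align")
    scaled = p / extent
    return scaled - scaled.mean(axis=0)


# ------------------------------------------------------------- grid averages

def average_density_grid(
    maps: list[tuple[DensityMap, ProjectionCoords]],
    n_axial: int = 20,
    n_angle: int = 16,
) -> DensityGrid:
    """Resample per-cell density maps onto a regular cylindrical grid and
    average across maps (nearest-cell resampling; angle wraps around).
    """
    if not maps:
        raise ValueError("need at least one density map")
    ax_edges = np.linspace(0, 1, n_axial + 1)
    ang_edges = np.linspace(-np.pi, np.pi, n_angle + 1)
    ax_c = 0.5 * (ax_edges[:-1] + ax_edges[1:])
    ang_c = 0.5 * (ang_edges[:-1] + ang_edges[1:])
    gx, ga = np.meshgrid(ax_c, ang_c, indexing="ij")
    nodes = np.column_stack([gx.ravel(), ga.ravel()])

    samples = np.empty((len(maps), n_axial, n_angle))
    for mi, (dm, pc) in enumerate(maps):
        # duplicate cells at angle ± 2π so nearest-neighbor search wraps
        pts = np.column_stack([
            np.tile(pc.axial, 3),
            np.concatenate([pc.angle - 2 * np.pi, pc.angle, pc.angle + 2 * np.pi]),
        ])
        vals = np.tile(dm.values, 3)
        tree = cKDTree(pts)
        _, idx = tree.query(nodes)
        samples[mi] = vals[idx].reshape(n_axial, n_angle)

    return DensityGrid(
        axial_centers=ax_c,
        angle_centers=ang_c,
        mean=samples.mean(axis=0),
        sd=samples.std(axis=0, ddof=0),
        n=len(maps),
        samples=samples,
    )
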