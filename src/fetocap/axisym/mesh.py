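"""Structured triangular meshes of the axisymmetric meridian domain.

The tube {0 <= r <= R(z), 0 <= z <= L} is meshed by a tensor grid:
``resolution`` cells across the radius (optionally graded toward the
wall to resolve the high-Péclet concentration boundary layer) and a
near-uniform axial subdivision, each quad split into two triangles.
Boundary edges carry exactly one tag: ``gamma_in`` (z = 0), ``gamma_out``
(z = L), ``axis`` (r = 0), and the wall split into ``gamma_d`` (the
dilation window, where oxygen is supplied) and ``gamma_u`` (the
remaining, impermeable wall).  An annulus variant replaces the axis with
an ``inner`` boundary for the villous-tissue diffusion oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..shape import DilationShape, shape_extrema

__all__ = ["AxisymMesh", "build_annulus_mesh", "build_mesh"]


@dataclass
class AxisymMesh:
    """Triangulated meridian domain with tagged boundary edges.

    ``nodes`` holds (r, z) in um for the corner (P1) nodes; ``tris`` is
    the (ntri, 3) corner connectivity with positive orientation;
    ``boundary`` maps tag -> (nedge, 2) arrays of corner-node pairs,
    ordered along the boundary.
    """

    nodes: np.ndarray
    tris: np.ndarray
    boundary: dict[str, np.ndarray]
    shape: DilationShape | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.nodes[:, 0] < -1e-12):
            raise ValueError("mesh nodes must have r >= 0")
        seen: set[tuple[int, int]] = set()
        for tag, edges in self.boundary.items():
            for e in np.asarray(edges).reshape(-1, 2):
                key = (min(e), max(e))
                if key in seen:
                    raise ValueError(f"boundary edge {key} carries more than one tag")
                seen.add(key)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tris(self) -> int:
        return self.tris.shape[0]

    def volume(self) -> float:
        """Volume of revolution 2*pi * sum over elements of r dA."""
        p = self.nodes[self.tris]
        det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        r_cent = p[:, :, 0].mean(axis=1)
        return float(2.0 * math.pi * np.sum(0.5 * det * r_cent))


def _radial_fractions(nr: int, grading_exponent: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, nr + 1)
    if grading_exponent == 1.0:
        return t
    return 1.0 - (1.0 - t) ** grading_exponent


def _grading_for_target(nr: int, target_peclet: float) -> float:
    """Exponent so the wall cell is <= R * Pe^{-1/3} / 4 (and never coarser than uniform)."""
    frac = min(target_peclet ** (-1.0 / 3.0) / 4.0, 1.0 / nr)
    q = math.log(frac) / math.log(1.0 / nr)
    return min(max(q, 1.0), 3.0)


def _structured_mesh(
    r_inner: np.ndarray,
    r_outer: np.ndarray,
    z_nodes: np.ndarray,
    eta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    nr = len(eta) - 1
    nz = len(z_nodes) - 1
    rr = r_inner[None, :] + eta[:, None] * (r_outer - r_inner)[None, :]
    zz = np.broadcast_to(z_nodes[None, :], rr.shape)
    nodes = np.column_stack([rr.T.ravel(), zz.T.ravel()])  # idx = j*(nr+1)+i

    def idx(i, j):
        return j * (nr + 1) + i

    tris = []
    for j in range(nz):
        for i in range(nr):
            n00, n10 = idx(i, j), idx(i + 1, j)
            n01, n11 = idx(i, j + 1), idx(i + 1, j + 1)
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    tris = np.asarray(tris, dtype=np.int64)
    # enforce positive orientation in the (r, z) plane
    p = nodes[tris]
    det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = det < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return nodes, tris, nr, nz


def build_mesh(
    shape: DilationShape,
    resolution: int = 13,
    bl_refine: bool = True,
    target_peclet: float = 500.0,
    axial_spacing: float | None = None,
    max_axial_cells: int = 400,
) -> AxisymMesh:
    """Mesh the dilated tube described by ``shape``.

    ``resolution`` is the number of cells across the radius (>= 8).  With
    ``bl_refine`` the radial grid is graded toward the wall so that the
    first cell is no thicker than R0*Pe^{-1/3}/4 at ``target_peclet``.
    Axial spacing defaults to max(R0/8, L/160) (capped at
    ``max_axial_cells`` cells), with the grid conforming to the dilation
    window so that ``gamma_d`` spans it exactly and grid lines cluster
    toward the window edges where the wall concentration jumps.
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    r_min, _, _ = shape_extrema(shape)
    if r_min < shape.r_min_fraction * shape.R0 - 1e-12:
        raise ValueError(
            f"shape violates the occlusion floor: min R = {r_min:.4g} um < "
            f"{shape.r_min_fraction:.2f} * R0 = {shape.r_min_fraction * shape.R0:.4g} um"
        )
    L = shape.L
    dz = axial_spacing if axial_spacing is not None else max(shape.R0 / 8.0, L / 160.0)
    # piecewise axial grid conforming to the window, with grid lines
    # clustered toward the window edges where the wall concentration jumps
    breaks = sorted({0.0, shape.z_start, shape.z_start + shape.lam, L})
    segments = [
        (a, b) for a, b in zip(breaks[:-1], breaks[1:]) if b - a > 1e-12
    ]
    total_cells = min(max(int(math.ceil(L / dz)), 16), max_axial_cells)
    z_parts: list[np.ndarray] = []
    for a, b in segments:
        m = max(int(round(total_cells * (b - a) / L)), 4)
        t = np.linspace(0.0, 1.0, m + 1)
        cluster = 0.5 * (1.0 - np.cos(math.pi * t))  # both-end clustering
        tt = 0.5 * t + 0.5 * cluster
        z_parts.append(a + (b - a) * tt)
    z_nodes = np.unique(np.concatenate(z_parts))
    nz = len(z_nodes) - 1
    if np.any(np.diff(z_nodes) <= 0):
        raise ValueError("degenerate axial grid")

    q = _grading_for_target(resolution, target_peclet) if bl_refine else 1.0
    eta = _radial_fractions(resolution, q)
    r_wall = np.asarray(shape.radius(z_nodes), dtype=float)
    nodes, tris, nr, nz = _structured_mesh(
        np.zeros_like(z_nodes), r_wall, z_nodes, eta
    )

    def idx(i, j):
        return j * (nr + 1) + i

    inlet = np.array([[idx(i, 0), idx(i + 1, 0)] for i in range(nr)])
    outlet = np.array([[idx(i, nz), idx(i + 1, nz)] for i in range(nr)])
    axis = np.array([[idx(0, j), idx(0, j + 1)] for j in range(nz)])
    wall = np.array([[idx(nr, j), idx(nr, j + 1)] for j in range(nz)])
    z_mid = 0.5 * (z_nodes[:-1] + z_nodes[1:])
    in_window = (z_mid >= shape.z_start - 1e-9) & (
        z_mid <= shape.z_start + shape.lam + 1e-9
    )
    boundary = {
        "gamma_in": inlet,
        "gamma_out": outlet,
        "axis": axis,
        "gamma_d": wall[in_window],
        "gamma_u": wall[~in_window],
    }
    return AxisymMesh(
        nodes=nodes,
        tris=tris,
        boundary=boundary,
        shape=shape,
        meta={
            "nr": nr,
            "nz": nz,
            "grading_exponent": q,
            "wall_cell_fraction": (1.0 / nr) ** q,
            "target_peclet": target_peclet,
        },
    )


def build_annulus_mesh(
    R0: float, d: float, L: float, resolution: int = 10, n_axial: int = 16
) -> AxisymMesh:
    """Mesh the concentric annulus R0 <= r <= R0 + d, 0 <= z <= L.

    Tags: ``inner`` (capillary surface), ``gamma_d`` (oxygenated villous
    surface at r = R0 + d), ``gamma_in``/``gamma_out`` the two end caps.
    """
    if R0 <= 0 or d <= 0 or L <= 0:
        raise ValueError("R0, d and L must be positive")
    z_nodes = np.linspace(0.0, L, n_axial + 1)
    eta = np.linspace(0.0, 1.0, resolution + 1)
    nodes, tris, nr, nz = _structured_mesh(
        np.full_like(z_nodes, R0), np.full_like(z_nodes, R0 + d), z_nodes, eta
    )

    def idx(i, j):
        return j * (nr + 1) + i

    boundary = {
        "gamma_in": np.array([[idx(i, 0), idx(i + 1, 0)] for i in range(nr)]),
        "gamma_out": np.array([[idx(i, nz), idx(i + 1, nz)] for i in range(nr)]),
        "inner": np.array([[idx(0, j), idx(0, j + 1)] for j in range(nz)]),
        "gamma_d": np.array([[idx(nr, j), idx(nr, j + 1)] for j in range(nz)]),
    }
    return AxisymMesh(nodes=nodes, tris=tris, boundary=boundary, meta={"nr": nr, "nz": nz})
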