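"""Body-fitted hexahedral tube meshes with a mesh-fidelity slider.

The mesh is a structured "butterfly" (O-H) topology: an m x m core block
surrounded by rings of cells, swept along the vessel centerline.  A fidelity
percentage in [1, 100] maps geometrically onto a target cell count between
``n_min`` and ``n_max``; five canonical levels (10/25/50/75/100%) form the
fidelity experiment.  The three wall-adjacent cell rings are geometrically
graded (ratio 1.3) so the viscous boundary layer is better resolved than the
interior, in the spirit of prism layers.

Cell counts are desk-scale (defaults 600–6,000 cells, reference arm at
12,000): small enough for an interpreted finite-volume solver to sweep a
40-vessel cohort, large enough for the convergence behaviour the fidelity
experiment probes.  Meshing is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MeshingError, ValidationError
from .geometry import VesselGeometry, _parallel_transport_frames
from .units import MM

__all__ = [
    "FidelityLevel",
    "TubeMesh",
    "QualityReport",
    "CANONICAL_FIDELITIES",
    "N_MIN_DEFAULT",
    "N_MAX_DEFAULT",
    "REFERENCE_FACTOR",
    "fidelity_to_cells",
    "fidelity_level",
    "build_mesh",
    "cell_volumes",
    "mesh_volume",
    "analytic_volume",
    "mesh_quality",
    "write_vtu",
]

CANONICAL_FIDELITIES = (10, 25, 50, 75, 100)

#: Desk-scale cell budget of the fidelity slider.
N_MIN_DEFAULT = 600
N_MAX_DEFAULT = 6_000
#: The reference ("CPU-analog") arm runs at REFERENCE_FACTOR * n_max cells.
REFERENCE_FACTOR = 2

_WALL_LAYERS = 3
_WALL_RATIO = 1.3
_CORE_HALF_WIDTH = 0.45  # core square half-width on the unit disk


def fidelity_to_cells(percent: int, n_min: int = N_MIN_DEFAULT,
                      n_max: int = N_MAX_DEFAULT) -> int:
    """Geometric fidelity -> cell-count law.

    ``n_min * (n_max/n_min) ** ((percent-1)/99)`` rounded to an integer:
    percent=1 maps to ``n_min``, percent=100 to ``n_max``, strictly
    increasing in between.
    """
    if not (isinstance(percent, (int, np.integer)) and 1 <= percent <= 100):
        raise ValidationError(f"fidelity percent must be an integer in [1, 100], got {percent!r}")
    if not n_min < n_max:
        raise ValidationError(f"need n_min < n_max, got {n_min} >= {n_max}")
    return int(round(n_min * (n_max / n_min) ** ((percent - 1) / 99.0)))


@dataclass(frozen=True)
class FidelityLevel:
    percent: int
    target_cells: int

    def __post_init__(self):
        if not 1 <= self.percent <= 100:
            raise ValidationError(f"fidelity percent must be in [1, 100], got {self.percent}")
        if self.target_cells <= 0:
            raise ValidationError("target_cells must be positive")


def fidelity_level(percent: int, n_min: int = N_MIN_DEFAULT,
                   n_max: int = N_MAX_DEFAULT) -> FidelityLevel:
    return FidelityLevel(percent=int(percent),
                         target_cells=fidelity_to_cells(int(percent), n_min, n_max))


@dataclass
class TubeMesh:
    """Structured hex mesh of a tube, stored in SI metres.

    Faces are unique; ``face_owner``/``face_neigh`` give the adjacent cells
    (-1 for boundary) and ``face_tag`` is -1 (internal), 0 (inlet cap),
    1 (outlet cap) or 2 (wall).  Face nodes are ordered outward from the
    owner cell.
    """

    nodes: np.ndarray            # (Nn, 3) m
    cells: np.ndarray            # (Nc, 8) node ids
    cell_layer: np.ndarray       # (Nc,) axial layer index
    face_nodes: np.ndarray       # (Nf, 4)
    face_owner: np.ndarray       # (Nf,)
    face_neigh: np.ndarray       # (Nf,) -1 for boundary
    face_tag: np.ndarray         # (Nf,)
    station_arclength_mm: np.ndarray  # (n_axial + 1,)
    station_radius_mm: np.ndarray     # (n_axial + 1,)
    fidelity: FidelityLevel
    n_axial: int
    section_cells: int

    INLET, OUTLET, WALL = 0, 1, 2

    @property
    def cell_count(self) -> int:
        return len(self.cells)

    @property
    def layer_arclength_mm(self) -> np.ndarray:
        """Mid-cell arclength of each axial layer (mm)."""
        s = self.station_arclength_mm
        return 0.5 * (s[:-1] + s[1:])

    def signature(self) -> tuple:
        """Cheap identity token used to pair solutions on one mesh."""
        return (self.cell_count, self.n_axial, self.section_cells,
                float(self.nodes[0, 0]), float(self.nodes[-1, 2]),
                float(self.station_radius_mm.min()),
                float(self.station_radius_mm.sum()))


# ---------------------------------------------------------------------------
# section template

def _ring_fractions(n_rings: int) -> np.ndarray:
    """Radial blend fractions of the ring loops, wall layers graded."""
    n_uniform = n_rings - _WALL_LAYERS
    if n_uniform < 1:
        raise MeshingError(f"need at least {_WALL_LAYERS + 1} rings, got {n_rings}")
    graded = 1.0 / _WALL_RATIO ** np.arange(1, _WALL_LAYERS + 1)
    widths = np.concatenate([np.ones(n_uniform), graded])
    widths /= widths.sum()
    return np.cumsum(widths)


def _section_template(m: int):
    """Butterfly section on the unit disk.

    Returns (nodes2d, quads, n_outer) where the last ``n_outer`` nodes form
    the wall loop.  Core m x m cells plus m rings of 4m cells = 5 m^2 cells.
    """
    a = _CORE_HALF_WIDTH
    xs = np.linspace(-a, a, m + 1)
    core = np.array([[x, y] for y in xs for x in xs])  # id = j*(m+1)+i
    nid = np.arange((m + 1) ** 2).reshape(m + 1, m + 1)  # [j, i]

    # core quads, CCW in (x, y)
    quads = []
    for j in range(m):
        for i in range(m):
            quads.append([nid[j, i], nid[j, i + 1], nid[j + 1, i + 1], nid[j + 1, i]])

    # core perimeter, CCW from corner (-a, -a)
    perim = ([nid[0, i] for i in range(m)]
             + [nid[j, m] for j in range(m)]
             + [nid[m, m - i] for i in range(m)]
             + [nid[m - j, 0] for j in range(m)])
    perim = np.array(perim)
    n_per = len(perim)  # 4m

    nodes = [core]
    fractions = _ring_fractions(m)
    sq = core[perim]
    theta = np.arctan2(sq[:, 1], sq[:, 0])
    # inflate the wall loop so the inscribed polygon preserves the disc area
    # (a k-gon at radius r has area (k/2) r^2 sin(2 pi / k))
    k_seg = n_per
    lam = np.sqrt(2.0 * np.pi / k_seg / np.sin(2.0 * np.pi / k_seg))
    circ = lam * np.column_stack([np.cos(theta), np.sin(theta)])
    base = len(core)
    prev_loop = perim
    for t in fractions:
        ring = (1.0 - t) * sq + t * circ
        ids = base + np.arange(n_per)
        base += n_per
        nodes.append(ring)
        nxt = np.roll(np.arange(n_per), -1)
        for k in range(n_per):
            quads.append([prev_loop[k], ids[k], ids[nxt[k]], prev_loop[nxt[k]]])
        prev_loop = ids
    nodes2d = np.vstack(nodes)
    return nodes2d, np.asarray(quads, dtype=np.int64), n_per


def _choose_resolution(target_cells: int) -> tuple[int, int]:
    """Pick (m, n_axial) from the target cell count.

    Both the section parameter m and the axial count grow monotonically
    with the target (floor for m, remainder into the axial direction), so
    the fidelity ladder forms a nested-resolution family: refinement never
    trades axial for radial resolution, which keeps discretization error
    decreasing along the ladder.
    """
    m = max(4, int((target_cells / 30.0) ** (1.0 / 3.0)))
    n_ax = max(10, int(round(target_cells / (5.0 * m * m))))
    return m, n_ax


_HEX_FACES = np.array([
    [0, 3, 2, 1],   # upstream cap side
    [4, 5, 6, 7],   # downstream side
    [0, 1, 5, 4],
    [1, 2, 6, 5],
    [2, 3, 7, 6],
    [3, 0, 4, 7],
])


def build_mesh(geometry: VesselGeometry, fidelity: FidelityLevel | int,
               n_min: int = N_MIN_DEFAULT, n_max: int = N_MAX_DEFAULT) -> TubeMesh:
    """Sweep a butterfly section along the centerline at a fidelity level."""
    if not isinstance(fidelity, FidelityLevel):
        fidelity = fidelity_level(int(fidelity), n_min, n_max)
    m, n_ax = _choose_resolution(fidelity.target_cells)
    nodes2d, quads2d, _ = _section_template(m)
    n_sec_nodes = len(nodes2d)
    n_sec_cells = len(quads2d)

    s = np.linspace(0.0, geometry.arclength_total, n_ax + 1)
    centers = geometry.center_at(s)
    radii = geometry.radius_at(s)

    # sweep frames from the resampled vessel centerline
    cl = np.column_stack([
        np.interp(s, geometry.arclength, geometry.centerline[:, k]) for k in range(3)])
    tang = np.diff(cl, axis=0)
    angles = np.array([0.0] + [
        np.degrees(np.arccos(np.clip(
            np.dot(tang[i], tang[i + 1])
            / (np.linalg.norm(tang[i]) * np.linalg.norm(tang[i + 1])), -1, 1)))
        for i in range(len(tang) - 1)])
    too_sharp = np.nonzero(angles > 45.0)[0]
    if too_sharp.size:
        raise MeshingError("centerline turns too sharply for a structured sweep",
                           station=int(too_sharp[0]))
    frames = _parallel_transport_frames(cl)

    # nodes: (station, section node) in mm, then SI
    pos = (centers[:, None, :]
           + radii[:, None, None] * (nodes2d[None, :, 0, None] * frames[:, None, 1, :]
                                     + nodes2d[None, :, 1, None] * frames[:, None, 2, :]))
    nodes = pos.reshape(-1, 3) * MM

    k = np.arange(n_ax)[:, None, None]
    q = quads2d[None, :, :]
    bottom = k * n_sec_nodes + q
    top = (k + 1) * n_sec_nodes + q
    cells = np.concatenate([bottom, top], axis=2).reshape(-1, 8)
    cell_layer = np.repeat(np.arange(n_ax), n_sec_cells)

    face_nodes, face_owner, face_neigh, face_tag = _extract_faces(
        cells, n_sec_nodes, n_ax)

    return TubeMesh(nodes=nodes, cells=cells, cell_layer=cell_layer,
                    face_nodes=face_nodes, face_owner=face_owner,
                    face_neigh=face_neigh, face_tag=face_tag,
                    station_arclength_mm=s, station_radius_mm=radii,
                    fidelity=fidelity, n_axial=n_ax, section_cells=n_sec_cells)


def _extract_faces(cells: np.ndarray, n_sec_nodes: int, n_ax: int):
    n_cells = len(cells)
    faces_all = cells[:, _HEX_FACES]                    # (Nc, 6, 4)
    flat = faces_all.reshape(-1, 4)
    keys = np.sort(flat, axis=1)
    _, first, inverse, counts = np.unique(
        keys, axis=0, return_index=True, return_inverse=True, return_counts=True)
    if counts.max() > 2:
        raise MeshingError("non-manifold face detected")
    order = np.argsort(inverse, kind="stable")
    starts = np.concatenate([[0], np.cumsum(counts)])[:-1]
    idx_first = order[starts]
    owner = idx_first // 6
    face_nodes = flat[idx_first]                        # owner-outward ordering
    neigh = np.full(len(counts), -1, dtype=np.int64)
    internal = counts == 2
    idx_second = order[starts[internal] + 1]
    neigh[internal] = idx_second // 6

    station = face_nodes // n_sec_nodes
    tag = np.full(len(counts), -1, dtype=np.int64)
    boundary = ~internal
    all0 = (station == 0).all(axis=1)
    allN = (station == n_ax).all(axis=1)
    tag[boundary & all0] = TubeMesh.INLET
    tag[boundary & allN] = TubeMesh.OUTLET
    tag[boundary & ~(all0 | allN)] = TubeMesh.WALL
    return face_nodes, owner, neigh, tag


# ---------------------------------------------------------------------------
# geometric measures and quality

def _face_geometry(mesh: TubeMesh):
    p = mesh.nodes[mesh.face_nodes]                     # (Nf, 4, 3)
    sf = 0.5 * np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
    cf = p.mean(axis=1)
    return sf, cf


def cell_volumes(mesh: TubeMesh) -> np.ndarray:
    """Per-cell volumes (m^3) via the divergence theorem over faces."""
    sf, cf = _face_geometry(mesh)
    contrib = np.einsum("ij,ij->i", cf, sf) / 3.0
    vol = np.bincount(mesh.face_owner, weights=contrib, minlength=mesh.cell_count)
    internal = mesh.face_neigh >= 0
    vol -= np.bincount(mesh.face_neigh[internal], weights=contrib[internal],
                       minlength=mesh.cell_count)
    return vol


def mesh_volume(mesh: TubeMesh) -> float:
    """Total mesh volume in m^3."""
    return float(cell_volumes(mesh).sum())


def analytic_volume(geometry: VesselGeometry, n_quad: int = 4096) -> float:
    """pi * integral r(s)^2 ds of the generating radius profile, in m^3."""
    s = np.linspace(0.0, geometry.arclength_total, n_quad)
    r = geometry.radius_at(s)
    return float(np.pi * np.trapezoid((r * MM) ** 2, s * MM))


_CORNER_TRIPLES = np.array([
    [1, 3, 4], [2, 0, 5], [3, 1, 6], [0, 2, 7],
    [7, 5, 0], [4, 6, 1], [5, 7, 2], [6, 4, 3],
])


@dataclass
class QualityReport:
    min_scaled_jacobian: float
    max_aspect_ratio: float
    min_orthogonality: float
    mean_scaled_jacobian: float
    mean_aspect_ratio: float
    flagged_cells: np.ndarray
    n_cells: int

    def summary(self) -> dict:
        return {
            "min_scaled_jacobian": self.min_scaled_jacobian,
            "mean_scaled_jacobian": self.mean_scaled_jacobian,
            "max_aspect_ratio": self.max_aspect_ratio,
            "mean_aspect_ratio": self.mean_aspect_ratio,
            "min_orthogonality": self.min_orthogonality,
            "n_flagged": int(len(self.flagged_cells)),
            "n_cells": self.n_cells,
        }


def mesh_quality(mesh: TubeMesh, jacobian_floor: float = 0.0,
                 aspect_ceiling: float = 100.0) -> QualityReport:
    """Corner-Jacobian, aspect-ratio and face-orthogonality report.

    The scaled Jacobian at each hex corner is the determinant of the three
    edge vectors normalized by their lengths; any corner <= ``jacobian_floor``
    (or aspect ratio above ``aspect_ceiling``) flags the cell.
    """
    x = mesh.nodes[mesh.cells]                           # (Nc, 8, 3)
    corners = np.arange(8)
    e1 = x[:, _CORNER_TRIPLES[corners, 0]] - x[:, corners]
    e2 = x[:, _CORNER_TRIPLES[corners, 1]] - x[:, corners]
    e3 = x[:, _CORNER_TRIPLES[corners, 2]] - x[:, corners]
    det = np.einsum("nkj,nkj->nk", np.cross(e1, e2), e3)
    norm = (np.linalg.norm(e1, axis=2) * np.linalg.norm(e2, axis=2)
            * np.linalg.norm(e3, axis=2))
    scaled = det / np.maximum(norm, 1e-300)
    cell_jac = scaled.min(axis=1)

    edges = np.stack([np.linalg.norm(e, axis=2) for e in (e1, e2, e3)], axis=2)
    aspect = edges.max(axis=(1, 2)) / np.maximum(edges.min(axis=(1, 2)), 1e-300)

    sf, cf = _face_geometry(mesh)
    internal = mesh.face_neigh >= 0
    centroids = x.mean(axis=1)
    d = centroids[mesh.face_neigh[internal]] - centroids[mesh.face_owner[internal]]
    cosang = (np.einsum("ij,ij->i", sf[internal], d)
              / (np.linalg.norm(sf[internal], axis=1) * np.linalg.norm(d, axis=1)))

    flagged = np.nonzero((cell_jac <= jacobian_floor) | (aspect > aspect_ceiling))[0]
    return QualityReport(
        min_scaled_jacobian=float(cell_jac.min()),
        max_aspect_ratio=float(aspect.max()),
        min_orthogonality=float(cosang.min()),
        mean_scaled_jacobian=float(cell_jac.mean()),
        mean_aspect_ratio=float(aspect.mean()),
        flagged_cells=flagged,
        n_cells=mesh.cell_count,
    )


def write_vtu(mesh: TubeMesh, path, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Write the mesh (plus optional fields) as an ASCII VTK .vtu file."""
    def _fmt(arr):
        a = np.asarray(arr, dtype=float)
        return "\n".join(" ".join(f"{v:.9g}" for v in np.atleast_1d(row))
                         for row in a)

    n_pts, n_cells = len(mesh.nodes), mesh.cell_count
    conn = _fmt(mesh.cells)
    offsets = _fmt(np.arange(1, n_cells + 1) * 8)
    types = _fmt(np.full(n_cells, 12))
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.nodes), "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">', conn,
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">', offsets,
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">', types,
        "</DataArray>", "</Cells>",
    ]
    for label, data in (("CellData", cell_data), ("PointData", point_data)):
        parts.append(f"<{label}>")
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(f'<DataArray type="Float64" Name="{name}" '
                         f'NumberOfComponents="{ncomp}" format="ascii">')
            parts.append(_fmt(arr))
            parts.append("</DataArray>")
        parts.append(f"</{label}>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))
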