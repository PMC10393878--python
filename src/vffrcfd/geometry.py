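"""Parametric stenosed-vessel lumens and STL interchange.

A vessel is a tube of (possibly varying) circular cross-section swept along a
centerline.  A stenosis is a smooth cosine-tapered narrowing of the radius
over a lesion window; percent diameter stenosis is the conventional clinical
descriptor, ``100 * (1 - d_throat / d_reference)``.  All lengths are in
millimetres.

The triangulated lumen surface is the interchange object (STL in, STL out);
the analytic centerline + radius profile is the ground truth every
downstream stage (meshing, solver oracles, vFFR localization) consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .errors import GeometryError, STLParseError, ValidationError

__all__ = [
    "StenosisSpec",
    "VesselGeometry",
    "make_stenosed_vessel",
    "write_stl",
    "read_stl",
    "extract_radius_profile",
    "stenosis_pct_from_profile",
    "default_cohort",
    "COHORT_SEED",
]

#: Seed of the default synthetic 40-vessel cohort (the study conditions).
COHORT_SEED = 20230421


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric description of a single stenosed vessel.

    Parameters
    ----------
    reference_diameter : float
        Healthy lumen diameter, mm.
    stenosis_pct : float
        Percent diameter reduction at the throat, in [0, 100).
    lesion_length : float
        Axial extent of the narrowing, mm.
    lesion_center : float
        Arclength position of the throat, mm.
    vessel_length : float
        Total vessel arclength, mm.
    eccentricity : float
        Fraction in [0, 1] by which the lumen center is offset radially
        inside the lesion (0 = axisymmetric).  The cross-section stays
        circular, so cross-sectional area is preserved.
    curvature_radius : float or None
        Radius of a circular-arc centerline, mm; None for a straight vessel.
    case_id : str
        Optional label carried through the benchmark harness.
    """

    reference_diameter: float
    stenosis_pct: float
    lesion_length: float
    lesion_center: float
    vessel_length: float
    eccentricity: float = 0.0
    curvature_radius: float | None = None
    case_id: str = ""

    def __post_init__(self):
        if not self.reference_diameter > 0:
            raise ValidationError(
                f"reference_diameter must be > 0 mm, got {self.reference_diameter}")
        if not (0 <= self.stenosis_pct < 100):
            raise ValidationError(
                f"stenosis_pct must satisfy 0 <= pct < 100, got {self.stenosis_pct}")
        if not self.lesion_length > 0:
            raise ValidationError(
                f"lesion_length must be > 0 mm, got {self.lesion_length}")
        if not self.vessel_length > 0:
            raise ValidationError(
                f"vessel_length must be > 0 mm, got {self.vessel_length}")
        half = self.lesion_length / 2.0
        if self.lesion_center - half < 0 or self.lesion_center + half > self.vessel_length:
            raise ValidationError(
                "lesion must fit inside [0, vessel_length]: "
                f"[{self.lesion_center - half}, {self.lesion_center + half}] "
                f"outside [0, {self.vessel_length}]")
        if not (0 <= self.eccentricity <= 1):
            raise ValidationError(
                f"eccentricity must be in [0, 1], got {self.eccentricity}")
        if self.curvature_radius is not None and not self.curvature_radius > 0:
            raise ValidationError(
                f"curvature_radius must be > 0 mm or None, got {self.curvature_radius}")

    @property
    def reference_radius(self) -> float:
        return self.reference_diameter / 2.0

    @property
    def throat_diameter(self) -> float:
        return self.reference_diameter * (1.0 - self.stenosis_pct / 100.0)

    def radius_at(self, s):
        """Lumen radius (mm) at arclength ``s`` (mm); vectorized.

        The narrowing follows a raised-cosine taper over ``lesion_length``:
        C1-smooth, reference radius outside the lesion window, throat radius
        exactly at ``lesion_center``.
        """
        s = np.asarray(s, dtype=float)
        r_ref = self.reference_radius
        depth = r_ref - self.throat_diameter / 2.0
        x = (s - self.lesion_center) / self.lesion_length  # in [-0.5, 0.5] inside
        inside = np.abs(x) <= 0.5
        taper = np.where(inside, 0.5 * (1.0 + np.cos(2.0 * np.pi * np.clip(x, -0.5, 0.5))), 0.0)
        return r_ref - depth * taper

    def center_offset_at(self, s):
        """Radial offset (mm) of the lumen center inside the lesion."""
        s = np.asarray(s, dtype=float)
        r = self.radius_at(s)
        return self.eccentricity * (self.reference_radius - r)


@dataclass
class VesselGeometry:
    """A lumen: centerline + radius profile + triangulated surface (mm units).

    ``lumen_center`` is the actual tube axis (equals ``centerline`` for
    axisymmetric vessels; offset inside eccentric lesions).  ``frames`` holds
    parallel-transported (tangent, normal, binormal) triads per sample.
    """

    centerline: np.ndarray          # (n, 3) mm
    arclength: np.ndarray           # (n,) mm, monotone increasing from 0
    radius: np.ndarray              # (n,) mm, strictly positive
    surface: trimesh.Trimesh
    lumen_center: np.ndarray = None  # (n, 3) mm
    frames: np.ndarray = None        # (n, 3, 3): rows tangent/normal/binormal
    spec: StenosisSpec | None = None

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.lumen_center is None:
            self.lumen_center = self.centerline.copy()
        if self.frames is None:
            self.frames = _parallel_transport_frames(self.centerline)
        if np.any(self.radius <= 0):
            raise ValidationError("radius_profile must be strictly positive")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValidationError("arclength must be monotone increasing")

    @property
    def arclength_total(self) -> float:
        return float(self.arclength[-1])

    def radius_at(self, s):
        return np.interp(s, self.arclength, self.radius)

    def center_at(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.column_stack([
            np.interp(s, self.arclength, self.lumen_center[:, k]) for k in range(3)])
        return out

    def tangent_at(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        t = np.column_stack([
            np.interp(s, self.arclength, self.frames[:, 0, k]) for k in range(3)])
        return t / np.linalg.norm(t, axis=1, keepdims=True)


def _parallel_transport_frames(points: np.ndarray) -> np.ndarray:
    """Minimal-twist orthonormal frames along a polyline."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    seg = np.diff(pts, axis=0)
    tangents = np.empty((n, 3))
    tangents[:-1] = seg
    tangents[-1] = seg[-1]
    tangents[1:-1] = seg[:-1] + seg[1:]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    frames = np.empty((n, 3, 3))
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = ref - np.dot(ref, t0) * t0
    n0 /= np.linalg.norm(n0)
    normal = n0
    for i in range(n):
        t = tangents[i]
        if i > 0:
            # rotate previous normal by the rotation taking t_{i-1} to t_i
            tp = tangents[i - 1]
            axis = np.cross(tp, t)
            s = np.linalg.norm(axis)
            c = np.clip(np.dot(tp, t), -1.0, 1.0)
            if s > 1e-12:
                axis = axis / s
                ang = np.arctan2(s, c)
                normal = (normal * np.cos(ang)
                          + np.cross(axis, normal) * np.sin(ang)
                          + axis * np.dot(axis, normal) * (1 - np.cos(ang)))
            normal = normal - np.dot(normal, t) * t
            normal /= np.linalg.norm(normal)
        frames[i, 0] = t
        frames[i, 1] = normal
        frames[i, 2] = np.cross(t, normal)
    return frames


def _centerline_points(spec: StenosisSpec, s: np.ndarray) -> np.ndarray:
    if spec.curvature_radius is None:
        return np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    rc = spec.curvature_radius
    phi = s / rc
    return np.column_stack([rc * (1.0 - np.cos(phi)), np.zeros_like(s), rc * np.sin(phi)])


def make_stenosed_vessel(spec: StenosisSpec,
                         axial_samples: int = 128,
                         circumferential_samples: int = 64) -> VesselGeometry:
    """Generate the lumen geometry for a stenosis descriptor.

    Returns a :class:`VesselGeometry` whose surface is a closed, watertight,
    outward-oriented triangulation (side strips plus two planar end caps).
    """
    if axial_samples < 16:
        raise ValidationError(f"axial_samples must be >= 16, got {axial_samples}")
    if circumferential_samples < 8:
        raise ValidationError(
            f"circumferential_samples must be >= 8, got {circumferential_samples}")

    s = np.linspace(0.0, spec.vessel_length, axial_samples)
    centerline = _centerline_points(spec, s)
    frames = _parallel_transport_frames(centerline)
    radius = spec.radius_at(s)
    offset = spec.center_offset_at(s)
    lumen_center = centerline + offset[:, None] * frames[:, 1, :]

    theta = np.linspace(0.0, 2.0 * np.pi, circumferential_samples, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # ring vertices: (axial, circumferential, 3)
    rings = (lumen_center[:, None, :]
             + radius[:, None, None] * (cos_t[None, :, None] * frames[:, None, 1, :]
                                        + sin_t[None, :, None] * frames[:, None, 2, :]))
    na, nc = axial_samples, circumferential_samples
    verts = rings.reshape(na * nc, 3)
    v_in = len(verts)
    v_out = v_in + 1
    verts = np.vstack([verts, lumen_center[0], lumen_center[-1]])

    i = np.arange(na - 1)[:, None]
    j = np.arange(nc)[None, :]
    jn = (j + 1) % nc
    a = (i * nc + j).ravel()
    b = (i * nc + jn).ravel()
    c = ((i + 1) * nc + jn).ravel()
    d = ((i + 1) * nc + j).ravel()
    # outward winding for a ring laid out counter-clockwise about the tangent
    side = np.concatenate([np.column_stack([a, c, b]), np.column_stack([a, d, c])])
    jj = np.arange(nc)
    jjn = (jj + 1) % nc
    cap_in = np.column_stack([np.full(nc, v_in), jjn, jj])
    base = (na - 1) * nc
    cap_out = np.column_stack([np.full(nc, v_out), base + jj, base + jjn])
    faces = np.vstack([side, cap_in, cap_out])

    surface = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if surface.volume < 0:
        surface.invert()
    return VesselGeometry(centerline=centerline, arclength=s, radius=radius,
                          surface=surface, lumen_center=lumen_center,
                          frames=frames, spec=spec)


def write_stl(geometry: VesselGeometry, path, ascii: bool = False) -> None:
    """Write the lumen surface as binary (default) or ASCII STL."""
    if not geometry.surface.is_watertight:
        raise GeometryError("surface is not watertight; refusing to write STL")
    file_type = "stl_ascii" if ascii else "stl"
    geometry.surface.export(str(path), file_type=file_type)


def _validate_stl_bytes(path) -> None:
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(512)
    if size < 15:
        raise STLParseError("file too short to be STL", byte_offset=0)
    is_ascii = head.lstrip()[:5] == b"solid" and b"facet" in head + b""
    if head.lstrip()[:5] == b"solid" and not is_ascii:
        # could still be binary starting with 'solid'; fall through to binary check
        pass
    if is_ascii:
        with open(path, "rb") as fh:
            body = fh.read()
        if b"facet" not in body:
            raise STLParseError("ASCII STL contains no facets", byte_offset=len(b"solid"))
        return
    if size < 84:
        raise STLParseError("binary STL truncated before triangle count", byte_offset=80)
    n_tri = int(np.frombuffer(head[80:84], dtype="<u4")[0])
    if n_tri == 0:
        raise STLParseError("binary STL declares zero facets", byte_offset=80)
    expected = 84 + 50 * n_tri
    if size != expected:
        raise STLParseError(
            f"binary STL size {size} != 84 + 50*{n_tri} = {expected}",
            byte_offset=min(size, expected))


def read_stl(path, n_stations: int = 96) -> VesselGeometry:
    """Read an STL lumen and reconstruct centerline + radius profile.

    The centerline is recovered by slicing the surface perpendicular to its
    principal axis and chaining the cross-section centroids; the radius is
    the effective radius sqrt(area/pi) of each cut.  Works for straight and
    gently curved tubes (the package's domain).
    """
    _validate_stl_bytes(path)
    try:
        mesh = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises assorted types for bad payloads
        raise STLParseError(f"could not parse STL: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise STLParseError("STL contains no triangles")
    mesh.merge_vertices()
    if not mesh.is_watertight:
        raise GeometryError("loaded STL surface is not watertight")

    # principal axis via PCA of the vertex cloud
    verts = mesh.vertices
    centroid = verts.mean(axis=0)
    _, _, vt = np.linalg.svd(verts - centroid, full_matrices=False)
    axis = vt[0]
    proj = (verts - centroid) @ axis
    lo, hi = proj.min(), proj.max()
    pad = 0.015 * (hi - lo)
    stations = np.linspace(lo + pad, hi - pad, n_stations)

    centers, radii = [], []
    for t in stations:
        origin = centroid + t * axis
        area, ctr, n_loops = _section_area(mesh, origin, axis)
        centers.append(ctr)
        radii.append(np.sqrt(area / np.pi))
    centers = np.asarray(centers)
    radii = np.asarray(radii)
    seg = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    return VesselGeometry(centerline=centers, arclength=arclength, radius=radii,
                          surface=mesh)


def _section_area(mesh: trimesh.Trimesh, origin, normal):
    """Area, centroid and loop count of a plane cut through the surface."""
    path3d = mesh.section(plane_origin=origin, plane_normal=normal)
    if path3d is None:
        raise GeometryError("section plane does not intersect the surface")
    planar, T = path3d.to_2D()
    polys = planar.polygons_full
    if len(polys) == 0:
        raise GeometryError("section produced no closed loop")
    if len(polys) > 1:
        raise GeometryError(
            f"section plane intersects the surface in {len(polys)} loops "
            "(vessel too tortuous for a single cut)")
    poly = polys[0]
    c2 = np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0])
    c3 = (T @ c2)[:3]
    return poly.area, c3, len(polys)


def extract_radius_profile(geometry: VesselGeometry, n_stations: int = 64) -> pd.DataFrame:
    """Effective radius sqrt(A/pi) of perpendicular cuts along the centerline.

    Returns a DataFrame with columns ``arclength_mm`` and ``radius_mm``.
    Stations span the interior of the vessel (end caps excluded).
    """
    if not geometry.surface.is_watertight:
        raise GeometryError("surface must be watertight to extract a radius profile")
    total = geometry.arclength_total
    stations = np.linspace(0.015 * total, 0.985 * total, n_stations)
    radii = np.empty(n_stations)
    centers = geometry.center_at(stations)
    tangents = geometry.tangent_at(stations)
    for k in range(n_stations):
        area, _, _ = _section_area(geometry.surface, centers[k], tangents[k])
        radii[k] = np.sqrt(area / np.pi)
    return pd.DataFrame({"arclength_mm": stations, "radius_mm": radii})


def stenosis_pct_from_profile(profile: pd.DataFrame) -> float:
    """Percent diameter stenosis recovered from a radius-vs-arclength table."""
    r = profile["radius_mm"].to_numpy()
    return float(100.0 * (1.0 - r.min() / r.max()))


def default_cohort(n_vessels: int = 40, seed: int = COHORT_SEED) -> list[StenosisSpec]:
    """The default synthetic analysis cohort.

    40 straight axisymmetric vessels with percent diameter stenosis drawn
    uniformly in [30, 90] and reference diameter in [2.5, 4.0] mm — the
    clinical inclusion range — with 8–12 mm lesions in the distal half of a
    30 mm segment (the interrogated vessel is truncated a few millimetres
    beyond the lesion, as when the reconstruction ends near the distal
    pressure-measurement position).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_vessels):
        vessel_length = 30.0
        lesion_length = rng.uniform(8.0, 12.0)
        runoff = rng.uniform(0.5, 1.5)
        specs.append(StenosisSpec(
            reference_diameter=rng.uniform(2.5, 4.0),
            stenosis_pct=rng.uniform(30.0, 90.0),
            lesion_length=lesion_length,
            lesion_center=vessel_length - runoff - lesion_length / 2.0,
            vessel_length=vessel_length,
            eccentricity=0.0,
            curvature_radius=None,
            case_id=f"case{i + 1:02d}",
        ))
    return specs
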