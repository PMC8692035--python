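"""Construction and sectioning of the posterior rectus sheath plane volume.

Each side's PRSP is the convex hull of its boundary landmarks (xiphoid tip,
pubis tip, linea alba points, and that side's semilunar points): a Delaunay
tetrahedralization of a point set tessellates exactly its convex hull, so
the enclosed volume is the hull volume.

The fitting planes are frontal sections: a minimal-volume oriented bounding
box is fitted around the hull, and the stack of planes parallel to its two
largest axes (i.e. perpendicular to the thinnest, dorsoventral axis) is cut
at a fixed spacing. Each plane ∩ hull intersection is a convex polygon
expressed in the plane's own 2D frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .io import LandmarkSet

__all__ = [
    "DegeneracyError",
    "PRSPVolume",
    "OrientedBox",
    "CrossSection",
    "build_prsp",
    "convex_volume_from_points",
    "minimal_bounding_box",
    "slice_volume",
    "largest_slice",
    "write_off",
]


class DegeneracyError(ValueError):
    """The input point set or volume is geometrically degenerate."""


@dataclass(frozen=True)
class PRSPVolume:
    """A side's triangulated convex volume (mm / mm³)."""

    patient_id: str
    side: str
    vertices: np.ndarray  # (n, 3) hull vertices
    faces: np.ndarray     # (m, 3) triangle indices into vertices
    volume: float

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise DegeneracyError(
                f"patient {self.patient_id} ({self.side}): hull volume must be > 0")


@dataclass(frozen=True)
class OrientedBox:
    """Minimal-volume oriented bounding box.

    ``axes`` rows are orthonormal directions, ordered so ``extents`` is
    descending; the third axis is therefore the thin (dorsoventral) one.
    """

    center: np.ndarray
    axes: np.ndarray     # (3, 3), rows are unit vectors
    extents: np.ndarray  # (3,), descending

    @property
    def volume(self) -> float:
        return float(np.prod(self.extents))


@dataclass(frozen=True)
class CrossSection:
    """One frontal slice: a convex CCW polygon with its 3D placement."""

    slice_index: int
    offset: float              # mm along the slicing axis from the dorsal face
    polygon: np.ndarray        # (k, 2) CCW vertices in the slice frame
    area: float
    origin: np.ndarray         # 3D point mapped to (0, 0)
    basis_u: np.ndarray        # 3D direction of the slice x axis
    basis_v: np.ndarray        # 3D direction of the slice y axis

    def to_3d(self, uv: np.ndarray) -> np.ndarray:
        """Map 2D slice-frame points (k, 2) back into patient coordinates."""
        uv = np.atleast_2d(uv)
        return self.origin + uv[:, :1] * self.basis_u + uv[:, 1:2] * self.basis_v


def convex_volume_from_points(points: np.ndarray, patient_id: str = "",
                              side: str = "") -> PRSPVolume:
    """Convex hull volume of a 3D point cloud as a :class:`PRSPVolume`."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise DegeneracyError("need at least 4 points in 3D")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegeneracyError(f"degenerate point set (coplanar or fewer than 4 "
                              f"distinct points): {exc}") from exc
    vidx = hull.vertices
    remap = -np.ones(len(points), dtype=int)
    remap[vidx] = np.arange(len(vidx))
    return PRSPVolume(patient_id=patient_id, side=side,
                      vertices=points[vidx], faces=remap[hull.simplices],
                      volume=float(hull.volume))


def build_prsp(landmarks: LandmarkSet, side: str) -> PRSPVolume:
    """Build one side's PRSP from a patient's landmarks.

    Both sides share the xiphoid, pubis and linea alba points; the side
    argument selects which semilunar point column bounds the volume
    laterally.
    """
    pts = landmarks.side_points(side)
    return convex_volume_from_points(pts, patient_id=landmarks.patient_id, side=side)


# ---------------------------------------------------------------------------
# minimal oriented bounding box


def _min_area_rect_2d(pts2: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area enclosing rectangle of 2D points by rotating calipers.

    Returns (angle, width, height) with width >= height; the optimal
    rectangle has one side parallel to a hull edge.
    """
    hull = ConvexHull(pts2)
    hv = pts2[hull.vertices]
    edges = np.diff(np.vstack([hv, hv[:1]]), axis=0)
    angles = np.arctan2(edges[:, 1], edges[:, 0]) % (np.pi / 2)
    angles = np.unique(np.round(angles, 12))
    best = (np.inf, 0.0, 0.0, 0.0)
    for th in angles:
        c, s = np.cos(th), np.sin(th)
        rot = hv @ np.array([[c, -s], [s, c]])
        w = float(np.ptp(rot[:, 0]))
        h = float(np.ptp(rot[:, 1]))
        if w * h < best[0]:
            best = (w * h, th, w, h)
    _, th, w, h = best
    if h > w:
        th, w, h = th + np.pi / 2, h, w
    return th, w, h


def minimal_bounding_box(volume: PRSPVolume) -> OrientedBox:
    """Minimal-volume box over facet-normal-aligned candidates.

    One candidate box per hull facet normal (in-plane orientation refined by
    rotating calipers), plus the three coordinate axes so the result never
    exceeds the axis-aligned bounding box. Ties are broken by the
    lexicographically smallest axis triple.
    """
    pts = volume.vertices
    hull = ConvexHull(pts)
    normals = hull.equations[:, :3]
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    cand_normals = np.vstack([normals, np.eye(3)])
    # dedupe antipodal / repeated directions
    sign = np.sign(cand_normals[np.arange(len(cand_normals)),
                                np.abs(cand_normals).argmax(axis=1)])
    canon = cand_normals * sign[:, None]
    _, keep = np.unique(np.round(canon, 9), axis=0, return_index=True)
    cand_normals = cand_normals[np.sort(keep)]

    best_vol = np.inf
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    best_key: tuple | None = None
    for n in cand_normals:
        # orthonormal in-plane basis
        a = np.array([1.0, 0.0, 0.0])
        if abs(n @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        t = pts @ n
        pts2 = np.column_stack([pts @ u, pts @ v])
        th, w, h = _min_area_rect_2d(pts2)
        c, s = np.cos(th), np.sin(th)
        ax_u = c * u + s * v
        ax_v = -s * u + c * v
        ext = np.array([w, h, np.ptp(t)])
        axes = np.vstack([ax_u, ax_v, n])
        order = np.argsort(-ext, kind="stable")
        ext = ext[order]
        axes = axes[order]
        # canonical signs for determinism
        for i in range(3):
            nz = np.flatnonzero(np.abs(axes[i]) > 1e-9)
            if len(nz) and axes[i, nz[0]] < 0:
                axes[i] = -axes[i]
        vol = float(np.prod(ext))
        key = tuple(np.round(axes, 9).ravel())
        if vol < best_vol * (1 - 1e-12) or (
                abs(vol - best_vol) <= 1e-12 * max(vol, best_vol)
                and best_key is not None and key < best_key):
            lo = np.array([(pts @ ax).min() for ax in axes])
            hi = np.array([(pts @ ax).max() for ax in axes])
            center = axes.T @ ((lo + hi) / 2)
            best_vol, best, best_key = vol, (center, axes, ext), key
    assert best is not None
    return OrientedBox(center=best[0], axes=best[1], extents=best[2])


# ---------------------------------------------------------------------------
# slicing


def _hull_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def slice_volume(volume: PRSPVolume, box: OrientedBox,
                 spacing: float = 1.0) -> list[CrossSection]:
    """Cut the hull into frontal sections at a fixed spacing.

    The slicing axis is the box axis with the smallest extent (dorsoventral
    for the thin lens-like PRSP — a runtime warning fires if the volume is
    not actually thin). The plane stack is centred on the box: planes sit
    every ``spacing`` symmetric about the mid-thickness plane, which
    coincides with the half-spacing-from-the-face convention whenever the
    extent is an integer multiple of the spacing, keeps the stack invariant
    under reversal of the slicing direction, and gives a volume thinner
    than the spacing its mid-plane slice. Empty intersections are dropped.
    """
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    if not box.extents[2] < 0.5 * box.extents[1]:
        warnings.warn(
            "volume is not thin: smallest box extent is not < half the next; "
            "the frontal-slicing assumption may be inappropriate", stacklevel=2)
    axis = box.axes[2]
    u, v = box.axes[0], box.axes[1]
    pts = volume.vertices
    t = pts @ axis
    t0 = t.min()
    extent = box.extents[2]
    edges = _hull_edges(volume.faces)
    te = t[edges]
    lo = te.min(axis=1)
    hi = te.max(axis=1)
    n_planes = max(1, int(np.floor(extent / spacing + 0.5)))
    offsets = extent / 2 + (np.arange(n_planes) - (n_planes - 1) / 2) * spacing
    sections: list[CrossSection] = []
    for offset in offsets:
        level = t0 + offset
        cross = (lo <= level) & (hi >= level)
        cut_pts = []
        for (i, j), crossing in zip(edges, cross):
            if not crossing:
                continue
            ti, tj = t[i], t[j]
            if abs(tj - ti) < 1e-12:
                cut_pts.append(pts[i])
                cut_pts.append(pts[j])
            else:
                lam = (level - ti) / (tj - ti)
                cut_pts.append(pts[i] + lam * (pts[j] - pts[i]))
        if cut_pts:
            P = np.asarray(cut_pts)
            origin = P.mean(axis=0)
            uv = np.column_stack([(P - origin) @ u, (P - origin) @ v])
            try:
                h2 = ConvexHull(uv)
            except QhullError:
                h2 = None
            if h2 is not None and h2.volume > 1e-9:
                poly = uv[h2.vertices]  # scipy 2D hull vertices are CCW
                sections.append(CrossSection(
                    slice_index=len(sections), offset=float(offset),
                    polygon=poly, area=float(h2.volume),
                    origin=origin, basis_u=u, basis_v=v))
    if not sections:
        raise DegeneracyError(
            f"patient {volume.patient_id} ({volume.side}): no non-empty slice")
    return sections


def largest_slice(sections: list[CrossSection]) -> CrossSection:
    """Maximal-area section; ties go to the smallest slice index."""
    if not sections:
        raise ValueError("empty section list")
    best = sections[0]
    for s in sections[1:]:
        if s.area > best.area:
            best = s
    return best


def write_off(volume: PRSPVolume, path: str | Path) -> Path:
    """Export the triangulated hull surface as an OFF mesh for inspection."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(volume.vertices)} {len(volume.faces)} 0\n")
        for p in volume.vertices:
            fh.write(f"{p[0]!r} {p[1]!r} {p[2]!r}\n")
        for f in volume.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    return path
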