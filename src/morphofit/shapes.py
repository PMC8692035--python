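"""Maximal inscribed device shapes in a convex cross-section.

Four device geometries are fitted into each convex slice polygon:

* circle — the Chebyshev centre problem, an exact linear program over the
  polygon's edge half-planes;
* rectangle — free-orientation area maximisation over (centre, angle,
  width, height) with four-corner containment, solved by a deterministic
  coarse orientation scan followed by multi-start SLSQP refinement;
* ellipse — the maximum-area inscribed ellipse, the convex log-det program
  maximise log det B  s.t.  ‖B aᵢ‖ + aᵢ·d ≤ bᵢ for every edge half-plane
  aᵢ·x ≤ bᵢ, with B the symmetric positive-definite shape matrix and d the
  centre (globally optimal for convex input);
* polygon — the slice itself, reduced to at most ``max_sides`` vertices by
  greedy least-area-loss vertex removal.

All fitters are deterministic: identical input gives identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, minimize

__all__ = [
    "InscribedCircle",
    "InscribedRectangle",
    "InscribedEllipse",
    "DevicePolygon",
    "PatientFits",
    "polygon_area",
    "polygon_halfplanes",
    "max_circle",
    "max_rectangle",
    "max_ellipse",
    "device_polygon",
    "fit_patient",
]


@dataclass(frozen=True)
class InscribedCircle:
    center: np.ndarray
    radius: float

    @property
    def area(self) -> float:
        return float(np.pi * self.radius ** 2)

    def params(self) -> dict:
        return {"cx": float(self.center[0]), "cy": float(self.center[1]),
                "r": float(self.radius)}


@dataclass(frozen=True)
class InscribedRectangle:
    center: np.ndarray
    angle: float
    width: float
    height: float

    @property
    def area(self) -> float:
        return float(self.width * self.height)

    @property
    def aspect_ratio(self) -> float:
        return float(max(self.width, self.height) / min(self.width, self.height))

    def corners(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        t1 = np.array([c, s])
        t2 = np.array([-s, c])
        hw, hh = self.width / 2, self.height / 2
        return np.array([self.center + s1 * hw * t1 + s2 * hh * t2
                         for s1 in (-1, 1) for s2 in (-1, 1)])

    def params(self) -> dict:
        return {"cx": float(self.center[0]), "cy": float(self.center[1]),
                "angle": float(self.angle), "w": float(self.width),
                "h": float(self.height)}


@dataclass(frozen=True)
class InscribedEllipse:
    center: np.ndarray
    semi_major: float
    semi_minor: float
    angle: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    def boundary(self, n: int = 256) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        pts = np.column_stack([self.semi_major * np.cos(t),
                               self.semi_minor * np.sin(t)])
        return self.center + pts @ rot.T

    def params(self) -> dict:
        return {"cx": float(self.center[0]), "cy": float(self.center[1]),
                "a": float(self.semi_major), "b": float(self.semi_minor),
                "angle": float(self.angle)}


@dataclass(frozen=True)
class DevicePolygon:
    vertices: np.ndarray

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)

    def params(self) -> dict:
        return {"vertices": [[float(x), float(y)] for x, y in self.vertices]}


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a simple polygon given as (k, 2) vertices."""
    poly = np.asarray(poly, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def polygon_halfplanes(poly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge half-planes aᵢ·x ≤ bᵢ (unit outward normals) of a CCW convex polygon."""
    poly = np.asarray(poly, dtype=float)
    d = np.roll(poly, -1, axis=0) - poly
    n = np.column_stack([d[:, 1], -d[:, 0]])
    lengths = np.linalg.norm(n, axis=1)
    keep = lengths > 1e-12
    n = n[keep] / lengths[keep, None]
    b = np.einsum("ij,ij->i", n, poly[keep])
    return n, b


def _require_ccw(poly: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return poly if signed >= 0 else poly[::-1]


# ---------------------------------------------------------------------------
# circle


def max_circle(poly: np.ndarray, tol: float = 1e-9) -> InscribedCircle:
    """Largest inscribed circle: the Chebyshev centre linear program."""
    poly = _require_ccw(poly)
    if polygon_area(poly) <= tol:
        raise ValueError("degenerate polygon: area below tolerance")
    A, b = polygon_halfplanes(poly)
    res = linprog(c=[0.0, 0.0, -1.0],
                  A_ub=np.column_stack([A, np.ones(len(A))]), b_ub=b,
                  bounds=[(None, None), (None, None), (0, None)],
                  method="highs")
    if not res.success:
        raise RuntimeError(f"Chebyshev LP failed: {res.message}")
    return InscribedCircle(center=res.x[:2].copy(), radius=float(res.x[2]))


# ---------------------------------------------------------------------------
# rectangle


def _max_product(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Maximise u·v subject to pᵢu + qᵢv ≤ rᵢ, u, v ≥ 0, with pᵢ, qᵢ ≥ 0.

    Exact: the optimum is at a single-constraint stationary point or a
    vertex of the feasible region; all candidates are enumerated.
    """
    if np.any(r < -1e-12):
        return 0.0, 0.0
    r = np.maximum(r, 0.0)
    cand_u, cand_v = [], []
    act = (p > 1e-14) & (q > 1e-14)
    cand_u.extend(r[act] / (2 * p[act]))
    cand_v.extend(r[act] / (2 * q[act]))
    m = len(p)
    ii, jj = np.triu_indices(m, k=1)
    det = p[ii] * q[jj] - p[jj] * q[ii]
    ok = np.abs(det) > 1e-14
    ui = (r[ii] * q[jj] - r[jj] * q[ii])[ok] / det[ok]
    vi = (p[ii] * r[jj] - p[jj] * r[ii])[ok] / det[ok]
    pos = (ui > 0) & (vi > 0)
    cand_u.extend(ui[pos])
    cand_v.extend(vi[pos])
    if not cand_u:
        return 0.0, 0.0
    U = np.asarray(cand_u)
    V = np.asarray(cand_v)
    feas = np.all(p[None, :] * U[:, None] + q[None, :] * V[:, None]
                  <= r[None, :] * (1 + 1e-9) + 1e-12, axis=1)
    if not feas.any():
        return 0.0, 0.0
    U, V = U[feas], V[feas]
    k = int(np.argmax(U * V))
    return float(U[k]), float(V[k])


def _polygon_seed(poly: np.ndarray) -> int:
    h = hashlib.sha256(np.ascontiguousarray(np.round(poly, 9)).tobytes())
    return int.from_bytes(h.digest()[:4], "little")


def _rect_fixed_angle(A: np.ndarray, b: np.ndarray, angle: float,
                      c0: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Largest rectangle at a fixed orientation, centre free.

    Maximising log(u) + log(v) over the linear constraints
    aᵢ·c + pᵢu + qᵢv ≤ bᵢ is convex; SLSQP from an interior start finds
    the global fixed-angle optimum. Returns (centre, half-width,
    half-height).
    """
    t1 = np.array([np.cos(angle), np.sin(angle)])
    t2 = np.array([-t1[1], t1[0]])
    p = np.abs(A @ t1)
    q = np.abs(A @ t2)
    u0, v0 = _max_product(p, q, b - A @ c0)
    if u0 <= 0 or v0 <= 0:
        return c0, 0.0, 0.0
    M = np.column_stack([A, p, q])

    def neg(x):
        return -np.log(x[2]) - np.log(x[3])

    def grad(x):
        return np.array([0.0, 0.0, -1 / x[2], -1 / x[3]])

    res = minimize(neg, np.array([c0[0], c0[1], 0.98 * u0, 0.98 * v0]),
                   jac=grad, method="SLSQP",
                   bounds=[(None, None), (None, None), (1e-9, None),
                           (1e-9, None)],
                   constraints=[{"type": "ineq",
                                 "fun": lambda x: b - M @ x,
                                 "jac": lambda x: -M}],
                   options={"maxiter": 100, "ftol": 1e-12})
    c = res.x[:2]
    u, v = _max_product(p, q, b - A @ c)  # exact re-expansion at the centre
    if u * v < u0 * v0:
        return c0, u0, v0
    return c, u, v


def max_rectangle(poly: np.ndarray, tol: float = 1e-6, n_starts: int = 32,
                  seed: int | None = None,
                  axis_aligned: bool = False) -> InscribedRectangle:
    """Largest inscribed rectangle, orientation free by default.

    A deterministic coarse scan (orientation grid at the Chebyshev centre,
    with the width/height subproblem solved exactly) seeds ``n_starts``
    local SLSQP refinements over (centre, angle, width, height); extra
    starts perturb the pose with a seeded RNG (seed defaults to a hash of
    the polygon, so the fit is a pure function of its input).

    ``axis_aligned=True`` pins the angle at 0 for sensitivity analysis.
    """
    poly = _require_ccw(poly)
    area = polygon_area(poly)
    if area <= tol:
        raise ValueError("degenerate polygon: area below tolerance")
    A, b = polygon_halfplanes(poly)
    cheb = max_circle(poly)
    scale = np.sqrt(area)

    if axis_aligned:
        c, u, v = _rect_fixed_angle(A, b, 0.0, cheb.center)
        return InscribedRectangle(center=c, angle=0.0, width=2 * u, height=2 * v)

    # multi-start: a uniform orientation grid of exact fixed-angle solves
    # (centre free), plus seeded random poses for any remaining budget
    n_grid = int(np.clip(n_starts, 6, 24))
    grid = np.linspace(0.0, np.pi / 2, n_grid, endpoint=False)
    start_angles = list(grid)
    start_centers = [cheb.center] * n_grid
    rng = np.random.default_rng(_polygon_seed(poly) if seed is None else seed)
    while len(start_angles) < n_starts:
        c = cheb.center + rng.normal(scale=0.3 * scale, size=2)
        if np.any(A @ c > b):
            continue
        start_angles.append(float(rng.uniform(0, np.pi / 2)))
        start_centers.append(c)

    best_c, best_u, best_v, best_th = cheb.center, 0.0, 0.0, 0.0
    for th, c0 in zip(start_angles, start_centers):
        c, u, v = _rect_fixed_angle(A, b, th, np.asarray(c0))
        if u * v > best_u * best_v:
            best_c, best_u, best_v, best_th = c, u, v, th

    # 1-D hill-climb of the orientation around the incumbent
    step = grid[1]
    for delta in (step / 2, step / 6, step / 18, step / 54):
        improved = True
        while improved:
            improved = False
            for th in (best_th - delta, best_th + delta):
                c, u, v = _rect_fixed_angle(A, b, th, best_c)
                if u * v > best_u * best_v * (1 + 1e-12):
                    best_c, best_u, best_v, best_th = c, u, v, th
                    improved = True
    return InscribedRectangle(center=best_c, angle=float(best_th % np.pi),
                              width=2 * best_u, height=2 * best_v)


# ---------------------------------------------------------------------------
# ellipse


def max_ellipse(poly: np.ndarray, tol: float = 1e-9) -> InscribedEllipse:
    """Maximum-area inscribed ellipse via the log-det convex program.

    Containment is certified by the half-plane constraints themselves
    (‖B aᵢ‖ + aᵢ·d ≤ bᵢ is exact for every edge), so no boundary sampling
    enters the optimisation. The problem is convex; SLSQP with analytic
    gradients converges to the global optimum from the Chebyshev-ball
    start.
    """
    poly = _require_ccw(poly)
    area = polygon_area(poly)
    if area <= tol:
        raise ValueError("degenerate polygon: area below tolerance")
    # normalise scale for solver conditioning
    scale = np.sqrt(area)
    P = poly / scale
    A, b = polygon_halfplanes(P)
    cheb = max_circle(P)
    r0 = 0.9 * cheb.radius
    # x = (d1, d2, b11, b12, b22)
    x0 = np.array([cheb.center[0], cheb.center[1], r0, 0.0, r0])

    def neg_logdet(x):
        det = max(x[2] * x[4] - x[3] ** 2, 1e-14)  # det_con keeps iterates PSD
        return -np.log(det)

    def neg_logdet_grad(x):
        det = max(x[2] * x[4] - x[3] ** 2, 1e-14)
        return np.array([0.0, 0.0, -x[4] / det, 2 * x[3] / det, -x[2] / det])

    def cons_f(x):
        d = x[:2]
        Ba = np.column_stack([x[2] * A[:, 0] + x[3] * A[:, 1],
                              x[3] * A[:, 0] + x[4] * A[:, 1]])
        nrm = np.sqrt(np.einsum("ij,ij->i", Ba, Ba) + 1e-300)
        return b - A @ d - nrm

    def cons_jac(x):
        Ba = np.column_stack([x[2] * A[:, 0] + x[3] * A[:, 1],
                              x[3] * A[:, 0] + x[4] * A[:, 1]])
        nrm = np.sqrt(np.einsum("ij,ij->i", Ba, Ba) + 1e-300)
        J = np.zeros((len(A), 5))
        J[:, 0] = -A[:, 0]
        J[:, 1] = -A[:, 1]
        J[:, 2] = -(Ba[:, 0] * A[:, 0]) / nrm
        J[:, 3] = -(Ba[:, 0] * A[:, 1] + Ba[:, 1] * A[:, 0]) / nrm
        J[:, 4] = -(Ba[:, 1] * A[:, 1]) / nrm
        return J

    def det_con(x):
        return x[2] * x[4] - x[3] ** 2 - 1e-10

    def solve(start):
        res = minimize(neg_logdet, start, jac=neg_logdet_grad, method="SLSQP",
                       constraints=[{"type": "ineq", "fun": cons_f,
                                     "jac": cons_jac},
                                    {"type": "ineq", "fun": det_con}],
                       bounds=[(None, None), (None, None), (1e-8, None),
                               (None, None), (1e-8, None)],
                       options={"maxiter": 500, "ftol": 1e-14})
        x = res.x.copy()
        # project B back to exact feasibility: shrink by the worst ratio
        # (bᵢ − aᵢ·d) / ‖B aᵢ‖ so every half-plane constraint holds
        d = x[:2]
        Ba = np.column_stack([x[2] * A[:, 0] + x[3] * A[:, 1],
                              x[3] * A[:, 0] + x[4] * A[:, 1]])
        nrm = np.sqrt(np.einsum("ij,ij->i", Ba, Ba))
        room = b - A @ d
        if (room <= 0).any():
            return None, res
        s = float(min(1.0, (room / np.maximum(nrm, 1e-300)).min()))
        x[2:] *= s
        if x[2] * x[4] - x[3] ** 2 <= 0 or not np.isfinite(x).all():
            return None, res
        return x, res

    x, res = solve(x0)
    # the optimum must dominate the feasible Chebyshev ball (det = r^2)
    if x is None or x[2] * x[4] - x[3] ** 2 < (0.85 * cheb.radius) ** 2:
        # retry from a smaller, strictly interior ball
        x2, res2 = solve(np.array([cheb.center[0], cheb.center[1],
                                   0.5 * cheb.radius, 0.0,
                                   0.5 * cheb.radius]))
        if x2 is not None and (x is None or
                               x2[2] * x2[4] - x2[3] ** 2
                               > x[2] * x[4] - x[3] ** 2):
            x, res = x2, res2
    if x is None:
        raise RuntimeError(
            f"inscribed-ellipse solver did not converge: {res.message} "
            f"(status {res.status}, worst constraint {cons_f(res.x).min():.3e})")
    B = np.array([[x[2], x[3]], [x[3], x[4]]])
    evals, evecs = np.linalg.eigh(B)  # ascending
    semi_minor, semi_major = evals * scale
    vmaj = evecs[:, 1]
    angle = float(np.arctan2(vmaj[1], vmaj[0]) % np.pi)
    return InscribedEllipse(center=x[:2] * scale, semi_major=float(semi_major),
                            semi_minor=float(semi_minor), angle=angle)


# ---------------------------------------------------------------------------
# polygon device


def device_polygon(slice_polygon: np.ndarray, max_sides: int = 9) -> DevicePolygon:
    """Reduce the slice polygon to at most ``max_sides`` vertices.

    A polygon already within the limit is returned unchanged. Otherwise the
    vertex whose removal (joining its neighbours by a chord) loses the
    least area is deleted repeatedly; the chord lies inside the convex
    polygon, so the result stays convex and inscribed.
    """
    poly = _require_ccw(np.asarray(slice_polygon, dtype=float))
    verts = list(poly)
    while len(verts) > max_sides:
        n = len(verts)
        losses = []
        for i in range(n):
            a, c, b2 = verts[i - 1], verts[i], verts[(i + 1) % n]
            losses.append(0.5 * abs((c[0] - a[0]) * (b2[1] - a[1])
                                    - (c[1] - a[1]) * (b2[0] - a[0])))
        verts.pop(int(np.argmin(losses)))
    return DevicePolygon(vertices=np.asarray(verts))


# ---------------------------------------------------------------------------
# per-patient aggregation


@dataclass(frozen=True)
class PatientFits:
    """Best device of each shape for one side's slice stack."""

    circle: InscribedCircle
    circle_slice: int
    rectangle: InscribedRectangle
    rectangle_slice: int
    ellipse: InscribedEllipse
    ellipse_slice: int
    polygon: DevicePolygon
    polygon_slice: int

    def areas(self) -> dict[str, float]:
        return {"circle": self.circle.area, "rectangle": self.rectangle.area,
                "ellipse": self.ellipse.area, "polygon": self.polygon.area}

    def slice_indices(self) -> dict[str, int]:
        return {"circle": self.circle_slice, "rectangle": self.rectangle_slice,
                "ellipse": self.ellipse_slice, "polygon": self.polygon_slice}


def fit_patient(sections, max_sides: int = 9, n_starts: int = 8,
                seed: int | None = None) -> PatientFits:
    """Fit every device shape across a side's slice stack.

    The circle, rectangle and ellipse are fitted in every slice and the
    largest of each kept (ties to the smallest slice index); the polygon
    device comes from the largest slice. ``n_starts`` trades rectangle
    refinement effort for throughput across a cohort.
    """
    if not sections:
        raise ValueError("empty section stack")
    best = {"circle": (None, -np.inf, -1), "rectangle": (None, -np.inf, -1),
            "ellipse": (None, -np.inf, -1)}
    for sec in sections:
        fits = {"circle": max_circle(sec.polygon),
                "rectangle": max_rectangle(sec.polygon, n_starts=n_starts,
                                           seed=seed),
                "ellipse": max_ellipse(sec.polygon)}
        for name, fit in fits.items():
            # ties within 1e-9 relative keep the earlier slice
            if fit.area > best[name][1] * (1 + 1e-9):
                best[name] = (fit, fit.area, sec.slice_index)
    from .geometry import largest_slice
    big = largest_slice(list(sections))
    poly = device_polygon(big.polygon, max_sides=max_sides)
    return PatientFits(
        circle=best["circle"][0], circle_slice=best["circle"][2],
        rectangle=best["rectangle"][0], rectangle_slice=best["rectangle"][2],
        ellipse=best["ellipse"][0], ellipse_slice=best["ellipse"][2],
        polygon=poly, polygon_slice=big.slice_index)
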