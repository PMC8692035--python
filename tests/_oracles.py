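"""Independent brute-force oracles for the inscribed-shape fitters.

These deliberately avoid the implementation's solution path: the circle
oracle is a dense grid of candidate centres; the rectangle and ellipse
oracles brute-force the orientation on a fine grid and solve each
fixed-orientation subproblem with trust-constr (a different scipy
algorithm from the SLSQP used in the package) started from a
grid-derived interior point, with a local orientation refinement around
the incumbent. The 9-gon oracle is exhaustive subset search. The hull-volume oracle decomposes the hull into tetrahedra from
the point centroid instead of using Qhull's volume.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize
from scipy.spatial import ConvexHull

from morphofit.shapes import polygon_area, polygon_halfplanes


def _quiet_minimize(*args, **kwargs):
    # trust-constr emits a benign delta_grad warning on linear subproblems
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        return minimize(*args, **kwargs)


def random_convex_polygon(rng: np.random.Generator, n_vertices: int,
                          radius: float = 60.0,
                          elongation: float = 1.0) -> np.ndarray:
    """Random convex polygon: angular-sorted points on a jittered circle."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = radius * rng.uniform(0.6, 1.0, n_vertices)
    pts = np.column_stack([r * np.cos(th) * elongation, r * np.sin(th)])
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def grid_deepest_point(poly: np.ndarray,
                       pitch: float = 0.2) -> tuple[np.ndarray, float]:
    """Grid centre with the largest clearance to all edges, and that clearance."""
    A, b = polygon_halfplanes(poly)
    xs = np.arange(poly[:, 0].min(), poly[:, 0].max() + pitch, pitch)
    ys = np.arange(poly[:, 1].min(), poly[:, 1].max() + pitch, pitch)
    X, Y = np.meshgrid(xs, ys)
    C = np.column_stack([X.ravel(), Y.ravel()])
    r = (b[None, :] - C @ A.T).min(axis=1)
    k = int(np.argmax(r))
    return C[k], float(r[k])


def grid_circle_oracle(poly: np.ndarray, pitch: float = 0.2) -> float:
    """Best inscribed-circle radius over a dense centre grid."""
    return grid_deepest_point(poly, pitch)[1]


def _interior_starts(poly: np.ndarray) -> list[np.ndarray]:
    deep, _ = grid_deepest_point(poly, pitch=1.0)
    return [deep]


def orientation_scan_rectangle_oracle(poly: np.ndarray,
                                      n_angles: int = 45) -> float:
    """Best rectangle area over an exhaustive orientation grid.

    At fixed orientation the problem — maximise log u + log v over the
    linear constraints aᵢ·c + pᵢu + qᵢv ≤ bᵢ (u, v half-extents, c free
    centre) — is convex; each angle is solved with trust-constr from an
    interior start and the best kept.
    """
    A, b = polygon_halfplanes(poly)
    starts = _interior_starts(poly)

    def solve_at(th: float) -> float:
        t1 = np.array([np.cos(th), np.sin(th)])
        t2 = np.array([-t1[1], t1[0]])
        p = np.abs(A @ t1)
        q = np.abs(A @ t2)
        M = np.column_stack([A, p, q])
        con = NonlinearConstraint(lambda x: M @ x, -np.inf, b)

        def neg(x):
            return -(np.log(x[2]) + np.log(x[3]))

        def grad(x):
            return np.array([0.0, 0.0, -1 / x[2], -1 / x[3]])

        out = 0.0
        for c0 in starts:
            slack = b - A @ c0
            if slack.min() <= 0:
                continue
            u0 = max(float((slack / np.maximum(p, 1e-9)).min()) * 0.4, 1e-6)
            v0 = max(float((slack / np.maximum(q, 1e-9)).min()) * 0.4, 1e-6)
            res = _quiet_minimize(neg, np.array([c0[0], c0[1], u0, v0]), jac=grad,
                           method="trust-constr", constraints=[con],
                           options={"gtol": 1e-8, "xtol": 1e-10,
                                    "maxiter": 150})
            x = res.x
            if (M @ x <= b + 1e-9).all() and x[2] > 0 and x[3] > 0:
                out = max(out, 4 * x[2] * x[3])
        return out

    step = np.pi / 2 / n_angles
    best, best_th = 0.0, 0.0
    for th in np.linspace(0.0, np.pi / 2, n_angles, endpoint=False):
        a = solve_at(th)
        if a > best:
            best, best_th = a, th
    # refine the orientation bracket around the incumbent
    for sub in (step / 4, step / 16):
        for th in (best_th - 2 * sub, best_th - sub, best_th + sub,
                   best_th + 2 * sub):
            a = solve_at(th)
            if a > best:
                best, best_th = a, th
    return best


def orientation_scan_ellipse_oracle(poly: np.ndarray,
                                    n_angles: int = 45) -> float:
    """Best ellipse area over an exhaustive orientation grid.

    For fixed axis orientation the containment constraint
    sqrt(a²(aᵢ·t1)² + b²(aᵢ·t2)²) ≤ bᵢ − aᵢ·d is convex in (a, b, d);
    maximise log(ab) with trust-constr per angle.
    """
    A, b = polygon_halfplanes(poly)
    starts = _interior_starts(poly)

    def solve_at(th: float) -> float:
        t1 = np.array([np.cos(th), np.sin(th)])
        t2 = np.array([-t1[1], t1[0]])
        p = A @ t1
        q = A @ t2

        def neg(x):
            return -(np.log(x[2]) + np.log(x[3]))

        def grad(x):
            return np.array([0.0, 0.0, -1 / x[2], -1 / x[3]])

        def cons(x):
            return b - A @ x[:2] - np.sqrt((p * x[2]) ** 2 + (q * x[3]) ** 2)

        out = 0.0
        for c0 in starts:
            slack = float((b - A @ c0).min())
            if slack <= 0:
                continue
            x0 = np.array([c0[0], c0[1], 0.4 * slack, 0.4 * slack])
            res = _quiet_minimize(neg, x0, jac=grad, method="trust-constr",
                           constraints=[NonlinearConstraint(cons, 0, np.inf)],
                           options={"gtol": 1e-8, "xtol": 1e-10,
                                    "maxiter": 150})
            x = res.x
            if x[2] > 0 and x[3] > 0 and cons(x).min() > -1e-6:
                out = max(out, np.pi * x[2] * x[3])
        return out

    step = np.pi / n_angles
    best, best_th = 0.0, 0.0
    for th in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        a = solve_at(th)
        if a > best:
            best, best_th = a, th
    for sub in (step / 4, step / 16):
        for th in (best_th - 2 * sub, best_th - sub, best_th + sub,
                   best_th + 2 * sub):
            a = solve_at(th)
            if a > best:
                best, best_th = a, th
    return best


def best_subset_polygon_area(poly: np.ndarray, k: int) -> float:
    """Exhaustive best k-vertex-subset area of a convex polygon."""
    best = 0.0
    for idx in combinations(range(len(poly)), k):
        best = max(best, polygon_area(poly[list(idx)]))
    return best


def centroid_decomposition_volume(points: np.ndarray) -> float:
    """Hull volume by summing tetrahedra (centroid, facet) — independent of
    Qhull's own volume computation beyond the facet list."""
    hull = ConvexHull(points)
    c = points[hull.vertices].mean(axis=0)
    vol = 0.0
    for simplex in hull.simplices:
        a, b, d = points[simplex]
        vol += abs(np.dot(a - c, np.cross(b - c, d - c))) / 6.0
    return vol
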