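"""Synthetic cohort generator: demographics plus PRSP landmark geometry.

The study population this emulates is a 642-participant CT reference
cohort (47.35% female). Demographic and anthropometric marginals are
truncated normals anchored to the published per-sex means ± SDs; joint
structure is a Gaussian copula with a documented correlation matrix (the
source reports only marginals). Landmark geometry places the linea alba
along a ventrally bulging midline between xiphoid and pubis and offsets
the semilunar points laterally and posteriorly, so each side's boundary
cloud encloses a thin lens-like convex volume whose thinnest bounding-box
axis is dorsoventral — the property the slicing stage relies on.

The xiphoid–pubis distance uses anatomically plausible adult defaults
(~340/360 mm) rather than the published table entry for that one field,
whose printed magnitude is inconsistent with the other mm-scale distances.

Exact-answer geometric fixtures (boxes and prisms with closed-form largest
slices and inscribed shapes) are provided for testing the geometry and
shape-fitting stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, truncnorm

from .io import LandmarkSet, PatientRecord, Station
from .shapes import polygon_area

__all__ = [
    "VARIABLES",
    "DEFAULT_MARGINALS",
    "DEFAULT_FEMALE_FRACTION",
    "CohortParams",
    "AnatomyParams",
    "generate_cohort",
    "make_box_fixture",
    "make_prism_fixture",
    "generate_screening_truth",
    "truncated_mean",
]

#: Sampled variables, in copula order.
VARIABLES = ("age", "bmi", "height", "weight", "asis", "xiphoid_pubis",
             "depth", "width", "circumference")

#: Per-sex (mean, sd, lower, upper) truncated-normal marginals. Means/SDs
#: follow the published cohort table except xiphoid_pubis (see module
#: docstring). Bounds are physical floors; upper bounds sit at mean + 3 sd,
#: and lower bounds at mean − 3 sd unless the floor binds first.
def _m(mean, sd, floor=None):
    lo = mean - 3 * sd if floor is None else max(mean - 3 * sd, floor)
    return (mean, sd, lo, mean + 3 * sd)


DEFAULT_MARGINALS: dict[str, dict[str, tuple]] = {
    "female": {
        "age": (34.36, 23.94, 0.0, 34.36 + 3 * 23.94),
        "bmi": _m(26.3, 7.51, 13.0),
        "height": _m(1.59, 0.15),
        "weight": _m(64.79, 25.37, 20.0),
        "asis": _m(213.67, 31.52, 100.0),
        "xiphoid_pubis": _m(340.0, 30.0, 180.0),
        "depth": _m(216.69, 54.74, 80.0),
        "width": _m(315.84, 62.56, 140.0),
        "circumference": _m(878.93, 192.70, 350.0),
    },
    "male": {
        "age": (31.02, 20.84, 0.0, 31.02 + 3 * 20.84),
        "bmi": _m(26.33, 6.90, 13.0),
        "height": _m(1.72, 0.20),
        "weight": _m(76.97, 28.97, 20.0),
        "asis": _m(219.66, 32.80, 100.0),
        "xiphoid_pubis": _m(360.0, 32.0, 180.0),
        "depth": _m(222.35, 58.66, 80.0),
        "width": _m(314.41, 61.20, 140.0),
        "circumference": _m(880.89, 198.36, 350.0),
    },
}

DEFAULT_FEMALE_FRACTION = 304 / 642  # 47.35%

#: Copula correlations: size variables (everything but age) share 0.5
#: pairwise; age correlates 0.25 with each size variable. Documented
#: constants — the source reports marginals only.
SIZE_CORR = 0.5
AGE_SIZE_CORR = 0.25


def _default_corr() -> np.ndarray:
    k = len(VARIABLES)
    C = np.full((k, k), SIZE_CORR)
    C[0, :] = AGE_SIZE_CORR
    C[:, 0] = AGE_SIZE_CORR
    np.fill_diagonal(C, 1.0)
    return C


def truncated_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Analytic mean of the truncated normal marginal actually sampled."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.mean(a, b, loc=mean, scale=sd))


@dataclass(frozen=True)
class CohortParams:
    """Demographic sampling configuration."""

    n: int = 642
    seed: int = 0
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    marginals: dict = field(default_factory=lambda: DEFAULT_MARGINALS)
    correlation: np.ndarray = field(default_factory=_default_corr)
    missingness: float = 0.0  # per optional field, independent

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be in [0, 1]")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        C = np.asarray(self.correlation, dtype=float)
        if np.linalg.eigvalsh(C).min() < 1e-10:
            raise ValueError("correlation matrix must be positive definite")
        for sex, table in self.marginals.items():
            for var, (mean, sd, lo, hi) in table.items():
                if sd < 0:
                    raise ValueError(f"{sex}/{var}: sd must be >= 0")
                if not lo < hi:
                    raise ValueError(f"{sex}/{var}: infeasible truncation bounds")


@dataclass(frozen=True)
class AnatomyParams:
    """Landmark-geometry configuration (all lengths mm).

    The half-width profile is w(t) = half_width · (4t(1−t))^width_power for
    t ∈ (0, 1) along the trunk — width_power = 0.5 is an elliptical
    (bluntly tapering) semilunar line, larger powers a pointier leaf. The
    midline bulges ventrally by curvature_depth · sin(πt) and the
    semilunar points sit at (1 − posterior_drop) of the midline bulge,
    which makes the enclosed hull a thin lens. half_width scales with body
    width, curvature_depth with body depth and BMI, so PRSP size covaries
    with habitus.
    """

    station_spacing: float = 30.0
    station_margin: float = 15.0
    half_width: float = 80.0
    width_power: float = 0.5
    curvature_depth: float = 22.0
    posterior_drop: float = 0.85
    bmi_exponent: float = 0.4
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.station_spacing <= 0:
            raise ValueError("station_spacing must be > 0")
        if self.half_width <= 0 or self.curvature_depth <= 0:
            raise ValueError("half_width and curvature_depth must be > 0")
        if not 0 < self.posterior_drop < 1:
            raise ValueError("posterior_drop must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


_REF = {"width": 315.0, "depth": 220.0, "bmi": 26.3}


def _sample_sex_block(rng: np.random.Generator, params: CohortParams,
                      sex: str, n: int) -> dict[str, np.ndarray]:
    """Gaussian-copula draw preserving each truncated-normal marginal."""
    C = np.asarray(params.correlation, dtype=float)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n, len(VARIABLES))) @ L.T
    U = norm.cdf(Z)
    out = {}
    for j, var in enumerate(VARIABLES):
        mean, sd, lo, hi = params.marginals[sex][var]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        u = np.clip(U[:, j], 1e-12, 1 - 1e-12)
        out[var] = truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    return out


def _make_landmarks(pid: str, rng: np.random.Generator, anat: AnatomyParams,
                    length: float, width_mm: float, depth_mm: float,
                    bmi: float) -> LandmarkSet:
    W = anat.half_width * (width_mm / _REF["width"])
    D = anat.curvature_depth * (depth_mm / _REF["depth"]) \
        * (bmi / _REF["bmi"]) ** anat.bmi_exponent
    # thin-volume guarantee: keep the dorsoventral sag well below the
    # lateral extent so the smallest bounding-box axis stays dorsoventral
    D = min(D, 0.45 * W)
    m = anat.station_margin
    zs = []
    z = length - m
    while z >= m - 1e-9:
        zs.append(z)
        z -= anat.station_spacing
    if len(zs) < 3:  # very short trunks: tighten the margin instead of failing
        zs = list(np.linspace(length * 0.9, length * 0.1, 3))
    stations = []
    for k, z in enumerate(zs):
        t = z / length
        bulge = D * np.sin(np.pi * t)
        w = W * (4 * t * (1 - t)) ** anat.width_power
        la = np.array([0.0, bulge, z])
        sl = np.array([w, (1 - anat.posterior_drop) * bulge, z])
        sr = np.array([-w, (1 - anat.posterior_drop) * bulge, z])
        stations.append((k, la, sl, sr))
    xi = np.array([0.0, 0.0, length])
    pu = np.array([0.0, 0.0, 0.0])
    if anat.noise_sd > 0:
        noise = rng.normal(scale=anat.noise_sd,
                           size=(2 + 3 * len(stations), 3))
        xi = xi + noise[0]
        pu = pu + noise[1]
        stations = [(k, la + noise[2 + 3 * i], sl + noise[3 + 3 * i],
                     sr + noise[4 + 3 * i])
                    for i, (k, la, sl, sr) in enumerate(stations)]
    return LandmarkSet(
        patient_id=pid, xiphoid_tip=xi, pubis_tip=pu,
        stations=tuple(Station(k, la, sl, sr) for k, la, sl, sr in stations))


def generate_cohort(params: CohortParams | None = None,
                    anatomy: AnatomyParams | None = None,
                    ) -> tuple[list[PatientRecord], list[LandmarkSet]]:
    """Draw a reproducible synthetic cohort (records + landmark sets)."""
    params = params or CohortParams()
    anatomy = anatomy or AnatomyParams()
    rng = np.random.default_rng(params.seed)
    sexes = np.where(rng.random(params.n) < params.female_fraction,
                     "female", "male")
    blocks = {}
    for sex in ("female", "male"):
        idx = np.flatnonzero(sexes == sex)
        if len(idx):
            blocks[sex] = (idx, _sample_sex_block(rng, params, sex, len(idx)))
    vals = {var: np.empty(params.n) for var in VARIABLES}
    for sex, (idx, block) in blocks.items():
        for var in VARIABLES:
            vals[var][idx] = block[var]

    records: list[PatientRecord] = []
    landmarks: list[LandmarkSet] = []
    width_id = int(np.ceil(np.log10(params.n + 1)))
    optional = ("height", "weight", "bmi", "asis", "xiphoid_pubis", "depth",
                "width", "circumference")
    for i in range(params.n):
        pid = f"SYN{i:0{width_id}d}"
        present = {f: (params.missingness == 0.0
                       or rng.random() >= params.missingness)
                   for f in optional}
        records.append(PatientRecord(
            patient_id=pid, sex=str(sexes[i]), age=float(vals["age"][i]),
            height=vals["height"][i] if present["height"] else None,
            weight=vals["weight"][i] if present["weight"] else None,
            bmi=vals["bmi"][i] if present["bmi"] else None,
            asis_distance=vals["asis"][i] if present["asis"] else None,
            xiphoid_pubis_distance=(vals["xiphoid_pubis"][i]
                                    if present["xiphoid_pubis"] else None),
            body_depth=vals["depth"][i] if present["depth"] else None,
            body_width=vals["width"][i] if present["width"] else None,
            body_circumference=(vals["circumference"][i]
                                if present["circumference"] else None)))
        landmarks.append(_make_landmarks(
            pid, rng, anatomy, length=float(vals["xiphoid_pubis"][i]),
            width_mm=float(vals["width"][i]), depth_mm=float(vals["depth"][i]),
            bmi=float(vals["bmi"][i])))
    return records, landmarks


# ---------------------------------------------------------------------------
# exact-answer fixtures


def make_box_fixture(width: float, height: float, thickness: float,
                     edge_points: int = 0) -> tuple[np.ndarray, dict]:
    """Axis-aligned box point cloud with closed-form ground truth.

    The box spans width (x) × height (y) × thickness (z); the largest
    frontal slice is the w × h face. Returns (points, truth) where truth
    holds volume, slice area, incircle radius, max rectangle and max
    ellipse area.
    """
    if min(width, height, thickness) <= 0:
        raise ValueError("all box dimensions must be > 0")
    xs = np.array([0.0, width])
    ys = np.array([0.0, height])
    zs = np.array([0.0, thickness])
    pts = [np.array([x, y, z]) for x in xs for y in ys for z in zs]
    if edge_points:
        for f in np.linspace(0, 1, edge_points + 2)[1:-1]:
            for y in ys:
                for z in zs:
                    pts.append(np.array([f * width, y, z]))
    points = np.array(pts)
    truth = {
        "volume": width * height * thickness,
        "slice_area": width * height,
        "circle_radius": min(width, height) / 2,
        "rectangle_area": width * height,
        "ellipse_area": np.pi * width * height / 4,
    }
    return points, truth


def make_prism_fixture(polygon_2d: np.ndarray,
                       thickness: float) -> tuple[np.ndarray, dict]:
    """Right prism over a convex polygon, thin axis = z.

    Every frontal slice equals the base polygon, so 2D shape oracles on the
    base are ground truth for the whole volume.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    poly = np.asarray(polygon_2d, dtype=float)
    area = polygon_area(poly)
    if area <= 0:
        raise ValueError("degenerate polygon")
    # convexity check: all cross products one sign
    d = np.roll(poly, -1, axis=0) - poly
    cross = d[:, 0] * np.roll(d, -1, axis=0)[:, 1] \
        - d[:, 1] * np.roll(d, -1, axis=0)[:, 0]
    if not (np.all(cross >= -1e-9) or np.all(cross <= 1e-9)):
        raise ValueError("fixture polygon must be convex")
    pts = np.vstack([np.column_stack([poly, np.zeros(len(poly))]),
                     np.column_stack([poly, np.full(len(poly), thickness)])])
    truth = {"volume": area * thickness, "slice_area": area}
    return pts, truth


# ---------------------------------------------------------------------------
# screening-model parameter-recovery harness


def generate_screening_truth(features: np.ndarray, coefficients: dict,
                             noise_sd: float = 0.0,
                             seed: int = 0) -> np.ndarray:
    """Quadratic response surface plus Gaussian noise, reproducible by seed.

    ``coefficients`` holds 'intercept' (scalar), 'linear' (p,), and
    'quadratic' (p, p) symmetric; the response is
    c0 + x·l + x·Q·x evaluated row-wise.
    """
    X = np.asarray(features, dtype=float)
    c0 = float(coefficients.get("intercept", 0.0))
    lin = np.asarray(coefficients.get("linear", np.zeros(X.shape[1])), float)
    Q = np.asarray(coefficients.get("quadratic",
                                    np.zeros((X.shape[1], X.shape[1]))), float)
    y = c0 + X @ lin + np.einsum("ij,jk,ik->i", X, Q, X)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(scale=noise_sd, size=len(y))
    return y


def default_quadratic_coefficients(p: int = 8, seed: int = 0,
                                   scale: float = 1.0) -> dict:
    """A reproducible, well-scaled quadratic coefficient set for recovery tests."""
    rng = np.random.default_rng(seed)
    Q = rng.normal(size=(p, p)) * 0.5
    return {"intercept": float(rng.normal()) * scale,
            "linear": rng.normal(size=p) * scale,
            "quadratic": (Q + Q.T) / 2 * scale}
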