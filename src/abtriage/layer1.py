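"""Unsupervised gate: rbf kernel PCA to two components and a rotated-ellipse
containment test built from the reference (clinical) projections.

Ellipse construction: the major axis lies along whichever of the two
principal components has the greater reference range; its endpoints are the
two actual reference points whose major-axis coordinates are closest to
mean +/- Z*sd (for Z="all", the extreme points themselves); the minor
height is 2*Z*sd of the minor-axis coordinates (full minor range for
"all").  Containment is analytic: translate to the center, rotate by the
endpoint angle, and test (x/a)^2 + (y/b)^2 <= 1 with the boundary inside.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import KernelPCA

from .errors import (
    DegenerateEllipse,
    DegenerateKernel,
    DimensionMismatch,
    EmptyGroup,
    InsufficientReference,
)

_RANK_TOL = 1e-12  # eigenvalues below tol * lambda_1 count as rank-deficient


@dataclass(frozen=True)
class KPCAConfig:
    kernel: str = "rbf"
    gamma: float = 500.0
    n_components: int = 2

    def __post_init__(self):
        if self.kernel not in ("rbf", "cosine", "poly"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class KPCAModel:
    """Fitted kernel PCA with a stable per-component sign convention."""

    config: KPCAConfig
    _kpca: KernelPCA
    signs: np.ndarray
    eigenvalues: np.ndarray
    training_projections: np.ndarray
    n_features: int
    fingerprint: str


def _fingerprint(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X, dtype=np.float64).tobytes()).hexdigest()[:16]


def fit_kpca(X: np.ndarray, config: KPCAConfig | None = None) -> KPCAModel:
    """Fit kernel PCA; training projections are the eigenvectors of the
    double-centered kernel scaled by sqrt(eigenvalue)."""
    config = config or KPCAConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values")
    kwargs = {"n_components": config.n_components, "kernel": config.kernel,
              "eigen_solver": "dense"}
    if config.kernel in ("rbf", "poly"):
        kwargs["gamma"] = config.gamma
    kpca = KernelPCA(**kwargs)
    proj = kpca.fit_transform(X)
    eig = np.asarray(kpca.eigenvalues_, dtype=float)
    if eig.size < config.n_components or eig[config.n_components - 1] <= max(
        _RANK_TOL * max(eig[0], 0.0), 1e-14
    ):
        raise DegenerateKernel(
            f"centered kernel rank < {config.n_components} (eigenvalues {eig})"
        )
    # sign convention: largest-magnitude training coordinate positive
    signs = np.ones(config.n_components)
    for j in range(config.n_components):
        idx = int(np.argmax(np.abs(proj[:, j])))
        if proj[idx, j] < 0:
            signs[j] = -1.0
    proj = proj * signs
    return KPCAModel(config=config, _kpca=kpca, signs=signs, eigenvalues=eig,
                     training_projections=proj, n_features=X.shape[1],
                     fingerprint=_fingerprint(X))


def project(model: KPCAModel, X_new: np.ndarray) -> np.ndarray:
    """Kernel-centered projection of new rows into the fitted component space."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.size == 0:
        return np.empty((0, model.config.n_components))
    if X_new.ndim != 2 or X_new.shape[1] != model.n_features:
        raise DimensionMismatch(
            f"expected {model.n_features} features, got {X_new.shape}"
        )
    return model._kpca.transform(X_new) * model.signs


# ---------------------------------------------------------------------------
# ellipse gate


@dataclass(frozen=True)
class EllipseSpec:
    """Rotated ellipse from two major-axis endpoints and a minor height."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    h: float
    a: float = field(init=False)
    b: float = field(init=False)
    theta: float = field(init=False)
    center: tuple[float, float] = field(init=False)

    def __post_init__(self):
        dx = self.p2[0] - self.p1[0]
        dy = self.p2[1] - self.p1[1]
        a = float(np.hypot(dx, dy) / 2.0)
        if a == 0.0:
            raise DegenerateEllipse("major-axis endpoints coincide")
        if self.h <= 0:
            raise DegenerateEllipse("minor height must be positive")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", float(self.h) / 2.0)
        object.__setattr__(self, "theta", float(np.arctan2(dy, dx)))
        object.__setattr__(
            self, "center",
            ((self.p1[0] + self.p2[0]) / 2.0, (self.p1[1] + self.p2[1]) / 2.0),
        )

    def polygon(self, n: int = 100) -> np.ndarray:
        """The parametric n-vertex polygon approximation (test oracle)."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = np.column_stack([self.a * np.cos(t), self.b * np.sin(t)])
        rot = np.array([[np.cos(self.theta), -np.sin(self.theta)],
                        [np.sin(self.theta), np.cos(self.theta)]])
        return pts @ rot.T + np.asarray(self.center)


def make_ellipse(p1, p2, h: float) -> EllipseSpec:
    """Ellipse through major-axis endpoints p1, p2 with minor height h."""
    return EllipseSpec(p1=(float(p1[0]), float(p1[1])),
                       p2=(float(p2[0]), float(p2[1])), h=float(h))


def _canonical_form(e: EllipseSpec, p) -> float:
    x = p[0] - e.center[0]
    y = p[1] - e.center[1]
    c, s = np.cos(e.theta), np.sin(e.theta)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / e.a) ** 2 + (v / e.b) ** 2


def point_in_ellipse(e: EllipseSpec, p) -> bool:
    """Analytic containment; the boundary counts as inside."""
    return _canonical_form(e, p) <= 1.0


def ellipse_from_reference(points_2d: np.ndarray, z: float | str) -> EllipseSpec:
    """Build the gate ellipse from reference projections at stringency Z.

    Z is a nonnegative real, or the string "all": the smallest stringency
    whose ellipse captures every reference point (endpoints saturate at the
    extreme reference points while the minor height keeps growing).
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise InsufficientReference("need >= 3 reference points in 2-D")
    if z == "all":
        mj, mn, _ = _axes(pts)
        sd_mj, sd_mn = mj.std(ddof=1), mn.std(ddof=1)
        z_sat = max(
            float(np.max(np.abs(mj - mj.mean())) / sd_mj) if sd_mj > 0 else 1.0,
            float(np.max(np.abs(mn - mn.mean())) / sd_mn) if sd_mn > 0 else 1.0,
        )
        e = _ellipse_at_z(pts, z_sat)
        # minimal uniform inflation putting the worst point on the boundary
        worst = max(_canonical_form(e, p) for p in pts)
        if worst > 1.0:
            s = float(np.sqrt(worst)) * (1.0 + 1e-9)
            cx, cy = e.center
            p1 = (cx + (e.p1[0] - cx) * s, cy + (e.p1[1] - cy) * s)
            p2 = (cx + (e.p2[0] - cx) * s, cy + (e.p2[1] - cy) * s)
            e = make_ellipse(p1, p2, e.h * s)
        return e
    z = float(z)
    if z < 0:
        raise ValueError("Z must be nonnegative")
    return _ellipse_at_z(pts, z)


def _axes(pts: np.ndarray):
    ranges = pts.max(axis=0) - pts.min(axis=0)
    major = int(np.argmax(ranges))
    return pts[:, major], pts[:, 1 - major], major


def _ellipse_at_z(pts: np.ndarray, z: float) -> EllipseSpec:
    mj, mn, _ = _axes(pts)
    mu, sd = mj.mean(), mj.std(ddof=1)
    i1 = int(np.argmin(np.abs(mj - (mu - z * sd))))
    i2 = int(np.argmin(np.abs(mj - (mu + z * sd))))
    if i1 == i2:
        raise DegenerateEllipse("Z too small: both endpoints are the same point")
    return make_ellipse(pts[i1], pts[i2], float(2.0 * z * mn.std(ddof=1)))


def capture_rates(e: EllipseSpec, groups: dict) -> dict:
    """Percentage of each labeled 2-D point group inside the ellipse."""
    out = {}
    for name, pts in groups.items():
        pts = np.asarray(pts, dtype=float)
        if pts.size == 0:
            raise EmptyGroup(f"group {name!r} is empty")
        inside = sum(point_in_ellipse(e, p) for p in pts)
        out[name] = 100.0 * inside / len(pts)
    return out


def layer1_select(ids, projections: np.ndarray, e: EllipseSpec) -> list:
    """Ids whose projections fall inside the gate ellipse."""
    projections = np.asarray(projections, dtype=float)
    return [i for i, p in zip(ids, projections) if point_in_ellipse(e, p)]


@dataclass(frozen=True)
class GateResult:
    ellipse: EllipseSpec
    z: float | str
    inside: tuple[bool, ...]
    capture: dict

    def __post_init__(self):
        for pct in self.capture.values():
            if not 0.0 <= pct <= 100.0:
                raise ValueError("capture percentage out of [0, 100]")


def gate(reference_projections: np.ndarray, query_projections: np.ndarray,
         z: float | str, extra_groups: dict | None = None) -> GateResult:
    """Construct the ellipse from the reference cloud and gate the query."""
    e = ellipse_from_reference(reference_projections, z)
    inside = tuple(bool(point_in_ellipse(e, p)) for p in np.asarray(query_projections))
    groups = {"reference": reference_projections}
    if len(query_projections):
        groups["query"] = query_projections
    groups.update(extra_groups or {})
    return GateResult(ellipse=e, z=z, inside=inside, capture=capture_rates(e, groups))
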