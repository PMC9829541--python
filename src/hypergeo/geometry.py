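"""Point samples from candidate latent geometries and their distances.

Two hypothesis families are screened against neural similarity
matrices: d-dimensional Euclidean geometry (points uniform in the unit
cube) and the native model of d-dimensional hyperbolic geometry with
curvature K = -zeta^2, zeta fixed to 1 and the ball radius R_max varied
(equivalent, up to rescaling, to fixing R_max and varying curvature).
In the native model a point is a radius r in [0, R_max] with density
proportional to sinh^(d-1)(r) — the uniform measure on the hyperbolic
ball — and a direction uniform on the (d-1)-sphere.

Model distance matrices receive i.i.d. multiplicative Gaussian noise
per unordered pair, D_ij * (1 + eps * N(0, 1)), mimicking trial-to-
trial variability in correlation estimates; only the rank order of the
entries feeds the topological analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GeometrySpec",
    "DistanceMatrix",
    "sample_hyperbolic",
    "sample_euclidean",
    "hyperbolic_distance",
    "hyperbolic_distance_matrix",
    "euclidean_distance_matrix",
    "apply_noise",
    "sample_distance_matrix",
]


@dataclass(frozen=True)
class GeometrySpec:
    """Hypothesis: which geometry, its dimension, size and noise level."""

    kind: str  # "hyperbolic" | "euclidean"
    dim: int
    r_max: float = 0.0  # hyperbolic only; curvature zeta fixed at 1
    noise_eps: float = 0.05

    def __post_init__(self):
        if self.kind not in ("hyperbolic", "euclidean"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.dim < 1:
            raise ValueError("dimension must be >= 1")
        if self.kind == "hyperbolic" and self.r_max <= 0:
            raise ValueError("hyperbolic geometry requires r_max > 0")
        if self.noise_eps < 0:
            raise ValueError("noise level must be >= 0")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with provenance."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v


def _sphere_uniform(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vectors on S^(dim-1) via normalized Gaussians."""
    v = rng.standard_normal((n, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_hyperbolic(dim: int, r_max: float, n_points: int,
                      rng: np.random.Generator | int | None = None,
                      grid_size: int = 4096):
    """Uniform sample from the hyperbolic ball (native model, zeta = 1).

    Radii follow rho(r) ~ sinh^(d-1)(r) on [0, r_max] (inverse-CDF on a
    dense grid); directions are uniform on the sphere.

    Returns
    -------
    radii : (n_points,) array
    directions : (n_points, dim) array of unit vectors
    """
    if dim < 2:
        raise ValueError("hyperbolic sampling needs dim >= 2 (angular part)")
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    if n_points < 1:
        raise ValueError("need at least one point")
    rng = np.random.default_rng(rng)
    grid = np.linspace(0.0, r_max, grid_size)
    # sinh^(d-1) normalized on the grid; trapezoid CDF then inverted
    density = np.sinh(grid) ** (dim - 1)
    cdf = np.concatenate([[0.0], np.cumsum((density[1:] + density[:-1]) / 2)])
    cdf /= cdf[-1]
    radii = np.interp(rng.uniform(size=n_points), cdf, grid)
    directions = _sphere_uniform(n_points, dim, rng)
    return radii, directions


def sample_euclidean(dim: int, n_points: int,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """I.i.d. uniform points in the d-dimensional unit cube."""
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.uniform(size=(n_points, dim))


def hyperbolic_distance(r, r_prime, delta_theta, zeta: float = 1.0):
    """Hyperbolic law of cosines distance between points at radii r, r'.

    cosh(zeta x) = cosh(zeta r) cosh(zeta r')
                   - sinh(zeta r) sinh(zeta r') cos(delta_theta)

    Round-off can push the acosh argument slightly below 1; it is
    clamped.  Radii beyond ~700/zeta would overflow cosh in double
    precision; the radii used here (R_max <= ~25) are far from that.
    """
    r = np.asarray(r, dtype=float)
    rp = np.asarray(r_prime, dtype=float)
    dth = np.asarray(delta_theta, dtype=float)
    arg = (np.cosh(zeta * r) * np.cosh(zeta * rp)
           - np.sinh(zeta * r) * np.sinh(zeta * rp) * np.cos(dth))
    return np.arccosh(np.maximum(arg, 1.0)) / zeta


def hyperbolic_distance_matrix(radii: np.ndarray, directions: np.ndarray,
                               zeta: float = 1.0) -> DistanceMatrix:
    """All pairwise hyperbolic distances of a native-model point set."""
    radii = np.asarray(radii, dtype=float)
    cosang = np.clip(directions @ directions.T, -1.0, 1.0)
    ch = np.cosh(zeta * radii)
    sh = np.sinh(zeta * radii)
    arg = ch[:, None] * ch[None, :] - sh[:, None] * sh[None, :] * cosang
    D = np.arccosh(np.maximum(arg, 1.0)) / zeta
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, provenance="hyperbolic")


def euclidean_distance_matrix(points: np.ndarray) -> DistanceMatrix:
    """All pairwise Euclidean distances of a point cloud."""
    return DistanceMatrix(squareform(pdist(np.asarray(points, dtype=float))),
                          provenance="euclidean")


def apply_noise(D: DistanceMatrix, eps: float,
                rng: np.random.Generator | int | None = None) -> DistanceMatrix:
    """Multiplicative Gaussian noise D_ij * (1 + eps N(0,1)) per pair.

    Noise is drawn once per unordered pair so symmetry is preserved.
    Negative noisy entries are possible at large eps and are left in
    place: only the rank order matters downstream.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if eps == 0:
        return DistanceMatrix(D.values.copy(), provenance=D.provenance)
    rng = np.random.default_rng(rng)
    n = D.values.shape[0]
    iu = np.triu_indices(n, 1)
    noisy = D.values.copy()
    noisy[iu] = noisy[iu] * (1.0 + eps * rng.standard_normal(iu[0].size))
    noisy.T[iu] = noisy[iu]
    return DistanceMatrix(noisy, provenance=D.provenance + "+noise")


def sample_distance_matrix(spec: GeometrySpec, n_points: int,
                           rng: np.random.Generator | int | None = None
                           ) -> DistanceMatrix:
    """Sample a point set from ``spec`` and return its noisy distances."""
    rng = np.random.default_rng(rng)
    if spec.kind == "hyperbolic":
        radii, dirs = sample_hyperbolic(spec.dim, spec.r_max, n_points, rng)
        D = hyperbolic_distance_matrix(radii, dirs)
    else:
        D = euclidean_distance_matrix(sample_euclidean(spec.dim, n_points, rng))
    return apply_noise(D, spec.noise_eps, rng)
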