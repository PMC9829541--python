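"""Betti curves of the clique (flag) complex of a similarity matrix.

The order filtration thresholds a symmetric similarity matrix at every
possible edge density rho = k / C(n, 2): the graph at density rho
contains the k most-similar pairs.  beta_m(rho) counts the
m-dimensional holes of the clique complex of that graph, excluding
those that are boundaries of higher cliques.  Because only the *order*
of the entries matters, the curves are invariant under any strictly
monotone transform of the similarities — the property that makes them
usable on neural correlation matrices distorted by unknown
monotone nonlinearities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._flagph import flag_persistence_pairs

__all__ = [
    "BettiCurveSet",
    "betti_curves",
    "integrated_betti",
    "l1_curve_distance",
    "smooth_curve_for_display",
]


@dataclass
class BettiCurveSet:
    """Betti curves beta_1..beta_max_dim on the exact edge-density grid.

    curves[m - 1, k] is beta_m of the graph containing the k
    highest-similarity edges, for k = 0..E with E = C(n_nodes, 2);
    edge_densities[k] = k / E.
    """

    edge_densities: np.ndarray
    curves: np.ndarray  # (max_dim, E + 1), integer-valued
    n_nodes: int
    source: str = ""

    @property
    def max_dim(self) -> int:
        return self.curves.shape[0]

    def curve(self, m: int) -> np.ndarray:
        """beta_m as a vector over the density grid (m is 1-based)."""
        if not 1 <= m <= self.max_dim:
            raise ValueError(f"beta_{m} was not computed (max_dim={self.max_dim})")
        return self.curves[m - 1]


def betti_curves(S: np.ndarray, max_dim: int = 3, source: str = "") -> BettiCurveSet:
    """Betti curves of the decreasing-similarity flag filtration of ``S``.

    Parameters
    ----------
    S : symmetric (n, n) similarity matrix; diagonal ignored; ties in
        off-diagonal entries are broken by lexicographic (i, j) order.
    max_dim : highest Betti curve to compute (1..3 typical).  Cliques of
        up to ``max_dim + 2`` vertices are enumerated, so cost grows
        steeply with this parameter.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    # for n < max_dim + 2 the higher curves are identically zero
    eff_dim = min(max_dim, n - 2)
    E, pairs = flag_persistence_pairs(S, max_dim=eff_dim)
    curves = np.zeros((max_dim, E + 1), dtype=np.int64)
    for m in range(1, eff_dim + 1):
        births, deaths = pairs[m]
        diff = np.zeros(E + 2, dtype=np.int64)
        keep = deaths > births
        np.add.at(diff, births[keep], 1)
        np.add.at(diff, np.minimum(deaths[keep], E + 1), -1)
        curves[m - 1] = np.cumsum(diff)[: E + 1]
    densities = np.arange(E + 1) / E
    return BettiCurveSet(edge_densities=densities, curves=curves, n_nodes=n,
                         source=source)


def integrated_betti(curve: np.ndarray) -> float:
    """Integral of a Betti curve over rho in [0, 1] (step function).

    The curve value at grid index k is taken as constant on the density
    interval ((k-1)/E, k/E], so the integral is the mean of the values
    at k = 1..E.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or curve.size < 2:
        raise ValueError("curve must be a vector on the density grid")
    return float(curve[1:].mean())


def _regrid(curve: np.ndarray, densities: np.ndarray,
            target_densities: np.ndarray) -> np.ndarray:
    """Step interpolation of a curve onto another density grid."""
    idx = np.searchsorted(densities, target_densities, side="left")
    idx = np.clip(idx, 0, densities.size - 1)
    return np.asarray(curve, dtype=float)[idx]


def l1_curve_distance(curve: np.ndarray, reference: np.ndarray,
                      densities: np.ndarray | None = None,
                      reference_densities: np.ndarray | None = None) -> float:
    """L1 distance between two Betti curves, integral of |beta - beta_ref|.

    Curves on different grids are re-gridded onto the first curve's grid
    by step interpolation.
    """
    curve = np.asarray(curve, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if curve.shape != reference.shape:
        if densities is None or reference_densities is None:
            raise ValueError("grid mismatch: pass both density grids to re-grid")
        reference = _regrid(reference, reference_densities, densities)
    return float(np.abs(curve[1:] - reference[1:]).mean())


def smooth_curve_for_display(curve: np.ndarray, kernel_fraction: float = 1 / 50
                             ) -> np.ndarray:
    """Moving-average smoothing, display only — never used in statistics."""
    curve = np.asarray(curve, dtype=float)
    w = max(1, round(curve.size * kernel_fraction))
    if w <= 1:
        return curve.copy()
    kernel = np.ones(w) / w
    return np.convolve(curve, kernel, mode="same")
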