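"""Curvature of the representation from place-field size statistics.

If place-cell responses tile a hyperbolic ball of curvature zeta (unit
radius scale), 1-D place-field sizes s follow the sinh-truncated
exponential law

    p(s) = zeta * sinh(zeta (s_max - s)) / (cosh(zeta s_max) - 1),
    0 <= s <= s_max,

which approaches zeta * exp(-zeta s) when zeta * s_max >> 1.  The
curvature is therefore the inverse mean field size and can be
estimated from observed sizes.  Because experiments only resolve
fields within a size window (arena size, rate threshold, map binning),
the estimator works with the window-truncated exponential likelihood

    P(s | zeta) = zeta e^(-zeta s) / Z(zeta),
    Z(zeta) = exp(-zeta s_l) - exp(-zeta s_u),

with a uniform prior over a curvature grid (posterior maximum =
estimate, central interval = credibility band).

The module also covers the information-acquisition law that mirrors
the empirically observed logarithmic growth of the hyperbolic radius
with exploration time,

    I(T) = log(1 + T/t0) + (T/t0) log(1 + t0/T)      [natural log],

its least-squares fits to (time, radius) data, the mechanistic limit
R = log(T/t0), and a simulation showing how detection bias (sigmoidal
suppression of small fields) plus pooling across curvatures makes
exponential size distributions masquerade as log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SinhSizeLaw",
    "TruncationWindow",
    "CurvaturePosterior",
    "sinh_pdf",
    "fit_curvature_bayes",
    "fit_curvature_mle_excluding_small",
    "info_acquired",
    "fit_radius_growth",
    "lognormal_gof",
    "lognormal_emergence_sim",
    "DEFAULT_ZETA_GRID",
]

DEFAULT_ZETA_GRID = np.geomspace(1e-3, 1.0, 400)


@dataclass(frozen=True)
class SinhSizeLaw:
    """Field-size law p(s) on [0, s_max] for curvature zeta (1/cm)."""

    zeta: float
    s_max: float

    def __post_init__(self):
        if self.zeta <= 0 or self.s_max <= 0:
            raise ValueError("zeta and s_max must be positive")

    def pdf(self, s):
        return sinh_pdf(s, self.zeta, self.s_max)

    def sample(self, n: int, rng=None) -> np.ndarray:
        """Inverse-CDF sampling on a dense grid."""
        rng = np.random.default_rng(rng)
        grid = np.linspace(0, self.s_max, 4096)
        pdf = self.pdf(grid)
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)])
        cdf /= cdf[-1]
        return np.interp(rng.uniform(size=n), cdf, grid)


@dataclass(frozen=True)
class TruncationWindow:
    """Observable field-size range (s_l, s_u) in cm."""

    s_l: float
    s_u: float

    def __post_init__(self):
        if not self.s_l < self.s_u:
            raise ValueError("require s_l < s_u")


@dataclass
class CurvaturePosterior:
    """Posterior over the curvature grid with its point summaries."""

    zeta_grid: np.ndarray
    posterior: np.ndarray  # normalized density on the grid
    zeta_map: float
    ci95: tuple


def sinh_pdf(s, zeta: float, s_max: float):
    """Density of the sinh-truncated field-size law; 0 outside [0, s_max]."""
    if zeta <= 0 or s_max <= 0:
        raise ValueError("zeta and s_max must be positive")
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    inside = (s >= 0) & (s <= s_max)
    out[inside] = (zeta * np.sinh(zeta * (s_max - s[inside]))
                   / (np.cosh(zeta * s_max) - 1.0))
    return out if out.ndim else float(out)


def fit_curvature_bayes(sizes, window: TruncationWindow,
                        zeta_grid=None) -> CurvaturePosterior:
    """MAP curvature from window-truncated exponential sizes.

    log-posterior (uniform prior):  N log zeta - N log Z(zeta)
    - zeta * sum(s).  The posterior is normalized on the grid by
    trapezoid quadrature; the central 95% credible interval comes from
    the grid CDF.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size < 1:
        raise ValueError("need at least one field size")
    if np.any(sizes <= window.s_l) or np.any(sizes >= window.s_u):
        raise ValueError(
            f"{int(np.sum((sizes <= window.s_l) | (sizes >= window.s_u)))} "
            f"sizes fall outside the window ({window.s_l}, {window.s_u})")
    grid = DEFAULT_ZETA_GRID if zeta_grid is None else np.asarray(zeta_grid)
    N = sizes.size
    with np.errstate(over="ignore"):
        logZ = np.log(np.exp(-grid * window.s_l) - np.exp(-grid * window.s_u))
    loglik = N * np.log(grid) - N * logZ - grid * sizes.sum()
    loglik -= loglik.max()
    dens = np.exp(loglik)
    norm = np.trapezoid(dens, grid)
    dens /= norm
    cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid)
                                           * (dens[1:] + dens[:-1]) / 2)])
    cdf /= cdf[-1]
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    return CurvaturePosterior(grid, dens, float(grid[np.argmax(dens)]),
                              (lo, hi))


def fit_curvature_mle_excluding_small(sizes, exclusion_cutoff: float = 25.0
                                      ) -> float:
    """ML exponent of a left-truncated exponential size distribution.

    Fields below the cutoff (undersampled by recording and detection)
    are discarded; by memorylessness the ML rate is
    1 / mean(s - cutoff | s >= cutoff).
    """
    sizes = np.asarray(sizes, dtype=float)
    kept = sizes[sizes >= exclusion_cutoff]
    if kept.size == 0:
        raise ValueError("no sizes at or above the exclusion cutoff")
    excess = kept - exclusion_cutoff
    m = excess.mean()
    if m <= 0:
        raise ValueError("degenerate sample: all sizes equal the cutoff")
    return float(1.0 / m)


def info_acquired(T, t0: float):
    """Maximal information (nats) acquirable after exploration time T.

    I = log(1 + T/t0) + (T/t0) log(1 + t0/T); I(0) = 0 by continuity;
    I ~ log(T/t0) for T >> t0 and I ~ (T/t0) log(...) linear for small
    T.  t0 sets the crossover from the novel (linear) to the familiar
    (logarithmic) regime.
    """
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be nonnegative")
    x = T / t0
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.log1p(x[pos]) + x[pos] * np.log1p(1.0 / x[pos])
    return out if out.ndim else float(out)


def fit_radius_growth(times, radii, model: str = "log_linear",
                      include_intercept: bool = False) -> dict:
    """Least-squares fit of radius-vs-time growth.

    model="log_linear": R = a log T + b.  model="eq2_scaled":
    R = gamma * I(T; t0) (+ b if ``include_intercept``), nonlinear
    least squares over (gamma, t0[, b]).  Returns the parameters, the
    Pearson correlation of R with log T, and residuals.
    """
    T = np.asarray(times, dtype=float)
    R = np.asarray(radii, dtype=float)
    if T.size != R.size or T.size < 2:
        raise ValueError("need >= 2 (time, radius) points of equal length")
    if np.any(T <= 0):
        raise ValueError("times must be positive")
    if np.allclose(T, T[0]):
        raise ValueError("degenerate input: all times equal")
    logT = np.log(T)
    r_pearson = (float(np.corrcoef(logT, R)[0, 1]) if T.size > 2
                 else 1.0)
    if model == "log_linear":
        a, b = np.polyfit(logT, R, 1)
        fitted = a * logT + b
        return {"model": model, "a": float(a), "b": float(b),
                "r": r_pearson, "residuals": R - fitted, "fitted": fitted}
    if model != "eq2_scaled":
        raise ValueError(f"unknown model {model!r}")

    def predict(params):
        gamma, log_t0 = params[0], params[1]
        b = params[2] if include_intercept else 0.0
        return gamma * info_acquired(T, np.exp(log_t0)) + b

    def loss(params):
        return predict(params) - R

    # multi-start over t0 to avoid local minima of the nonlinear fit
    best = None
    for t0_init in np.geomspace(T.min() / 10, T.max(), 7):
        x0 = [max(R.max(), 1.0) / max(info_acquired(T.max(), t0_init), 1e-9),
              np.log(t0_init)]
        if include_intercept:
            x0.append(0.0)
        sol = optimize.least_squares(loss, x0)
        if best is None or sol.cost < best.cost:
            best = sol
    gamma, log_t0 = best.x[0], best.x[1]
    fitted = predict(best.x)
    out = {"model": model, "gamma": float(gamma), "t0": float(np.exp(log_t0)),
           "r": r_pearson, "residuals": R - fitted, "fitted": fitted}
    if include_intercept:
        out["b"] = float(best.x[2])
    return out


def lognormal_gof(sizes, n_bins: int = 10, min_expected: float = 5.0) -> dict:
    """Chi-square GOF of a fitted log-normal on a binned histogram.

    The log-normal is fitted by ML (location fixed at 0), the sample is
    histogrammed in ``n_bins`` equal-width bins over its range (the
    left edge extended to 0 and the right to infinity), adjacent bins
    are merged until every expected count reaches ``min_expected``, and
    degrees of freedom = bins - 1 - 2 (two fitted parameters).
    """
    sizes = np.asarray(sizes, dtype=float)
    shape, _, scale = stats.lognorm.fit(sizes, floc=0)
    edges = np.linspace(sizes.min(), sizes.max(), n_bins + 1)
    edges[0], edges[-1] = 0.0, np.inf
    observed, _ = np.histogram(sizes, bins=edges)
    expected = sizes.size * np.diff(stats.lognorm.cdf(edges, shape, loc=0,
                                                      scale=scale))
    # merge low-expectation bins from the right (tail) inward
    obs, exp = list(observed), list(expected)
    i = len(obs) - 1
    while i > 0:
        if exp[i] < min_expected:
            exp[i - 1] += exp[i]
            obs[i - 1] += obs[i]
            del exp[i], obs[i]
        i -= 1
    if exp and exp[0] < min_expected and len(exp) > 1:
        exp[1] += exp[0]
        obs[1] += obs[0]
        del exp[0], obs[0]
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = max(obs.size - 1 - 2, 1)
    pvalue = float(stats.chi2.sf(chi2, df))
    return {"chi2": chi2, "df": df, "pvalue": pvalue,
            "shape": float(shape), "scale": float(scale)}


def lognormal_emergence_sim(n_dists: int = 8, zetas=None,
                            sigmoid_mid: float = 10.0,
                            sigmoid_steepness: float = 0.4,
                            n_samples: int = 800, s_max: float = 400.0,
                            pooled: bool = True, suppress: bool = True,
                            n_bins: int = 10, seed=None) -> dict:
    """Detection bias turning exponential size laws into log-normal ones.

    Sizes are drawn from sinh laws (one per curvature in ``zetas``),
    small fields are suppressed by a logistic acceptance
    1 / (1 + exp(-steepness (s - mid))) (rejection sampling), and the
    accepted sizes — from one distribution or pooled across all — are
    tested against a fitted log-normal by chi-square GOF.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    if zetas is None:
        zetas = np.linspace(0.02, 0.06, n_dists)
    zetas = np.asarray(zetas, dtype=float)
    if not pooled:
        zetas = zetas[:1]
    per = int(np.ceil(n_samples / zetas.size))
    accepted = []
    for z in zetas:
        law = SinhSizeLaw(z, s_max)
        got = []
        attempts = 0
        while sum(a.size for a in got) < per:
            draw = law.sample(4 * per, rng)
            attempts += draw.size
            if suppress:
                p_acc = 1.0 / (1.0 + np.exp(-sigmoid_steepness
                                            * (draw - sigmoid_mid)))
                draw = draw[rng.uniform(size=draw.size) < p_acc]
            got.append(draw)
            if attempts > 1000 * per and sum(a.size for a in got) < 0.01 * attempts:
                raise ValueError("acceptance rate below 1%: pathological "
                                 "sigmoid parameters")
        accepted.append(np.concatenate(got)[:per])
    sizes = np.concatenate(accepted)[:n_samples]
    gof = lognormal_gof(sizes, n_bins=n_bins)
    return {"sizes": sizes, "zetas": zetas, **gof}
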