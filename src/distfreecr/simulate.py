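"""Seeded samplers for the three bivariate study designs.

Design I  — bivariate normal with cross-correlation ``r_xy``.
Design II — bivariate noncentral F: each margin is exactly
            F(df1, df2, lambda); cross-dependence comes from a Gaussian
            copula whose latent correlation is solved numerically so the
            achieved Pearson correlation of the outputs matches ``r_xy``.
Design III — equal-proportion (by default) mixture of two bivariate
            normals with distinct means.

All samplers draw through an ``(n, 2)`` matrix of standard-normal
innovations, so the AR(1) variant (serially dependent replicates, e.g. MCMC
draws) plugs into any design by coloring those innovations while preserving
the stationary marginal variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import optimize, stats

from .geometry import GeometryError, PointSet

__all__ = [
    "SimDesign",
    "sample_bvn",
    "sample_bvf",
    "sample_mixture",
    "sample_ar1",
    "sample",
]

_DESIGNS = ("normal", "noncentral_F", "normal_mixture")

# design-specific parameter defaults (paper-style study settings)
_NORMAL_DEFAULTS: dict[str, Any] = {
    "mean": (0.0, 0.0),
    "sigma": (1.0, 1.0),
}
_NCF_DEFAULTS: dict[str, Any] = {"df1": 5.0, "df2": 10.0, "ncp": 3.0}
_MIXTURE_DEFAULTS: dict[str, Any] = {
    "mean1": (0.0, 0.0),
    "mean2": (4.0, 4.0),
    "sigma": (1.0, 1.0),
    "weight": 0.5,
}


@dataclass(frozen=True)
class SimDesign:
    """Configuration of one simulated bivariate sampling design.

    Parameters
    ----------
    design
        One of ``"normal"``, ``"noncentral_F"``, ``"normal_mixture"``.
    n
        Sample size.
    r_xy
        Target cross-correlation between the two margins, ``|r_xy| < 1``.
    seed
        RNG seed; identical designs produce bit-identical samples.
    params
        Design-specific overrides (``mean``/``sigma`` for normal;
        ``df1``/``df2``/``ncp`` for noncentral F; ``mean1``/``mean2``/
        ``sigma``/``weight`` for the mixture).
    """

    design: str
    n: int
    r_xy: float = 0.0
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise GeometryError(f"unknown design {self.design!r}; use {_DESIGNS}")
        if self.n < 1:
            raise GeometryError("n must be >= 1")
        if not abs(self.r_xy) < 1.0:
            raise GeometryError("|r_xy| must be < 1")
        p = self.params
        if self.design == "noncentral_F":
            merged = {**_NCF_DEFAULTS, **p}
            if merged["df1"] <= 0 or merged["df2"] <= 0:
                raise GeometryError("degrees of freedom must be positive")
            if merged["ncp"] < 0:
                raise GeometryError("noncentrality must be >= 0")
        if self.design == "normal_mixture":
            w = {**_MIXTURE_DEFAULTS, **p}["weight"]
            if not (0.0 < w < 1.0):
                raise GeometryError("mixing weight must lie in (0, 1)")

    def resolved_params(self) -> dict[str, Any]:
        base = {
            "normal": _NORMAL_DEFAULTS,
            "noncentral_F": _NCF_DEFAULTS,
            "normal_mixture": _MIXTURE_DEFAULTS,
        }[self.design]
        return {**base, **self.params}


def _corr_cholesky(r: float) -> np.ndarray:
    """Cholesky factor of the 2x2 correlation matrix [[1, r], [r, 1]]."""
    return np.array([[1.0, 0.0], [r, np.sqrt(1.0 - r * r)]])


def _innovations(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) iid standard-normal driving noise."""
    return rng.standard_normal((design.n, 2))


def _ar1_color(z: np.ndarray, phi: float) -> np.ndarray:
    """Turn iid N(0,1) columns into stationary AR(1) columns, same variance.

    z_t = phi z_{t-1} + sqrt(1 - phi^2) e_t with z_0 = e_0, so phi = 0
    returns the input unchanged (same draws for the same seed).
    """
    if phi == 0.0:
        return z
    out = np.empty_like(z)
    out[0] = z[0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, z.shape[0]):
        out[t] = phi * out[t - 1] + c * z[t]
    return out


def _bvn_from_innovations(design: SimDesign, z: np.ndarray) -> PointSet:
    p = design.resolved_params()
    sx, sy = p["sigma"]
    if sx <= 0 or sy <= 0:
        raise GeometryError("marginal standard deviations must be positive")
    L = _corr_cholesky(design.r_xy)
    corr = z @ L.T
    pts = corr * np.array([sx, sy]) + np.asarray(p["mean"], float)
    return PointSet(pts)


def sample_bvn(design: SimDesign) -> PointSet:
    """Draw n iid points from a bivariate normal (design I)."""
    if design.design != "normal":
        raise GeometryError("sample_bvn requires design='normal'")
    rng = np.random.default_rng(design.seed)
    return _bvn_from_innovations(design, _innovations(design, rng))


def _ncf_ppf_interpolant(df1: float, df2: float, ncp: float):
    """Monotone interpolant of z -> ncf.ppf(Phi(z)) on a fine z-grid.

    Used only inside the latent-correlation solver, where the transform is
    evaluated at many quadrature nodes; sampling itself uses the exact ppf.
    """
    zg = np.linspace(-8.0, 8.0, 3001)
    hg = stats.ncf.ppf(stats.norm.cdf(zg), df1, df2, ncp)
    return lambda z: np.interp(z, zg, hg)


def _solve_latent_corr(design: SimDesign) -> float:
    """Latent Gaussian-copula correlation giving output Pearson corr r_xy.

    The output correlation as a function of the latent correlation rho is
    estimated by Gauss–Hermite quadrature of E[h(z1) h(z2)] with
    h = F^{-1} o Phi, and inverted with Brent's method.
    """
    r_target = design.r_xy
    if r_target == 0.0:
        return 0.0
    p = design.resolved_params()
    h = _ncf_ppf_interpolant(p["df1"], p["df2"], p["ncp"])
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / np.sqrt(2.0 * np.pi)
    hz = h(nodes)
    mu = float(w @ hz)
    var = float(w @ (hz - mu) ** 2)

    def out_corr(rho: float) -> float:
        # z2 | z1 = rho z1 + sqrt(1-rho^2) w2
        z2 = rho * nodes[:, None] + np.sqrt(1.0 - rho * rho) * nodes[None, :]
        e_cross = float(w @ (hz * (h(z2) @ w)))
        return (e_cross - mu * mu) / var

    lo, hi = -0.9999, 0.9999
    c_lo, c_hi = out_corr(lo), out_corr(hi)
    if not (c_lo <= r_target <= c_hi):
        raise GeometryError(
            f"r_xy={r_target} unattainable for F({p['df1']}, {p['df2']}, "
            f"{p['ncp']}) margins; feasible range is [{c_lo:.3f}, {c_hi:.3f}]"
        )
    return float(optimize.brentq(lambda r: out_corr(r) - r_target, lo, hi,
                                 xtol=1e-6))


def sample_bvf(design: SimDesign) -> PointSet:
    """Draw n points with exact noncentral-F margins (design II).

    Each margin is F(df1, df2, ncp) via the exact ``scipy.stats.ncf``
    inverse CDF applied to Gaussian-copula uniforms; the latent correlation
    is solved so the output Pearson correlation approximates ``r_xy``.
    """
    if design.design != "noncentral_F":
        raise GeometryError("sample_bvf requires design='noncentral_F'")
    p = design.resolved_params()
    rho = _solve_latent_corr(design)
    rng = np.random.default_rng(design.seed)
    z = _innovations(design, rng) @ _corr_cholesky(rho).T
    u = stats.norm.cdf(z)
    pts = stats.ncf.ppf(u, p["df1"], p["df2"], p["ncp"])
    return PointSet(pts)


def sample_mixture(design: SimDesign) -> PointSet:
    """Draw n points from a two-component bivariate-normal mixture (design III)."""
    if design.design != "normal_mixture":
        raise GeometryError("sample_mixture requires design='normal_mixture'")
    p = design.resolved_params()
    rng = np.random.default_rng(design.seed)
    comp = rng.random(design.n) < p["weight"]  # True -> component 1
    z = _innovations(design, rng)
    sx, sy = p["sigma"]
    if sx <= 0 or sy <= 0:
        raise GeometryError("marginal standard deviations must be positive")
    corr = z @ _corr_cholesky(design.r_xy).T * np.array([sx, sy])
    means = np.where(
        comp[:, None], np.asarray(p["mean1"], float), np.asarray(p["mean2"], float)
    )
    return PointSet(corr + means)


def sample(design: SimDesign) -> PointSet:
    """Dispatch to the sampler matching ``design.design``."""
    fn = {
        "normal": sample_bvn,
        "noncentral_F": sample_bvf,
        "normal_mixture": sample_mixture,
    }[design.design]
    return fn(design)


def sample_ar1(design: SimDesign, phi: float) -> PointSet:
    """Sample any design with AR(1) serial dependence in the driving noise.

    The iid standard-normal innovations of the base sampler are replaced by
    stationary AR(1) series with lag-1 coefficient ``phi`` and unit
    variance, so marginal distributions are preserved while consecutive
    draws become dependent (emulating, e.g., autocorrelated resampling
    chains).  ``phi = 0`` reproduces the base sampler draw-for-draw.
    """
    if not abs(phi) < 1.0:
        raise GeometryError("|phi| must be < 1")
    rng = np.random.default_rng(design.seed)
    if design.design == "normal":
        z = _ar1_color(_innovations(design, rng), phi)
        return _bvn_from_innovations(design, z)
    if design.design == "noncentral_F":
        p = design.resolved_params()
        rho = _solve_latent_corr(design)
        z = _ar1_color(_innovations(design, rng), phi) @ _corr_cholesky(rho).T
        u = stats.norm.cdf(z)
        return PointSet(stats.ncf.ppf(u, p["df1"], p["df2"], p["ncp"]))
    # normal_mixture: color the component-normal noise, keep iid labels
    p = design.resolved_params()
    comp = rng.random(design.n) < p["weight"]
    z = _ar1_color(_innovations(design, rng), phi)
    sx, sy = p["sigma"]
    corr = z @ _corr_cholesky(design.r_xy).T * np.array([sx, sy])
    means = np.where(
        comp[:, None], np.asarray(p["mean1"], float), np.asarray(p["mean2"], float)
    )
    return PointSet(corr + means)


def with_seed(design: SimDesign, seed: int) -> SimDesign:
    """Copy of ``design`` with a different seed."""
    return replace(design, seed=seed)
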