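"""Coverage-discrepancy studies, the chi-square coverage test, and a
bootstrap utility for turning paired estimates into a point cloud.

The adequacy metric throughout is the *realized* significance level — the
in-sample proportion of points falling outside a constructed region — and
its *discrepancy* from the nominal level.  A coverage-discrepancy study
sweeps designs, methods and nominal levels, recording one row per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .baselines import convex_hull_peeling_region, ellipse_region
from .calibration import calibrate, realized_alpha
from .geometry import DirectionGrid, GeometryError, PointSet
from .simulate import SimDesign, sample

__all__ = [
    "CoverageRecord",
    "coverage_discrepancy",
    "chisq_coverage_test",
    "bootstrap_pairs",
    "DEFAULT_ALPHA_GRID",
]

# the standard seven-level significance grid of the simulation study
DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.005, 0.01, 0.025, 0.05, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class CoverageRecord:
    """One cell of a coverage study: a (design, replicate, method, alpha)."""

    design: str
    n: int
    r_xy: float
    method: str
    alpha_nominal: float
    alpha_realized: float
    replicate: int
    seed: int
    error: str | None = None

    @property
    def discrepancy(self) -> float:
        return self.alpha_realized - self.alpha_nominal


def _region_for(method: str, pts: PointSet, alpha: float, K: int):
    if method == "distfree":
        return calibrate(pts, alpha, grid=DirectionGrid.equally_spaced(K)).region
    if method == "ellipse":
        return ellipse_region(pts, alpha)
    if method == "peel":
        return convex_hull_peeling_region(pts, alpha)
    raise GeometryError(f"unknown method {method!r}")


def coverage_discrepancy(
    designs: Iterable[SimDesign],
    methods: Sequence[str] = ("distfree", "ellipse", "peel"),
    alphas: Sequence[float] = DEFAULT_ALPHA_GRID,
    reps: int = 3,
    K: int = 72,
) -> pd.DataFrame:
    """Run a coverage-discrepancy study over a grid of conditions.

    For every (design, replicate, method, nominal alpha): draw a fresh
    sample (the replicate index is folded into the design seed, so the grid
    is fully re-runnable), build the region, and record the realized level
    and its discrepancy.  A method failure on one cell is recorded in the
    ``error`` column and does not abort the grid.

    Returns
    -------
    pandas.DataFrame
        Long format, one :class:`CoverageRecord` per row.
    """
    if reps < 1:
        raise GeometryError("reps must be >= 1")
    if any(not (0.0 < a < 1.0) for a in alphas):
        raise GeometryError("all alphas must lie in (0, 1)")
    rows: list[CoverageRecord] = []
    for design in designs:
        for rep in range(reps):
            seed = int((design.seed + 7919 * rep) % (2**31 - 1))
            pts = sample(replace(design, seed=seed))
            for method in methods:
                for alpha in alphas:
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            region = _region_for(method, pts, alpha, K)
                        ra = realized_alpha(pts, region)
                        err = None
                    except Exception as exc:  # recorded, not fatal
                        ra, err = np.nan, f"{type(exc).__name__}: {exc}"
                    rows.append(
                        CoverageRecord(
                            design=design.design,
                            n=design.n,
                            r_xy=design.r_xy,
                            method=method,
                            alpha_nominal=float(alpha),
                            alpha_realized=ra,
                            replicate=rep,
                            seed=seed,
                            error=err,
                        )
                    )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["discrepancy"] = df["alpha_realized"] - df["alpha_nominal"]
    return df


def chisq_coverage_test(
    m_outside: int, n: int, alpha0: float
) -> tuple[float, float]:
    """One-df chi-square goodness-of-fit test of a realized coverage rate.

    Compares the observed (outside, inside) counts with the expected
    ``(n * alpha0, n * (1 - alpha0))`` under the nominal level:

        X^2 = sum (observed - expected)^2 / expected

    over the two cells; the p-value is the chi-square(1) upper tail.  No
    continuity correction is applied.

    Returns
    -------
    (statistic, p_value)
    """
    if n <= 0:
        raise GeometryError("n must be positive")
    if not (0 <= m_outside <= n):
        raise GeometryError("m_outside must lie in [0, n]")
    if not (0.0 < alpha0 < 1.0):
        raise GeometryError("alpha0 must lie in (0, 1)")
    expected = np.array([n * alpha0, n * (1.0 - alpha0)])
    observed = np.array([m_outside, n - m_outside], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    p = float(chi2.sf(stat, df=1))
    return stat, p


def bootstrap_pairs(
    data: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], tuple[float, float]],
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> PointSet:
    """Bootstrap a cloud of paired estimates from a data table.

    Draws ``B`` case resamples (rows with replacement, original size),
    evaluates ``statistic`` — any callable mapping a resampled table to a
    pair of real numbers, e.g. two regression coefficients — on each, and
    returns the pairs as a :class:`PointSet` ready for
    :func:`distfreecr.confidence_region`.  A resample on which the
    statistic raises or returns non-finite values is redrawn (the redraw
    count is reported in a warning).

    Notes
    -----
    ``B`` must be at least 100: the region quantiles are meaningless on a
    thinner cloud.
    """
    if B < 100:
        raise GeometryError("B must be >= 100 for a usable point cloud")
    rng = np.random.default_rng(seed)
    n = len(data)
    out = np.empty((B, 2))
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                sx, sy = statistic(data.iloc[idx])
            except Exception:
                redraws += 1
                continue
            if np.isfinite(sx) and np.isfinite(sy):
                out[b] = (sx, sy)
                break
            redraws += 1
        else:
            raise GeometryError(
                f"statistic failed on {max_redraws} consecutive resamples"
            )
    if redraws:
        warnings.warn(f"{redraws} resample(s) redrawn", UserWarning, stacklevel=2)
    return PointSet(out)
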