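"""Posterior-draw inference: conditional survival, annual change, breakpoints.

All inference operates directly on posterior curve draws: the conditional
5/1-year survival is the per-draw ratio of the 5-year and 1-year model
draws; annual-change (first-derivative) and curvature (second-derivative)
curves are central finite differences applied to every draw; "plausible"
trends and breakpoints are read off the pointwise 95% credible intervals of
those derivative draws.

Definitions
-----------
plausible trend segment
    A maximal run of consecutive grid years over which the 95% CrI of the
    first derivative stays on one side of zero, lasting at least 5 years.
breakpoint
    Within a maximal run of at least 3 years where the 95% CrI of the
    second derivative excludes zero, the year with the largest magnitude
    of the median second derivative (ties to the earliest year); positive
    curvature is an acceleration, negative a deceleration.

The boundary grid years consumed by central differencing are excluded from
segment/breakpoint eligibility (no one-sided differences at the edges).
"At least 5 years" / "3 years" count consecutive annual grid points by
default; ``run_units="span"`` switches to the year-span reading (a run of
k points spans k - 1 years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trend import PosteriorCurves


@dataclass
class DerivativeSummary:
    """Pointwise posterior summary of d^order(survival)/d(year)^order."""

    order: int
    grid: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    draws: np.ndarray   # (n_draws, len(grid)) raw derivative draws
    measure: str = ""

    @property
    def units(self) -> str:
        return "% per year" if self.order == 1 else "% per year^2"


@dataclass
class TrendSegment:
    """Interval of credibly monotone change in a survival measure."""

    start_year: float
    end_year: float
    sign: str            # "increasing" | "decreasing"
    measure: str = ""


@dataclass
class Breakpoint:
    """Year where the trend's annual change itself changes credibly."""

    year: float
    direction: str       # "acceleration" | "deceleration"
    interval: tuple[float, float]
    peak_second_derivative: float
    measure: str = ""


def conditional_draws(
    pc5: PosteriorCurves, pc1: PosteriorCurves
) -> PosteriorCurves:
    """Conditional 5/1-year survival draws: 100 * pc5 / pc1, paired by index.

    Draw i of the 5-year model is divided by draw i of the 1-year model, so
    the ratio's posterior propagates the uncertainty of both fits. The two
    posteriors are independent, so index pairing is a convention;
    ``repair_random`` in :func:`repaired_conditional_draws` verifies
    insensitivity.
    """
    if not np.array_equal(pc5.grid, pc1.grid):
        raise ValueError("grids of the two models differ")
    if pc5.n_draws != pc1.n_draws:
        raise ValueError("draw counts differ")
    if np.any(pc1.draws <= 0):
        raise ValueError(
            "1-year survival draws must be positive for the ratio"
        )
    ratio = 100.0 * pc5.draws / pc1.draws
    return PosteriorCurves(
        grid=pc5.grid.copy(), draws=ratio, measure="5/1-year",
        meta={"from": [pc5.measure, pc1.measure]},
    )


def repaired_conditional_draws(
    pc5: PosteriorCurves, pc1: PosteriorCurves, seed: int = 0
) -> PosteriorCurves:
    """Conditional draws with the 1-year draws randomly re-paired."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pc1.n_draws)
    shuffled = PosteriorCurves(grid=pc1.grid.copy(),
                               draws=pc1.draws[perm], measure=pc1.measure)
    return conditional_draws(pc5, shuffled)


def derivative_draws(pc: PosteriorCurves, order: int) -> DerivativeSummary:
    """Central finite differences of every draw (annual step).

    Exact for polynomial draws up to the difference order: linear draws give
    their slope everywhere (order 1), quadratics give twice their leading
    coefficient (order 2). One boundary year is lost on each side.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if pc.grid.size < order + 2:
        raise ValueError("grid too short for this derivative order")
    c = pc.draws
    if order == 1:
        d = 0.5 * (c[:, 2:] - c[:, :-2])
    else:
        d = c[:, 2:] - 2.0 * c[:, 1:-1] + c[:, :-2]
    grid = pc.grid[1:-1]
    lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5], axis=0)
    return DerivativeSummary(order=order, grid=grid, median=med,
                             ci_low=lo, ci_high=hi, draws=d,
                             measure=pc.measure)


def _credible_runs(ds: DerivativeSummary, min_points: int,
                   run_units: str) -> list[tuple[int, int, int]]:
    """Maximal same-signed runs where the 95% CrI excludes zero.

    Returns (start_idx, end_idx inclusive, sign) triples meeting the length
    rule: >= min_points grid points, or a span of >= min_points years when
    ``run_units == "span"``.
    """
    sign = np.where(ds.ci_low > 0, 1, np.where(ds.ci_high < 0, -1, 0))
    runs = []
    i = 0
    n = sign.size
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        length = j - i + 1 if run_units == "points" else ds.grid[j] - ds.grid[i]
        if length >= min_points:
            runs.append((i, j, int(sign[i])))
        i = j + 1
    return runs


def classify_plausible_trend(
    d1: DerivativeSummary,
    min_years: int = 5,
    run_units: str = "points",
) -> list[TrendSegment]:
    """Segments where the annual change is credibly nonzero for >= 5 years."""
    if d1.order != 1:
        raise ValueError("expects first-derivative draws")
    segs = []
    for i, j, sgn in _credible_runs(d1, min_years, run_units):
        segs.append(
            TrendSegment(
                start_year=float(d1.grid[i]), end_year=float(d1.grid[j]),
                sign="increasing" if sgn > 0 else "decreasing",
                measure=d1.measure,
            )
        )
    return segs


def detect_breakpoints(
    d2: DerivativeSummary,
    min_years: int = 3,
    run_units: str = "points",
) -> list[Breakpoint]:
    """Peak-curvature years within sustained credibly-curved intervals."""
    if d2.order != 2:
        raise ValueError("expects second-derivative draws")
    out = []
    for i, j, sgn in _credible_runs(d2, min_years, run_units):
        seg_med = d2.median[i:j + 1]
        k = i + int(np.argmax(np.abs(seg_med)))  # argmax takes earliest tie
        out.append(
            Breakpoint(
                year=float(d2.grid[k]),
                direction="acceleration" if sgn > 0 else "deceleration",
                interval=(float(d2.grid[i]), float(d2.grid[j])),
                peak_second_derivative=float(d2.median[k]),
                measure=d2.measure,
            )
        )
    return out
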