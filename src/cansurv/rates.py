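"""Age-standardized incidence/mortality rates and smoothed rate curves.

Registry rate tables carry, per calendar year and 5-year age group, event
counts and person-years. This module computes the world-standard
age-standardized rate (ASR, per 100,000 person-years), the cumulative risk
of the event before age 75, and a cubic smoothing spline for plotting rate
time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

# Segi world standard population, 5-year groups 0-4 ... 80-84, 85+
SEGI_WEIGHTS = (
    12000, 10000, 9000, 9000, 8000, 8000, 6000, 6000, 6000,
    6000, 5000, 4000, 4000, 3000, 2000, 1000, 500, 500,
)
SEGI_BOUNDARIES = tuple(5 * i for i in range(18)) + (np.inf,)


@dataclass
class StandardPopulation:
    """Age-group weights of a standard population (world standard default)."""

    boundaries: tuple = SEGI_BOUNDARIES
    weights: tuple = SEGI_WEIGHTS

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        if len(self.boundaries) != w.size + 1:
            raise ValueError("need one more boundary than weights")
        self._w = w / w.sum()

    @property
    def normalized(self) -> np.ndarray:
        return self._w

    @property
    def n_groups(self) -> int:
        return self._w.size


@dataclass
class RateSeries:
    """Counts and person-years per age group for one (population, year).

    ``counts[g]`` events observed in age group g; ``person_years[g] > 0``.
    Age groups follow ``std`` boundaries (5-year groups by default).
    """

    counts: np.ndarray
    person_years: np.ndarray
    year: int = 0
    country: str = "XX"
    sex: str = "all"
    site: str = ""
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.person_years <= 0):
            raise ValueError("person_years must be positive")
        if self.counts.shape != self.person_years.shape:
            raise ValueError("counts and person_years must align")

    @property
    def rates(self) -> np.ndarray:
        """Age-group-specific rates per person-year."""
        return self.counts / self.person_years


def asr(rs: RateSeries, std: StandardPopulation | None = None) -> float:
    """Age-standardized rate per 100,000 person-years (world standard)."""
    std = std or StandardPopulation()
    if rs.counts.size != std.n_groups:
        raise ValueError(
            f"rate series has {rs.counts.size} groups, standard population "
            f"{std.n_groups}"
        )
    return float(np.sum(std.normalized * rs.rates) * 1e5)


def cumulative_risk(rs: RateSeries, age_cap: int = 74,
                    group_width: float = 5.0) -> float:
    """Cumulative risk (%) of the event before ``age_cap + 1`` years.

    Assumes the series' groups are consecutive ``group_width``-year bands
    starting at age 0; with the default 5-year bands and cap 74, the first
    15 groups enter: 100 * (1 - exp(-5 * sum of their rates)).
    """
    if (age_cap + 1) % group_width != 0:
        raise ValueError("age_cap + 1 must be a multiple of the group width")
    k = int((age_cap + 1) // group_width)
    if rs.counts.size < k:
        raise ValueError("series does not cover ages through the cap")
    return float(100.0 * (1.0 - np.exp(-group_width * np.sum(rs.rates[:k]))))


# -- cubic smoothing spline ------------------------------------------------


def spar_to_lambda(spar: float, x, n_knots: int = 12) -> float:
    """Monotone map from a [0, 1] smoothness parameter to the penalty lambda.

    Uses the ratio convention lambda = r * 256^(3*spar - 1) with
    r = tr(B'B) / tr(Omega), so spar is comparable across rescalings of x.
    """
    B, Om, _ = _spline_system(np.asarray(x, dtype=float), n_knots)
    r = np.trace(B.T @ B) / max(np.trace(Om), 1e-300)
    return float(r * 256.0 ** (3.0 * spar - 1.0))


def _knot_vector(x: np.ndarray, n_knots: int) -> np.ndarray:
    xu = np.unique(x)
    if n_knots >= xu.size:
        inner = xu
    else:
        qs = np.linspace(0, 1, n_knots)
        inner = np.quantile(xu, qs)
        inner = np.unique(inner)
    return np.concatenate([[inner[0]] * 3, inner, [inner[-1]] * 3])


def _spline_system(x: np.ndarray, n_knots: int):
    """Cubic B-spline design matrix and exact second-derivative penalty."""
    t = _knot_vector(x, n_knots)
    nb = t.size - 4
    eye = np.eye(nb)
    B = np.empty((x.size, nb))
    for j in range(nb):
        B[:, j] = BSpline(t, eye[j], 3)(x)
    # Omega_ij = int B_i'' B_j'' : second derivatives are piecewise linear,
    # so 2-point Gauss-Legendre per inter-knot interval is exact
    uniq = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    Om = np.zeros((nb, nb))
    d2 = [BSpline(t, eye[j], 3).derivative(2) for j in range(nb)]
    for a, b in zip(uniq[:-1], uniq[1:]):
        half = 0.5 * (b - a)
        pts = 0.5 * (a + b) + half * gauss
        vals = np.array([f(pts) for f in d2])          # (nb, 2)
        Om += half * (vals @ vals.T)
    return B, Om, t


@dataclass
class SmoothCurve:
    """Fitted cubic smoothing spline."""

    spline: BSpline
    lam: float
    n_knots: int

    def __call__(self, x):
        return self.spline(np.asarray(x, dtype=float))


def cubic_smoothing_spline(
    x, y, penalty: float, n_knots: int = 12
) -> SmoothCurve:
    """Penalized cubic spline: minimize sum (y - f(x))^2 + lambda int f''^2.

    ``penalty`` is lambda >= 0; use :func:`spar_to_lambda` for the [0, 1]
    smoothness parameterization. At lambda -> 0 with knots at every data
    point the fit interpolates; at lambda -> infinity it converges to the
    least-squares straight line (the penalty's null space). The solution is
    linear in y at fixed lambda.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct x values")
    B, Om, t = _spline_system(x, n_knots)
    # normal equations in the penalty eigenbasis: the exact null space of
    # Omega (straight lines) is never penalized, so the fit converges to the
    # least-squares line as penalty -> infinity without conditioning issues
    w, V = np.linalg.eigh(Om)
    null = w < w.max() * 1e-12
    BV = B @ V
    A = BV.T @ BV
    A[~null, ~null] += penalty * w[~null]
    rhs = BV.T @ y
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        # singular data term (more basis functions than points at small
        # penalty): minimum-norm solution
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    coef = V @ sol
    return SmoothCurve(spline=BSpline(t, coef, 3), lam=float(penalty),
                       n_knots=n_knots)


# -- rate table I/O (Table-1-style layout) ---------------------------------

RATE_COLUMNS = ["year", "sex", "country", "site", "age_group", "cases",
                "person_years"]


def read_rate_table(path, std: StandardPopulation | None = None
                    ) -> list[RateSeries]:
    """Read a long rate CSV into one RateSeries per (country, sex, site, year).

    ``age_group`` is the lower bound of each 5-year band (0, 5, ..., 85).
    """
    std = std or StandardPopulation()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rate CSV missing columns: {missing}")
    lower = np.asarray(std.boundaries[:-1], dtype=float)
    out = []
    keys = ["country", "sex", "site", "year"]
    for (country, sex, site, year), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("age_group")
        if not np.array_equal(grp["age_group"].to_numpy(dtype=float), lower):
            raise ValueError(
                f"{country}/{sex}/{site}/{year}: age groups must match the "
                "standard population bands"
            )
        out.append(
            RateSeries(counts=grp["cases"].to_numpy(dtype=float),
                       person_years=grp["person_years"].to_numpy(dtype=float),
                       year=int(year), country=str(country), sex=str(sex),
                       site=str(site))
        )
    return out


def rate_summary_table(series: list[RateSeries],
                       std: StandardPopulation | None = None) -> pd.DataFrame:
    """ASR and cumulative-risk summary, one row per rate series."""
    std = std or StandardPopulation()
    rows = [
        {
            "country": rs.country, "sex": rs.sex, "site": rs.site,
            "year": rs.year, "cases": float(rs.counts.sum()),
            "asr_per_100k": asr(rs, std),
            "cum_risk_0_74_pct": cumulative_risk(rs),
        }
        for rs in series
    ]
    return pd.DataFrame(rows)
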