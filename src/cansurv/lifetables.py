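"""Background-population life tables.

A life table gives, for one sex and country, the annual survival probability
``p(age, year)`` — the probability that a person of integer ``age`` alive at
the start of calendar ``year`` survives that year — for ages 0–109 and a span
of calendar years. Everything downstream (expected survival of a cancer
patient, Pohar Perme weighting, background death simulation) consumes the
table through the attained-age / calendar-year *diagonal*: a patient
diagnosed at age ``a`` at continuous date ``d`` experiences the hazard of
cell ``(floor(a + t), floor(d + t))`` at time ``t`` since diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_MAX = 109


@dataclass
class LifeTable:
    """Annual background survival probabilities for one sex and country.

    Parameters
    ----------
    sex : str
        Population label, e.g. ``"male"`` / ``"female"``.
    country : str
        Population label, e.g. ``"SE"``.
    years : ndarray of int
        Consecutive calendar years covered by the table.
    surv : ndarray, shape (110, n_years)
        ``surv[age, j]`` is the annual survival probability in ``(0, 1]`` for
        integer ``age`` during calendar year ``years[j]``.
    """

    sex: str
    country: str
    years: np.ndarray
    surv: np.ndarray
    _hazard: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.surv.shape != (AGE_MAX + 1, self.years.size):
            raise ValueError(
                f"surv must have shape ({AGE_MAX + 1}, {self.years.size}), "
                f"got {self.surv.shape}"
            )
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        if np.any(self.surv <= 0) or np.any(self.surv > 1):
            raise ValueError("annual survival probabilities must lie in (0, 1]")
        # annual hazard of the (age, year) cell; p = exp(-h) exactly
        self._hazard = -np.log(self.surv)

    @property
    def year_start(self) -> int:
        return int(self.years[0])

    @property
    def year_end(self) -> int:
        """First calendar year *not* covered."""
        return int(self.years[-1]) + 1

    def annual_surv(self, age: int, year: int) -> float:
        """Annual survival probability of cell ``(age, year)``."""
        return float(self.surv[self._cell(age, year)])

    def hazard(self, age: int, year: int) -> float:
        """Constant hazard rate (per year) of cell ``(age, year)``."""
        return float(self._hazard[self._cell(age, year)])

    def _cell(self, age: int, year: int) -> tuple[int, int]:
        age = int(age)
        year = int(year)
        if not 0 <= age <= AGE_MAX:
            raise ValueError(f"age {age} outside table domain 0..{AGE_MAX}")
        j = year - self.year_start
        if not 0 <= j < self.years.size:
            raise ValueError(
                f"calendar year {year} outside table span "
                f"[{self.year_start}, {self.year_end})"
            )
        return age, j

    # -- diagonal traversal ------------------------------------------------

    def diagonal(
        self, age_at_diagnosis: float, diagnosis_date: float, t_max: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Piecewise-constant hazard along the attained-age/calendar diagonal.

        Returns ``(knots, cumhaz, rates)`` where ``knots`` are times since
        diagnosis ``0 = t_0 < ... < t_K = t_max`` at which the occupied table
        cell changes, ``rates[k]`` is the hazard on ``(t_k, t_{k+1}]`` and
        ``cumhaz[k]`` the cumulative hazard at ``t_k`` (``cumhaz[0] = 0``).
        The cumulative hazard is continuous piecewise linear, so the expected
        survival ``exp(-cumhaz)`` raises partial-year annual factors to the
        fractional power.
        """
        if t_max < 0:
            raise ValueError("t_max must be nonnegative")
        if age_at_diagnosis < 0:
            raise ValueError("age_at_diagnosis must be nonnegative")
        # times where attained age or calendar year crosses an integer
        cuts = set()
        for x0 in (age_at_diagnosis, diagnosis_date):
            first = math.floor(x0) + 1 - x0
            k = first
            while k < t_max:
                cuts.add(k)
                k += 1.0
        knots = np.array(sorted({0.0, t_max} | cuts))
        rates = np.empty(knots.size - 1)
        for k in range(knots.size - 1):
            mid = 0.5 * (knots[k] + knots[k + 1])
            age = min(math.floor(age_at_diagnosis + mid), AGE_MAX)
            year = math.floor(diagnosis_date + mid)
            rates[k] = self._hazard[self._cell(age, year)]
        cumhaz = np.concatenate([[0.0], np.cumsum(rates * np.diff(knots))])
        return knots, cumhaz, rates

    def cumulative_hazard(
        self, age_at_diagnosis: float, diagnosis_date: float, t: float
    ) -> float:
        """Population cumulative hazard from diagnosis to time ``t``."""
        if t == 0:
            return 0.0
        knots, cumhaz, _ = self.diagonal(age_at_diagnosis, diagnosis_date, t)
        return float(cumhaz[-1])


def make_life_table(
    makeham_lambda: float = 5e-4,
    gompertz_a: float = 2e-5,
    gompertz_b: float = 0.095,
    calendar_drift: float = 0.0,
    sex: str = "all",
    country: str = "XX",
    years: tuple[int, int] = (1960, 2022),
) -> LifeTable:
    """Build a Gompertz–Makeham life table with optional calendar improvement.

    The age-specific hazard is ``h(u) = lambda + a * exp(b * u)``; the annual
    cell probability integrates the hazard over the year of age exactly,
    ``p(age, year) = exp(-drift_factor * int_age^{age+1} h(u) du)``, with
    ``drift_factor = exp(-calendar_drift * (year - years[0]))`` so a positive
    drift means mortality improves over calendar time.

    Parameters are per-year hazard scales and must be nonnegative
    (``gompertz_b`` strictly positive when ``gompertz_a > 0``).
    """
    if makeham_lambda < 0 or gompertz_a < 0:
        raise ValueError("hazard parameters must be nonnegative")
    if gompertz_a > 0 and gompertz_b <= 0:
        raise ValueError("gompertz_b must be positive when gompertz_a > 0")
    yr = np.arange(years[0], years[1] + 1)
    ages = np.arange(AGE_MAX + 1)
    # exact integral of the hazard over one year of age
    if gompertz_a > 0:
        gomp = gompertz_a / gompertz_b * (
            np.exp(gompertz_b * (ages + 1)) - np.exp(gompertz_b * ages)
        )
    else:
        gomp = np.zeros_like(ages, dtype=float)
    h_age = makeham_lambda + gomp
    drift = np.exp(-calendar_drift * (yr - yr[0]))
    cell_haz = h_age[:, None] * drift[None, :]
    return LifeTable(sex=sex, country=country, years=yr, surv=np.exp(-cell_haz))


def unit_life_table(
    sex: str = "all", country: str = "XX", years: tuple[int, int] = (1960, 2022)
) -> LifeTable:
    """Life table with no background mortality (p = 1 everywhere)."""
    return make_life_table(0.0, 0.0, 0.1, sex=sex, country=country, years=years)


# -- CSV round-trip (HMD-like long format) ---------------------------------

LIFE_TABLE_COLUMNS = ["country", "sex", "age", "year", "surv_prob"]


def write_life_table(lt: LifeTable, path) -> None:
    """Write one life table as long CSV: country, sex, age, year, surv_prob."""
    ages = np.arange(AGE_MAX + 1)
    df = pd.DataFrame(
        {
            "country": lt.country,
            "sex": lt.sex,
            "age": np.repeat(ages, lt.years.size),
            "year": np.tile(lt.years, ages.size),
            "surv_prob": lt.surv.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_life_table(path) -> list[LifeTable]:
    """Read life tables from CSV; one `LifeTable` per (country, sex) stratum."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LIFE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"life-table CSV missing columns: {missing}")
    out = []
    for (country, sex), grp in df.groupby(["country", "sex"], sort=True):
        years = np.sort(grp["year"].unique())
        ages = np.sort(grp["age"].unique())
        if not np.array_equal(ages, np.arange(AGE_MAX + 1)):
            raise ValueError(
                f"life table for {country}/{sex} must cover ages 0..{AGE_MAX}"
            )
        piv = grp.pivot_table(index="age", columns="year", values="surv_prob")
        piv = piv.reindex(index=ages, columns=years)
        if piv.isna().any().any():
            raise ValueError(f"life table for {country}/{sex} has missing cells")
        out.append(
            LifeTable(sex=str(sex), country=str(country), years=years,
                      surv=piv.to_numpy())
        )
    return out
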