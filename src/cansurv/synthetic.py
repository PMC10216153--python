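"""Synthetic cancer-registry cohorts and aggregated survival series.

Registry microdata behind published Nordic survival statistics are not
public, so this module generates individual-level cohorts and per-period
survival series with *known* ground truth. Cohorts combine a background
mortality draw from a life table (along the attained-age/calendar diagonal)
with an excess (cancer) hazard from one of three families — constant,
piecewise-constant, or cure-mixture — all of which have closed-form net
survival, enabling exact recovery tests. Aggregated series emulate the
structure of database exports such as NORDCAN: one relative-survival
estimate in percent per 5-year diagnosis period, 1971–2020.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .lifetables import LifeTable


@dataclass
class IndividualRecord:
    """One patient's diagnosis and follow-up.

    ``follow_up_time`` is years from diagnosis to death or censoring;
    ``event`` is ``"death"`` or ``"censored"``. ``true_net_event`` is
    simulation bookkeeping: True when the death was caused by the excess
    (cancer) hazard rather than background mortality.
    """

    id: int
    sex: str
    country: str
    age_at_diagnosis: float
    diagnosis_date: float
    follow_up_time: float
    event: str
    true_net_event: bool = False

    def __post_init__(self) -> None:
        if self.follow_up_time < 0:
            raise ValueError("follow_up_time must be nonnegative")
        if not 0 <= self.age_at_diagnosis <= 89:
            raise ValueError("age_at_diagnosis must lie in [0, 89]")
        if self.event not in ("death", "censored"):
            raise ValueError(f"invalid event {self.event!r}")


@dataclass
class ExcessHazard:
    """Excess-hazard model: constant, piecewise-constant, or cure-mixture.

    * constant: rate ``lam`` for all t; net survival exp(-lam t).
    * piecewise: rates on [0, cut_1), [cut_1, cut_2), ... (len(rates) =
      len(cuts)+1); net survival from the piecewise-linear cumulative hazard.
    * cure: fraction ``cure_pi`` is never subject to excess mortality, the
      rest has constant rate ``lam``; net survival pi + (1-pi) exp(-lam t).
    """

    kind: Literal["constant", "piecewise", "cure"] = "constant"
    lam: float = 0.0
    cuts: tuple[float, ...] = ()
    rates: tuple[float, ...] = ()
    cure_pi: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if self.lam < 0:
                raise ValueError("excess rate must be nonnegative")
        elif self.kind == "piecewise":
            if len(self.rates) != len(self.cuts) + 1:
                raise ValueError("need len(rates) == len(cuts) + 1")
            if any(r < 0 for r in self.rates):
                raise ValueError("excess rates must be nonnegative")
            if list(self.cuts) != sorted(self.cuts):
                raise ValueError("cuts must be sorted")
        elif self.kind == "cure":
            if not 0 <= self.cure_pi <= 1:
                raise ValueError("cure fraction must lie in [0, 1]")
            if self.lam < 0:
                raise ValueError("excess rate must be nonnegative")
        else:
            raise ValueError(f"unknown excess-hazard kind {self.kind!r}")

    def net_survival(self, t: float) -> float:
        """True net survival S_E(t) in [0, 1] (closed form)."""
        if self.kind == "constant":
            return float(np.exp(-self.lam * t))
        if self.kind == "cure":
            return float(self.cure_pi + (1 - self.cure_pi) * np.exp(-self.lam * t))
        edges = np.concatenate([[0.0], np.asarray(self.cuts), [np.inf]])
        dt = np.clip(t - edges[:-1], 0.0, edges[1:] - edges[:-1])
        return float(np.exp(-np.sum(np.asarray(self.rates) * dt)))

    def draw_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n excess-death times (np.inf where no excess death occurs)."""
        if self.kind == "constant":
            if self.lam == 0:
                return np.full(n, np.inf)
            return rng.exponential(1.0 / self.lam, size=n)
        if self.kind == "cure":
            t = np.full(n, np.inf)
            sick = rng.random(n) >= self.cure_pi
            if self.lam > 0:
                t[sick] = rng.exponential(1.0 / self.lam, size=int(sick.sum()))
            return t
        # piecewise: invert the piecewise-linear cumulative hazard
        edges = np.concatenate([[0.0], np.asarray(self.cuts)])
        rates = np.asarray(self.rates)
        widths = np.diff(np.concatenate([edges, [np.inf]]))
        chunks = rates * widths  # last is inf if last rate > 0
        cum = np.concatenate([[0.0], np.cumsum(chunks[:-1])])
        e = rng.exponential(size=n)
        t = np.full(n, np.inf)
        for j in range(rates.size):
            hi = cum[j] + chunks[j]
            sel = (e >= cum[j]) & (e < hi) if np.isfinite(hi) else (e >= cum[j])
            if rates[j] > 0:
                t[sel] = edges[j] + (e[sel] - cum[j]) / rates[j]
        return t


@dataclass
class CohortSpec:
    """Accrual plan for one simulated cohort.

    Ages are drawn from a normal truncated to [0, 89]; diagnosis dates are
    uniform over ``period`` (half-open ``[start, end)``); emigration is an
    independent exponential censoring cause; everyone still at risk is
    administratively censored at ``cutoff`` (calendar time, e.g. 2021.0 for
    follow-up through the end of 2020).
    """

    n_patients: int = 1000
    period: tuple[float, float] = (2011.0, 2016.0)
    age_mean: float = 65.0
    age_sd: float = 12.0
    excess: ExcessHazard = field(default_factory=ExcessHazard)
    emigration_rate: float = 0.005
    cutoff: float = 2021.0
    sex: str = "all"
    country: str = "XX"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.period[1] <= self.period[0]:
            raise ValueError("period must be a nonempty half-open interval")
        if self.emigration_rate < 0:
            raise ValueError("emigration_rate must be nonnegative")


def _background_death_time(
    lt: LifeTable, age: float, date: float, t_max: float, e: float
) -> float:
    """Invert the diagonal cumulative hazard at exponential draw ``e``.

    Returns np.inf when the cumulative hazard through ``t_max`` never
    reaches ``e`` (no background death before the horizon).
    """
    knots, cumhaz, rates = lt.diagonal(age, date, t_max)
    if e >= cumhaz[-1]:
        return np.inf
    k = int(np.searchsorted(cumhaz, e, side="right") - 1)
    return float(knots[k] + (e - cumhaz[k]) / rates[k])


def simulate_cohort(spec: CohortSpec, lt: LifeTable) -> list[IndividualRecord]:
    """Simulate one registry cohort.

    Observed time is the minimum of background death, excess death,
    emigration, and the administrative cutoff; the record is a death when
    either death cause fires first. Deterministic under ``spec.seed``.
    """
    if spec.period[0] < lt.year_start or spec.cutoff > lt.year_end:
        raise ValueError(
            f"cohort span [{spec.period[0]}, {spec.cutoff}] outside life-table "
            f"span [{lt.year_start}, {lt.year_end})"
        )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    a, b = (0 - spec.age_mean) / spec.age_sd, (89 - spec.age_mean) / spec.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )
    dates = rng.uniform(spec.period[0], spec.period[1], size=n)
    t_admin = spec.cutoff - dates
    e_bg = rng.exponential(size=n)
    t_excess = spec.excess.draw_times(n, rng)
    if spec.emigration_rate > 0:
        t_emig = rng.exponential(1.0 / spec.emigration_rate, size=n)
    else:
        t_emig = np.full(n, np.inf)

    records = []
    for i in range(n):
        t_bg = _background_death_time(lt, ages[i], dates[i], t_admin[i], e_bg[i])
        t_death = min(t_bg, t_excess[i])
        t_cens = min(t_emig[i], t_admin[i])
        if t_death <= t_cens:
            t_obs, event = t_death, "death"
            net = t_excess[i] <= t_bg
        else:
            t_obs, event = t_cens, "censored"
            net = False
        records.append(
            IndividualRecord(
                id=i,
                sex=spec.sex,
                country=spec.country,
                age_at_diagnosis=float(ages[i]),
                diagnosis_date=float(dates[i]),
                follow_up_time=float(t_obs),
                event=event,
                true_net_event=bool(net),
            )
        )
    return records


# -- aggregated trend scenarios --------------------------------------------

PERIODS_1971_2020: tuple[tuple[int, int], ...] = tuple(
    (y, y + 5) for y in range(1971, 2020, 5)
)


def sigmoid_truth(
    low: float = 25.0,
    high: float = 75.0,
    center: float = 1995.0,
    width: float = 10.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth survival trend rising from ``low`` to ``high`` percent."""

    def f(year):
        year = np.asarray(year, dtype=float)
        return low + (high - low) / (1.0 + np.exp(-(year - center) / width))

    return f


def piecewise_linear_truth(
    start_value: float = 30.0,
    slopes: Sequence[float] = (0.4, 1.6),
    changepoints: Sequence[float] = (2000.0,),
    start_year: float = 1971.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear trend with known slope changes ("waves").

    Defaults follow the historical scale of Nordic kidney-cancer survival:
    ~30% in the early 1970s, slow gains before 2000, rapid gains after.
    """
    if len(slopes) != len(changepoints) + 1:
        raise ValueError("need len(slopes) == len(changepoints) + 1")
    cps = np.concatenate([[start_year], np.asarray(changepoints, dtype=float)])

    def f(year):
        year = np.asarray(year, dtype=float)
        out = np.full(year.shape, start_value, dtype=float)
        for j, s in enumerate(slopes):
            seg_start = cps[j]
            seg_end = cps[j + 1] if j + 1 < cps.size else np.inf
            out += s * np.clip(year - seg_start, 0.0, seg_end - seg_start)
        return out

    return f


@dataclass
class TrendScenario:
    """Ground truth + noise model for one aggregated survival series."""

    truth: Callable[[np.ndarray], np.ndarray]
    se: float = 1.5
    periods: tuple[tuple[int, int], ...] = PERIODS_1971_2020
    seed: int = 0
    country: str = "XX"
    sex: str = "all"
    site: str = "kidney"
    measure: str = "5-year"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("observation SE must be nonnegative")

    @property
    def midpoints(self) -> np.ndarray:
        # half-open [start, end): midpoint of 1971-1976 coded [1971,1976) is
        # 1973.5; the conventional label for diagnosis years 1971-1975 is 1973
        return np.array([0.5 * (a + b - 1) for a, b in self.periods])


def simulate_survival_series(scenario: TrendScenario):
    """Aggregated per-period estimates: truth(midpoint) + N(0, SE^2) noise.

    Returns a :class:`cansurv.relsurv.SurvivalSeries` whose points carry the
    Gaussian standard error as their variance, plus the noise-free truth in
    ``series.meta["truth"]`` for recovery tests.
    """
    from .relsurv import SurvivalEstimate, SurvivalSeries  # cycle guard

    rng = np.random.default_rng(scenario.seed)
    mids = scenario.midpoints
    truth = np.asarray(scenario.truth(mids), dtype=float)
    est = truth + rng.normal(0.0, scenario.se, size=mids.size)
    z = 1.959963984540054
    points = []
    for (period, m, e) in zip(scenario.periods, mids, est):
        se = scenario.se
        points.append(
            SurvivalEstimate(
                estimate=float(e),
                variance=float(se**2),
                ci=(float(e - z * se), float(e + z * se)),
                n_contributing=0,
                period=(float(period[0]), float(period[1])),
                midpoint=float(m),
                mode="cohort",
            )
        )
    return SurvivalSeries(
        country=scenario.country,
        sex=scenario.sex,
        site=scenario.site,
        measure=scenario.measure,
        points=points,
        meta={"truth": truth, "seed": scenario.seed, "se": scenario.se},
    )
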