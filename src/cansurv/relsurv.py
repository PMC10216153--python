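"""Age-standardized relative (net) survival via the Pohar Perme estimator.

Net survival is the survival patients would experience if their cancer were
the only cause of death. The Pohar Perme estimator removes the bias of
informative background mortality by weighting each individual's at-risk and
event contributions by the inverse of their expected survival — the survival
probability a demographically matched member of the general population would
have, accumulated from a life table along the attained-age / calendar-year
diagonal.

The estimator here is the product-limit (product-integral) form: discrete
weighted event factors combined with a continuous background-hazard
correction,

    S_net(t) = prod_{s_k <= t} (1 - dN~(s_k) / Y~(s_k))
               * exp( int_0^t sum_i Y_i(s) w_i(s) dLambda_Pi(s) / Y~(s) ),

with w_i(s) = 1 / S_Pi(s), Y~(s) = sum_i Y_i(s) w_i(s) and dN~ the weighted
death counts. Under a life table with no background mortality all weights
are 1 and the population integral vanishes, so the estimator coincides
exactly with Kaplan–Meier. The continuous integral is discretized on a
partition refined to ``max_step`` years, with weights and population hazards
evaluated at subinterval midpoints; the variance is the Poisson-type
estimator sum w_i^2 dN_i / Y~^2 on the cumulative-excess-hazard scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lifetables import LifeTable
from .synthetic import IndividualRecord

Z95 = 1.959963984540054


@dataclass
class SurvivalEstimate:
    """One relative-survival point estimate on the percent scale.

    Relative survival may exceed 100% (patients out-surviving the matched
    general population); no clipping is applied.
    """

    estimate: float
    variance: float
    ci: tuple[float, float]
    n_contributing: int
    period: tuple[float, float] | None = None
    midpoint: float | None = None
    mode: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_contributing < 0:
            raise ValueError("n_contributing must be nonnegative")


@dataclass
class SurvivalSeries:
    """Per-period estimates for one (country, sex, site, measure) stratum."""

    country: str
    sex: str
    site: str
    measure: str
    points: list[SurvivalEstimate]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        periods = [p.period for p in self.points]
        if any(p is None for p in periods):
            raise ValueError("every point needs a period")
        for (a0, b0), (a1, b1) in zip(periods, periods[1:]):
            if a1 < b0:
                raise ValueError("periods must be disjoint and chronological")

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([p.midpoint for p in self.points], dtype=float)

    @property
    def estimates(self) -> np.ndarray:
        return np.array([p.estimate for p in self.points], dtype=float)


@dataclass
class AgeGroupWeights:
    """External standardization weights over an age-group partition of [0, 90).

    Default is an ICSS-like stand-in (the canonical external weights are
    published by IARC and configurable here): groups [0,45), [45,55),
    [55,65), [65,75), [75,90) with weights 0.07/0.12/0.23/0.29/0.29.
    """

    boundaries: tuple[float, ...] = (0.0, 45.0, 55.0, 65.0, 75.0, 90.0)
    weights: tuple[float, ...] = (0.07, 0.12, 0.23, 0.29, 0.29)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        w = np.asarray(self.weights)
        if w.size != b.size - 1:
            raise ValueError("need one weight per age group")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        if b[0] != 0.0 or b[-1] != 90.0:
            raise ValueError("groups must partition [0, 90)")

    @property
    def n_groups(self) -> int:
        return len(self.weights)

    def group_of(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(np.asarray(self.boundaries), ages, side="right") - 1
        if np.any((ages < 0) | (ages >= 90)):
            raise ValueError("ages outside [0, 90)")
        return np.minimum(idx, self.n_groups - 1)


# -- expected survival -----------------------------------------------------


def expected_survival(
    record: IndividualRecord, lt: LifeTable, t: float
) -> float:
    """Expected (background population) survival of one patient at time t.

    The product of annual life-table survival probabilities along the
    patient's attained-age/calendar diagonal from diagnosis to ``t``, with
    partial years entering as fractional powers.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    return float(
        np.exp(-lt.cumulative_hazard(record.age_at_diagnosis,
                                     record.diagnosis_date, t))
    )


# -- analysis datasets -----------------------------------------------------


@dataclass
class PeriodDataset:
    """Risk intervals for one period analysis.

    Each row is one patient contribution: at risk on ``(entry, exit]`` years
    since diagnosis, with ``event[i]`` True when the exit is a death. Cohort
    datasets have ``entry == 0``; hybrid datasets are left-truncated at the
    calendar start of the final window.
    """

    age: np.ndarray
    date: np.ndarray
    entry: np.ndarray
    exit: np.ndarray
    event: np.ndarray
    mode: str = "cohort"

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.date = np.asarray(self.date, dtype=float)
        self.entry = np.asarray(self.entry, dtype=float)
        self.exit = np.asarray(self.exit, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if np.any(self.exit <= self.entry):
            raise ValueError("exit must exceed entry for every contribution")

    @property
    def n(self) -> int:
        return self.age.size

    def subset(self, mask) -> "PeriodDataset":
        return PeriodDataset(self.age[mask], self.date[mask], self.entry[mask],
                             self.exit[mask], self.event[mask], self.mode)


def records_to_dataset(records: list[IndividualRecord]) -> PeriodDataset:
    """Full-cohort dataset: at risk from diagnosis to end of follow-up."""
    keep = [r for r in records if r.follow_up_time > 0]
    return PeriodDataset(
        age=np.array([r.age_at_diagnosis for r in keep]),
        date=np.array([r.diagnosis_date for r in keep]),
        entry=np.zeros(len(keep)),
        exit=np.array([r.follow_up_time for r in keep]),
        event=np.array([r.event == "death" for r in keep]),
    )


def build_period_dataset(
    records: list[IndividualRecord],
    period: tuple[float, float],
    mode: str = "cohort",
    horizon: float = 5.0,
    analysis_start: float | None = None,
) -> PeriodDataset:
    """Select and window the patients contributing to one period estimate.

    cohort mode
        Patients diagnosed within ``[start, end)``, followed from diagnosis
        to ``min(horizon, observed follow-up)``.
    hybrid mode
        Period + cohort construction for the final window: every patient
        whose person-time intersects the calendar window contributes, with
        diagnoses from the penultimate 5-year period supplying the
        follow-up years the final period cannot. Contributions are
        left-truncated at calendar window entry (a patient diagnosed two
        years before the window enters the risk set at two years since
        diagnosis) and end at min(follow-up, horizon, window end).
    """
    if horizon not in (1.0, 5.0, 1, 5):
        raise ValueError("horizon must be 1 or 5 years")
    start, end = float(period[0]), float(period[1])
    if end <= start:
        raise ValueError("period must be half-open [start, end) with end > start")
    if mode == "cohort":
        sel = [r for r in records if start <= r.diagnosis_date < end]
        exit_ = np.array([min(r.follow_up_time, horizon) for r in sel])
        event = np.array(
            [r.event == "death" and r.follow_up_time <= horizon for r in sel]
        )
        keep = exit_ > 0
        return PeriodDataset(
            age=np.array([r.age_at_diagnosis for r in sel])[keep],
            date=np.array([r.diagnosis_date for r in sel])[keep],
            entry=np.zeros(len(sel))[keep],
            exit=exit_[keep],
            event=event[keep],
            mode="cohort",
        )
    if mode != "hybrid":
        raise ValueError(f"unknown mode {mode!r}")
    window = end - start
    if analysis_start is not None and start - window < analysis_start:
        raise ValueError(
            "hybrid analysis needs a penultimate period before the window"
        )
    sel = [r for r in records if start - window <= r.diagnosis_date < end]
    age, date, entry, exit_, event = [], [], [], [], []
    for r in sel:
        e0 = max(0.0, start - r.diagnosis_date)
        e1 = min(r.follow_up_time, float(horizon), end - r.diagnosis_date)
        if e1 <= e0:
            continue
        age.append(r.age_at_diagnosis)
        date.append(r.diagnosis_date)
        entry.append(e0)
        exit_.append(e1)
        event.append(r.event == "death" and r.follow_up_time <= e1)
    return PeriodDataset(np.array(age), np.array(date), np.array(entry),
                         np.array(exit_), np.array(event), mode="hybrid")


# -- Pohar Perme -----------------------------------------------------------


@dataclass
class PoharPermeResult:
    """Net-survival curve on the probability scale with Poisson-type variance."""

    times: np.ndarray
    survival: np.ndarray          # may exceed 1; NaN where undefined
    sigma2: np.ndarray            # variance of the cumulative excess hazard
    n_contributing: int
    undefined_after: float | None = None

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        """95% CI, log-cumulative-hazard scale: S * exp(-/+ 1.96 sigma)."""
        s = np.sqrt(self.sigma2)
        return self.survival * np.exp(-Z95 * s), self.survival * np.exp(Z95 * s)

    def at(self, t: float, period=None, midpoint=None,
           mode: str = "cohort") -> SurvivalEstimate:
        """Percent-scale estimate at one evaluation time."""
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t):
            raise ValueError(f"t={t} was not an evaluation time")
        s, v = self.survival[i], self.sigma2[i]
        lo, hi = self.ci
        return SurvivalEstimate(
            estimate=100.0 * s,
            variance=(100.0 * s) ** 2 * v,
            ci=(100.0 * lo[i], 100.0 * hi[i]),
            n_contributing=self.n_contributing,
            period=period, midpoint=midpoint, mode=mode,
        )


def _refine(points: np.ndarray, max_step: float) -> np.ndarray:
    out = [np.array([points[0]])]
    for a, b in zip(points[:-1], points[1:]):
        m = max(1, int(np.ceil((b - a) / max_step)))
        out.append(np.linspace(a, b, m + 1)[1:])
    return np.concatenate(out)


def pohar_perme(
    data,
    lt: LifeTable,
    eval_times,
    max_step: float = 0.2,
) -> PoharPermeResult:
    """Pohar Perme net-survival estimator (product-limit form).

    Parameters
    ----------
    data : list of IndividualRecord or PeriodDataset
        Risk intervals; records are taken at risk from diagnosis.
    lt : LifeTable
        Background mortality for the expected-survival weights.
    eval_times : array-like
        Sorted nonnegative times (years since diagnosis) to report.
    max_step : float
        Maximum discretization step (years) for the population-hazard
        integral; weights are evaluated at subinterval midpoints.
    """
    ds = data if isinstance(data, PeriodDataset) else records_to_dataset(data)
    if ds.n == 0:
        raise ValueError("no contributing records")
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.size == 0 or np.any(eval_times < 0):
        raise ValueError("eval_times must be nonnegative")
    if np.any(np.diff(eval_times) < 0):
        raise ValueError("eval_times must be sorted")
    t_max = float(eval_times[-1])

    entry = ds.entry
    exit_ = ds.exit
    cap = np.minimum(exit_, t_max)

    # per-individual population cumulative hazard along the diagonal
    knots, cumhaz, rates = [], [], []
    for i in range(ds.n):
        kn, ch, rt = lt.diagonal(ds.age[i], ds.date[i], float(exit_[i]))
        knots.append(kn)
        cumhaz.append(ch)
        rates.append(rt)
    total_ch = np.array([c[-1] for c in cumhaz])

    base = np.unique(np.concatenate(
        [[0.0, t_max], eval_times, entry[entry < t_max], cap]))
    s = _refine(base, max_step)           # partition points, s[0] = 0
    K = s.size - 1                        # intervals I_k = (s[k], s[k+1]]
    mid = 0.5 * (s[:-1] + s[1:])
    dt = np.diff(s)

    Yw = np.zeros(K)      # sum of weights at interval right endpoints
    Ymid = np.zeros(K)    # sum of weights at interval midpoints
    pop = np.zeros(K)     # weighted population-hazard mass per interval
    dN = np.zeros(K)      # weighted deaths at right endpoints
    dN2 = np.zeros(K)     # squared-weight deaths (variance)

    # individual i is at risk on intervals I_k for k in [ia_i, ib_i);
    # s[ia_i] == entry_i, s[ib_i] == cap_i, death counted in interval ib_i - 1
    ia = np.searchsorted(s, np.minimum(entry, t_max), side="left")
    ib = np.searchsorted(s, cap, side="right") - 1
    death_here = ds.event & (exit_ <= t_max + 1e-12)

    trivial = total_ch == 0.0   # unit expected survival: w = 1, lambda = 0
    idx_triv = np.flatnonzero(trivial)
    if idx_triv.size:
        # algebraically identical constant-weight path, O(1) per individual
        add = np.zeros(K + 1)
        for i in idx_triv:
            if ib[i] <= ia[i]:
                continue
            add[ia[i]] += 1.0
            add[ib[i]] -= 1.0
            if death_here[i]:
                dN[ib[i] - 1] += 1.0
                dN2[ib[i] - 1] += 1.0
        run = np.cumsum(add)[:K]
        Yw += run
        Ymid += run
    for i in np.flatnonzero(~trivial):
        if ib[i] <= ia[i]:
            continue
        kk = np.arange(ia[i], ib[i])
        w_right = np.exp(np.interp(s[kk + 1], knots[i], cumhaz[i]))
        w_mid = np.exp(np.interp(mid[kk], knots[i], cumhaz[i]))
        lam = rates[i][
            np.clip(np.searchsorted(knots[i], mid[kk], side="right") - 1,
                    0, rates[i].size - 1)
        ]
        Yw[kk] += w_right
        Ymid[kk] += w_mid
        pop[kk] += w_mid * lam * dt[kk]
        if death_here[i]:
            w_end = w_right[-1]
            dN[ib[i] - 1] += w_end
            dN2[ib[i] - 1] += w_end**2

    with np.errstate(invalid="ignore", divide="ignore"):
        dLamO = np.where(Yw > 0, dN / Yw, 0.0)
        dLamP = np.where(Ymid > 0, pop / Ymid, 0.0)
        dVar = np.where(Yw > 0, dN2 / Yw**2, 0.0)

    surv_path = np.cumprod(1.0 - dLamO) * np.exp(np.cumsum(dLamP))
    sig2_path = np.cumsum(dVar)

    # beyond the last exit the curve is defined only if that exit is a death
    if np.any(exit_ > t_max):
        undefined_after = None
    else:
        last_exit = float(np.max(cap))
        last_is_death = bool(np.any(death_here & np.isclose(cap, last_exit)))
        undefined_after = None if last_is_death else last_exit

    surv = np.empty(eval_times.size)
    sig2 = np.empty(eval_times.size)
    for j, t in enumerate(eval_times):
        if undefined_after is not None and t > undefined_after + 1e-12:
            surv[j] = np.nan
            sig2[j] = np.nan
            continue
        if t == 0:
            surv[j] = 1.0
            sig2[j] = 0.0
        else:
            k = int(np.searchsorted(s, t))   # eval times are partition points
            surv[j] = surv_path[k - 1]
            sig2[j] = sig2_path[k - 1]
    if np.any(np.isnan(surv)):
        warnings.warn(
            "risk set exhausted before some evaluation times; "
            "estimates there are undefined (NaN)",
            RuntimeWarning, stacklevel=2,
        )
    return PoharPermeResult(
        times=eval_times, survival=surv, sigma2=sig2,
        n_contributing=ds.n, undefined_after=undefined_after,
    )


# -- standardization and conditional survival ------------------------------


def age_standardize(
    per_group: dict, w: AgeGroupWeights
) -> SurvivalEstimate:
    """Externally weighted combination of age-group-specific estimates.

    ``per_group`` maps group index (0..n_groups-1) to a SurvivalEstimate or
    None for an empty group. Empty groups are dropped and the remaining
    weights renormalized, with a recorded warning.
    """
    weights = np.asarray(w.weights, dtype=float)
    present = [
        g for g in range(w.n_groups)
        if per_group.get(g) is not None
        and per_group[g].n_contributing > 0
        and np.isfinite(per_group[g].estimate)
    ]
    if not present:
        raise ValueError("all age groups empty")
    if len(present) < w.n_groups:
        warnings.warn(
            f"{w.n_groups - len(present)} empty age group(s) dropped; "
            "weights renormalized", RuntimeWarning, stacklevel=2,
        )
    wk = weights[present]
    wk = wk / wk.sum()
    est = float(sum(wi * per_group[g].estimate for wi, g in zip(wk, present)))
    var = float(sum(wi**2 * per_group[g].variance for wi, g in zip(wk, present)))
    n = int(sum(per_group[g].n_contributing for g in present))
    half = Z95 * np.sqrt(var)
    ref = per_group[present[0]]
    return SurvivalEstimate(
        estimate=est, variance=var, ci=(est - half, est + half),
        n_contributing=n, period=ref.period, midpoint=ref.midpoint,
        mode=ref.mode,
    )


def age_standardized_estimate(
    ds: PeriodDataset,
    lt: LifeTable,
    horizon: float,
    weights: AgeGroupWeights | None = None,
    max_step: float = 0.2,
    period=None,
    midpoint=None,
) -> SurvivalEstimate:
    """Pohar Perme within each age group, then external-weight combination."""
    w = weights or AgeGroupWeights()
    groups = w.group_of(ds.age)
    per_group: dict[int, SurvivalEstimate | None] = {}
    for g in range(w.n_groups):
        sub = ds.subset(groups == g)
        if sub.n == 0:
            per_group[g] = None
            continue
        res = pohar_perme(sub, lt, [horizon], max_step=max_step)
        per_group[g] = res.at(horizon, period=period, midpoint=midpoint,
                              mode=ds.mode)
    return age_standardize(per_group, w)


def conditional_ratio(
    s5: SurvivalEstimate, s1: SurvivalEstimate
) -> SurvivalEstimate:
    """Conditional 5/1-year survival: 100 * S(5)/S(1), delta-method variance."""
    if s1.estimate <= 0:
        raise ValueError("1-year survival must be positive")
    r = 100.0 * s5.estimate / s1.estimate
    var = r**2 * (
        s5.variance / s5.estimate**2 + s1.variance / s1.estimate**2
    ) if s5.estimate != 0 else 0.0
    half = Z95 * np.sqrt(var)
    return SurvivalEstimate(
        estimate=r, variance=var, ci=(r - half, r + half),
        n_contributing=min(s5.n_contributing, s1.n_contributing),
        period=s5.period, midpoint=s5.midpoint, mode=s5.mode,
    )
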