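"""Independent brute-force net-survival oracle for small cohorts.

Implements the same estimator definition as ``cansurv.relsurv.pohar_perme``
— product-limit weighted event factors plus a midpoint-discretized
population-hazard integral — but by direct enumeration with plain Python
loops, computing each individual's expected survival from raw life-table
lookups (fractional-power annual factors) rather than through the package's
diagonal machinery. Deliberately slow and simple.
"""

from __future__ import annotations

import math


def expected_surv_naive(lt, age0: float, date0: float, t: float) -> float:
    """Expected survival by stepping year fractions one at a time."""
    if t <= 0:
        return 1.0
    surv = 1.0
    u = 0.0
    while u < t - 1e-12:
        age = min(math.floor(age0 + u), 109)
        year = math.floor(date0 + u)
        # next boundary: age change, calendar change, or t
        nxt = min(
            math.floor(age0 + u) + 1 - age0,
            math.floor(date0 + u) + 1 - date0,
            t,
        )
        frac = nxt - u
        surv *= lt.annual_surv(age, year) ** frac
        u = nxt
    return surv


def pop_hazard_naive(lt, age0: float, date0: float, t: float) -> float:
    age = min(math.floor(age0 + t), 109)
    year = math.floor(date0 + t)
    return -math.log(lt.annual_surv(age, year))


def pohar_perme_naive(ds, lt, eval_times, max_step: float = 0.2):
    """Direct-enumeration Pohar Perme estimate at each evaluation time."""
    t_max = float(eval_times[-1])
    base = {0.0, t_max}
    base.update(float(t) for t in eval_times)
    for i in range(ds.n):
        if ds.entry[i] < t_max:
            base.add(float(ds.entry[i]))
        base.add(float(min(ds.exit[i], t_max)))
    pts = sorted(base)
    part = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        m = max(1, math.ceil((b - a) / max_step))
        for j in range(1, m + 1):
            part.append(a + (b - a) * j / m)

    results = []
    for t_eval in eval_times:
        prod = 1.0
        pop_int = 0.0
        var = 0.0
        for k in range(1, len(part)):
            lo_t, hi_t = part[k - 1], part[k]
            if hi_t > t_eval + 1e-12:
                break
            mid_t = 0.5 * (lo_t + hi_t)
            Y_hi = 0.0
            Y_mid = 0.0
            pop_num = 0.0
            dN = 0.0
            dN2 = 0.0
            for i in range(ds.n):
                cap = min(ds.exit[i], t_max)
                if not (ds.entry[i] <= lo_t + 1e-12 and cap >= hi_t - 1e-12):
                    continue
                w_hi = 1.0 / expected_surv_naive(lt, ds.age[i], ds.date[i],
                                                 hi_t)
                w_mid = 1.0 / expected_surv_naive(lt, ds.age[i], ds.date[i],
                                                  mid_t)
                Y_hi += w_hi
                Y_mid += w_mid
                pop_num += w_mid * pop_hazard_naive(lt, ds.age[i], ds.date[i],
                                                    mid_t) * (hi_t - lo_t)
                if (ds.event[i] and ds.exit[i] <= t_max + 1e-12
                        and abs(cap - hi_t) < 1e-12):
                    dN += w_hi
                    dN2 += w_hi**2
            if Y_hi > 0:
                prod *= 1.0 - dN / Y_hi
                var += dN2 / Y_hi**2
            if Y_mid > 0:
                pop_int += pop_num / Y_mid
        results.append((prod * math.exp(pop_int), var))
    return results
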