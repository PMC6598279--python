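"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: plain Python loops over
definitions, so they can arbitrate the vectorized/compiled implementations.
"""

import numpy as np


def logrank_oracle(tl, sl, tr, sr):
    """Two-group log-rank statistic (O-E)^2/V by direct evaluation of the
    O, E, V sums over the pooled distinct event times."""
    pooled = sorted(
        [(t, s, "L") for t, s in zip(tl, sl)] + [(t, s, "R") for t, s in zip(tr, sr)]
    )
    event_times = sorted({t for t, s, _ in pooled if s == 1})
    O = E = V = 0.0
    for tk in event_times:
        at_risk = [(t, s, g) for t, s, g in pooled if t >= tk]
        nk = len(at_risk)
        nkl = sum(1 for t, s, g in at_risk if g == "L")
        dk = sum(1 for t, s, g in at_risk if t == tk and s == 1)
        dkl = sum(1 for t, s, g in at_risk if t == tk and s == 1 and g == "L")
        O += dkl
        E += dk * nkl / nk
        V += dk * (nkl / nk) * (1 - nkl / nk) * (nk - dk) / max(nk - 1, 1)
    if V == 0:
        return None
    return (O - E) ** 2 / V


def harrell_oracle(risk, time, status):
    """Harrell's C by exhaustive O(n^2) pair enumeration with the standard
    tie rules (equal times + both events: 1/2; equal times + one event:
    event treated as earlier; tied risks: 1/2)."""
    comparable = 0.0
    concordant = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, si, sj = time[i], time[j], status[i], status[j]
            ri, rj = risk[i], risk[j]
            if ti == tj:
                if si == 1 and sj == 1:
                    comparable += 1
                    concordant += 0.5
                elif si == 1 or sj == 1:
                    comparable += 1
                    hi, lo = (ri, rj) if si == 1 else (rj, ri)
                    concordant += 1.0 if hi > lo else (0.5 if hi == lo else 0.0)
            else:
                if ti < tj:
                    short_s, hi, lo = si, ri, rj
                else:
                    short_s, hi, lo = sj, rj, ri
                if short_s == 1:
                    comparable += 1
                    concordant += 1.0 if hi > lo else (0.5 if hi == lo else 0.0)
    if comparable == 0:
        return None
    return concordant / comparable


def nelson_aalen_oracle(time, status, grid):
    """Pooled Nelson-Aalen estimate at each grid point, from the definition."""
    out = np.zeros(len(grid))
    for g, t in enumerate(grid):
        H = 0.0
        for tk in sorted(set(np.asarray(time)[np.asarray(status) == 1])):
            if tk <= t:
                d = int(((time == tk) & (status == 1)).sum())
                n_at_risk = int((time >= tk).sum())
                H += d / n_at_risk
        out[g] = H
    return out
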