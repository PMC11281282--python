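"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorised code paths: plain
Python loops and textbook formulas only.
"""

import numpy as np
from scipy import stats as sps


def fcm_oracle_objective(x, c, m, seed, iters=500):
    """One randomly initialised alternating-optimisation FCM run; returns J."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    v = rng.choice(np.unique(x), size=c, replace=False).astype(float)

    def memberships(v):
        u = np.zeros((len(x), c))
        for i, xi in enumerate(x):
            d = np.abs(xi - v)
            if np.any(d == 0):
                u[i, int(np.argmin(d))] = 1.0
            else:
                for k in range(c):
                    u[i, k] = 1.0 / np.sum((d[k] / d) ** (2.0 / (m - 1.0)))
        return u

    for _ in range(iters):
        u = memberships(v)
        v_new = np.array(
            [np.sum(u[:, k] ** m * x) / np.sum(u[:, k] ** m) for k in range(c)]
        )
        if np.max(np.abs(v_new - v)) < 1e-12:
            v = v_new
            break
        v = v_new
    u = memberships(v)
    return float(sum(u[i, k] ** m * (x[i] - v[k]) ** 2 for i in range(len(x)) for k in range(c)))


def fcm_oracle_best(x, c=2, m=2.0, restarts=50):
    """Best objective over independently restarted brute-force FCM runs."""
    return min(fcm_oracle_objective(x, c, m, seed=s) for s in range(restarts))


def pooled_ttest_oracle(a, b):
    """Textbook pooled two-sample t-test computed long-hand.

    Returns (t, df, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss1 = sum((v - m1) ** 2 for v in a)
    ss2 = sum((v - m2) ** 2 for v in b)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def kaplan_meier_oracle(times, events):
    """Hand product-limit computation; returns {event_time: S(t)}."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= (at_risk - d) / at_risk
        out[float(t)] = s
    return out
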