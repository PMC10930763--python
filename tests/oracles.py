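"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity from first principles with explicit
enumeration (plain Python loops, no shared code with the package
implementation), so agreement is evidence of correctness rather than of
calling the same routine twice.
"""

import math

import numpy as np


def breslow_negloglik(times, events, scores):
    """Negative Breslow partial log-likelihood averaged over events, with
    risk sets {j : t_j >= t_i} enumerated explicitly."""
    times = list(map(float, times))
    events = list(map(int, events))
    scores = list(map(float, scores))
    n = len(times)
    total, n_events = 0.0, 0
    for i in range(n):
        if events[i] == 1:
            n_events += 1
            denom = math.fsum(
                math.exp(scores[j]) for j in range(n) if times[j] >= times[i]
            )
            total += scores[i] - math.log(denom)
    if n_events == 0:
        raise ValueError("no events")
    return -total / n_events


def harrell_c(times, events, risk):
    """Harrell's concordance by O(n^2) pair enumeration.

    A pair (i, j) is admissible when i had an event and either t_i < t_j,
    or t_i == t_j with j censored (j is then known to outlive i).  Two
    events at the same time are not orderable.  Ties in the risk score
    count one half; higher risk should pair with shorter survival.
    """
    n = len(times)
    num, den = 0.0, 0
    for i in range(n):
        for j in range(n):
            if i == j or events[i] != 1:
                continue
            if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no admissible pairs")
    return num / den


def logrank_statistic(times, events, groups):
    """Two-group log-rank chi-square from explicit observed/expected tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def km_curve(times, events):
    """Product-limit estimate by explicit risk-set counting."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def kmeans2_exhaustive(values):
    """Optimal 1-D two-cluster split by trying every threshold."""
    v = np.sort(np.asarray(values, float))
    best = (np.inf, None)
    for i in range(1, len(v)):
        if v[i] == v[i - 1]:
            continue
        lo, hi = v[:i], v[i:]
        wcss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if wcss < best[0]:
            best = (wcss, 0.5 * (lo.mean() + hi.mean()))
    return best[1]


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values from the direct formula."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def attention_eq1(h, V, w):
    """Scalar-by-scalar evaluation of the softmax attention definition."""
    K = len(h)
    raw = []
    for k in range(K):
        acc = 0.0
        for a in range(V.shape[0]):
            dot = 0.0
            for b in range(V.shape[1]):
                dot += V[a, b] * h[k][b]
            acc += w[a] * math.tanh(dot)
        raw.append(acc)
    denom = math.fsum(math.exp(r) for r in raw)
    return np.array([math.exp(r) / denom for r in raw])
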