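"""Independent straight-line oracles used by the tests.

Everything here is deliberately written from first principles — scalar
loops, explicit formulas, no calls into the package under test — so that
agreement between package and oracle is informative.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple


# --------------------------------------------------------------- HGF filter

def oracle_hgf_filter(choices: Sequence[int], outcomes: Sequence[int],
                      mu3_0: float, mu2_0=(0.0, 0.0, 0.0), sigma2_0: float = 1.0,
                      sigma3_0: float = 1.0, kappa: float = 1.0,
                      omega2: float = -0.5, omega3: float = -6.0,
                      phi: float = 0.1, m: float = 0.0) -> Dict[str, list]:
    """Scalar re-derivation of the three-level filter, one assignment per line."""
    m2 = [mu2_0[0], mu2_0[1], mu2_0[2]]
    s2 = [sigma2_0, sigma2_0, sigma2_0]
    m3 = mu3_0
    s3 = sigma3_0
    out = {"muhat1": [], "mu2": [], "sigma2": [], "mu3": [], "sigma3": [],
           "muhat3": [], "delta1": [], "resp_prob": []}
    for t in range(len(choices)):
        v2 = math.exp(kappa * m3 + omega2)
        m2hat = [m2[i] + phi * (m - m2[i]) for i in range(3)]
        s2hat = [s2[i] + v2 for i in range(3)]
        mh1 = [1.0 / (1.0 + math.exp(-m2hat[i])) for i in range(3)]
        m3hat = m3
        s3hat = s3 + math.exp(omega3)

        beta = math.exp(-m3hat)
        ex = [math.exp(beta * mh1[i]) for i in range(3)]
        tot = ex[0] + ex[1] + ex[2]
        out["resp_prob"].append([e / tot for e in ex])
        out["muhat1"].append(list(mh1))
        out["muhat3"].append(m3hat)

        c = choices[t] - 1
        d1 = outcomes[t] - mh1[c]
        out["delta1"].append(d1)

        s1hat = mh1[c] * (1.0 - mh1[c])
        s2new = 1.0 / (1.0 / s2hat[c] + s1hat)
        m2new = m2hat[c] + s2new * d1

        w2 = v2 / s2hat[c]
        d2 = (s2new + (m2new - m2hat[c]) ** 2) / s2hat[c] - 1.0
        pi3 = 1.0 / s3hat + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        assert pi3 > 0.0, "oracle: precision collapse"
        m3 = m3hat + 0.5 * kappa * w2 * d2 / pi3
        s3 = 1.0 / pi3

        m2 = list(m2hat)
        s2 = list(s2hat)
        m2[c] = m2new
        s2[c] = s2new
        out["mu2"].append(list(m2))
        out["sigma2"].append(list(s2))
        out["mu3"].append(m3)
        out["sigma3"].append(s3)
    return out


def oracle_neg_log_likelihood(choices, outcomes, **params) -> float:
    traj = oracle_hgf_filter(choices, outcomes, **params)
    return -sum(math.log(traj["resp_prob"][t][choices[t] - 1])
                for t in range(len(choices)))


# ----------------------------------------------------------- behavior rates

def oracle_rates(choices: Sequence[int], outcomes: Sequence[int]):
    """Exhaustive-count win-switch and lose-stay rates (None = undefined)."""
    win_n = win_d = lose_n = lose_d = 0
    for t in range(len(choices) - 1):
        if outcomes[t] == 1:
            win_d += 1
            if choices[t + 1] != choices[t]:
                win_n += 1
        else:
            lose_d += 1
            if choices[t + 1] == choices[t]:
                lose_n += 1
    ws = win_n / win_d if win_d else None
    ls = lose_n / lose_d if lose_d else None
    return ws, ls


# ------------------------------------------------------------ graph metrics

def oracle_density(n_alters: int, edges: Sequence[Tuple[int, int]]):
    if n_alters < 2:
        return None
    return len(set(map(frozenset, edges))) / (n_alters * (n_alters - 1) / 2)


def _adjacency(n_alters: int, edges):
    """Ego-inclusive adjacency; node 0 is the ego, alters are 1..n."""
    n = n_alters + 1
    a = [[0] * n for _ in range(n)]
    for i in range(1, n):
        a[0][i] = a[i][0] = 1
    for u, v in edges:
        a[u + 1][v + 1] = a[v + 1][u + 1] = 1
    return a


def oracle_centralization(n_alters: int, edges):
    if n_alters < 2:
        return None
    a = _adjacency(n_alters, edges)
    n = len(a)
    deg = [sum(row) for row in a]
    dmax = max(deg)
    return sum(dmax - d for d in deg) / ((n - 1) * (n - 2))


def oracle_constraint(n_alters: int, edges):
    """Burt's constraint of the ego (node 0) on the binary graph."""
    if n_alters < 1:
        return None
    a = _adjacency(n_alters, edges)
    n = len(a)

    def p(i, j):
        tot = sum(a[i])
        return a[i][j] / tot if tot else 0.0

    total = 0.0
    for j in range(n):
        if not a[0][j]:
            continue
        indirect = sum(p(0, q) * p(q, j) for q in range(n) if q not in (0, j))
        total += (p(0, j) + indirect) ** 2
    return total


# ----------------------------------------------------- stepwise / regression

def aic_of_subset(X_cols: Dict[str, list], y: Sequence[float],
                  subset: Sequence[str]) -> float:
    """AIC of an OLS fit with intercept, computed via explicit least squares."""
    import numpy as np

    X = np.column_stack([np.ones(len(y))] + [np.asarray(X_cols[c], float)
                                             for c in subset])
    yv = np.asarray(y, float)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    nobs = len(yv)
    rss = float(resid @ resid)
    ll = -nobs / 2 * (math.log(2 * math.pi * rss / nobs) + 1)
    k = X.shape[1]  # mean parameters (the variance term is a shared constant)
    return 2 * k - 2 * ll


def backward_reachable_subsets(terms: List[Tuple[str, ...]]):
    """All term subsets reachable from the full model by marginality-
    respecting single-term removals (the search space of backward stepwise)."""
    def droppable(ts):
        return [t for t in ts
                if not any(set(t) < set(u) for u in ts if u != t)]

    seen = set()
    frontier = [tuple(sorted(terms))]
    while frontier:
        cur = frontier.pop()
        if cur in seen:
            continue
        seen.add(cur)
        for t in droppable(list(cur)):
            nxt = tuple(sorted(u for u in cur if u != t))
            frontier.append(nxt)
    return seen


def oracle_greedy_backward(terms, cols, y, name):
    """Independent re-implementation of AIC backward elimination.

    Straight-line code over :func:`aic_of_subset`: repeatedly drop the
    marginality-respecting term whose removal lowers AIC the most, stopping
    when no single removal improves.  Returns (term set, AIC).
    """
    def droppable(ts):
        return [t for t in ts if not any(set(t) < set(u) for u in ts if u != t)]

    cur = list(terms)
    cur_aic = aic_of_subset(cols, y, [name[t] for t in cur])
    while True:
        best_t, best_aic = None, cur_aic
        for t in droppable(cur):
            cand = [u for u in cur if u != t]
            aic = aic_of_subset(cols, y, [name[u] for u in cand])
            if aic < best_aic:
                best_t, best_aic = t, aic
        if best_t is None:
            return set(cur), cur_aic
        cur = [u for u in cur if u != best_t]
        cur_aic = best_aic


# -------------------------------------------------------------- Bayes factor

def oracle_jzs_bf10(x, y, r_scale=math.sqrt(2) / 2) -> float:
    """Two-sample JZS Bayes factor by direct quadrature (Rouder et al. form)."""
    import numpy as np
    from scipy import integrate, stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    n_eff = nx * ny / (nx + ny)
    nu = nx + ny - 2
    t = stats.ttest_ind(x, y).statistic

    def integrand(g):
        return ((1 + n_eff * g) ** -0.5
                * (1 + t * t / ((1 + n_eff * g) * nu)) ** (-(nu + 1) / 2)
                * (2 * math.pi) ** -0.5 * r_scale * g ** -1.5
                * math.exp(-r_scale ** 2 / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, limit=300)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den
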