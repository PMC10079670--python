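"""Independent reference implementations used only by the test suite.

Each function here is written straight from the defining formula or by
exhaustive enumeration, sharing no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special, stats


# --- moderated t, from the formulas ----------------------------------------


def moderated_t_oracle(lfc, s2, df, n1, n2, d0, s0_sq):
    """t and two-sided P from the posterior-variance formula, elementwise."""
    lfc = np.asarray(lfc, float)
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    out_t, out_p = [], []
    for i in range(len(lfc)):
        if math.isinf(d0):
            s_post = s0_sq
            t = lfc[i] / math.sqrt(s_post * (1 / n1[i] + 1 / n2[i]))
            p = 2 * stats.norm.sf(abs(t))
        else:
            s_post = (d0 * s0_sq + df[i] * s2[i]) / (d0 + df[i])
            t = lfc[i] / math.sqrt(s_post * (1 / n1[i] + 1 / n2[i]))
            p = 2 * stats.t.sf(abs(t), d0 + df[i])
        out_t.append(t)
        out_p.append(p)
    return np.array(out_t), np.array(out_p)


def moment_match_oracle(s2, df):
    """(d0, s0_sq) by the log-variance moment equations, scalar loop."""
    z = [math.log(v) for v in s2]
    e = [
        zi - special.digamma(d / 2) + math.log(d / 2)
        for zi, d in zip(z, df)
    ]
    emean = sum(e) / len(e)
    evar = sum((ei - emean) ** 2 for ei in e) / (len(e) - 1)
    excess = evar - sum(special.polygamma(1, d / 2) for d in df) / len(df)
    if excess <= 0:
        return math.inf, math.exp(emean)
    # bisection solve trigamma(y) = excess
    lo, hi = 1e-8, 1e8
    for _ in range(200):
        midv = math.sqrt(lo * hi)
        if special.polygamma(1, midv) > excess:
            lo = midv
        else:
            hi = midv
    half_d0 = math.sqrt(lo * hi)
    s0 = math.exp(emean + special.digamma(half_d0) - math.log(half_d0))
    return 2 * half_d0, s0


# --- BH step-up by direct enumeration --------------------------------------


def bh_oracle(p):
    """Adjusted values by sorting, cumulative minimum from the largest rank."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


# --- GSEA ES by prefix enumeration ------------------------------------------


def es_oracle(metric, hits, weight=1.0):
    """Running sum evaluated explicitly at every prefix; signed extremum."""
    n = len(metric)
    nh = sum(hits)
    w = [abs(m) ** weight if h else 0.0 for m, h in zip(metric, hits)]
    tot = sum(w)
    if tot == 0:
        w = [1.0 if h else 0.0 for h in hits]
        tot = float(nh)
    running = 0.0
    best = 0.0
    for i in range(n):
        if hits[i]:
            running += w[i] / tot
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running  # exact ties resolve to the positive deviation
    return best


# --- hypergeometric upper tail by enumeration --------------------------------


def hypergeom_tail_oracle(n_universe, n_set, n_list, k):
    """P(overlap >= k) summed from the counting formula."""
    total = math.comb(n_universe, n_list)
    acc = 0
    for j in range(k, min(n_set, n_list) + 1):
        acc += math.comb(n_set, j) * math.comb(n_universe - n_set, n_list - j)
    return acc / total


# --- misc -------------------------------------------------------------------


def pairwise_complete_r(x, y):
    """Pearson r on the manually intersected finite index set."""
    pairs = [(a, b) for a, b in zip(x, y) if np.isfinite(a) and np.isfinite(b)]
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    n = len(pairs)
    mx, my = sum(xs) / n, sum(ys) / n
    num = sum((a - mx) * (b - my) for a, b in pairs)
    den = math.sqrt(sum((a - mx) ** 2 for a in xs) * sum((b - my) ** 2 for b in ys))
    return num / den


def ols_oracle(x, y):
    """Simple-regression closed form with the slope t-test."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    resid = [b - (intercept + slope * a) for a, b in zip(x, y)]
    sse = sum(r * r for r in resid)
    se = math.sqrt(sse / (n - 2) / sxx)
    t = slope / se if se > 0 else math.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, intercept, p


def zmad_oracle(mat):
    """Per-gene modified z by an explicit loop; returns (z, dropped_cols)."""
    import pandas as pd

    z = {}
    dropped = []
    for col in mat.columns:
        v = mat[col].to_numpy(float)
        med = float(np.median(v))
        scale = float(np.mean(np.abs(v - med)))
        if scale == 0:
            dropped.append(col)
            continue
        z[col] = (v - med) / scale
    return pd.DataFrame(z, index=mat.index), dropped


def components_oracle(genes, edges):
    """Connected components by union-find over an explicit edge list."""
    parent = {g: g for g in genes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for g in genes:
        comps.setdefault(find(g), set()).add(g)
    return sorted(sorted(c) for c in comps.values())
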