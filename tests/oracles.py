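"""Independent brute-force reference implementations of every entropy measure.

Plain-Python loops over all template pairs / patterns, deliberately written
without the vectorized code paths of the package, for cross-checking on
short signals.
"""

from __future__ import annotations

import cmath
import math


def _chebyshev(a, b):
    return max(abs(p - q) for p, q in zip(a, b))


def _templates(x, m, tau=1):
    n = len(x) - (m - 1) * tau
    return [tuple(x[i + tau * k] for k in range(m)) for i in range(n)]


def _shannon(counts, base=math.e):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p, base)
    return h


def shannon_oracle(x, n_bins=256, lo=0.0, hi=255.0):
    counts = [0] * n_bins
    width = (hi - lo) / n_bins
    for v in x:
        if lo <= v <= hi:
            idx = min(int((v - lo) / width), n_bins - 1)
            counts[idx] += 1
    return _shannon(counts, base=2.0)


def apen_oracle(x, m, r):
    def phi(mm):
        if mm == 0:
            return 0.0
        t = _templates(x, mm)
        total = 0.0
        for a in t:
            c = sum(1 for b in t if _chebyshev(a, b) <= r) / len(t)
            total += math.log(c)
        return total / len(t)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m, r):
    n_sig = len(x)
    n = n_sig - m
    t_long = _templates(x, m + 1)
    a = sum(
        1
        for i in range(n)
        for j in range(n)
        if i != j and _chebyshev(t_long[i], t_long[j]) <= r
    )
    if m == 0:
        b = n * (n - 1)
    else:
        t_short = _templates(x, m)[:n]
        b = sum(
            1
            for i in range(n)
            for j in range(n)
            if i != j and _chebyshev(t_short[i], t_short[j]) <= r
        )
    if b == 0:
        return math.log(n) + math.log(max(n - 1, 1))
    if a == 0:
        return math.log(b) + math.log(n_sig - m)
    return -math.log(a / b)


def fuzzy_oracle(x, m, r, n_exp=2.0):
    n = len(x) - m

    def phi(mm):
        t = [tuple(v - sum(tpl) / len(tpl) for v in tpl) for tpl in _templates(x, mm)[:n]]
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    total += math.exp(-((_chebyshev(t[i], t[j]) / r) ** n_exp))
        return total / (n * (n - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def rangeen_oracle(x, m, r):
    n_sig = len(x)
    n = n_sig - m

    def count(mm):
        t = _templates(x, mm)[:n]
        c = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                diffs = [abs(p - q) for p, q in zip(t[i], t[j])]
                dmax, dmin = max(diffs), min(diffs)
                d = 0.0 if dmax + dmin == 0 else (dmax - dmin) / (dmax + dmin)
                if d <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if b == 0:
        return math.log(n) + math.log(max(n - 1, 1))
    if a == 0:
        return math.log(b) + math.log(n_sig - m)
    return -math.log(a / b)


def cmse_oracle(x, scale, m, r):
    vals = []
    for offset in range(scale):
        n = (len(x) - offset) // scale
        series = [
            sum(x[offset + i * scale : offset + (i + 1) * scale]) / scale for i in range(n)
        ]
        vals.append(sampen_oracle(series, m, r))
    return sum(vals) / len(vals)


def permen_oracle(x, m, tau=1):
    patterns = {}
    for tpl in _templates(x, m, tau):
        key = tuple(sorted(range(m), key=lambda k: (tpl[k], k)))  # stable ranks
        patterns[key] = patterns.get(key, 0) + 1
    return _shannon(patterns.values(), base=2.0) / math.log2(math.factorial(m))


def dispen_oracle(x, m, c, tau=1):
    n = len(x)
    mu = sum(x) / n
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / n)
    if sd == 0:
        y = [0.5] * n
    else:
        y = [0.5 * (1 + math.erf((v - mu) / (sd * math.sqrt(2)))) for v in x]
    classes = [min(int(c * v) + 1, c) for v in y]
    patterns = {}
    for tpl in _templates(classes, m, tau):
        patterns[tpl] = patterns.get(tpl, 0) + 1
    return _shannon(patterns.values()) / math.log(c**m)


def spectral_oracle(x):
    n = len(x)
    n_bins = n // 2
    power = []
    for k in range(1, n_bins + 1):
        s = sum(x[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        power.append(abs(s) ** 2)
    total = sum(power)
    if total == 0:
        return 0.0
    p = [v / total for v in power]
    return _shannon([v for v in p]) / math.log(len(p)) if len(p) > 1 else 0.0


def _shannon_probs(p, base=math.e):
    return -sum(v * math.log(v, base) for v in p if v > 0)


def disten_oracle(x, m, n_bins=512):
    t = _templates(x, m)
    dists = [
        _chebyshev(t[i], t[j]) for i in range(len(t)) for j in range(i + 1, len(t))
    ]
    dmax = max(dists)
    if dmax == 0:
        return 0.0
    counts = [0] * n_bins
    width = dmax / n_bins
    for d in dists:
        counts[min(int(d / width), n_bins - 1)] += 1
    return _shannon(counts, base=2.0) / math.log2(n_bins)


def _cos_sim(a, b):
    na = math.sqrt(sum(v * v for v in a))
    nb = math.sqrt(sum(v * v for v in b))
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    cs = sum(p * q for p, q in zip(a, b)) / (na * nb)
    return max(-1.0, min(1.0, cs))


def cse_oracle(x, m, r):
    t = _templates(x, m)
    n = len(t)
    hits = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if math.acos(_cos_sim(t[i], t[j])) / math.pi < r:
                hits += 1
    p = hits / total
    if p in (0.0, 1.0):
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def diven_oracle(x, m, n_bins=5):
    t = _templates(x, m)
    sims = [_cos_sim(t[i], t[i + 1]) for i in range(len(t) - 1)]
    counts = [0] * n_bins
    width = (2.0 + 1e-12) / n_bins
    for s in sims:
        counts[min(int((s + 1.0) / width), n_bins - 1)] += 1
    return _shannon(counts) / math.log(n_bins)


def attention_oracle(x):
    n = len(x)
    maxima = [i for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    minima = [i for i in range(1, n - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]

    def h(src, dst, same):
        if same:
            iv = [b - a for a, b in zip(src, src[1:])]
        else:
            iv = []
            for s in src:
                nxt = [d for d in dst if d > s]
                if nxt:
                    iv.append(nxt[0] - s)
        if not iv:
            return 0.0
        counts = {}
        for v in iv:
            counts[v] = counts.get(v, 0) + 1
        return _shannon(counts.values(), base=2.0)

    return (h(maxima, maxima, True) + h(minima, minima, True)
            + h(maxima, minima, False) + h(minima, maxima, False)) / 4.0


def bubble_oracle(x, m):
    def h2(mm):
        counts = {}
        for tpl in _templates(x, mm):
            inv = sum(
                1
                for i in range(mm)
                for j in range(i + 1, mm)
                if tpl[i] > tpl[j]
            )
            counts[inv] = counts.get(inv, 0) + 1
        total = sum(counts.values())
        return -math.log(sum((c / total) ** 2 for c in counts.values()))

    return (h2(m + 1) - h2(m)) / math.log((m + 1) / (m - 1))


def cce_oracle(x, m, n_bins=6):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    q = [min(int(n_bins * (v - lo) / (hi - lo)), n_bins - 1) for v in x]

    def counts(mm):
        patterns = {}
        for tpl in _templates(q, mm):
            patterns[tpl] = patterns.get(tpl, 0) + 1
        return patterns

    def ent(mm):
        return _shannon(counts(mm).values())

    cm = counts(m)
    perc = sum(1 for c in cm.values() if c == 1) / sum(cm.values())
    return ent(m) - ent(m - 1) + perc * ent(1)


def eoe_oracle(x, window=5, n_levels=5):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    level = [min(int(n_levels * (v - lo) / (hi - lo)), n_levels - 1) for v in x]
    n_win = len(x) // window
    ents = []
    for w in range(n_win):
        chunk = level[w * window : (w + 1) * window]
        counts = {}
        for v in chunk:
            counts[v] = counts.get(v, 0) + 1
        ents.append(_shannon(counts.values()))
    hmax = math.log(n_levels)
    slots = [min(int(n_levels * e / hmax), n_levels - 1) for e in ents]
    counts = {}
    for s in slots:
        counts[s] = counts.get(s, 0) + 1
    return _shannon(counts.values())


def gde_oracle(x, n_grid=3):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    cells = {}
    for a, b in zip(x[:-1], x[1:]):
        gx = min(int(n_grid * (a - lo) / (hi - lo)), n_grid - 1)
        gy = min(int(n_grid * (b - lo) / (hi - lo)), n_grid - 1)
        cells[(gx, gy)] = cells.get((gx, gy), 0) + 1
    return _shannon(cells.values(), base=2.0) / math.log2(n_grid * n_grid)


def phase_oracle(x, n_sectors=4):
    d = [b - a for a, b in zip(x[:-1], x[1:])]
    sectors = {}
    n_pts = 0
    for u, v in zip(d[:-1], d[1:]):
        if u == 0 and v == 0:
            continue
        theta = math.atan2(v, u) % (2 * math.pi)
        s = min(int(theta / (2 * math.pi / n_sectors)), n_sectors - 1)
        sectors[s] = sectors.get(s, 0) + 1
        n_pts += 1
    if n_pts == 0:
        return 0.0
    return _shannon(sectors.values()) / math.log(n_sectors)


def slopen_oracle(x, m=2, gamma=5.0, delta=0.001):
    d = [b - a for a, b in zip(x[:-1], x[1:])]

    def sym(v):
        if v > gamma:
            return 2
        if v > delta:
            return 1
        if v >= -delta:
            return 0
        if v >= -gamma:
            return -1
        return -2

    symbols = [sym(v) for v in d]
    patterns = {}
    for tpl in _templates(symbols, m - 1):
        patterns[tpl] = patterns.get(tpl, 0) + 1
    return _shannon(patterns.values()) / math.log(5 ** (m - 1))


# --- cross measures ---------------------------------------------------------

def xapen_oracle(u, v, m, r):
    def phi(mm):
        if mm == 0:
            return 0.0
        tu, tv = _templates(u, mm), _templates(v, mm)
        total = 0.0
        for a in tu:
            c = sum(1 for b in tv if _chebyshev(a, b) <= r) / len(tv)
            total += math.log(c) if c > 0 else -math.inf
        return total / len(tu)

    return phi(m) - phi(m + 1)


def xsampen_oracle(u, v, m, r):
    n_sig = len(u)
    n = n_sig - m
    tu1, tv1 = _templates(u, m + 1), _templates(v, m + 1)
    a = sum(
        1 for i in range(n) for j in range(n) if _chebyshev(tu1[i], tv1[j]) <= r
    )
    if m == 0:
        b = n * n
    else:
        tu, tv = _templates(u, m)[:n], _templates(v, m)[:n]
        b = sum(
            1 for i in range(n) for j in range(n) if _chebyshev(tu[i], tv[j]) <= r
        )
    if b == 0:
        return math.log(n) + math.log(max(n - 1, 1))
    if a == 0:
        return math.log(b) + math.log(n_sig - m)
    return -math.log(a / b)


def xfuzzy_oracle(u, v, m, r, n_exp=2.0):
    n = len(u) - m

    def phi(mm):
        tu = [tuple(x - sum(t) / len(t) for x in t) for t in _templates(u, mm)[:n]]
        tv = [tuple(x - sum(t) / len(t) for x in t) for t in _templates(v, mm)[:n]]
        total = 0.0
        for i in range(n):
            for j in range(n):
                total += math.exp(-((_chebyshev(tu[i], tv[j]) / r) ** n_exp))
        return total / (n * n)

    return math.log(phi(m)) - math.log(phi(m + 1))


def xk2_oracle(u, v, m, r):
    def corr(mm):
        tu, tv = _templates(u, mm), _templates(v, mm)
        hits = sum(
            1 for a in tu for b in tv if _chebyshev(a, b) <= r
        )
        return hits / (len(tu) * len(tv))

    cm, cm1 = corr(m), corr(m + 1)
    if cm == 0:
        return math.nan
    if cm1 == 0:
        return math.inf
    return math.log(cm / cm1)


def xdisten_oracle(u, v, m, n_bins=512):
    tu, tv = _templates(u, m), _templates(v, m)
    dists = [_chebyshev(a, b) for a in tu for b in tv]
    dmax = max(dists)
    if dmax == 0:
        return 0.0
    counts = [0] * n_bins
    width = dmax / n_bins
    for d in dists:
        counts[min(int(d / width), n_bins - 1)] += 1
    return _shannon(counts, base=2.0) / math.log2(n_bins)


def xcce_oracle(u, v, m, n_bins=6):
    def quant(x):
        lo, hi = min(x), max(x)
        if hi == lo:
            return [0] * len(x)
        return [min(int(n_bins * (val - lo) / (hi - lo)), n_bins - 1) for val in x]

    qu, qv = quant(u), quant(v)
    n = len(u) - (m - 1)
    mixed = {}
    for i in range(n):
        key = tuple(qu[i : i + m - 1]) + (qv[i + m - 1],)
        mixed[key] = mixed.get(key, 0) + 1
    e_mixed = _shannon(mixed.values())
    upat = {}
    for tpl in _templates(qu, m - 1):
        upat[tpl] = upat.get(tpl, 0) + 1
    e_u = _shannon(upat.values())
    v1 = {}
    for val in qv:
        v1[val] = v1.get(val, 0) + 1
    e_v1 = _shannon(v1.values())
    perc = sum(1 for c in mixed.values() if c == 1) / sum(mixed.values())
    return e_mixed - e_u + perc * e_v1


def xspectral_oracle(u, v):
    n = len(u)
    n_bins = n // 2
    mags = []
    for k in range(1, n_bins + 1):
        su = sum(u[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        sv = sum(v[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        mags.append(abs(su * sv.conjugate()))
    total = sum(mags)
    if total == 0:
        return 0.0
    p = [m_ / total for m_ in mags]
    return _shannon(p) / math.log(len(p))


def auc_rank_oracle(scores, labels, positive=1):
    """Pairwise rank statistic: P(score_pos > score_neg), ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == positive]
    neg = [s for s, y in zip(scores, labels) if y != positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
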