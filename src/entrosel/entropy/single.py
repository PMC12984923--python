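"""Single-signal entropy and complexity measures.

Every measure operates on a finite 1-D float signal.  Template-based measures
(approximate, sample, fuzzy, range entropy) use Chebyshev distance between
delay-embedded templates; tolerance ``r`` defaults to 0.2 x SD of the signal
unless the measure's metric is already scale-free.  Normalized measures
(permutation, dispersion, spectral, diversity, distribution, slope, gridded,
phase, cosine-similarity) return values in [0, 1].
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import ndtr

from ..errors import InsufficientLengthError, InvalidArgumentError, InvalidInputError

#: minimum signal length accepted by the feature registry
MIN_SIGNAL_LENGTH = 32

_EPS = 1e-12


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise InvalidInputError("empty signal")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite values")
    return x


def default_tolerance(x, fraction: float = 0.2) -> float:
    """Matching tolerance r = fraction x SD; guarded for constant signals."""
    x = _as_signal(x)
    r = fraction * float(np.std(x))
    return max(r, _EPS)


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Delay embedding: rows are length-m templates x[i], x[i+tau], ..."""
    n = x.size - (m - 1) * tau
    if n < 1:
        raise InsufficientLengthError(f"need N >= {(m - 1) * tau + 1}, got {x.size}")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _shannon(p: np.ndarray, base: float = math.e) -> float:
    p = p[p > 0]
    return float(-(p * (np.log(p) / math.log(base))).sum())


# ---------------------------------------------------------------------------
# Histogram / Shannon
# ---------------------------------------------------------------------------

def shannon_entropy(x, n_bins: int = 256, value_range: tuple[float, float] = (0.0, 255.0)) -> float:
    """Shannon entropy (bits) of the intensity histogram over ``value_range``."""
    x = _as_signal(x)
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    counts, _ = np.histogram(x, bins=n_bins, range=value_range)
    total = counts.sum()
    if total == 0:
        raise InvalidInputError("no samples fall inside the histogram range")
    return _shannon(counts / total, base=2.0)


# ---------------------------------------------------------------------------
# Approximate / sample / fuzzy / range entropy (template matching)
# ---------------------------------------------------------------------------

def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r): Phi^m - Phi^{m+1}; self-matches included.

    m = 0 is handled by defining Phi^0 = 0 (zero-length templates all match),
    so ApEn(0) = -Phi^1 >= 0.
    """
    x = _as_signal(x)
    if m < 0:
        raise InvalidArgumentError("m must be >= 0")
    if x.size <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(x)
    if r <= 0:
        raise InvalidArgumentError("r must be > 0")

    def phi(mm: int) -> float:
        if mm == 0:
            return 0.0
        t = _embed(x, mm)
        d = cdist(t, t, "chebyshev")
        c = (d <= r).mean(axis=1)  # self-match keeps c > 0
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


def sample_entropy_info(x, m: int = 2, r: float | None = None) -> tuple[float, bool]:
    """SampEn(m, r) = -ln(A/B), self-matches excluded; returns (value, capped).

    A counts (m+1)-template matches, B counts m-template matches over a common
    index range.  m = 0 takes B as all ordered pairs of points.  A degenerate
    count (A = 0 or B = 0) returns the finite cap ln(B) + ln(N - m) instead of
    infinity, with ``capped = True``.
    """
    x = _as_signal(x)
    if m < 0:
        raise InvalidArgumentError("m must be >= 0")
    n_sig = x.size
    if n_sig <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(x)
    if r <= 0:
        raise InvalidArgumentError("r must be > 0")

    n = n_sig - m  # number of (m+1)-templates; common range for both lengths
    t_long = _embed(x, m + 1)
    d_long = cdist(t_long, t_long, "chebyshev")
    np.fill_diagonal(d_long, np.inf)
    a = int((d_long <= r).sum())
    if m == 0:
        b = n * (n - 1)
    else:
        t_short = _embed(x, m)[:n]
        d_short = cdist(t_short, t_short, "chebyshev")
        np.fill_diagonal(d_short, np.inf)
        b = int((d_short <= r).sum())
    if b == 0:
        return math.log(n) + math.log(max(n - 1, 1)), True
    if a == 0:
        return math.log(b) + math.log(n_sig - m), True
    return -math.log(a / b), False


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    return sample_entropy_info(x, m, r)[0]


def fuzzy_entropy(x, m: int = 1, r: float | None = None, n_exp: float = 2.0) -> float:
    """Fuzzy entropy with exponential membership on mean-subtracted templates.

    Baseline removal makes the measure exactly translation-invariant.
    """
    x = _as_signal(x)
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    if n_exp <= 0:
        raise InvalidArgumentError("n_exp must be > 0")
    if x.size <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(x)
    if r <= 0:
        raise InvalidArgumentError("r must be > 0")
    n = x.size - m

    def phi(mm: int) -> float:
        t = _embed(x, mm)[:n]
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, "chebyshev")
        mu = np.exp(-((d / r) ** n_exp))
        return float((mu.sum() - n) / (n * (n - 1)))

    return math.log(phi(m)) - math.log(phi(m + 1))


def range_entropy_info(x, m: int = 2, r: float = 0.2) -> tuple[float, bool]:
    """RangeEn-B: SampEn with the range-ratio template distance.

    The distance between templates is (max|diff| - min|diff|) /
    (max|diff| + min|diff|), which lies in [0, 1]; r is therefore a fixed
    ratio (default 0.2) rather than an amplitude-scaled tolerance.
    """
    x = _as_signal(x)
    if m < 2:
        raise InvalidArgumentError("m must be >= 2 for a non-degenerate range")
    if not 0 < r < 1:
        raise InvalidArgumentError("r must lie in (0, 1)")
    n_sig = x.size
    if n_sig <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    n = n_sig - m

    def count(mm: int) -> int:
        t = _embed(x, mm)[:n]
        total = 0
        block = 256
        for s in range(0, n, block):
            diff = np.abs(t[s : s + block, None, :] - t[None, :, :])
            dmax = diff.max(axis=2)
            dmin = diff.min(axis=2)
            denom = dmax + dmin
            d = np.where(denom > 0, (dmax - dmin) / np.where(denom > 0, denom, 1.0), 0.0)
            rows = np.arange(s, min(s + block, n))
            d[np.arange(rows.size), rows] = np.inf  # exclude self
            total += int((d <= r).sum())
        return total

    b = count(m)
    a = count(m + 1)
    if b == 0:
        return math.log(n) + math.log(max(n - 1, 1)), True
    if a == 0:
        return math.log(b) + math.log(n_sig - m), True
    return -math.log(a / b), False


def range_entropy(x, m: int = 2, r: float = 0.2) -> float:
    return range_entropy_info(x, m, r)[0]


# ---------------------------------------------------------------------------
# Multiscale
# ---------------------------------------------------------------------------

def coarse_grain(x: np.ndarray, scale: int, offset: int = 0) -> np.ndarray:
    """Non-overlapping block means of width ``scale`` starting at ``offset``."""
    x = _as_signal(x)
    n = (x.size - offset) // scale
    if n < 1:
        raise InsufficientLengthError("coarse-grained series is empty")
    return x[offset : offset + n * scale].reshape(n, scale).mean(axis=1)


def composite_multiscale_entropy(x, scale: int = 1, m: int = 2, r: float | None = None) -> float:
    """CMSE: mean sample entropy over the ``scale`` offset coarse-grainings.

    r is fixed from the original signal's SD so that values are comparable
    across scales.
    """
    x = _as_signal(x)
    if scale < 1:
        raise InvalidArgumentError("scale must be >= 1")
    if r is None:
        r = default_tolerance(x)
    vals = []
    for offset in range(scale):
        series = coarse_grain(x, scale, offset)
        if series.size <= m + 1:
            raise InsufficientLengthError("coarse-grained series too short")
        vals.append(sample_entropy(series, m, r))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Symbolic / ordinal measures
# ---------------------------------------------------------------------------

def permutation_entropy(x, m: int = 3, tau: int = 1) -> float:
    """Normalized permutation entropy in [0, 1]; ties broken by occurrence order."""
    x = _as_signal(x)
    if m < 2:
        raise InvalidArgumentError("m must be >= 2")
    if tau < 1:
        raise InvalidArgumentError("tau must be >= 1")
    if x.size < (m - 1) * tau + 1:
        raise InsufficientLengthError(f"need N >= {(m - 1) * tau + 1}")
    t = _embed(x, m, tau)
    patterns = np.argsort(t, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    h = _shannon(counts / counts.sum(), base=2.0)
    return h / math.log2(math.factorial(m))


def dispersion_entropy(x, m: int = 2, c: int = 6, tau: int = 1) -> float:
    """Normalized dispersion entropy: NCDF mapping to c classes, m-patterns."""
    x = _as_signal(x)
    if c < 2 or m < 2 or tau < 1:
        raise InvalidArgumentError("need c >= 2, m >= 2, tau >= 1")
    if x.size < (m - 1) * tau + 1:
        raise InsufficientLengthError(f"need N >= {(m - 1) * tau + 1}")
    sd = x.std()
    y = ndtr((x - x.mean()) / sd) if sd > 0 else np.full(x.size, 0.5)
    classes = np.minimum(np.floor(c * y).astype(int) + 1, c)
    t = _embed(classes.astype(float), m, tau)
    _, counts = np.unique(t, axis=0, return_counts=True)
    h = _shannon(counts / counts.sum())
    return h / math.log(c**m)


def slope_entropy(x, m: int = 2, gamma: float = 5.0, delta: float = 0.001) -> float:
    """Normalized slope entropy: consecutive differences mapped to 5 symbols.

    |d| <= delta -> 0; delta < |d| <= gamma -> +/-1; |d| > gamma -> +/-2.
    Patterns are m-1 consecutive symbols.
    """
    x = _as_signal(x)
    if m < 2:
        raise InvalidArgumentError("m must be >= 2")
    if not 0 <= delta < gamma:
        raise InvalidArgumentError("need 0 <= delta < gamma")
    if x.size < m + 1:
        raise InsufficientLengthError(f"need N >= {m + 1}")
    d = np.diff(x)
    sym = np.select(
        [d > gamma, d > delta, d >= -delta, d >= -gamma], [2, 1, 0, -1], default=-2
    ).astype(float)
    t = _embed(sym, m - 1)
    _, counts = np.unique(t, axis=0, return_counts=True)
    h = _shannon(counts / counts.sum())
    return h / math.log(5 ** (m - 1))


def bubble_entropy(x, m: int = 10) -> float:
    """Bubble entropy: Renyi-2 entropy growth of bubble-sort swap counts.

    B = (H2_{m+1} - H2_m) / log((m+1)/(m-1)), H2 from the distribution of the
    number of inversions in each embedded template.
    """
    x = _as_signal(x)
    if m < 2:
        raise InvalidArgumentError("m must be >= 2")
    if x.size < m + 2:
        raise InsufficientLengthError(f"need N >= {m + 2}")

    def h2(mm: int) -> float:
        t = _embed(x, mm)
        # inversions = pairs i<j with t[:, i] > t[:, j]
        gt = t[:, :, None] > t[:, None, :]
        iu = np.triu_indices(mm, k=1)
        inv = gt[:, iu[0], iu[1]].sum(axis=1)
        _, counts = np.unique(inv, return_counts=True)
        p = counts / counts.sum()
        return -math.log(float((p**2).sum()))

    return (h2(m + 1) - h2(m)) / math.log((m + 1) / (m - 1))


def attention_entropy(x) -> float:
    """Attention entropy: Shannon entropy (bits) of intervals between key points.

    Key points are strict local maxima and minima; the four interval streams
    (max-max, min-min, max-min, min-max) are scored separately and averaged.
    """
    x = _as_signal(x)
    if x.size < 3:
        raise InsufficientLengthError("need N >= 3")
    interior = np.arange(1, x.size - 1)
    maxima = interior[(x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])]
    minima = interior[(x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])]

    def interval_entropy(src: np.ndarray, dst: np.ndarray, same: bool) -> float:
        if same:
            iv = np.diff(src)
        else:
            iv = []
            j = 0
            for s in src:
                while j < dst.size and dst[j] <= s:
                    j += 1
                if j < dst.size:
                    iv.append(dst[j] - s)
            iv = np.asarray(iv)
        if iv.size == 0:
            return 0.0
        _, counts = np.unique(iv, return_counts=True)
        return _shannon(counts / counts.sum(), base=2.0)

    return float(
        np.mean(
            [
                interval_entropy(maxima, maxima, True),
                interval_entropy(minima, minima, True),
                interval_entropy(maxima, minima, False),
                interval_entropy(minima, maxima, False),
            ]
        )
    )


# ---------------------------------------------------------------------------
# Distributional measures
# ---------------------------------------------------------------------------

def distribution_entropy(x, m: int = 2, n_bins: int = 512) -> float:
    """DistEn: normalized Shannon entropy of the template-distance histogram."""
    x = _as_signal(x)
    if m < 1 or n_bins < 2:
        raise InvalidArgumentError("need m >= 1 and n_bins >= 2")
    if x.size < m + 1:
        raise InsufficientLengthError(f"need N >= {m + 1}")
    t = _embed(x, m)
    d = cdist(t, t, "chebyshev")
    iu = np.triu_indices(t.shape[0], k=1)
    dists = d[iu]
    dmax = dists.max()
    if dmax == 0:
        return 0.0
    counts, _ = np.histogram(dists, bins=n_bins, range=(0.0, dmax))
    return _shannon(counts / counts.sum(), base=2.0) / math.log2(n_bins)


def _cosine_similarity_rows(t: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(t, axis=1)
    sims = t @ t.T
    denom = norms[:, None] * norms[None, :]
    both_zero = (norms[:, None] == 0) & (norms[None, :] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cs = np.where(denom > 0, sims / np.where(denom > 0, denom, 1.0), 0.0)
    cs[both_zero] = 1.0
    return np.clip(cs, -1.0, 1.0)


def cosine_similarity_entropy(x, m: int = 2, r: float = 0.1) -> float:
    """CSE: binary Shannon entropy (bits) of the similar-pattern probability.

    Pairs of embedded templates are "similar" when their angular distance
    arccos(cos_sim)/pi is below r.
    """
    x = _as_signal(x)
    if m < 2 or not 0 < r < 1:
        raise InvalidArgumentError("need m >= 2 and r in (0, 1)")
    if x.size < m + 1:
        raise InsufficientLengthError(f"need N >= {m + 1}")
    t = _embed(x, m)
    cs = _cosine_similarity_rows(t)
    ang = np.arccos(cs) / math.pi
    iu = np.triu_indices(t.shape[0], k=1)
    p = float((ang[iu] < r).mean())
    if p in (0.0, 1.0):
        return 0.0
    return float(-(p * math.log2(p) + (1 - p) * math.log2(1 - p)))


def diversity_entropy(x, m: int = 2, n_bins: int = 5) -> float:
    """DivEn: normalized entropy of successive-template cosine similarities."""
    x = _as_signal(x)
    if m < 2 or n_bins < 2:
        raise InvalidArgumentError("need m >= 2 and n_bins >= 2")
    if x.size < m + 2:
        raise InsufficientLengthError(f"need N >= {m + 2}")
    t = _embed(x, m)
    a, b = t[:-1], t[1:]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    dots = (a * b).sum(axis=1)
    denom = na * nb
    cs = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    cs[(na == 0) & (nb == 0)] = 1.0
    cs = np.clip(cs, -1.0, 1.0)
    counts, _ = np.histogram(cs, bins=n_bins, range=(-1.0, 1.0 + _EPS))
    return _shannon(counts / counts.sum()) / math.log(n_bins)


def entropy_of_entropy(x, window: int = 5, n_levels: int = 5) -> float:
    """EoE: Shannon entropy of windowed Shannon entropies.

    The signal is sliced into amplitude levels (global range), split into
    non-overlapping windows, and each window's level-distribution entropy
    becomes a sample for a second-stage entropy over ``n_levels`` slices of
    [0, ln(n_levels)].
    """
    x = _as_signal(x)
    if window < 2 or n_levels < 2:
        raise InvalidArgumentError("need window >= 2 and n_levels >= 2")
    n_win = x.size // window
    if n_win < 2:
        raise InsufficientLengthError("need at least two full windows")
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return 0.0
    level = np.minimum((n_levels * (x - xmin) / (xmax - xmin)).astype(int), n_levels - 1)
    wins = level[: n_win * window].reshape(n_win, window)
    ent = np.empty(n_win)
    for i in range(n_win):
        _, counts = np.unique(wins[i], return_counts=True)
        ent[i] = _shannon(counts / counts.sum())
    hmax = math.log(n_levels)
    slot = np.minimum((n_levels * ent / hmax).astype(int), n_levels - 1)
    _, counts = np.unique(slot, return_counts=True)
    return _shannon(counts / counts.sum())


def gridded_distribution_entropy(x, n_grid: int = 3) -> float:
    """Normalized entropy of Poincare-plot (x_i, x_{i+1}) occupancy on a grid."""
    x = _as_signal(x)
    if n_grid < 2:
        raise InvalidArgumentError("n_grid must be >= 2")
    if x.size < 3:
        raise InsufficientLengthError("need N >= 3")
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return 0.0
    gx = np.minimum((n_grid * (x[:-1] - xmin) / (xmax - xmin)).astype(int), n_grid - 1)
    gy = np.minimum((n_grid * (x[1:] - xmin) / (xmax - xmin)).astype(int), n_grid - 1)
    cell = gx * n_grid + gy
    _, counts = np.unique(cell, return_counts=True)
    return _shannon(counts / counts.sum(), base=2.0) / math.log2(n_grid * n_grid)


def phase_entropy(x, n_sectors: int = 4) -> float:
    """Normalized entropy of second-order difference plot angles by sector."""
    x = _as_signal(x)
    if n_sectors < 2:
        raise InvalidArgumentError("n_sectors must be >= 2")
    if x.size < 4:
        raise InsufficientLengthError("need N >= 4")
    d = np.diff(x)
    u, v = d[:-1], d[1:]
    keep = ~((u == 0) & (v == 0))
    u, v = u[keep], v[keep]
    if u.size == 0:
        return 0.0
    theta = np.mod(np.arctan2(v, u), 2 * math.pi)
    sector = np.minimum((theta / (2 * math.pi / n_sectors)).astype(int), n_sectors - 1)
    _, counts = np.unique(sector, return_counts=True)
    return _shannon(counts / counts.sum()) / math.log(n_sectors)


def corrected_conditional_entropy(x, m: int = 2, n_bins: int = 6) -> float:
    """CCE: conditional pattern entropy plus the single-occurrence correction.

    The signal is uniformly quantized into ``n_bins`` levels; CCE(m) =
    E(m) - E(m-1) + perc(m) * E(1), where perc(m) is the fraction of length-m
    patterns occurring exactly once.
    """
    x = _as_signal(x)
    if m < 2 or n_bins < 2:
        raise InvalidArgumentError("need m >= 2 and n_bins >= 2")
    if x.size < m + 1:
        raise InsufficientLengthError(f"need N >= {m + 1}")
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return 0.0
    q = np.minimum((n_bins * (x - xmin) / (xmax - xmin)).astype(int), n_bins - 1).astype(float)

    def pattern_counts(mm: int) -> np.ndarray:
        t = _embed(q, mm)
        _, counts = np.unique(t, axis=0, return_counts=True)
        return counts

    def ent(mm: int) -> float:
        counts = pattern_counts(mm)
        return _shannon(counts / counts.sum())

    counts_m = pattern_counts(m)
    perc = float((counts_m == 1).sum() / counts_m.sum())
    return ent(m) - ent(m - 1) + perc * ent(1)


# ---------------------------------------------------------------------------
# Spectral
# ---------------------------------------------------------------------------

def spectral_entropy(x) -> float:
    """Normalized entropy of the one-sided periodogram power, DC excluded.

    A constant (DC-only) signal has zero spectral spread and returns 0;
    the all-zero signal is rejected as invalid.
    """
    x = _as_signal(x)
    if x.size < 8:
        raise InsufficientLengthError("need N >= 8")
    if np.all(x == 0):
        raise InvalidInputError("spectral entropy of the all-zero signal is undefined")
    power = np.abs(np.fft.rfft(x)) ** 2
    power = power[1:]  # exclude DC
    total = power.sum()
    if total == 0:
        return 0.0
    p = power / total
    return _shannon(p) / math.log(p.size)
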