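"""Two-signal (cross) entropy measures.

Each measure quantifies the asynchrony between a primary signal ``u`` and a
reference signal ``v`` of the same length by matching templates drawn from one
against templates drawn from the other.  Unlike the self variants there is no
self-match guarantee, so a measure can be non-finite when no cross template
pair falls inside the tolerance; callers that need guaranteed-finite output
apply the table-level imputation rule.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist

from ..errors import InsufficientLengthError, InvalidArgumentError, InvalidInputError
from .single import _as_signal, _embed, _shannon, default_tolerance


def _pair(u, v) -> tuple[np.ndarray, np.ndarray]:
    u, v = _as_signal(u), _as_signal(v)
    if u.size != v.size:
        raise InvalidInputError("cross measures require equal-length signals")
    return u, v


def cross_approximate_entropy(u, v, m: int = 1, r: float | None = None) -> float:
    """Cross-ApEn: Phi^m - Phi^{m+1} with templates of u matched against v.

    m = 0 uses Phi^0 = 0.  May return +inf when some u-template has no
    v-match within r.
    """
    u, v = _pair(u, v)
    if m < 0:
        raise InvalidArgumentError("m must be >= 0")
    if u.size <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(u)

    def phi(mm: int) -> float:
        if mm == 0:
            return 0.0
        tu = _embed(u, mm)
        tv = _embed(v, mm)
        d = cdist(tu, tv, "chebyshev")
        c = (d <= r).mean(axis=1)
        with np.errstate(divide="ignore"):
            return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


def cross_sample_entropy_info(u, v, m: int = 1, r: float | None = None) -> tuple[float, bool]:
    """Cross-SampEn = -ln(A/B) over all ordered cross template pairs.

    B counts m-template matches and A counts (m+1)-template matches between
    u-templates and v-templates on a common index range; m = 0 defines B as
    all cross pairs (every zero-length template matches).  Degenerate counts
    return the finite cap ln(B) + ln(N - m) with ``capped = True``.
    """
    u, v = _pair(u, v)
    if m < 0:
        raise InvalidArgumentError("m must be >= 0")
    n_sig = u.size
    if n_sig <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(u)
    n = n_sig - m
    tu = _embed(u, m + 1)
    tv = _embed(v, m + 1)
    a = int((cdist(tu, tv, "chebyshev") <= r).sum())
    if m == 0:
        b = n * n
    else:
        su = _embed(u, m)[:n]
        sv = _embed(v, m)[:n]
        b = int((cdist(su, sv, "chebyshev") <= r).sum())
    if b == 0:
        return math.log(n) + math.log(max(n - 1, 1)), True
    if a == 0:
        return math.log(b) + math.log(n_sig - m), True
    return -math.log(a / b), False


def cross_sample_entropy(u, v, m: int = 1, r: float | None = None) -> float:
    return cross_sample_entropy_info(u, v, m, r)[0]


def cross_fuzzy_entropy(u, v, m: int = 1, r: float | None = None, n_exp: float = 2.0) -> float:
    """Cross-fuzzy entropy with exponential membership on centred templates."""
    u, v = _pair(u, v)
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    if u.size <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(u)
    n = u.size - m

    def phi(mm: int) -> float:
        tu = _embed(u, mm)[:n]
        tv = _embed(v, mm)[:n]
        tu = tu - tu.mean(axis=1, keepdims=True)
        tv = tv - tv.mean(axis=1, keepdims=True)
        d = cdist(tu, tv, "chebyshev")
        return float(np.exp(-((d / r) ** n_exp)).mean())

    return math.log(phi(m)) - math.log(phi(m + 1))


def cross_kolmogorov_entropy(u, v, m: int = 1, r: float | None = None) -> float:
    """K2-style cross estimator: ln(C_m(r) / C_{m+1}(r)) on cross correlation sums.

    C_mm is the fraction of all u-template / v-template pairs within r
    (Chebyshev).  The least standardized measure in the bank; may be
    non-finite when either correlation sum vanishes.
    """
    u, v = _pair(u, v)
    if m < 1:
        raise InvalidArgumentError("m must be >= 1")
    if u.size <= m + 1:
        raise InsufficientLengthError(f"need N > m+1 = {m + 1}")
    if r is None:
        r = default_tolerance(u)

    def corr_sum(mm: int) -> float:
        tu = _embed(u, mm)
        tv = _embed(v, mm)
        d = cdist(tu, tv, "chebyshev")
        return float((d <= r).mean())

    c_m = corr_sum(m)
    c_m1 = corr_sum(m + 1)
    if c_m == 0 or c_m1 == 0:
        return math.inf if c_m > 0 else math.nan
    return math.log(c_m / c_m1)


def cross_distribution_entropy(u, v, m: int = 2, n_bins: int = 512) -> float:
    """Normalized entropy of the cross template-distance histogram."""
    u, v = _pair(u, v)
    if m < 1 or n_bins < 2:
        raise InvalidArgumentError("need m >= 1 and n_bins >= 2")
    if u.size < m + 1:
        raise InsufficientLengthError(f"need N >= {m + 1}")
    tu = _embed(u, m)
    tv = _embed(v, m)
    dists = cdist(tu, tv, "chebyshev").ravel()
    dmax = dists.max()
    if dmax == 0:
        return 0.0
    counts, _ = np.histogram(dists, bins=n_bins, range=(0.0, dmax))
    return _shannon(counts / counts.sum(), base=2.0) / math.log2(n_bins)


def corrected_cross_conditional_entropy(u, v, m: int = 2, n_bins: int = 6) -> float:
    """Cross CCE: entropy of v's next sample conditioned on u's recent past.

    Both signals are quantized independently into ``n_bins`` uniform levels.
    Mixed patterns take m-1 samples from u followed by one from v:
    CCE(m) = E_mixed(m) - E_u(m-1) + perc(m) * E_v(1).
    """
    u, v = _pair(u, v)
    if m < 2 or n_bins < 2:
        raise InvalidArgumentError("need m >= 2 and n_bins >= 2")
    if u.size < m + 1:
        raise InsufficientLengthError(f"need N >= {m + 1}")

    def quantize(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.size)
        return np.minimum((n_bins * (x - lo) / (hi - lo)).astype(int), n_bins - 1).astype(float)

    qu, qv = quantize(u), quantize(v)
    n = u.size - (m - 1)
    mixed = np.column_stack([_embed(qu, m - 1)[:n], qv[m - 1 : m - 1 + n]])
    _, counts_mixed = np.unique(mixed, axis=0, return_counts=True)
    e_mixed = _shannon(counts_mixed / counts_mixed.sum())

    tu = _embed(qu, m - 1)
    _, counts_u = np.unique(tu, axis=0, return_counts=True)
    e_u = _shannon(counts_u / counts_u.sum())

    _, counts_v1 = np.unique(qv, return_counts=True)
    e_v1 = _shannon(counts_v1 / counts_v1.sum())

    perc = float((counts_mixed == 1).sum() / counts_mixed.sum())
    return e_mixed - e_u + perc * e_v1


def cross_spectral_entropy(u, v) -> float:
    """Normalized entropy of the cross-power spectrum magnitude, DC excluded."""
    u, v = _pair(u, v)
    if u.size < 8:
        raise InsufficientLengthError("need N >= 8")
    if np.all(u == 0) or np.all(v == 0):
        raise InvalidInputError("cross-spectral entropy undefined for all-zero input")
    puv = np.fft.rfft(u) * np.conj(np.fft.rfft(v))
    mag = np.abs(puv)[1:]
    total = mag.sum()
    if total == 0:
        return 0.0
    p = mag / total
    return _shannon(p) / math.log(p.size)
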