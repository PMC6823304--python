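"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or by its
defining formula, deliberately avoiding the package's vectorized code
paths, so the tests compare two independent routes to the same answer.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def episode_oracle(t: np.ndarray, v: np.ndarray, threshold: float,
                   merge_gap_s: float, min_duration_s: float,
                   min_duty: float) -> list[tuple[float, float, int, int]]:
    """Exhaustive episode segmentation by pairwise gap testing.

    Builds a graph over suprathreshold samples linking every pair whose
    time gap is at most the merge gap, takes connected components as
    potential episodes, then applies the duration and duty filters.
    Returns (start_s, end_s, n_samples, n_supra) tuples sorted by start.
    """
    supra = [i for i in range(len(t)) if v[i] >= threshold]
    if not supra:
        return []
    # connected components under |t_i - t_j| <= gap, by label propagation
    labels = {i: i for i in supra}

    def find(i):
        while labels[i] != i:
            labels[i] = labels[labels[i]]
            i = labels[i]
        return i

    for a in supra:
        for b in supra:
            if a < b and abs(t[b] - t[a]) <= merge_gap_s:
                ra, rb = find(a), find(b)
                if ra != rb:
                    labels[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in supra:
        comps.setdefault(find(i), []).append(i)

    out = []
    for members in comps.values():
        start, end = t[min(members)], t[max(members)]
        if end - start < min_duration_s:
            continue
        inside = [i for i in range(len(t)) if start <= t[i] <= end]
        n_supra = len(members)
        if n_supra / len(inside) < min_duty:
            continue
        out.append((float(start), float(end), len(inside), n_supra))
    return sorted(out)


def episode_oracle_pairwise(t: np.ndarray, v: np.ndarray, threshold: float,
                            merge_gap_s: float, min_duration_s: float,
                            min_duty: float) -> list:
    """Same enumeration as :func:`episode_oracle` but with the pairwise
    gap matrix built explicitly and components taken from scipy's graph
    routine, so it scales to thousands of suprathreshold samples."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    supra = np.flatnonzero(v >= threshold)
    if supra.size == 0:
        return []
    ts = t[supra]
    adj = np.abs(ts[:, None] - ts[None, :]) <= merge_gap_s
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    out = []
    for c in range(n_comp):
        members = supra[comp == c]
        start, end = t[members.min()], t[members.max()]
        if end - start < min_duration_s:
            continue
        inside = np.sum((t >= start) & (t <= end))
        if members.size / inside < min_duty:
            continue
        out.append((float(start), float(end), int(inside), int(members.size)))
    return sorted(out)


def apen_oracle(x, m: int, r: float) -> float:
    """ApEn by explicit template-pair counting (self-matches included)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            c = sum(1 for b in templates
                    if max(abs(ai - bi) for ai, bi in zip(a, b)) <= r)
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m: int, r: float) -> float | None:
    """SampEn by explicit pair counting; None where undefined (A or B = 0)."""
    x = list(map(float, x))
    n = len(x)
    tm = [x[i:i + m] for i in range(n - m)]
    tm1 = [x[i:i + m + 1] for i in range(n - m)]

    def pairs(templates) -> int:
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(a - b) for a, b in
                       zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    b, a = pairs(tm), pairs(tm1)
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def dft_power_oracle(x, period_s: float = 60.0,
                     f_max_hz: float = 1.0 / 120.0) -> float:
    """Total band power by direct DFT summation (explicit double loop)."""
    x = list(map(float, x))
    n = len(x)
    total = 0.0
    for k in range(n // 2 + 1):
        if k / (n * period_s) > f_max_hz + 1e-12:
            continue
        coef = sum(x[j] * cmath.exp(-2j * cmath.pi * k * j / n)
                   for j in range(n))
        total += abs(coef) ** 2
    return total


def autocorr_sum_oracle(x, max_lag: int) -> float:
    """Sum of lag-1..max_lag autocorrelations by direct lagged products."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    c0 = sum((xi - mean) ** 2 for xi in x)
    total = 0.0
    for k in range(1, max_lag + 1):
        ck = sum((x[i] - mean) * (x[i + k] - mean) for i in range(n - k))
        total += ck / c0
    return total


def ols_slope_oracle(t_min, values) -> float:
    """OLS slope from the normal equations."""
    t_min = list(map(float, t_min))
    values = list(map(float, values))
    n = len(t_min)
    st, sv = sum(t_min), sum(values)
    stt = sum(ti * ti for ti in t_min)
    stv = sum(ti * vi for ti, vi in zip(t_min, values))
    return (n * stv - st * sv) / (n * stt - st * st)


def auc_oracle(labels, scores) -> float:
    """AUC by exhaustive concordant-pair counting (ties count half)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
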