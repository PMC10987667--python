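"""Independent reference implementations used only to verify the package.

Each oracle takes a deliberately different route from the code it checks:
regular expressions instead of the positional matcher, direct O(n^3)
agglomeration instead of scipy linkage, normal equations instead of the
mean-shift batch fit, and exact hypergeometric point-mass sums instead of
library test functions.
"""

from __future__ import annotations

import math
import re

import numpy as np


# --- motif matching via regular expressions --------------------------------

_TOKEN_RE = re.compile(r"\[[A-Z]+\]\*?|[A-Z]\*?|x\*?")


def motif_regex(pattern_text: str, half_width: int = 15) -> re.Pattern:
    """Compile a consensus motif into a full-window regular expression."""
    tokens = _TOKEN_RE.findall(pattern_text)
    assert "".join(tokens) == pattern_text, f"tokenization gap: {pattern_text}"
    star = next(i for i, t in enumerate(tokens) if t.endswith("*"))
    parts = []
    for i, tok in enumerate(tokens):
        tok = tok.rstrip("*")
        if tok == "x":
            parts.append(".")
        elif tok.startswith("["):
            parts.append(f"[{tok[1:-1]}]")
        else:
            parts.append(f"[{tok}]")
    left_pad = half_width - star
    right_pad = half_width - (len(tokens) - 1 - star)
    assert left_pad >= 0 and right_pad >= 0
    return re.compile("^" + "." * left_pad + "".join(parts)
                      + "." * right_pad + "$")


# --- exact hypergeometric machinery ----------------------------------------

def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> float:
    """Point mass via exact integer combinatorics."""
    if not (max(0, n + K - N) <= k <= min(K, n)):
        return 0.0
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> float:
    return sum(hypergeom_pmf_exact(j, N, K, n)
               for j in range(k, min(K, n) + 1))


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing all point masses not exceeding the
    observed table's, with the customary 1 + 1e-7 tie tolerance."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    obs = hypergeom_pmf_exact(a, N, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
        p = hypergeom_pmf_exact(k, N, r1, c1)
        if p <= obs * (1.0 + 1e-7):
            total += p
    return min(total, 1.0)


# --- Welch t-test from first principles ------------------------------------

def welch_p_reference(a, b) -> float:
    """Welch p via the explicit statistic and the regularized incomplete
    beta function (no use of scipy.stats.ttest_*)."""
    from scipy.special import betainc

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # two-sided p = I_{df/(df+t^2)}(df/2, 1/2)
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


# --- naive ward.D2 agglomeration -------------------------------------------

def ward_d2_naive(X: np.ndarray):
    """O(n^3) Lance-Williams agglomeration with ward.D2 semantics.

    Returns (merges, heights, partitions) where merges is a list of
    (cluster_a, cluster_b) index pairs in scipy numbering, heights the
    un-squared merge distances, and partitions a dict k -> list of
    frozensets of original indices for every cut level.
    """
    n = len(X)
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())
    active = {i: (frozenset([i]), 1) for i in range(n)}  # id -> (members, size)
    next_id = n
    merges, heights = [], []
    partitions = {n: [frozenset([i]) for i in range(n)]}
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = (min(i, j), max(i, j))
                if best is None or d2[key] < best[0] - 1e-15:
                    best = (d2[key], i, j)
        h2, i, j = best
        mi, ni = active[i]
        mj, nj = active[j]
        merged = mi | mj
        merges.append((i, j))
        heights.append(math.sqrt(max(h2, 0.0)))
        del active[i], active[j]
        for k in list(active):
            nk = active[k][1]
            dik = d2[(min(i, k), max(i, k))]
            djk = d2[(min(j, k), max(j, k))]
            dij = h2
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (
                ni + nj + nk)
            d2[(min(next_id, k), max(next_id, k))] = new
        active[next_id] = (merged, ni + nj)
        next_id += 1
        partitions[len(active)] = [m for m, _ in active.values()]
    return merges, heights, partitions


# --- least-squares batch fit -----------------------------------------------

def batch_fit_reference(y: np.ndarray, batches: np.ndarray) -> np.ndarray:
    """Remove batch-mean differences from one feature's (complete) profile
    by an explicit least-squares fit of intercept + batch indicators with
    sum-to-zero coding, reconstructing intercept + residual."""
    levels = sorted(set(batches))
    n = len(y)
    # sum-to-zero coding: one column per non-last level
    Xd = np.ones((n, len(levels)))
    for c, lev in enumerate(levels[:-1]):
        Xd[:, c + 1] = np.where(
            batches == lev, 1.0, np.where(batches == levels[-1], -1.0, 0.0))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted_batch = Xd[:, 1:] @ beta[1:]
    return y - fitted_batch
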