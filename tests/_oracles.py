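"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is deliberately naive (exact rational arithmetic, explicit
pairwise loops, full eigendecompositions) and shares no code with the package
paths it checks.
"""

from fractions import Fraction
from math import comb, factorial

import numpy as np


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic.

    P(h het | n, allele counts) = n! / (n_hr! h! n_hc!) * 2^h / C(2n, n_rare)
    summed over all heterozygote counts h of the observed parity whose
    probability does not exceed the observed table's.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    probs = {}
    total = Fraction(0)
    for h in range(n_rare % 2, n_rare + 1, 2):
        n_hr = (n_rare - h) // 2
        n_hc = n - h - n_hr
        num = Fraction(
            Fraction(factorial(n), factorial(n_hr))
            / factorial(h)
            / factorial(n_hc)
        ) * Fraction(2) ** h
        probs[h] = num
        total += num
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hwe_support_probabilities(n_AA: int, n_Aa: int, n_aa: int):
    """The full conditional distribution over heterozygote counts (exact)."""
    n = n_AA + n_Aa + n_aa
    n_rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    probs = []
    total = Fraction(0)
    for h in range(n_rare % 2, n_rare + 1, 2):
        n_hr = (n_rare - h) // 2
        n_hc = n - h - n_hr
        num = Fraction(factorial(n)) / (
            factorial(n_hr) * factorial(h) * factorial(n_hc)
        ) * Fraction(2) ** h
        probs.append(num)
        total += num
    return [p / total for p in probs]


def auc_pairwise(scores, y) -> float:
    """AUC by explicit enumeration of all case/control pairs (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    cases = scores[y == 1]
    ctrls = scores[y == 0]
    wins = 0.0
    for c in cases:
        for d in ctrls:
            if c > d:
                wins += 1.0
            elif c == d:
                wins += 0.5
    return wins / (len(cases) * len(ctrls))


def pearson_r2(a, b) -> float:
    """Squared Pearson correlation straight from the definition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am @ bm) ** 2 / ((am @ am) * (bm @ bm)))


def clump_greedy(p_values, positions, chroms, r2, r2_max, window_bp, se=None):
    """Reference greedy clumping with explicit loops.

    ``r2`` is a dense pairwise matrix. Returns the sorted list of retained
    (original-order) indices.
    """
    m = len(p_values)
    se = np.zeros(m) if se is None else np.asarray(se)
    order = sorted(range(m), key=lambda i: (p_values[i], se[i], positions[i]))
    assigned = [False] * m
    kept = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        kept.append(i)
        for j in range(m):
            if assigned[j] or chroms[j] != chroms[i]:
                continue
            if abs(positions[j] - positions[i]) <= window_bp and r2[i][j] > r2_max:
                assigned[j] = True
    return sorted(kept)


def log_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """ln(ad / bc) for a 2x2 table [[a, b], [c, d]]."""
    return float(np.log((a * d) / (b * c)))


def pca_dense(dosage) -> tuple:
    """PCs of a standardized dosage matrix via a full eigendecomposition of
    the sample-sample covariance (independent of the SVD route)."""
    X = np.asarray(dosage, dtype=float)
    cols = []
    for j in range(X.shape[1]):
        col = X[:, j]
        mean = np.nanmean(col)
        col = np.where(np.isnan(col), mean, col)
        p = mean / 2.0
        var = 2 * p * (1 - p)
        if var <= 0:
            continue
        cols.append((col - 2 * p) / np.sqrt(var))
    Z = np.column_stack(cols)
    C = Z @ Z.T
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pcs = evecs * np.sqrt(np.maximum(evals, 0))[None, :]
    for c in range(pcs.shape[1]):
        imax = np.argmax(np.abs(pcs[:, c]))
        if pcs[imax, c] < 0:
            pcs[:, c] = -pcs[:, c]
    return pcs, evals
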