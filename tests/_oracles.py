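"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from first principles (explicit
loops, explicit sums, special-function p-values) and stays independent of
the code paths it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betainc


def brute_signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance from the mask edge by exhaustive scan."""
    mask = np.asarray(mask, dtype=bool)
    ins = np.argwhere(mask)
    outs = np.argwhere(~mask)
    d = np.zeros(mask.shape, dtype=float)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c]:
                diffs = outs - (r, c)
                d[r, c] = -math.sqrt((diffs**2).sum(axis=1).min())
            else:
                diffs = ins - (r, c)
                d[r, c] = math.sqrt((diffs**2).sum(axis=1).min())
    return d


def brute_regions(tumour: np.ndarray, fibro: np.ndarray) -> dict[str, np.ndarray]:
    d = brute_signed_distance(tumour)
    return {
        "S_I": d <= -2,
        "S_T": np.asarray(tumour, dtype=bool),
        "S_B": (d >= -2) & (d <= 2),
        "S_P": (d > 2) & (d <= 6) & fibro,
        "S_M": (d > 6) & (d <= 10) & fibro,
        "S_D": (d > 10) & (d <= 14) & fibro,
    }


def brute_stats(values: np.ndarray) -> dict[str, float]:
    """The eight histogram statistics via explicit sums and sorting."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n

    def quantile(q: float) -> float:
        # linear interpolation between order statistics (type 7)
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return {
        "mean": mean,
        "min": x[0],
        "max": x[-1],
        "variance": sum((v - mean) ** 2 for v in x) / (n - 1) if n > 1 else 0.0,
        "iqr": quantile(0.75) - quantile(0.25),
        "range": x[-1] - x[0],
        "skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "kurtosis": m4 / m2**2 - 3 if m2 > 0 else 0.0,
    }


def brute_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p via the regularised incomplete beta."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, 0.0
    df = n - 2
    # |t| = |r| sqrt(df / (1 - r^2)); two-sided p = I_{df/(df+t^2)}(df/2, 1/2)
    t2 = r * r * df / (1 - r * r)
    p = betainc(df / 2.0, 0.5, df / (df + t2))
    return r, float(p)


def brute_auc(labels, scores) -> float:
    """Exhaustive pairwise concordance AUC, ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_youden(scores, labels) -> tuple[float, float, float]:
    """Exhaustive Youden scan over midpoints of consecutive distinct scores."""
    distinct = sorted(set(float(s) for s in scores))
    if len(distinct) == 1:
        return distinct[0], 1.0, 0.0
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        t = (a + b) / 2
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= t)
        fn = sum(1 for s, l in zip(scores, labels) if l and s < t)
        tn = sum(1 for s, l in zip(scores, labels) if not l and s < t)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= t)
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-15:
            best = (j, t, sens, spec)
    return best[1], best[2], best[3]


def brute_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p from explicit sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    # p = P(F_{dfb,dfw} > f) via the incomplete beta
    p = betainc(dfw / 2.0, dfb / 2.0, dfw / (dfw + dfb * f))
    return f, float(p)


def brute_fcm(values: np.ndarray, n_clusters: int, m: float, seed: int,
              tol: float = 1e-5, max_iter: int = 300) -> np.ndarray:
    """Loop-based fuzzy C-means sharing only the documented initialisation."""
    x = [float(v) for v in np.asarray(values).ravel()]
    n = len(x)
    rng = np.random.default_rng(seed)
    u = rng.random((n, n_clusters))
    u = [[u[i, k] / u[i].sum() for k in range(n_clusters)] for i in range(n)]
    prev = float("inf")
    centroids = [0.0] * n_clusters
    for _ in range(max_iter):
        for k in range(n_clusters):
            num = sum(u[i][k] ** m * x[i] for i in range(n))
            den = sum(u[i][k] ** m for i in range(n))
            centroids[k] = num / den
        obj = sum(
            u[i][k] ** m * (x[i] - centroids[k]) ** 2
            for i in range(n)
            for k in range(n_clusters)
        )
        for i in range(n):
            d2 = [max((x[i] - c) ** 2, 1e-300) for c in centroids]
            inv = [d ** (-1.0 / (m - 1.0)) for d in d2]
            s = sum(inv)
            u[i] = [v / s for v in inv]
        if prev - obj < tol:
            break
        prev = obj
    return np.array(centroids)
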