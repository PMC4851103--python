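"""Naive reference implementations used as independent oracles in tests.

Everything here is deliberately written as literal loops over definitions,
independent of the package's vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np


def brute_window_count(T: int, L_w: int, d: int) -> int:
    """Count window placements by explicitly sliding until overflow."""
    n = 0
    start = 0
    while start + L_w <= T:
        n += 1
        start += d
    return n


def naive_sdbw(X: np.ndarray, labels: np.ndarray,
               variant: str = "printed") -> tuple[float, float]:
    """Term-by-term S_Dbw: returns (Scat, Dens_bw)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    ks = sorted(set(labels.tolist()))
    k = len(ks)

    def var_vec(pts):
        mu = pts.mean(axis=0)
        return np.array([np.mean((pts[:, j] - mu[j]) ** 2)
                         for j in range(pts.shape[1])])

    sigma_ds = var_vec(X)
    groups = [X[labels == lab] for lab in ks]
    norms = [math.sqrt(float(np.sum(var_vec(g) ** 2))) for g in groups]
    scat = sum(n / math.sqrt(float(np.sum(sigma_ds ** 2))) for n in norms) / k

    total = sum(norms)
    if variant == "printed":
        radius = math.sqrt(total) / k
    else:
        radius = math.sqrt(total / k)

    def density(points, center):
        c = 0
        for p in points:
            if math.dist(p.tolist(), center.tolist()) <= radius:
                c += 1
        return c

    centers = [g.mean(axis=0) for g in groups]
    own = [density(groups[i], centers[i]) for i in range(k)]
    acc = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            mx = max(own[i], own[j])
            if mx == 0:
                continue
            mid = (centers[i] + centers[j]) / 2.0
            union = np.vstack([groups[i], groups[j]])
            acc += density(union, mid) / mx
    dens = acc / (k * (k - 1))
    return scat, dens


def naive_pearson(x, t) -> float:
    """The cophenetic-correlation formula evaluated term by term."""
    x = list(map(float, x))
    t = list(map(float, t))
    xb = sum(x) / len(x)
    tb = sum(t) / len(t)
    num = sum((a - xb) * (b - tb) for a, b in zip(x, t))
    den = math.sqrt(sum((a - xb) ** 2 for a in x)
                    * sum((b - tb) ** 2 for b in t))
    return num / den


def naive_nmi(a, b) -> float:
    """NMI from the entropy definitions with a geometric-mean normalizer."""
    a = list(a)
    b = list(b)
    n = len(a)
    la, lb = sorted(set(a)), sorted(set(b))
    cont = {(x, y): 0 for x in la for y in lb}
    for x, y in zip(a, b):
        cont[(x, y)] += 1

    def H(labels, alphabet):
        h = 0.0
        for s in alphabet:
            p = labels.count(s) / n
            if p > 0:
                h -= p * math.log(p)
        return h

    ha, hb = H(a, la), H(b, lb)
    if ha == 0 or hb == 0:
        return 0.0
    mi = 0.0
    for x in la:
        px = a.count(x) / n
        for y in lb:
            pxy = cont[(x, y)] / n
            py = b.count(y) / n
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    return mi / math.sqrt(ha * hb)


def naive_runs(labels) -> list[tuple]:
    """Maximal constant runs by a left-to-right scan (1-based)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start + 1, i))
            start = i
    return runs


def random_clustering(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random labels 1..k with every cluster guaranteed non-empty."""
    labels = rng.integers(1, k + 1, size=n)
    # force one member per cluster
    idx = rng.choice(n, size=k, replace=False)
    labels[idx] = np.arange(1, k + 1)
    return labels
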