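"""Independent straight-from-definition oracles used by the test suite.

Everything here is deliberately written as plain transcriptions of the
definitions (loops, elementary formulas), independent of the package
implementation paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np


def first_order_oracle(values, voxel_volume_mm3: float, bin_width: float) -> dict:
    """The 18 first-order features computed by literal transcription."""
    x = [float(v) for v in np.asarray(values).ravel()]
    n = len(x)
    mean = sum(x) / n
    xs = sorted(x)

    def percentile(q):
        # linear interpolation between order statistics
        pos = (n - 1) * q / 100.0
        lo = math.floor(pos)
        hi = math.ceil(pos)
        if lo == hi:
            return xs[lo]
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    p10, q25, med, q75, p90 = (percentile(q) for q in (10, 25, 50, 75, 90))
    var = sum((v - mean) ** 2 for v in x) / n
    mad = sum(abs(v - mean) for v in x) / n
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    rmad = sum(abs(v - rmean) for v in robust) / len(robust)
    energy = sum(v * v for v in x)
    rms = math.sqrt(energy / n)
    if var > 0:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        skew = m3 / var**1.5
        kurt = m4 / var**2
    else:
        skew, kurt = 0.0, 0.0
    xmin = min(x)
    counts: dict[int, int] = {}
    for v in x:
        b = math.floor((v - xmin) / bin_width)
        counts[b] = counts.get(b, 0) + 1
    probs = [c / n for c in counts.values()]
    entropy = -sum(p * math.log2(p) for p in probs)
    uniformity = sum(p * p for p in probs)
    return {
        "mean": mean,
        "median": med,
        "p10": p10,
        "p90": p90,
        "min": min(x),
        "max": max(x),
        "iqr": q75 - q25,
        "range": max(x) - min(x),
        "variance": var,
        "mad": mad,
        "rmad": rmad,
        "rms": rms,
        "energy": energy,
        "total_energy": voxel_volume_mm3 * energy,
        "entropy": entropy,
        "skewness": skew,
        "kurtosis": kurt,
        "uniformity": uniformity,
    }


def auc_pair_counting(scores, labels) -> float:
    """Empirical AUC by exhaustive concordant-pair counting (ties half-weight)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels) -> tuple[float, float, float]:
    """Best (cutoff, sens, spec) over all midpoints; ties -> higher spec/cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    u = sorted(set(s.tolist()))
    best = None
    for lo, hi in zip(u[:-1], u[1:]):
        t = 0.5 * (lo + hi)
        sens = float(np.mean(s[y] > t))
        spec = float(np.mean(s[~y] <= t))
        key = (sens + spec - 1.0, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


def disc_search_exhaustive(volume, mask, slice_index: int, radius_mm: float):
    """Minimal-mean fully-in-mask disc by brute-force center enumeration."""
    sx, sy = volume.spacing_mm[0], volume.spacing_mm[1]
    sl = volume.voxels[:, :, slice_index]
    msk = mask[:, :, slice_index]
    nrow, ncol = sl.shape
    best = None
    for r in range(nrow):
        for c in range(ncol):
            if not msk[r, c]:
                continue
            members = []
            ok = True
            rr = int(radius_mm / sx) + 1
            cc = int(radius_mm / sy) + 1
            for i in range(r - rr, r + rr + 1):
                for j in range(c - cc, c + cc + 1):
                    if ((i - r) * sx) ** 2 + ((j - c) * sy) ** 2 <= radius_mm**2:
                        if i < 0 or j < 0 or i >= nrow or j >= ncol or not msk[i, j]:
                            ok = False
                            break
                        members.append(sl[i, j])
                if not ok:
                    break
            if not ok:
                continue
            mean = float(np.mean(members))
            key = (mean, r, c)
            if best is None or key < best[0]:
                best = (key, mean, (r, c))
    if best is None:
        return None
    return best[1], best[2]  # (mean, (row, col))


def linear_weighted_kappa(a, b, categories) -> float:
    """Hand-computed linear-weight kappa from the contingency table."""
    k = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    n = len(a)
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[index[x], index[y]] += 1
    obs /= n
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    w = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            w[i, j] = abs(i - j) / (k - 1)
    po = float(np.sum(w * obs))
    pe = float(np.sum(w * np.outer(row, col)))
    return 1.0 - po / pe
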