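"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (python loops, direct formula
transcription) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


# -- histogram thresholds ----------------------------------------------------


def quantize(plane, n_bins):
    plane = np.asarray(plane, dtype=float)
    lo, hi = plane.min(), plane.max()
    q = np.floor((plane - lo) / (hi - lo) * n_bins).astype(int)
    return np.minimum(q, n_bins - 1), lo, hi


def otsu_bruteforce(plane, n_bins=256):
    """Exhaustive search over all candidate thresholds, first maximum wins."""
    q, lo, hi = quantize(plane, n_bins)
    hist = np.bincount(q.ravel(), minlength=n_bins)
    total = hist.sum()
    best_sigma, best_k = -1.0, None
    for k in range(n_bins):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(i * hist[i] for i in range(k + 1)) / w0
        m1 = sum(i * hist[i] for i in range(k + 1, n_bins)) / w1
        sigma = w0 * w1 * (m0 - m1) ** 2
        if sigma > best_sigma:
            best_sigma, best_k = sigma, k
    mask = q > best_k
    threshold = lo + (best_k + 1) * (hi - lo) / n_bins
    return threshold, mask


def multi_otsu_bruteforce(plane, classes=3, n_bins=32):
    """All (n_bins choose classes-1) cut combinations, maximizing sum w*mu^2."""
    from itertools import combinations

    q, _, _ = quantize(plane, n_bins)
    hist = np.bincount(q.ravel(), minlength=n_bins)

    def wmu2(a, b):
        w = hist[a : b + 1].sum()
        if w == 0:
            return None
        mu = sum(i * hist[i] for i in range(a, b + 1)) / w
        return w * mu * mu

    best_score, best_cuts = -1.0, None
    for cuts in combinations(range(n_bins - 1), classes - 1):
        score, prev, ok = 0.0, 0, True
        for c in cuts:
            s = wmu2(prev, c)
            if s is None:
                ok = False
                break
            score += s
            prev = c + 1
        if not ok:
            continue
        s = wmu2(prev, n_bins - 1)
        if s is None:
            continue
        score += s
        if score > best_score:
            best_score, best_cuts = score, cuts
    return q > best_cuts[-1]  # top-class foreground mask


def local_threshold_naive(plane, block, offset=0.0):
    """Sliding-window mean with mirror padding, python loops."""
    plane = np.asarray(plane, dtype=float)
    r = block // 2
    padded = np.pad(plane, r, mode="symmetric")  # edge-repeating mirror
    out = np.zeros(plane.shape, dtype=bool)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            window = padded[i : i + block, j : j + block]
            out[i, j] = plane[i, j] > (window.mean() + offset)
    return out


# -- mask algebra ------------------------------------------------------------


def majority_vote_naive(masks):
    masks = [np.asarray(m, bool) for m in masks]
    out = np.zeros(masks[0].shape, dtype=bool)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            votes = sum(int(m[i, j]) for m in masks)
            out[i, j] = votes > len(masks) / 2
    return out


def and_by_coordinates(mask_a, mask_b):
    coords_a = {tuple(p) for p in np.argwhere(mask_a)}
    coords_b = {tuple(p) for p in np.argwhere(mask_b)}
    out = np.zeros(np.asarray(mask_a).shape, dtype=bool)
    for r, c in coords_a & coords_b:
        out[r, c] = True
    return out


def label_8connected_naive(mask):
    """BFS connected-component labeling, 8-connectivity."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels, current


def filter_small_naive(mask, min_area):
    labels, n = label_8connected_naive(mask)
    out = np.zeros(np.asarray(mask).shape, dtype=bool)
    kept = 0
    for lab in range(1, n + 1):
        area = int((labels == lab).sum())
        if area >= min_area:
            out |= labels == lab
            kept += 1
    return out, kept


def gaussian_kernel_convolve(plane, sigma, truncate=4.0):
    """Direct 2-D Gaussian kernel convolution (reflect boundary)."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(np.asarray(plane, float), radius, mode="reflect")
    out = np.zeros_like(np.asarray(plane, float))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            out[i, j] = (
                padded[i : i + 2 * radius + 1, j : j + 2 * radius + 1] * kernel
            ).sum()
    return out


# -- statistics --------------------------------------------------------------


def midranks(values):
    """Mid-rank computation by explicit sorting and tie averaging."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_wallis_oracle(groups):
    """Tie-corrected H via direct transcription of the rank-sum formula."""
    labels = list(groups)
    pooled = [x for k in labels for x in groups[k]]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for k in labels:
        m = len(groups[k])
        r = sum(ranks[start : start + m])
        h += r * r / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in ties.values())
    denom = 1 - tie_term / (n**3 - n)
    return 0.0 if denom == 0 else h / denom


def conover_oracle(groups):
    """Step-by-step Conover-Iman pairwise p-values (no adjustment)."""
    from scipy.stats import t as tdist

    labels = list(groups)
    pooled = [x for k in labels for x in groups[k]]
    n = len(pooled)
    k = len(labels)
    ranks = midranks(pooled)
    rank_by_group = {}
    start = 0
    for lab in labels:
        m = len(groups[lab])
        rank_by_group[lab] = ranks[start : start + m]
        start += m
    h = kruskal_wallis_oracle(groups)
    s2 = (sum(r * r for r in ranks) - n * (n + 1) ** 2 / 4) / (n - 1)
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            na, nb = len(rank_by_group[a]), len(rank_by_group[b])
            mean_a = sum(rank_by_group[a]) / na
            mean_b = sum(rank_by_group[b]) / nb
            denom = (s2 * (n - 1 - h) / (n - k) * (1 / na + 1 / nb)) ** 0.5
            t = (mean_a - mean_b) / denom
            out[(a, b)] = 2 * tdist.sf(abs(t), n - k)
    return out


def welch_oracle(x, y):
    """Closed-form Welch statistic evaluated in extended precision."""
    x = np.asarray(x, dtype=np.longdouble)
    y = np.asarray(y, dtype=np.longdouble)
    nx, ny = len(x), len(y)
    vx = ((x - x.mean()) ** 2).sum() / (nx - 1)
    vy = ((y - y.mean()) ** 2).sum() / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(float(t)), float(df))
    return float(t), float(df), float(p)
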