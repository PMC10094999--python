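"""Independent brute-force reference implementations used by the test suite.

Everything here is written as directly as possible (explicit loops, set
algebra, exhaustive enumeration) and stays independent of the library code it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# adaptive binarization / morphology


def naive_gaussian_binarize(image: np.ndarray, kernel: int, sigma: float,
                            offset: float = 0.0) -> np.ndarray:
    """Per-pixel Gaussian-weighted local mean via explicit window arithmetic.

    Weights: normalized 2-D Gaussian sampled on the exact kernel x kernel
    window; border handled by symmetric (edge-duplicating) padding.
    """
    image = np.asarray(image, dtype=float)
    r = kernel // 2
    ax = np.arange(-r, r + 1, dtype=float)
    w1 = np.exp(-0.5 * (ax / sigma) ** 2)
    w2 = np.outer(w1, w1)
    w2 = w2 / w2.sum()
    padded = np.pad(image, r, mode="symmetric")
    out = np.zeros(image.shape, dtype=bool)
    H, W = image.shape
    for y in range(H):
        for x in range(W):
            win = padded[y:y + kernel, x:x + kernel]
            out[y, x] = image[y, x] > (win * w2).sum() + offset
    return out


def naive_opening_square(mask: np.ndarray, f: int) -> np.ndarray:
    """Opening as the union of all f x f square translates contained in the
    mask (set definition; origin-free)."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    out = np.zeros_like(mask)
    for y in range(H - f + 1):
        for x in range(W - f + 1):
            if mask[y:y + f, x:x + f].all():
                out[y:y + f, x:x + f] = True
    return out


def naive_label_4(mask: np.ndarray) -> list[set]:
    """Exhaustive 4-connected component labeling by flood fill."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for y in range(H):
        for x in range(W):
            if mask[y, x] and not seen[y, x]:
                comp = set()
                stack = [(y, x)]
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    comp.add((cy, cx))
                    for ny, nx in ((cy - 1, cx), (cy + 1, cx), (cy, cx - 1), (cy, cx + 1)):
                        if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def naive_area_open(mask: np.ndarray, min_area: int) -> np.ndarray:
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in naive_label_4(mask):
        if len(comp) >= min_area:
            for y, x in comp:
                out[y, x] = True
    return out


def naive_clean(mask: np.ndarray, footprint: int, min_area: int) -> np.ndarray:
    return naive_area_open(naive_opening_square(mask, footprint), min_area)


def naive_roi_pipeline(post_stack: np.ndarray) -> np.ndarray:
    """The six detection steps composed naively; returns the final binary
    image (before component labeling)."""
    masks = [naive_clean(naive_gaussian_binarize(frame, 9, 1.5), 2, 15)
             for frame in post_stack]
    occupancy = np.mean(np.stack(masks).astype(float), axis=0)
    avg_bin = naive_gaussian_binarize(occupancy, 9, 2.5)
    return naive_clean(avg_bin, 3, 15)


# ---------------------------------------------------------------------------
# traces


def naive_bin_means(values, times, width_s, k_lo, n_bins):
    """Membership-test bin means on [k*width, (k+1)*width) bins."""
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for v, t in zip(values, times):
        for k in range(k_lo, k_lo + n_bins):
            if k * width_s - 1e-9 <= t < (k + 1) * width_s - 1e-9:
                sums[k - k_lo] += v
                counts[k - k_lo] += 1
                break
    with np.errstate(invalid="ignore"):
        return sums / counts, counts


def naive_peak_scan(values: np.ndarray, k_sd: float = 2.0):
    """Threshold-crossing run scan: one peak per maximal run strictly above
    mean + k_sd * SD, at the index of the run maximum."""
    values = np.asarray(values, dtype=float)
    thr = values.mean() + k_sd * values.std()
    idx = []
    in_run = False
    run_start = 0
    for i, v in enumerate(values):
        if v > thr and not in_run:
            in_run, run_start = True, i
        elif v <= thr and in_run:
            seg = values[run_start:i]
            idx.append(run_start + int(np.argmax(seg)))
            in_run = False
    if in_run:
        seg = values[run_start:]
        idx.append(run_start + int(np.argmax(seg)))
    return np.array(idx, dtype=int), thr


# ---------------------------------------------------------------------------
# statistics


def mw_u_statistic(a, b) -> float:
    """U of sample a by direct pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def naive_mw_exact_p(a, b) -> float:
    """Two-sided exact p by enumerating every assignment of the pooled values
    to the two groups (valid without ties)."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    u_obs = mw_u_statistic(a, b)
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(n) if i not in comb]
        us.append(mw_u_statistic(ga, gb))
    us = np.array(us)
    mu = n1 * (n - n1) / 2.0
    # two-sided: as or more extreme in distance from the null mean
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))


def naive_spearman_rho(x, y) -> float:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def naive_t_unpaired(x, y):
    """Classic pooled-variance Student t and two-sided p (textbook formulas)."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    s2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (y.mean() - x.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


def naive_t_paired(x, y):
    from scipy.stats import t as tdist

    d = np.asarray(y, float) - np.asarray(x, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p
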