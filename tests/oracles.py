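"""Independent brute-force reference implementations used to validate features.

Everything here is written as plain Python loops against the feature
definitions, deliberately sharing no code with the package implementation.
"""

import math


def periodogram_oracle(x, rate):
    """One-sided mean-removed periodogram (density scaling) by direct DFT."""
    n = len(x)
    mean = sum(x) / n
    xc = [v - mean for v in x]
    n_freq = n // 2 + 1
    freqs, power = [], []
    for k in range(n_freq):
        re = sum(xc[m] * math.cos(-2 * math.pi * k * m / n) for m in range(n))
        im = sum(xc[m] * math.sin(-2 * math.pi * k * m / n) for m in range(n))
        p = (re * re + im * im) / (rate * n)
        if 0 < k < (n + 1) // 2 or (n % 2 == 1 and k == n // 2):
            p *= 2.0
        freqs.append(k * rate / n)
        power.append(p)
    return freqs, power


def spectral_oracle(freqs, power):
    best = max(power)
    worst = min(power)
    # ties break toward the lowest frequency
    i_max = min(i for i in range(len(power)) if power[i] == best)
    i_min = min(i for i in range(len(power)) if power[i] == worst)
    return freqs[i_max], freqs[i_min], freqs[i_max] - freqs[i_min], power[i_max], power[i_min]


def amplitude_oracle(x):
    v_max = max(x)
    v_min = min(x)
    n = len(x)
    rms = math.sqrt(sum(v * v for v in x) / n)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    return v_max, v_min, v_max - v_min, rms, var


def morphology_oracle(x, per_sample):
    ssc = sum(
        1
        for k in range(1, len(x) - 1)
        if (x[k] - x[k - 1]) * (x[k + 1] - x[k]) < 0
    )
    zc = sum(1 for k in range(len(x) - 1) if x[k] * x[k + 1] < 0)
    wfl = sum(abs(x[k + 1] - x[k]) for k in range(len(x) - 1))
    if per_sample:
        n = len(x)
        return ssc / n, zc / n, wfl / n
    return float(ssc), float(zc), float(wfl)


def auc_oracle(x, per_sample):
    total = sum((abs(x[k]) + abs(x[k + 1])) / 2.0 for k in range(len(x) - 1))
    return total / len(x) if per_sample else total


def trace_oracle(positions):
    total = 0.0
    for k in range(len(positions) - 1):
        total += math.dist(positions[k], positions[k + 1])
    return total


def poc_oracle(y, hysteresis):
    """Zigzag reversal count via greedy swing extraction (plain loops)."""
    direction = 0
    hi = lo = y[0]
    ref = y[0]
    count = 0
    for v in y[1:]:
        if direction == 0:
            hi = max(hi, v)
            lo = min(lo, v)
            if hi - v >= hysteresis:
                direction, ref = -1, v
            elif v - lo >= hysteresis:
                direction, ref = 1, v
        elif direction == 1:
            if v > ref:
                ref = v
            elif ref - v >= hysteresis:
                direction, ref = -1, v
                count += 1
        else:
            if v < ref:
                ref = v
            elif v - ref >= hysteresis:
                direction, ref = 1, v
                count += 1
    return count


def angle_oracle(child, parent, axis):
    """Per-frame angles (degrees) between segment and axis; skips degenerate frames."""
    angles = []
    for c, p, a in zip(child, parent, axis):
        seg = [ci - pi for ci, pi in zip(c, p)]
        ns = math.sqrt(sum(v * v for v in seg))
        na = math.sqrt(sum(v * v for v in a))
        if ns < 1e-9 or na < 1e-9:
            continue
        cosang = sum(s * v for s, v in zip(seg, a)) / (ns * na)
        cosang = max(-1.0, min(1.0, cosang))
        angles.append(math.degrees(math.acos(cosang)))
    return angles


def median_pairs_oracle(a, b):
    """Median of all pairwise absolute differences by full enumeration."""
    d = sorted(abs(x - y) for x in a for y in b)
    n = len(d)
    if n % 2 == 1:
        return d[n // 2]
    return (d[n // 2 - 1] + d[n // 2]) / 2.0


def gg_epsilon_eigen_oracle(M):
    """Greenhouse-Geisser epsilon from the eigenvalues of M = C S C'."""
    import numpy as np

    lam = np.linalg.eigvalsh(M)
    k1 = M.shape[0]
    return float(lam.sum() ** 2 / (k1 * (lam**2).sum()))
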