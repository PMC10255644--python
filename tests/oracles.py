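"""Naive loop-based oracle implementations used only to check the package.

Everything here is written with plain Python loops, ``math`` and explicit
DFT sums, deliberately independent of the vectorized implementations under
test.
"""

from __future__ import annotations

import cmath
import math


def oracle_axis_features(s, sf):
    """The 13 single-axis statistics, computed the slow explicit way."""
    n = len(s)
    mean = sum(s) / n
    c = [v - mean for v in s]
    m2 = sum(v**2 for v in c) / n
    sd = math.sqrt(m2)
    if m2 > 0:
        skew = (sum(v**3 for v in c) / n) / m2**1.5
        kurt = (sum(v**4 for v in c) / n) / m2**2 - 3.0
    else:
        skew = kurt = 0.0
    q1 = _quantile(sorted(s), 0.25)
    q3 = _quantile(sorted(s), 0.75)
    mad = sum(abs(v) for v in c) / n
    med = _quantile(sorted(s), 0.5)
    medad = _quantile(sorted(abs(v - med) for v in s), 0.5)
    mcrs = 0
    for a, b in zip(c, c[1:]):
        if (a >= 0) != (b >= 0):
            mcrs += 1
    # explicit one-sided DFT of the centered signal, bins 1..n//2
    mags = []
    for k in range(1, n // 2 + 1):
        xk = sum(c[j] * cmath.exp(-2j * math.pi * k * j / n) for j in range(n))
        mags.append(abs(xk))
    total = sum(m**2 for m in mags)
    engy = total / n
    if total > 0:
        ps = [m**2 / total for m in mags]
        entr = -sum(p * math.log(p) for p in ps if p > 0)
        best = max(range(len(mags)), key=lambda i: (mags[i], -i))
        # ties -> lowest bin: max() returns the first maximal element anyway
        for i, m in enumerate(mags):
            if m == mags[best]:
                best = i
                break
        domif = (best + 1) * sf / n
    else:
        entr = 0.0
        domif = 0.0
    return {
        "MIN": min(s), "MAX": max(s), "MEAN": mean, "SD": sd,
        "SKEW": skew, "KURT": kurt, "IQR": q3 - q1, "MAD": mad,
        "MedAD": medad, "MCRS": float(mcrs), "ENGY": engy,
        "ENTR": entr, "DOMIF": domif,
    }


def _quantile(sorted_vals, q):
    """Linear-interpolation quantile of pre-sorted values."""
    n = len(sorted_vals)
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def oracle_pearson(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    ca = [v - ma for v in a]
    cb = [v - mb for v in b]
    va = sum(v**2 for v in ca) / n
    vb = sum(v**2 for v in cb) / n
    if va == 0 or vb == 0:
        return 0.0
    return sum(x * y for x, y in zip(ca, cb)) / n / math.sqrt(va * vb)


def oracle_metrics(counts):
    """Per-class precision/recall/F1 from a square count matrix (lists)."""
    k = len(counts)
    prec, rec, f1 = [], [], []
    for i in range(k):
        n_pred = sum(counts[r][i] for r in range(k))
        n_test = sum(counts[i])
        n_corr = counts[i][i]
        p = n_corr / n_pred if n_pred > 0 else 0.0
        r = n_corr / n_test if n_test > 0 else 0.0
        f = 2 / (1 / p + 1 / r) if p > 0 and r > 0 else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(f)
    return prec, rec, f1
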