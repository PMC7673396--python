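"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: the lag
search is an explicit loop over every candidate shift with the textbook
Pearson formula written out, so it can serve as an independent check of
the production implementation.
"""

import numpy as np
import scipy.signal


def trig_upsample(x, factor):
    """Band-limited interpolation onto a factor-times finer grid."""
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    n = len(x)
    u = scipy.signal.resample(x, factor * n)[: factor * (n - 1) + 1]
    u[::factor] = x
    return u


def textbook_pearson(a, b):
    """Pearson r from the definitional sums."""
    n = len(a)
    ma = a.sum() / n
    mb = b.sum() / n
    num = ((a - ma) * (b - mb)).sum()
    da = ((a - ma) ** 2).sum()
    db = ((b - mb) ** 2).sum()
    return num / np.sqrt(da * db)


def brute_force_lag(x, y, tr, search_halfwidth, factor=4,
                    min_overlap_frac=0.8):
    """Enumerate every shift; best positive r wins.

    Tie-break mirrors the stated rule: smallest |lag| first, negative
    before positive at equal |lag|, strict improvement required.
    Positive lag means x occurs later than y.
    """
    xu = trig_upsample(x, factor)
    yu = trig_upsample(y, factor)
    n = len(xu)
    step = tr / factor
    k_max = int(np.floor(search_halfwidth / step + 1e-9))
    k_max = min(k_max, int(np.floor((1.0 - min_overlap_frac) * n)))
    order = [0]
    for k in range(1, k_max + 1):
        order.extend([-k, k])
    best_lag, best_r = float("nan"), -np.inf
    for k in order:
        if k >= 0:
            a, b = xu[k:], yu[: n - k]
        else:
            a, b = xu[: n + k], yu[-k:]
        r = textbook_pearson(a, b)
        if r > 0 and r > best_r:
            best_lag, best_r = k * step, r
    if not np.isfinite(best_r) or best_r <= 0:
        return float("nan"), float("nan")
    return best_lag, best_r
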