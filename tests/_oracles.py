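"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_bh(p, q):
    """Literal Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    adj_sorted = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, reject
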