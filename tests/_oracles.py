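"""Independent brute-force oracles used by the test suite only."""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def exact_mw_p(a, b, alternative: str = "greater") -> float:
    """Exhaustive-permutation Mann-Whitney p-value.

    Enumerates every C(n+m, m) assignment of the pooled values to the first
    sample and counts tail weight of the rank-sum U statistic.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m = len(a)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
    us = np.array(
        [
            ranks[list(c)].sum() - m * (m + 1) / 2.0
            for c in combinations(range(len(pooled)), m)
        ]
    )
    p_greater = float((us >= u_obs - 1e-9).mean())
    if alternative == "greater":
        return p_greater
    p_less = float((us <= u_obs + 1e-9).mean())
    return min(1.0, 2.0 * min(p_greater, p_less))


def class_freq_loop(freq_row, scheme) -> dict:
    """Per-class frequency of one PSSM row by explicit looping."""
    from fsatool.alignment import AA_ORDER

    out = {}
    for cname, members in scheme.classes:
        total = 0.0
        for aa in members:
            total += freq_row[AA_ORDER.index(aa)]
        out[cname] = total
    return out
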