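"""Independent straight-loop oracles used to cross-check the implementation.

Deliberately written with plain Python loops and `math` only (no numpy
vectorization, no scipy tails), so they share no code path with the package.
"""

import math
from fractions import Fraction


def loop_fixed(effects, variances):
    sw = swy = 0.0
    for y, v in zip(effects, variances):
        w = 1.0 / v
        sw += w
        swy += w * y
    effect = swy / sw
    se = 1.0 / math.sqrt(sw)
    return effect, se


def loop_q(effects, variances):
    ybar, _ = loop_fixed(effects, variances)
    q = 0.0
    for y, v in zip(effects, variances):
        q += (y - ybar) ** 2 / v
    return q


def loop_dl_tau2(effects, variances):
    q = loop_q(effects, variances)
    df = len(effects) - 1
    sw = sw2 = 0.0
    for v in variances:
        w = 1.0 / v
        sw += w
        sw2 += w * w
    c = sw - sw2 / sw
    return max(0.0, (q - df) / c)


def loop_random(effects, variances):
    tau2 = loop_dl_tau2(effects, variances)
    shifted = [v + tau2 for v in variances]
    effect, se = loop_fixed(effects, shifted)
    return effect, se, tau2


def hypergeom_tail(n_overlap, universe, n_a, n_b):
    """Exact right tail P(X >= n_overlap) by full enumeration, X the overlap
    of a fixed set of size n_a with a uniform random set of size n_b drawn
    from `universe` genes.  Exact rational arithmetic."""
    total = math.comb(universe, n_b)
    acc = Fraction(0)
    for k in range(n_overlap, min(n_a, n_b) + 1):
        if n_b - k > universe - n_a:
            continue
        acc += Fraction(math.comb(n_a, k) * math.comb(universe - n_a, n_b - k), total)
    return float(acc)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up, straightforward textbook loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted
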