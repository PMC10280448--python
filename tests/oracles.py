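"""Independent brute-force reference implementations used as oracles.

Everything here is written in plain Python loops, deliberately sharing no
code with the package, so agreement is meaningful evidence of correctness.
"""

from __future__ import annotations

import math


def bf_mse(t, p) -> float:
    return sum((ti - pi) ** 2 for ti, pi in zip(t, p)) / len(t)


def bf_rmse(t, p) -> float:
    return math.sqrt(bf_mse(t, p))


def bf_mae(t, p) -> float:
    return sum(abs(ti - pi) for ti, pi in zip(t, p)) / len(t)


def bf_pearson(t, p) -> float:
    n = len(t)
    mt = sum(t) / n
    mp = sum(p) / n
    num = sum((ti - mt) * (pi - mp) for ti, pi in zip(t, p))
    dt = math.sqrt(sum((ti - mt) ** 2 for ti in t))
    dp = math.sqrt(sum((pi - mp) ** 2 for pi in p))
    return num / (dt * dp)


def bf_vecv(t, p) -> float:
    mt = sum(t) / len(t)
    ss_err = sum((ti - pi) ** 2 for ti, pi in zip(t, p))
    ss_tot = sum((ti - mt) ** 2 for ti in t)
    return 100.0 * (1.0 - ss_err / ss_tot)


def bf_ccc(t, p) -> float:
    n = len(t)
    mt = sum(t) / n
    mp = sum(p) / n
    var_t = sum((ti - mt) ** 2 for ti in t) / n
    var_p = sum((pi - mp) ** 2 for pi in p) / n
    cov = sum((ti - mt) * (pi - mp) for ti, pi in zip(t, p)) / n
    return 2.0 * cov / (var_t + var_p + (mt - mp) ** 2)
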