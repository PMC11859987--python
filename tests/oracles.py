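"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive every quantity from first principles with plain
loops over probability dictionaries, sharing no code with the package
implementations they check.
"""

import numpy as np


def empirical_probs(x, y):
    """p(y_next, y_now, x_now) for m = n = 1 from two aligned symbol arrays."""
    probs = {}
    n = len(x) - 1
    for t in range(n):
        key = (int(y[t + 1]), int(y[t]), int(x[t]))
        probs[key] = probs.get(key, 0.0) + 1.0 / n
    return probs


def brute_ste(x, y):
    """Triple-sum Shannon transfer entropy X -> Y, plug-in, in bits."""
    p3 = empirical_probs(x, y)
    p_yx = {}
    p_yy = {}
    p_y = {}
    for (yn, yt, xt), p in p3.items():
        p_yx[(yt, xt)] = p_yx.get((yt, xt), 0.0) + p
        p_yy[(yn, yt)] = p_yy.get((yn, yt), 0.0) + p
        p_y[yt] = p_y.get(yt, 0.0) + p
    total = 0.0
    for (yn, yt, xt), p in p3.items():
        cond_full = p / p_yx[(yt, xt)]
        cond_hist = p_yy[(yn, yt)] / p_y[yt]
        total += p * np.log2(cond_full / cond_hist)
    return total


def brute_rte(x, y, q):
    """Escort-weighted Renyi transfer entropy X -> Y, plug-in, in bits."""
    p3 = empirical_probs(x, y)
    p_yx = {}
    p_yy = {}
    p_y = {}
    for (yn, yt, xt), p in p3.items():
        p_yx[(yt, xt)] = p_yx.get((yt, xt), 0.0) + p
        p_yy[(yn, yt)] = p_yy.get((yn, yt), 0.0) + p
        p_y[yt] = p_y.get(yt, 0.0) + p
    z_y = sum(v**q for v in p_y.values())
    z_yx = sum(v**q for v in p_yx.values())
    numer = 0.0
    for (yn, yt), p in p_yy.items():
        numer += (p_y[yt] ** q / z_y) * (p / p_y[yt]) ** q
    denom = 0.0
    for (yn, yt, xt), p in p3.items():
        denom += (p_yx[(yt, xt)] ** q / z_yx) * (p / p_yx[(yt, xt)]) ** q
    return np.log2(numer / denom) / (1.0 - q)


def conditional_entropy_decomposition(x, y):
    """STE as H(Y+|Y) - H(Y+|Y,X) from the same empirical distribution."""
    p3 = empirical_probs(x, y)

    def entropy(dist):
        return -sum(p * np.log2(p) for p in dist.values() if p > 0)

    p_yy = {}
    p_y = {}
    p_yx = {}
    for (yn, yt, xt), p in p3.items():
        p_yy[(yn, yt)] = p_yy.get((yn, yt), 0.0) + p
        p_y[yt] = p_y.get(yt, 0.0) + p
        p_yx[(yt, xt)] = p_yx.get((yt, xt), 0.0) + p
    h_cond_hist = entropy(p_yy) - entropy(p_y)
    h_cond_full = entropy(p3) - entropy(p_yx)
    return h_cond_hist - h_cond_full
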