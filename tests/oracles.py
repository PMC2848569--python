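"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the Dempster
combination oracle enumerates every focal-set product, and the pseudo-PSSM
oracle is a plain double loop.
"""

from itertools import product


def brute_force_beliefs(masses):
    """Normalized combined singleton beliefs by exhaustive enumeration.

    ``masses`` is a list of ``(cls, m)`` pairs: each source puts mass m on
    the singleton {cls} and 1-m on the frame.  Feasible for len <= ~12.
    """
    acc: dict[int, float] = {}
    omega = 0.0
    conflict = 0.0
    for choice in product((0, 1), repeat=len(masses)):
        prod = 1.0
        classes = set()
        for (cls, m), pick in zip(masses, choice):
            prod *= m if pick else (1.0 - m)
            if pick:
                classes.add(cls)
        if len(classes) > 1:
            conflict += prod
        elif len(classes) == 1:
            cls = next(iter(classes))
            acc[cls] = acc.get(cls, 0.0) + prod
        else:
            omega += prod
    norm = sum(acc.values()) + omega
    return {cls: v / norm for cls, v in acc.items()}


def naive_psepssm(values, xi):
    """Plain-Python pseudo-PSSM: 20 column means followed by, for xi >= 1,
    20 squared-difference lag correlations."""
    length = len(values)
    means = [
        sum(values[i][j] for i in range(length)) / length for j in range(20)
    ]
    if xi == 0:
        return means
    corr = [
        sum(
            (values[i][j] - values[i + xi][j]) ** 2
            for i in range(length - xi)
        )
        / (length - xi)
        for j in range(20)
    ]
    return means + corr
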