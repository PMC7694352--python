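"""Independent exact-rational implementation of the Weir–Cockerham (1984)
single-locus variance components, used only as a test oracle.

Works symbol-by-symbol in fractions.Fraction so any disagreement with the
floating-point implementation beyond rounding is a real defect.
"""

from fractions import Fraction


def group_summary(dosages):
    """(n, p, h) as exact rationals; dosages may contain None for missing."""
    obs = [d for d in dosages if d is not None]
    n = len(obs)
    if n == 0:
        raise ValueError("no observed genotypes")
    p = Fraction(sum(obs), 2 * n)
    h = Fraction(sum(1 for d in obs if d == 1), n)
    return n, p, h


def wc_components(groups):
    """a, b, c, theta from per-group dosage lists (None = missing).

    Returns (a, b, c, theta) as Fractions; theta is None when a+b+c = 0.
    Raises ZeroDivisionError-family errors when n_bar <= 1 (undefined).
    """
    stats = [group_summary(g) for g in groups]
    r = len(stats)
    ns = [s[0] for s in stats]
    ps = [s[1] for s in stats]
    hs = [s[2] for s in stats]
    n_sum = sum(ns)
    n_bar = Fraction(n_sum, r)
    n_c = (n_sum - Fraction(sum(n * n for n in ns), n_sum)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(ns, ps)) / n_sum
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(ns, hs)) / n_sum
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - Fraction(r - 1, r) * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    theta = None if denom == 0 else a / denom
    return a, b, c, theta
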