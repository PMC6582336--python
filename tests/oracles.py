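"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: exact rational
arithmetic instead of log-gamma, explicit enumeration instead of
recursions, O(n^2) pair loops instead of contingency tables.
"""

from fractions import Fraction
from math import log


def rising_factorial(x: Fraction, n: int) -> Fraction:
    """x (x+1) ... (x+n-1) in exact rational arithmetic."""
    out = Fraction(1)
    for i in range(n):
        out *= x + i
    return out


def log_dirichlet_multinomial(counts, betas) -> float:
    """Exact log of the gamma-ratio product for one or more loci.

    ``counts``/``betas`` are lists of per-locus lists; every
    Gamma(b + n)/Gamma(b) ratio with integer n is a rising factorial,
    so the whole product is one exact Fraction.
    """
    p = Fraction(1)
    for locus_counts, locus_betas in zip(counts, betas):
        b = [Fraction(x).limit_denominator(10**9) for x in locus_betas]
        total = sum(locus_counts)
        p /= rising_factorial(sum(b), total)
        for n, beta in zip(locus_counts, b):
            p *= rising_factorial(beta, int(n))
    return log(p.numerator) - log(p.denominator)


def set_partitions(items):
    """All set partitions of a list (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def fm_pair_loop(assign_a, assign_b) -> float:
    """Fowlkes–Mallows by explicit O(n^2) pair enumeration."""
    n = len(assign_a)
    tp = fp = fn = 0
    for i in range(n):
        for j in range(i + 1, n):
            in_a = assign_a[i] == assign_a[j]
            in_b = assign_b[i] == assign_b[j]
            tp += in_a and in_b
            fp += in_b and not in_a
            fn += in_a and not in_b
    if tp + fp == 0 and tp + fn == 0:
        return 1.0
    if tp == 0:
        return 0.0
    return (tp / (tp + fp) * tp / (tp + fn)) ** 0.5
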