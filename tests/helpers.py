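"""Independent brute-force oracles used across the test suite.

These deliberately avoid numpy vectorization and scipy so they stay
independent of the code paths they check: plain-Python summation for
the product-moment correlation and hand-rolled average ranking for the
rank correlation.
"""

import math


def brute_pearson(xs, ys):
    """Direct term-by-term evaluation of the product-moment formula."""
    n = len(xs)
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    num = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - xbar) ** 2 for x in xs)) * math.sqrt(
        sum((y - ybar) ** 2 for y in ys)
    )
    return num / den


def average_ranks(xs):
    """1-based ranks with ties sharing the average of their positions."""
    order = sorted(range(len(xs)), key=lambda k: xs[k])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # mean of 1-based positions i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(xs, ys):
    """Rank both vectors by hand, then apply the brute Pearson formula."""
    return brute_pearson(average_ranks(list(xs)), average_ranks(list(ys)))
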