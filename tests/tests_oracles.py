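"""Brute-force scalar implementations of the five statistics.

Written with plain Python loops, independent of the vectorized code paths
they are used to check.
"""


def brute_pearson(a, b):
    am, bm = sum(a) / len(a), sum(b) / len(b)
    cov = sum((x - am) * (y - bm) for x, y in zip(a, b))
    va = sum((x - am) ** 2 for x in a)
    vb = sum((y - bm) ** 2 for y in b)
    return cov / (va ** 0.5 * vb ** 0.5)


def brute_mape(y, yhat, guard=1e-3):
    terms = [abs(a - b) / abs(a) for a, b in zip(y, yhat) if abs(a) >= guard]
    return sum(terms) / len(terms)


def brute_rmse(y, yhat):
    return (sum((a - b) ** 2 for a, b in zip(y, yhat)) / len(y)) ** 0.5


def brute_skew(x):
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return m3 / m2 ** 1.5
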