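"""Independent, literal brute-force implementations of every formula.

Written straight from the definitions with plain Python loops and ``math``
— no numpy vectorization, no caching — so they stay independent of the
production code paths they are used to check.
"""

import math


def oracle_freq_matrix(strings, symbols):
    """Pseudocounted position frequency matrix: list of per-position dicts."""
    L = len(strings[0])
    A = len(symbols)
    out = []
    for i in range(L):
        col = [s[i] for s in strings]
        N = len(col)
        probs = {}
        for sym in symbols:
            n = sum(1 for c in col if c == sym)
            probs[sym] = (n + math.sqrt(N) / A) / (N + math.sqrt(N))
        out.append(probs)
    return out


def oracle_background(strings, symbols):
    """Add-one smoothed pooled symbol frequencies."""
    total = 0
    counts = {sym: 0 for sym in symbols}
    for s in strings:
        for c in s:
            counts[c] += 1
            total += 1
    return {sym: (counts[sym] + 1) / (total + len(symbols)) for sym in symbols}


def oracle_weight_matrix(freq, background, base=math.e):
    return [
        {sym: math.log(row[sym] / background[sym], base) for sym in row} for row in freq
    ]


def oracle_conservation(freq, base=math.e):
    """C_i = 100/log(A) * (sum_j p log p + log A)."""
    out = []
    for row in freq:
        A = len(row)
        ent = sum(p * math.log(p, base) for p in row.values() if p > 0)
        out.append(100.0 / math.log(A, base) * (ent + math.log(A, base)))
    return out


def oracle_score(weight, conservation, encoded):
    num = 0.0
    den = 0.0
    for i, sym in enumerate(encoded):
        row = weight[i]
        m_min = min(row.values())
        m_max = max(row.values())
        num += conservation[i] * (row[sym] - m_min)
        den += conservation[i] * (m_max - m_min)
    if den == 0.0:
        return 0.0
    return num / den


def oracle_diversity(counts):
    """D(X) = N log N - sum n log n, 0 log 0 := 0."""
    total = sum(counts)
    d = total * math.log(total) if total > 0 else 0.0
    for n in counts:
        if n > 0:
            d -= n * math.log(n)
    return d


def oracle_mixed_diversity(x, y):
    return oracle_diversity([a + b for a, b in zip(x, y)])


def oracle_increment(x, y):
    return oracle_mixed_diversity(x, y) - oracle_diversity(x) - oracle_diversity(y)


def oracle_metrics(tp, fn, tn, fp):
    """Sn/Sp/Acc as percentages, MCC; None where a ratio is undefined."""
    sn = 100.0 * tp / (tp + fn) if tp + fn else None
    sp = 100.0 * tn / (tn + fp) if tn + fp else None
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return sn, sp, acc, mcc


def oracle_puk(x, y, omega, sigma):
    dist = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    return 1.0 / (1.0 + (2.0 * dist * math.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma) ** 2) ** omega


def oracle_dual_objective(alpha, y, gram):
    n = len(alpha)
    obj = sum(alpha)
    for i in range(n):
        for j in range(n):
            obj -= 0.5 * alpha[i] * alpha[j] * y[i] * y[j] * gram[i][j]
    return obj
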