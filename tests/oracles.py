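"""Independent brute-force reference implementations used only by tests.

Deliberately naive (dictionaries, explicit loops) and written against the
definitions, not against the package code paths they check.
"""

from collections import Counter
from itertools import permutations

import numpy as np


def ordinal_code_bruteforce(window, m):
    """Lexicographic rank of the argsort permutation, ties by temporal order."""
    order = sorted(range(m), key=lambda i: (window[i], i))
    perms = sorted(permutations(range(m)))
    return perms.index(tuple(order))


def cmi_bruteforce(x_codes, y_codes, delta):
    """I(y_{t+delta}; x_t | y_t) in bits from explicit triple enumeration."""
    n = len(x_codes)
    triples = [
        (y_codes[t + delta], x_codes[t], y_codes[t]) for t in range(n - delta)
    ]
    total = len(triples)
    p_xyz = Counter(triples)
    p_yy = Counter((a, c) for a, _, c in triples)
    p_xy = Counter((b, c) for _, b, c in triples)
    p_y = Counter(c for _, _, c in triples)
    cmi = 0.0
    for (a, b, c), n_abc in p_xyz.items():
        # p(y'|x,y) / p(y'|y) = [n_abc / n_xy] / [n_yy / n_y]
        ratio = (n_abc / p_xy[(b, c)]) / (p_yy[(a, c)] / p_y[c])
        cmi += (n_abc / total) * np.log2(ratio)
    return cmi


def auc_bruteforce(y_true, scores):
    """All positive-negative pair enumeration; ties count one half."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
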