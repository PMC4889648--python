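"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: BH by literal
step-up over sorted ranks, Fisher by exhaustive hypergeometric enumeration,
read classification by substring containment against full isoforms.
"""

from math import comb

import numpy as np


def bh_bruteforce(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    for rank0, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank0, m)
        ]
        q_sorted[rank0] = min(min(candidates), 1.0)
    q = [0.0] * m
    for rank0, idx in enumerate(order):
        q[idx] = q_sorted[rank0]
    return np.array(q)


def hypergeom_tail_bruteforce(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(overlap >= k) by summing exact hypergeometric point masses."""
    total = comb(n_universe, n_b)
    acc = 0
    for x in range(k, min(n_a, n_b) + 1):
        if n_b - x > n_universe - n_a:
            continue
        acc += comb(n_a, x) * comb(n_universe - n_a, n_b - x)
    return acc / total


def fisher_two_sided_bruteforce(k: int, n_universe: int, n_a: int, n_b: int) -> float:
    """Two-sided Fisher p: sum of all table probabilities <= P(observed)."""
    total = comb(n_universe, n_b)
    probs = []
    for x in range(0, min(n_a, n_b) + 1):
        if n_b - x > n_universe - n_a:
            probs.append(0.0)
            continue
        probs.append(comb(n_a, x) * comb(n_universe - n_a, n_b - x) / total)
    p_obs = probs[k]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


def classify_by_containment(seq: str, spliced_seq: str, unspliced_seq: str) -> str:
    """Alignment oracle: exact-substring containment against both isoforms."""
    in_spliced = seq in spliced_seq
    in_unspliced = seq in unspliced_seq
    if in_spliced and not in_unspliced:
        return "spliced"
    if in_unspliced and not in_spliced:
        return "unspliced"
    return "ambiguous"
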