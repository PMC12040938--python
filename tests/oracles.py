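"""Independent brute-force oracles used by the tests.

Deliberately naive: exhaustive path enumeration, term-by-term tail sums,
hand-rolled step-up adjustment.  They share no code with the package
implementations they check.
"""

import itertools
import math

import numpy as np


def enumerate_loglik(pi, A, E, X) -> float:
    """Log-likelihood by summing the joint probability of every state path."""
    T = len(X)
    K = len(pi)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]]
        for t, k in enumerate(path):
            for m, x in enumerate(X[t]):
                p *= E[k, m] if x else 1.0 - E[k, m]
        total += p
    return math.log(total)


def path_probability(pi, A, E, X, path) -> float:
    p = pi[path[0]]
    for t in range(1, len(path)):
        p *= A[path[t - 1], path[t]]
    for t, k in enumerate(path):
        for m, x in enumerate(X[t]):
            p *= E[k, m] if x else 1.0 - E[k, m]
    return p


def enumerate_viterbi(pi, A, E, X):
    """Exhaustive joint-probability argmax.

    Returns (lexicographically first best path, its probability, number of
    co-optimal paths); any co-optimal path is a valid Viterbi answer.
    """
    T = len(X)
    K = len(pi)
    probs = []
    paths = list(itertools.product(range(K), repeat=T))
    for path in paths:
        probs.append(path_probability(pi, A, E, X, path))
    best_p = max(probs)
    optimal = [paths[i] for i, p in enumerate(probs) if p >= best_p * (1 - 1e-12)]
    return np.array(optimal[0]), best_p, len(optimal)


def poisson_tail_threshold(lam: float, p: float) -> int:
    """Smallest c >= 1 with P(X >= c) <= p, by explicit pmf summation."""
    c = 1
    while True:
        # P(X >= c) = 1 - sum_{i<c} pmf(i), pmf by direct evaluation
        cdf = sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(c))
        if 1.0 - cdf <= p:
            return c
        c += 1


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return min(total, 1.0)


def bh_stepup(p):
    """Hand step-up: q_(i) = min_{j>=i} min(1, m p_(j) / j), input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q
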