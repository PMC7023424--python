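"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities by definitions unrelated to the
package implementation: kinship by the classical recursive coefficient, HPD
by exhaustive window search, variance components by pairwise covariance
U-statistics.
"""

from __future__ import annotations

import numpy as np


def kinship_matrix(parents: np.ndarray) -> np.ndarray:
    """Kinship coefficients by the textbook recursion.

    *parents* is an (n, 2) array of sire/dam positions (-1 unknown), with
    every parent preceding its offspring.  f(i,i) = (1 + f(s,d)) / 2 and for
    i earlier than j: f(i,j) = (f(i, s_j) + f(i, d_j)) / 2.
    """
    n = len(parents)
    memo: dict[tuple[int, int], float] = {}

    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            v = 0.5 * (1.0 + f(parents[i, 0], parents[i, 1]))
        else:
            v = 0.5 * (f(i, parents[j, 0]) + f(i, parents[j, 1]))
        memo[key] = v
        return v

    K = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = f(i, j)
    return K


def random_pedigree(rng: np.random.Generator, n: int):
    """Random valid pedigree as a list of (id, sire, dam) with parents first.

    Animals are male or female; parents are drawn among earlier animals of
    the right sex (or unknown), so the structure is acyclic by construction
    and can include inbreeding and multiple generations.
    """
    sex = rng.integers(0, 2, size=n)  # 0 male, 1 female
    rows = []
    for i in range(n):
        males = [j for j in range(i) if sex[j] == 0]
        females = [j for j in range(i) if sex[j] == 1]
        sire = dam = None
        if males and rng.random() < 0.7:
            sire = males[rng.integers(len(males))]
        if females and rng.random() < 0.7:
            dam = females[rng.integers(len(females))]
        rows.append((f"A{i}", f"A{sire}" if sire is not None else None,
                     f"A{dam}" if dam is not None else None))
    return rows


def hpd_bruteforce(x, prob):
    """Shortest interval over all sorted windows of size ceil(prob*n)."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)
    k = min(max(int(np.ceil(prob * n)), 2), n)
    best = (np.inf, None)
    for i in range(n - k + 1):
        w = xs[i + k - 1] - xs[i]
        if w < best[0]:
            best = (w, (xs[i], xs[i + k - 1]))
    return best[1]
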