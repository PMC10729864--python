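"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the implementation:
exhaustive enumeration of fixed-margin matrices, a naive checkerboard-swap
MCMC sampler, and brute-force pair counting.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_fixed_margin(row_sums, col_sums):
    """All 0/1 matrices with the given margins, by exhaustive search."""
    row_sums = list(row_sums)
    col_sums = np.asarray(col_sums)
    n_cols = len(col_sums)
    row_choices = [
        [np.array(c) for c in itertools.combinations(range(n_cols), r)]
        for r in row_sums
    ]
    out = []

    def rec(i, partial_cols, rows):
        if (partial_cols > col_sums).any():
            return
        if i == len(row_sums):
            if (partial_cols == col_sums).all():
                m = np.zeros((len(row_sums), n_cols), dtype=np.int8)
                for r, cols in enumerate(rows):
                    m[r, cols] = 1
                out.append(m)
            return
        for cols in row_choices[i]:
            add = np.zeros(n_cols, dtype=int)
            add[cols] = 1
            rec(i + 1, partial_cols + add, rows + [cols])

    rec(0, np.zeros(n_cols, dtype=int), [])
    return out


def checkerboard_sample(mat, n_swaps, rng):
    """Naive fixed-margin sampler: random 2x2 checkerboard swaps."""
    m = np.array(mat, dtype=np.int8)
    n_r, n_c = m.shape
    for _ in range(n_swaps):
        r1, r2 = rng.choice(n_r, 2, replace=False)
        c1, c2 = rng.choice(n_c, 2, replace=False)
        sub = m[np.ix_([r1, r2], [c1, c2])]
        if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
            m[np.ix_([r1, r2], [c1, c2])] = sub[::-1]
    return m


def brute_pair_counts(binary, signed=None):
    """Per-pair (n, n_discordant) by explicit column-wise iteration."""
    b = np.asarray(binary)
    out = {}
    for i in range(b.shape[0]):
        for j in range(i + 1, b.shape[0]):
            n = 0
            disc = 0
            for k in range(b.shape[1]):
                if b[i, k] == 1 and b[j, k] == 1:
                    n += 1
                    if signed is not None and signed[i, k] != signed[j, k]:
                        disc += 1
            out[(i, j)] = (n, disc)
    return out


def exact_null_pair_expectation(mat):
    """Exact E[co-count] per pair under the uniform fixed-margin ensemble."""
    mats = enumerate_fixed_margin(mat.sum(axis=1), mat.sum(axis=0))
    acc = {}
    for m in mats:
        for (i, j), (n, _) in brute_pair_counts(m).items():
            acc.setdefault((i, j), []).append(n)
    return {k: np.mean(v) for k, v in acc.items()}, len(mats)
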