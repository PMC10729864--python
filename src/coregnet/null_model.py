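"""Fixed-margin resampling of the binary DEG matrix.

The null hypothesis of the co-regulation test is that (i) every gene keeps
the chance of being a DEG it has in the real data and (ii) every contrast
yields the number of DEGs it yields in the real data — i.e. random binary
matrices with exactly the observed row and column sums.  Matrices are drawn
by **curveball trades**: pick two rows, pool the column indices that belong
to exactly one of them, and deal the pool back at random.  A trade preserves
both margins, and the chain's stationary distribution over fixed-margin
matrices is uniform.

For every retained gene pair the ensemble records, per sampling, the number
of contrasts in which the pair co-occurs; these per-pair count vectors are
the raw material for the beta-binomial fit.  Samplings are independent
restarts from the observed matrix separated by ``n_swaps`` trades (default
5x the number of nonzero entries), each driven by a sub-seed derived
deterministically from the ensemble seed.

The trade loop is JIT-compiled with numba; the matrix lives as a padded
row-major adjacency list so one trade costs O(row degree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "NullPairCounts",
    "sample_fixed_margins",
    "build_null_ensemble",
    "observed_pair_counts",
    "select_pairs",
]


@dataclass
class NullPairCounts:
    """Per-pair null co-regulation counts over a fixed-margin ensemble.

    ``counts[p, s]`` is the number of contrasts in which pair p co-occurs in
    sampling s.  ``pair_i``/``pair_j`` index into ``genes`` (i < j).
    """

    genes: np.ndarray          # gene identifiers (object array)
    pair_i: np.ndarray         # int32, row index of first gene
    pair_j: np.ndarray         # int32, row index of second gene
    counts: np.ndarray         # int32, (n_pairs, n_samplings)
    n_samplings: int
    n_contrasts: int
    seed: int

    def __post_init__(self):
        assert self.counts.shape == (len(self.pair_i), self.n_samplings)

    @property
    def pair_names(self) -> list[tuple[str, str]]:
        return [(self.genes[i], self.genes[j]) for i, j in zip(self.pair_i, self.pair_j)]

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            genes=np.asarray(self.genes, dtype=str),
            pair_i=self.pair_i,
            pair_j=self.pair_j,
            counts=self.counts,
            meta=np.array([self.n_samplings, self.n_contrasts, self.seed], dtype=np.int64),
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "NullPairCounts":
        with np.load(path, allow_pickle=False) as z:
            n_samplings, n_contrasts, seed = (int(x) for x in z["meta"])
            return cls(
                genes=z["genes"].astype(object),
                pair_i=z["pair_i"],
                pair_j=z["pair_j"],
                counts=z["counts"],
                n_samplings=n_samplings,
                n_contrasts=n_contrasts,
                seed=seed,
            )


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _trades(rows, row_len, stamp_a, stamp_s, pool, shared, n_trades):
    """Run curveball trades in place on the padded adjacency list."""
    n_rows = rows.shape[0]
    if n_rows < 2:
        return
    for t in range(n_trades):
        i = np.random.randint(n_rows)
        j = np.random.randint(n_rows)
        if i == j:
            continue
        li = row_len[i]
        lj = row_len[j]
        if li == 0 and lj == 0:
            continue
        for a in range(li):
            stamp_a[rows[i, a]] = t
        n_pool = 0
        n_shared = 0
        for b in range(lj):
            c = rows[j, b]
            if stamp_a[c] == t:
                stamp_s[c] = t
                shared[n_shared] = c
                n_shared += 1
            else:
                pool[n_pool] = c
                n_pool += 1
        for a in range(li):
            c = rows[i, a]
            if stamp_s[c] != t:
                pool[n_pool] = c
                n_pool += 1
        take_i = li - n_shared  # row i draws this many from the pool
        if take_i == 0 or take_i == n_pool:
            continue  # nothing exchangeable
        # partial Fisher-Yates: randomize the first take_i pool slots
        for a in range(take_i):
            b = a + np.random.randint(n_pool - a)
            pool[a], pool[b] = pool[b], pool[a]
        for a in range(n_shared):
            rows[i, a] = shared[a]
            rows[j, a] = shared[a]
        for a in range(take_i):
            rows[i, n_shared + a] = pool[a]
        for a in range(n_pool - take_i):
            rows[j, n_shared + a] = pool[take_i + a]


@njit(cache=True)
def _sample_one(rows0, row_len, n_cols, n_trades, seed):
    np.random.seed(seed)
    rows = rows0.copy()
    n_rows = rows.shape[0]
    kmax = rows.shape[1]
    stamp_a = np.full(n_cols, -1, np.int64)
    stamp_s = np.full(n_cols, -1, np.int64)
    pool = np.empty(2 * kmax, np.int32)
    shared = np.empty(kmax, np.int32)
    _trades(rows, row_len, stamp_a, stamp_s, pool, shared, n_trades)
    out = np.zeros((n_rows, n_cols), np.int8)
    for r in range(n_rows):
        for a in range(row_len[r]):
            out[r, rows[r, a]] = 1
    return out


@njit(cache=True)
def _ensemble_counts(rows0, row_len, n_cols, n_trades, pair_i, pair_j, seeds):
    n_pairs = pair_i.shape[0]
    n_samplings = seeds.shape[0]
    n_rows = rows0.shape[0]
    kmax = rows0.shape[1]
    counts = np.zeros((n_pairs, n_samplings), np.int32)
    stamp_a = np.full(n_cols, -1, np.int64)
    stamp_s = np.full(n_cols, -1, np.int64)
    pool = np.empty(2 * kmax, np.int32)
    shared = np.empty(kmax, np.int32)
    dense = np.zeros((n_rows, n_cols), np.bool_)
    for s in range(n_samplings):
        np.random.seed(seeds[s])
        rows = rows0.copy()
        stamp_a[:] = -1
        stamp_s[:] = -1
        _trades(rows, row_len, stamp_a, stamp_s, pool, shared, n_trades)
        dense[:, :] = False
        for r in range(n_rows):
            for a in range(row_len[r]):
                dense[r, rows[r, a]] = True
        for p in range(n_pairs):
            i = pair_i[p]
            j = pair_j[p]
            c = 0
            for k in range(n_cols):
                if dense[i, k] and dense[j, k]:
                    c += 1
            counts[p, s] = c
    return counts


# ---------------------------------------------------------------------------


def _as_array(observed) -> tuple[np.ndarray, np.ndarray | None, list | None]:
    if isinstance(observed, pd.DataFrame):
        return observed.to_numpy(dtype=np.int8), observed.index.to_numpy(object), list(observed.columns)
    return np.asarray(observed, dtype=np.int8), None, None


def _adjacency(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    row_len = mat.sum(axis=1).astype(np.int32)
    kmax = max(int(row_len.max(initial=0)), 1)
    rows = np.zeros((mat.shape[0], kmax), np.int32)
    for r in range(mat.shape[0]):
        nz = np.flatnonzero(mat[r])
        rows[r, : nz.size] = nz
    return rows, row_len


def _default_swaps(mat: np.ndarray) -> int:
    return max(5 * int(mat.sum()), 1)


def sample_fixed_margins(observed, seed: int = 0, n_swaps: int | None = None):
    """Draw one random 0/1 matrix with the observed row and column sums.

    Starts from ``observed`` and applies ``n_swaps`` curveball trades
    (default 5x the number of nonzero entries).  A matrix whose margins
    force it (e.g. all-zero rows/columns only) is returned unchanged.
    Returns the same container type as the input.
    """
    mat, index, columns = _as_array(observed)
    if not np.isin(mat, [0, 1]).all():
        raise ValueError("observed matrix must be 0/1")
    rows, row_len = _adjacency(mat)
    if n_swaps is None:
        n_swaps = _default_swaps(mat)
    out = _sample_one(rows, row_len, mat.shape[1], n_swaps, int(seed) % (2**31 - 1))
    if index is not None:
        return pd.DataFrame(out, index=index, columns=columns)
    return out


def observed_pair_counts(mat: np.ndarray) -> np.ndarray:
    """Co-occurrence count matrix ``C[i, j] = #contrasts where both are 1``."""
    b = np.asarray(mat, dtype=np.int32)
    return b @ b.T


def select_pairs(mat: np.ndarray, min_obs: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i < j) of pairs whose observed co-regulation count >= min_obs.

    Pairs never (or rarely) observed together cannot reach significance, so
    the default drops them before the expensive per-pair null tabulation;
    pass ``min_obs=0`` to keep every pair.
    """
    co = observed_pair_counts(mat)
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    keep = co[iu, ju] >= min_obs
    return iu[keep].astype(np.int32), ju[keep].astype(np.int32)


def build_null_ensemble(
    observed,
    n_samplings: int = 1000,
    seed: int = 0,
    min_obs: int = 2,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
    n_swaps: int | None = None,
) -> NullPairCounts:
    """Tabulate per-pair co-regulation counts over a fixed-margin ensemble.

    Each of the ``n_samplings`` matrices is an independent curveball restart
    from ``observed``; sub-seeds are derived deterministically from ``seed``,
    so identical inputs give bit-identical counts.  Samplings are processed
    one at a time (only the counts are kept).
    """
    if n_samplings < 2:
        raise ValueError("n_samplings must be >= 2")
    mat, index, _ = _as_array(observed)
    if not np.isin(mat, [0, 1]).all():
        raise ValueError("observed matrix must be 0/1")
    if pairs is None:
        pair_i, pair_j = select_pairs(mat, min_obs=min_obs)
    else:
        pair_i = np.asarray(pairs[0], dtype=np.int32)
        pair_j = np.asarray(pairs[1], dtype=np.int32)
    if pair_i.size == 0:
        warnings.warn("pair filter retained zero pairs; empty ensemble", stacklevel=2)
    rows, row_len = _adjacency(mat)
    if n_swaps is None:
        n_swaps = _default_swaps(mat)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_samplings).astype(np.int64)
    counts = _ensemble_counts(rows, row_len, mat.shape[1], n_swaps, pair_i, pair_j, seeds)
    genes = index if index is not None else np.array(
        [f"g{r}" for r in range(mat.shape[0])], dtype=object
    )
    return NullPairCounts(
        genes=genes,
        pair_i=pair_i,
        pair_j=pair_j,
        counts=counts,
        n_samplings=n_samplings,
        n_contrasts=mat.shape[1],
        seed=int(seed),
    )
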