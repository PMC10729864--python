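"""Concordance/discordance structure of significant gene pairs.

A co-regulated pair is *concordant* in a contrast when both genes move in
the same direction and *discordant* when they move oppositely.  With N
co-regulated contrasts of which N+/- are discordant, the **nonlinear
score**

    score = 1 - | 1 - 2 * N+/- / N |

is 1 when concordant and discordant contrasts are equally frequent and 0
when the pair is purely one-directional.  Pairs with a high score are
invisible to pooled-correlation methods: their per-contrast relationships
cancel in the pooled cloud.

A related pathology is **Simpson's paradox**: a pair consistently
negatively correlated within every contrast whose pooled correlation is
positive (or vice versa), typically because between-contrast shifts of the
joint mean dominate the within-contrast trend.  ``detect_simpson`` turns
the qualitative picture into a reproducible boolean with explicit
correlation cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "nonlinear_score",
    "categorize_pair",
    "annotate_pairs",
    "SimpsonResult",
    "detect_simpson",
]

CATEGORIES = ("linear_concordant", "linear_discordant", "nonlinear")


def nonlinear_score(n, n_discordant):
    """Nonlinear score ``1 - |1 - 2*N+/-/N|`` (scalar or elementwise).

    ``n`` is the number of co-regulated contrasts, ``n_discordant`` how many
    of those are discordant.  Raises if ``n`` is 0 (an un-co-regulated pair
    has no score) or counts are inconsistent.
    """
    n_arr = np.asarray(n, dtype=float)
    d_arr = np.asarray(n_discordant, dtype=float)
    if (n_arr < 1).any():
        raise ValueError("nonlinear score undefined for n = 0 (pair not co-regulated)")
    if ((d_arr < 0) | (d_arr > n_arr)).any():
        raise ValueError("need 0 <= n_discordant <= n")
    out = 1.0 - np.abs(1.0 - 2.0 * d_arr / n_arr)
    return float(out) if np.isscalar(n) else out


def categorize_pair(n: int, n_discordant: int, score_cutoff: float = 0.5) -> str:
    """Classify a pair: nonlinear if score >= cutoff, else by majority sign."""
    score = nonlinear_score(n, n_discordant)
    if score >= score_cutoff:
        return "nonlinear"
    return "linear_concordant" if n_discordant / n < 0.5 else "linear_discordant"


def annotate_pairs(pair_stats: pd.DataFrame, score_cutoff: float = 0.5) -> pd.DataFrame:
    """Attach nonlinear_score and category columns to a pair-statistics table."""
    out = pair_stats.copy()
    if len(out) == 0:
        out["nonlinear_score"] = pd.Series(dtype=float)
        out["category"] = pd.Series(dtype=object)
        return out
    out["nonlinear_score"] = nonlinear_score(
        out["n"].to_numpy(), out["n_discordant"].to_numpy()
    )
    out["category"] = [
        categorize_pair(int(n), int(d), score_cutoff)
        for n, d in zip(out["n"], out["n_discordant"])
    ]
    return out


@dataclass
class SimpsonResult:
    """Outcome of the Simpson's-paradox check for one gene pair."""

    simpson_flag: bool
    pooled_r: float
    per_contrast_r: np.ndarray = field(repr=False)
    contrast_ids: list = field(default_factory=list, repr=False)


def detect_simpson(
    pair_expression: dict[str, tuple[np.ndarray, np.ndarray]],
    r_within: float = 0.3,
    r_pooled: float = 0.3,
    min_contrasts: int = 3,
) -> SimpsonResult:
    """Flag a pair whose pooled correlation contradicts every within-contrast one.

    ``pair_expression`` maps contrast id -> (x, y) expression vectors of the
    two genes over that contrast's samples (both groups pooled, matching how
    per-contrast scatter is usually drawn).  The flag is raised iff

    * at least ``min_contrasts`` contrasts have |r| >= ``r_within`` and all
      of those per-contrast correlations share one sign, and
    * the pooled correlation over the union of the samples has the opposite
      sign with |r| >= ``r_pooled``.

    Contrasts with a constant expression vector are excluded with a warning
    (correlation undefined there).
    """
    xs, ys, rs, ids = [], [], [], []
    for cid, (x, y) in pair_expression.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError(f"contrast {cid!r}: x and y must be equal-length vectors")
        if x.size < 3:
            raise ValueError(f"contrast {cid!r}: need >= 3 samples for a correlation")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"contrast {cid!r} excluded: constant expression vector", stacklevel=2
            )
            continue
        xs.append(x)
        ys.append(y)
        rs.append(float(np.corrcoef(x, y)[0, 1]))
        ids.append(cid)

    per_r = np.asarray(rs)
    if len(ids) == 0:
        return SimpsonResult(False, np.nan, per_r, ids)
    pooled = np.concatenate(xs), np.concatenate(ys)
    pooled_r = float(np.corrcoef(pooled[0], pooled[1])[0, 1]) if np.ptp(
        pooled[0]
    ) > 0 and np.ptp(pooled[1]) > 0 else np.nan

    strong = np.abs(per_r) >= r_within
    flag = False
    if strong.sum() >= min_contrasts and not np.isnan(pooled_r):
        signs = np.sign(per_r[strong])
        if np.all(signs == signs[0]):
            flag = bool(
                abs(pooled_r) >= r_pooled and np.sign(pooled_r) == -signs[0]
            )
    return SimpsonResult(flag, pooled_r, per_r, ids)


def pair_expression_from_contrasts(
    gene_i: str,
    gene_j: str,
    contrast_sets,
    contrast_ids=None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Collect (x, y) expression vectors for a pair from ContrastSet objects.

    ``contrast_ids`` restricts to the contrasts in which the pair co-regulates
    (pass the co-DEG columns from the binary matrix); default: all contrasts.
    """
    wanted = None if contrast_ids is None else set(contrast_ids)
    out = {}
    for c in contrast_sets:
        if wanted is not None and c.contrast_id not in wanted:
            continue
        out[c.contrast_id] = (
            c.expression.loc[gene_i].to_numpy(dtype=float),
            c.expression.loc[gene_j].to_numpy(dtype=float),
        )
    return out
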