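"""Per-contrast differential expression and the binary/signed DEG matrices.

A *contrast* is one two-group comparison (treatment vs control) inside a
study.  Each contrast is reduced to a per-gene call: is the gene
differentially expressed (DEG), and in which direction does it move?
Stacking the calls over many contrasts yields the central objects of the
co-regulation method:

* the **binary DEG matrix** ``B`` (genes x contrasts, entries 0/1), and
* the **signed DEG matrix** ``S`` (entries -1/0/+1, the sign of the log2
  fold change wherever ``B`` is 1).

Everything downstream (the fixed-margin null, the beta-binomial fit, the
nonlinear score) consumes only these two matrices, so the DE caller is
deliberately replaceable: precomputed calls can be loaded from TSV with
:func:`read_deg_matrix` instead of being recomputed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEConfig",
    "ContrastSet",
    "DegenerateContrastError",
    "GeneUniverseError",
    "call_degs",
    "build_deg_matrices",
    "load_contrasts",
    "read_deg_matrix",
    "write_deg_matrix",
]


class DegenerateContrastError(ValueError):
    """A contrast does not have at least two samples in each group."""


class GeneUniverseError(ValueError):
    """Contrasts disagree on the gene universe; carries the offending ids."""

    def __init__(self, message: str, offending: Sequence[str] = ()):
        super().__init__(message)
        self.offending = list(offending)


@dataclass(frozen=True)
class DEConfig:
    """Differential-expression calling thresholds.

    alpha
        BH-adjusted p-value cutoff (default 0.05).
    min_lfc
        Minimum absolute log2 fold change (default 1.0).
    log_transformed
        Whether expression values are already on log2 scale.  If False,
        ``log2(x + 1)`` is applied before testing.
    """

    alpha: float = 0.05
    min_lfc: float = 1.0
    log_transformed: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_lfc < 0:
            raise ValueError(f"min_lfc must be >= 0, got {self.min_lfc}")


@dataclass
class ContrastSet:
    """One two-group contrast: expression table plus binary group labels.

    expression
        genes x samples DataFrame (index = gene ids).
    group_labels
        per-sample 0/1 array; group 1 is the "treatment" side, and log2FC
        is mean(group 1) - mean(group 0).
    """

    contrast_id: str
    expression: pd.DataFrame
    group_labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.group_labels = np.asarray(self.group_labels)
        if self.group_labels.shape[0] != self.expression.shape[1]:
            raise ValueError(
                f"contrast {self.contrast_id!r}: {self.group_labels.shape[0]} "
                f"labels for {self.expression.shape[1]} samples"
            )
        if not np.isin(self.group_labels, [0, 1]).all():
            raise ValueError(f"contrast {self.contrast_id!r}: labels must be 0/1")

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    def n_per_group(self) -> tuple[int, int]:
        n1 = int(self.group_labels.sum())
        return self.group_labels.shape[0] - n1, n1


def call_degs(
    contrast: ContrastSet, de_config: DEConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Call DEGs for one contrast with a Welch t-test and a fold-change floor.

    Returns ``(indicator, sign)``: two int8 arrays over the contrast's genes.
    ``indicator[g]`` is 1 iff gene g passes BH-adjusted Welch p < alpha and
    ``|log2FC| >= min_lfc``; ``sign[g]`` is the sign of the log2 fold change
    (group 1 minus group 0) where the gene is a DEG, else 0.

    All-constant genes (zero within-group variance and zero effect) yield
    (0, 0) without error; a group with fewer than two samples raises
    :class:`DegenerateContrastError`.
    """
    if de_config is None:
        de_config = DEConfig()
    n0, n1 = contrast.n_per_group()
    if n0 < 2 or n1 < 2:
        raise DegenerateContrastError(
            f"contrast {contrast.contrast_id!r} has group sizes {n0}/{n1}; "
            "need >= 2 samples per group"
        )

    values = contrast.expression.to_numpy(dtype=float)
    if not de_config.log_transformed:
        if (values < 0).any():
            raise ValueError("negative values in count-scale expression")
        values = np.log2(values + 1.0)

    g1 = values[:, contrast.group_labels == 1]
    g0 = values[:, contrast.group_labels == 0]
    lfc = g1.mean(axis=1) - g0.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = sps.ttest_ind(g1, g0, axis=1, equal_var=False)
    # zero-variance-in-both-groups rows give nan; a zero-effect constant row
    # can never be a DEG, treat as p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    indicator = (qvals < de_config.alpha) & (np.abs(lfc) >= de_config.min_lfc)
    sign = np.where(indicator, np.sign(lfc), 0.0)
    return indicator.astype(np.int8), sign.astype(np.int8)


def build_deg_matrices(
    contrast_list: Sequence[ContrastSet], de_config: DEConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`call_degs` over every contrast and assemble the matrices.

    Returns ``(binary, signed)``: aligned genes x contrasts DataFrames with
    values {0,1} and {-1,0,1}.  Every contrast must share the same ordered
    gene index; a mismatch raises :class:`GeneUniverseError` listing the
    offending identifiers.
    """
    if len(contrast_list) == 0:
        raise ValueError("need at least one contrast")
    genes = contrast_list[0].genes
    for c in contrast_list[1:]:
        if not c.genes.equals(genes):
            offending = genes.symmetric_difference(c.genes)
            if len(offending) == 0:  # same set, different order
                offending = genes[genes != c.genes]
            raise GeneUniverseError(
                f"contrast {c.contrast_id!r} disagrees on the gene universe "
                f"({len(offending)} identifiers differ)",
                offending=list(map(str, offending)),
            )
    ids = [c.contrast_id for c in contrast_list]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contrast_id values")

    bin_cols, sign_cols = [], []
    for c in contrast_list:
        ind, sgn = call_degs(c, de_config)
        bin_cols.append(ind)
        sign_cols.append(sgn)
    binary = pd.DataFrame(np.column_stack(bin_cols), index=genes, columns=ids)
    signed = pd.DataFrame(np.column_stack(sign_cols), index=genes, columns=ids)
    return binary, signed


# ---------------------------------------------------------------------------
# TSV interfaces


def load_contrasts(
    expression_paths: dict[str, str | Path] | Sequence[str | Path],
    design_path: str | Path,
) -> list[ContrastSet]:
    """Load per-contrast expression TSVs plus a design TSV.

    The design file has columns ``sample``, ``contrast_id``, ``group`` (0/1).
    ``expression_paths`` maps contrast_id -> TSV path (rows = genes, first
    column gene id, remaining columns samples); a plain sequence of paths is
    accepted when the file stem equals the contrast_id.
    """
    design = pd.read_csv(design_path, sep="\t", dtype={"sample": str, "contrast_id": str})
    required = {"sample", "contrast_id", "group"}
    if not required.issubset(design.columns):
        raise ValueError(f"design file must have columns {sorted(required)}")
    if not isinstance(expression_paths, dict):
        expression_paths = {Path(p).stem: p for p in expression_paths}

    out = []
    for cid, sub in design.groupby("contrast_id", sort=True):
        if cid not in expression_paths:
            raise ValueError(f"no expression file for contrast {cid!r}")
        expr = pd.read_csv(expression_paths[cid], sep="\t", index_col=0)
        missing = set(sub["sample"]) - set(expr.columns)
        if missing:
            raise ValueError(f"contrast {cid!r}: samples {sorted(missing)} not in expression")
        expr = expr[list(sub["sample"])]
        out.append(ContrastSet(cid, expr, sub["group"].to_numpy(dtype=int)))
    return out


def read_deg_matrix(path: str | Path, signed: bool = False) -> pd.DataFrame:
    """Read a binary (0/1) or signed (-1/0/1) DEG matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    allowed = {-1, 0, 1} if signed else {0, 1}
    bad = set(np.unique(df.to_numpy())) - allowed
    if bad:
        raise ValueError(f"unexpected values {sorted(bad)} in DEG matrix {path}")
    return df.astype(np.int8)


def write_deg_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def validate_pair(binary: pd.DataFrame, signed: pd.DataFrame) -> None:
    """Check the binary/signed invariant: nonzero sign exactly where DEG."""
    if binary.shape != signed.shape or not binary.index.equals(signed.index) \
            or not binary.columns.equals(signed.columns):
        raise GeneUniverseError("binary and signed matrices are not aligned")
    if not ((signed.to_numpy() != 0) == (binary.to_numpy() == 1)).all():
        raise ValueError("signed matrix is nonzero where binary is 0 (or vice versa)")
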