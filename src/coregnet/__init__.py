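"""coregnet: gene co-regulation networks from many small two-group contrasts.

Instead of correlating expression in a pooled sample cloud, the method
counts, for every gene pair, the number of contrasts in which both genes
are differentially expressed, and scores that count against a
beta-binomial null fitted to fixed-margin resamplings of the binary DEG
matrix.  Significant pairs are classified by the balance of concordant and
discordant co-events (the nonlinear score), screened for Simpson's
paradox, and assembled into a scale-free network with Louvain modules.

Typical use::

    from coregnet import (SimulationConfig, PlantedPair, simulate_contrast_set,
                          build_deg_matrices, run_pipeline)

    contrasts, truth = simulate_contrast_set(
        SimulationConfig(planted_pairs=(PlantedPair("concordant"),), seed=1))
    binary, signed = build_deg_matrices(contrasts)
    pairs = run_pipeline(binary, signed, n_samplings=1000, seed=1)
    print(pairs.sort_values("fdr").head())
"""

from __future__ import annotations

import pandas as pd

from .contrasts import (
    ContrastSet,
    DEConfig,
    DegenerateContrastError,
    GeneUniverseError,
    build_deg_matrices,
    call_degs,
    load_contrasts,
    read_deg_matrix,
    write_deg_matrix,
)
from .coreg_stats import (
    BetaBinomParams,
    betabinom_pmf,
    compute_fdr,
    count_coregulation,
    fit_betabinom,
    pair_pvalue,
    score_pairs,
)
from .network import (
    annotation_interaction_density,
    build_network,
    density_null_test,
    detect_modules,
    read_gmt,
    select_scale_free_cutoff,
)
from .nonlinearity import (
    SimpsonResult,
    annotate_pairs,
    categorize_pair,
    detect_simpson,
    nonlinear_score,
)
from .null_model import (
    NullPairCounts,
    build_null_ensemble,
    sample_fixed_margins,
)
from .synthetic_data import (
    GroundTruth,
    PlantedPair,
    SimulationConfig,
    simulate_contrast_set,
    simulate_simpson_pair,
)

__version__ = "0.1.0"

__all__ = [
    "ContrastSet", "DEConfig", "DegenerateContrastError", "GeneUniverseError",
    "build_deg_matrices", "call_degs", "load_contrasts", "read_deg_matrix",
    "write_deg_matrix",
    "NullPairCounts", "build_null_ensemble", "sample_fixed_margins",
    "BetaBinomParams", "betabinom_pmf", "compute_fdr", "count_coregulation",
    "fit_betabinom", "pair_pvalue", "score_pairs",
    "SimpsonResult", "annotate_pairs", "categorize_pair", "detect_simpson",
    "nonlinear_score",
    "annotation_interaction_density", "build_network", "density_null_test",
    "detect_modules", "read_gmt", "select_scale_free_cutoff",
    "GroundTruth", "PlantedPair", "SimulationConfig", "simulate_contrast_set",
    "simulate_simpson_pair",
    "run_pipeline",
]


def run_pipeline(
    binary: pd.DataFrame,
    signed: pd.DataFrame,
    n_samplings: int = 1000,
    seed: int = 0,
    min_obs: int = 2,
    score_cutoff: float = 0.5,
    fit_method: str = "moments",
) -> pd.DataFrame:
    """Binary/signed DEG matrices -> annotated pair-statistics table.

    Counts per-pair co-regulation, builds the fixed-margin null ensemble,
    fits the beta-binomial null per pair, computes p-values and BH FDR, and
    attaches the nonlinear score and category.  Returns one row per
    retained pair (observed co-count >= ``min_obs``).
    """
    stats = count_coregulation(binary, signed, min_obs=min_obs)
    pairs = None
    if len(stats):
        gene_pos = {g: i for i, g in enumerate(binary.index)}
        pairs = (
            stats["gene_i"].map(gene_pos).to_numpy(),
            stats["gene_j"].map(gene_pos).to_numpy(),
        )
    null = build_null_ensemble(
        binary, n_samplings=n_samplings, seed=seed, min_obs=min_obs, pairs=pairs
    )
    scored = score_pairs(stats, null, method=fit_method)
    return annotate_pairs(scored, score_cutoff=score_cutoff)
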