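"""Nonlinear co-regulation and Simpson's paradox on planted pairs.

A "mixed" pair changes in the same direction in about half of its
co-regulated contrasts and oppositely in the other half; its nonlinear
score approaches 1 and its pooled correlation is near 0.  A Simpson pair
is negatively correlated inside every contrast yet positively correlated
when the samples are pooled.
"""

import numpy as np

from coregnet import (
    PlantedPair,
    SimulationConfig,
    count_coregulation,
    detect_simpson,
    nonlinear_score,
    simulate_simpson_pair,
)
from coregnet.nonlinearity import annotate_pairs
from coregnet.synthetic_data import simulate_signed_truth

# score boundary cases: equal mixture -> 1, purely one-directional -> 0
print("score(N=100, N+/-=50) =", nonlinear_score(100, 50))
print("score(N=100, N+/-=0)  =", nonlinear_score(100, 0))
print("score(N=100, N+/-=100)=", nonlinear_score(100, 100))

truth = simulate_signed_truth(SimulationConfig(
    planted_pairs=(PlantedPair("mixed"), PlantedPair("concordant")), seed=2,
))
table = annotate_pairs(count_coregulation(truth.deg_truth, truth.deg_signs))
planted = table.merge(
    truth.planted[["gene_i", "gene_j", "pair_type"]], on=["gene_i", "gene_j"]
)
print("\nplanted pairs:")
print(planted[["gene_i", "gene_j", "pair_type", "n", "n_discordant",
               "nonlinear_score", "category"]].to_string(index=False))

coords = simulate_simpson_pair(
    n_contrasts=5, samples_per_contrast=20,
    within_slope=-1.0, between_trend=3.0, noise_sd=0.3, seed=0,
)
res = detect_simpson(coords)
print(f"\nSimpson fixture: flag={res.simpson_flag}, pooled r={res.pooled_r:.2f}, "
      f"per-contrast r={np.round(res.per_contrast_r, 2)}")
# Every within-contrast correlation is strongly negative while the pooled
# correlation is strongly positive: the pooled trend is the between-contrast
# drift, not the gene-gene relationship.
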