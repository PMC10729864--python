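"""End to end: simulated compendium -> DEG matrices -> significant pairs.

Simulates 100 small two-group contrasts over 200 genes with four planted
always-concordant pairs, calls DEGs per contrast, and scores every pair
against the beta-binomial null fitted to 1000 fixed-margin resamplings.
"""

from coregnet import (
    PlantedPair,
    SimulationConfig,
    build_deg_matrices,
    run_pipeline,
    simulate_contrast_set,
)

cfg = SimulationConfig(
    planted_pairs=tuple(PlantedPair("concordant", co_deg_rate=0.4) for _ in range(4)),
    seed=1,
)
contrasts, truth = simulate_contrast_set(cfg)
binary, signed = build_deg_matrices(contrasts)
print(f"{binary.shape[0]} genes x {binary.shape[1]} contrasts, "
      f"{int(binary.to_numpy().sum())} DEG calls")

pairs = run_pipeline(binary, signed, n_samplings=1000, seed=1)
sig = pairs[pairs["fdr"] < 0.05].sort_values("fdr")
print(f"{len(pairs)} pairs tested, {len(sig)} significant at FDR < 0.05:")
print(sig[["gene_i", "gene_j", "n", "n_discordant", "p_value", "fdr"]]
      .to_string(index=False))
print("\nplanted truth:")
print(truth.planted.to_string(index=False))
# Each significant pair co-regulates in ~40 of 100 contrasts, far above the
# ~15 the fixed-margin null expects for genes with these row sums; the four
# planted pairs should be exactly the ones recovered.
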