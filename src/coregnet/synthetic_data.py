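"""Synthetic multi-contrast expression data with known co-regulation truth.

The generator emulates the setting the method targets: many contrasts, each
a small two-group comparison (a handful of samples per arm) from a
heterogeneous compendium.  Genes are expressed on log2 scale as Gaussian
noise around per-gene baselines; where a gene is a DEG in a contrast, the
treatment group's mean is shifted by the effect size in the direction of
the gene's sign.

On top of independent background DEG calls, the generator plants gene
pairs with controlled joint behavior:

* ``concordant`` — co-DEG events always share one sign,
* ``discordant`` — co-DEG events always take opposite signs,
* ``mixed`` — each co-DEG event is concordant with probability 0.5
  (the nonlinear-score target population),
* ``simpson`` — expression follows the Simpson's-paradox geometry:
  within every contrast the two genes move oppositely along a negative
  within-contrast axis, while contrast centers drift upward together, so
  per-contrast correlations are negative and the pooled correlation is
  positive.

Effect sizes default to values at which the Welch caller has essentially
unit per-gene power, so the emitted DEG truth table is recovered exactly in
practice and downstream tests can treat it as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contrasts import ContrastSet

__all__ = [
    "PlantedPair",
    "SimulationConfig",
    "GroundTruth",
    "simulate_contrast_set",
    "simulate_signed_truth",
    "simulate_simpson_pair",
    "write_simulation",
]

PAIR_TYPES = ("concordant", "discordant", "mixed", "simpson")


@dataclass(frozen=True)
class PlantedPair:
    """A planted gene pair: joint DEG behavior with a known type."""

    pair_type: str
    co_deg_rate: float = 0.4
    effect_size_log2fc: float = 2.0

    def __post_init__(self):
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"pair_type must be one of {PAIR_TYPES}")
        if not 0 <= self.co_deg_rate <= 1:
            raise ValueError("co_deg_rate must be in [0, 1]")
        if self.effect_size_log2fc <= 0:
            raise ValueError("effect_size_log2fc must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic compendium.

    Defaults mirror the regime the method is built for: K = 100 contrasts,
    5 samples per arm, a 5% independent background DEG rate, log2 effect
    size 2 over within-group noise sd 0.25.
    """

    n_genes: int = 200
    n_contrasts: int = 100
    samples_per_group: int = 5
    background_deg_rate: float = 0.05
    planted_pairs: tuple[PlantedPair, ...] = ()
    effect_size_log2fc: float = 2.0
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0
    # Simpson-geometry knobs (used only for pair_type="simpson")
    simpson_between_step: float = 0.5
    simpson_within_sd: float = 0.4
    simpson_noise_sd: float = 0.1

    def __post_init__(self):
        if not 0 <= self.background_deg_rate <= 1:
            raise ValueError("background_deg_rate must be in [0, 1]")
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.n_contrasts < 1 or self.n_genes < 1:
            raise ValueError("n_genes and n_contrasts must be >= 1")
        if self.n_genes < 2 * len(self.planted_pairs):
            raise ValueError("not enough genes for the planted pairs")
        if self.effect_size_log2fc <= 0 or self.noise_sd <= 0:
            raise ValueError("effect and noise must be > 0")
        object.__setattr__(self, "planted_pairs", tuple(self.planted_pairs))


@dataclass
class GroundTruth:
    """What the generator planted.

    deg_signs
        genes x contrasts matrix of intended DEG signs (-1/0/+1); the DEG
        truth table is ``deg_signs != 0``.
    planted
        one row per planted pair: gene names, type, realized co-DEG count
        ``n_co`` and realized discordant count ``n_discordant``.
    simpson_coords
        (gene_i, gene_j) -> contrast_id -> (x, y) sample coordinates for
        planted Simpson pairs.
    """

    deg_signs: pd.DataFrame
    planted: pd.DataFrame
    simpson_coords: dict = field(default_factory=dict)

    @property
    def deg_truth(self) -> pd.DataFrame:
        return (self.deg_signs != 0).astype(np.int8)


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_signed_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the signed DEG truth table (no expression) for a config."""
    rng = np.random.default_rng(config.seed)
    G, K = config.n_genes, config.n_contrasts
    genes = _gene_names(G)

    # independent background for every gene
    deg = rng.random((G, K)) < config.background_deg_rate
    signs = np.where(deg, rng.choice([-1, 1], size=(G, K)), 0).astype(np.int8)

    planted_rows = []
    for p, pair in enumerate(config.planted_pairs):
        gi, gj = 2 * p, 2 * p + 1
        joint = rng.random(K) < pair.co_deg_rate
        if pair.pair_type == "concordant":
            s = rng.choice([-1, 1], size=K)
            si, sj = s, s
        elif pair.pair_type == "discordant":
            s = rng.choice([-1, 1], size=K)
            si, sj = s, -s
        elif pair.pair_type == "mixed":
            s = rng.choice([-1, 1], size=K)
            conc = rng.random(K) < 0.5
            si, sj = s, np.where(conc, s, -s)
        else:  # simpson: gene i always up, gene j always down within contrast
            si = np.ones(K, dtype=int)
            sj = -np.ones(K, dtype=int)
        # outside joint events the pair genes keep their independent
        # background draws
        signs[gi, joint] = si[joint]
        signs[gj, joint] = sj[joint]
        both = (signs[gi] != 0) & (signs[gj] != 0)
        n_disc = int((signs[gi][both] != signs[gj][both]).sum())
        planted_rows.append(
            {
                "gene_i": genes[gi],
                "gene_j": genes[gj],
                "pair_type": pair.pair_type,
                "n_co": int(both.sum()),
                "n_discordant": n_disc,
            }
        )

    deg_signs = pd.DataFrame(
        signs, index=genes, columns=[f"C{k:03d}" for k in range(K)]
    )
    planted = pd.DataFrame(
        planted_rows,
        columns=["gene_i", "gene_j", "pair_type", "n_co", "n_discordant"],
    )
    return GroundTruth(deg_signs=deg_signs, planted=planted)


def simulate_contrast_set(
    config: SimulationConfig,
) -> tuple[list[ContrastSet], GroundTruth]:
    """Generate per-contrast expression tables realizing the signed truth.

    Returns the contrast list plus the :class:`GroundTruth`.  Identical
    configs (including seed) give identical outputs.
    """
    truth = simulate_signed_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    G, K = config.n_genes, config.n_contrasts
    n_pg = config.samples_per_group
    genes = list(truth.deg_signs.index)
    signs = truth.deg_signs.to_numpy()

    baselines = config.baseline_mean + config.baseline_sd * rng.standard_normal(G)
    effects = np.full(G, config.effect_size_log2fc)
    simpson_idx = {}
    for p, pair in enumerate(config.planted_pairs):
        effects[2 * p] = effects[2 * p + 1] = pair.effect_size_log2fc
        if pair.pair_type == "simpson":
            simpson_idx[p] = (2 * p, 2 * p + 1)

    labels = np.repeat([0, 1], n_pg)
    contrast_list = []
    for k in range(K):
        cid = truth.deg_signs.columns[k]
        expr = (
            baselines[:, None]
            + config.noise_sd * rng.standard_normal((G, 2 * n_pg))
        )
        shift = signs[:, k] * effects  # per-gene treatment shift
        expr[:, labels == 1] += shift[:, None]

        # overwrite planted Simpson pairs with the paradox geometry
        for p, (gi, gj) in simpson_idx.items():
            center = baselines[gi] + k * config.simpson_between_step
            u = config.simpson_within_sd * rng.standard_normal(2 * n_pg)
            half = effects[gi] / 2.0
            g_shift = np.where(labels == 1, half, -half)
            if signs[gi, k] == 0:  # no co-DEG event in this contrast
                g_shift = np.zeros_like(g_shift)
            x = center + u + g_shift + config.simpson_noise_sd * rng.standard_normal(2 * n_pg)
            y = center - u - g_shift + config.simpson_noise_sd * rng.standard_normal(2 * n_pg)
            expr[gi] = x
            expr[gj] = y
            key = (genes[gi], genes[gj])
            truth.simpson_coords.setdefault(key, {})[cid] = (x.copy(), y.copy())

        contrast_list.append(
            ContrastSet(cid, pd.DataFrame(expr, index=genes), labels.copy())
        )
    return contrast_list, truth


def simulate_simpson_pair(
    n_contrasts: int = 5,
    samples_per_contrast: int = 20,
    within_slope: float = -1.0,
    between_trend: float = 3.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Two-gene expression coordinates realizing Simpson's paradox.

    Contrast c has its joint center at (c*between_trend, c*between_trend);
    within a contrast, samples spread along the ``within_slope`` axis
    (x = center + t, y = center + within_slope*t + noise with t ~ N(0,1)),
    so each per-contrast correlation carries the sign of the slope while
    the pooled correlation follows the between-contrast trend.  Returns a
    contrast_id -> (x, y) map ready for
    :func:`~coregnet.nonlinearity.detect_simpson`.
    """
    if within_slope * between_trend > 0:
        raise ValueError("within_slope and between_trend must not share a sign")
    if within_slope == 0:
        raise ValueError("within_slope must be nonzero")
    expected_r = abs(within_slope) / np.hypot(within_slope, noise_sd)
    if expected_r < 0.2:
        import warnings

        warnings.warn(
            f"noise_sd={noise_sd} swamps the within-contrast slope "
            f"(expected |r| ~ {expected_r:.2f}); the construction's signs may flip",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    out = {}
    for c in range(n_contrasts):
        t = rng.standard_normal(samples_per_contrast)
        x = c * between_trend + t
        y = (
            c * between_trend
            + within_slope * t
            + noise_sd * rng.standard_normal(samples_per_contrast)
        )
        out[f"C{c:03d}"] = (x, y)
    return out


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[list[ContrastSet], GroundTruth]:
    """Run the generator and write contrast TSVs, design TSV and truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contrast_list, truth = simulate_contrast_set(config)
    design_rows = []
    for c in contrast_list:
        samples = [f"{c.contrast_id}_s{i}" for i in range(len(c.group_labels))]
        expr = c.expression.copy()
        expr.columns = samples
        expr.to_csv(out_dir / f"{c.contrast_id}.tsv", sep="\t")
        for s, g in zip(samples, c.group_labels):
            design_rows.append({"sample": s, "contrast_id": c.contrast_id, "group": int(g)})
    pd.DataFrame(design_rows).to_csv(out_dir / "design.tsv", sep="\t", index=False)
    truth.deg_signs.to_csv(out_dir / "truth_signs.tsv", sep="\t")
    truth.planted.to_csv(out_dir / "truth_pairs.tsv", sep="\t", index=False)
    return contrast_list, truth
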