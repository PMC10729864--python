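"""Co-regulation network assembly, module detection and annotation validation.

Significant pairs are thresholded by FDR into an undirected network.  The
threshold is chosen by the scale-free topology criterion: at each candidate
FDR the degree distribution is fitted on log-log axes (log-binned) and the
candidate with the best linear fit (highest R^2, negative slope) wins, ties
going to the stricter cutoff.

Modules are found by recursive Louvain: communities larger than
``max_module_size`` are re-partitioned on their induced subgraph until no
module exceeds the bound or no further modularity gain is possible.

The biological-sanity check is the annotation interaction density: the
fraction of edges whose endpoint genes share at least one annotation term
(GO terms via GMT input), compared with Erdos-Renyi random networks on the
same genes with the same number of edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from gseapy import read_gmt as _read_gmt_terms
from scipy import stats as sps

__all__ = [
    "InsufficientNetworkError",
    "UndefinedDensityError",
    "build_network",
    "select_scale_free_cutoff",
    "detect_modules",
    "annotation_interaction_density",
    "density_null_test",
    "read_gmt",
    "write_edgelist",
    "write_partition",
]

UNASSIGNED = -1


class InsufficientNetworkError(ValueError):
    """No candidate FDR cutoff yields a usable network."""


class UndefinedDensityError(ValueError):
    """No edge has both endpoints annotated; density is undefined."""


def build_network(pair_stats: pd.DataFrame, fdr_cutoff: float) -> nx.Graph:
    """Graph of pairs with fdr <= cutoff; edges carry fdr, n (and score)."""
    sig = pair_stats[pair_stats["fdr"] <= fdr_cutoff]
    g = nx.Graph(fdr_cutoff=float(fdr_cutoff))
    attr_cols = [c for c in ("fdr", "n", "nonlinear_score") if c in sig.columns]
    for row in sig.itertuples(index=False):
        if row.gene_i == row.gene_j:
            continue
        g.add_edge(row.gene_i, row.gene_j, **{c: getattr(row, c) for c in attr_cols})
    return g


def scale_free_fit(graph: nx.Graph, n_bins: int = 10) -> tuple[float, float]:
    """(R^2, slope) of log10 degree density vs log10 degree, log-binned.

    Degrees are binned into up to ``n_bins`` logarithmically spaced bins;
    empty bins are dropped and the density is the bin count divided by the
    bin width.  Returns (nan, nan) when fewer than 3 occupied bins remain.
    """
    degrees = np.array([d for _, d in graph.degree() if d > 0], dtype=float)
    if degrees.size == 0 or degrees.max() == degrees.min():
        return np.nan, np.nan
    edges = np.logspace(
        np.log10(degrees.min()), np.log10(degrees.max() + 1), n_bins + 1
    )
    counts, edges = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return np.nan, np.nan
    density = counts[keep] / widths[keep]
    fit = sps.linregress(np.log10(centers[keep]), np.log10(density))
    return float(fit.rvalue**2), float(fit.slope)


def select_scale_free_cutoff(
    pair_stats: pd.DataFrame,
    candidate_fdrs,
    min_nodes: int = 10,
    n_bins: int = 10,
) -> tuple[float, pd.DataFrame]:
    """Scan candidate FDR cutoffs for the most scale-free network.

    Returns ``(fdr_cutoff, report)`` where the report has one row per
    candidate (fdr, n_nodes, n_edges, r_squared, slope).  The winner
    maximizes R^2 subject to a negative slope; ties break toward the
    stricter (smaller) cutoff.  Raises
    :class:`InsufficientNetworkError` when every candidate yields fewer
    than ``min_nodes`` nodes.
    """
    candidates = sorted(set(float(f) for f in candidate_fdrs))
    if not candidates:
        raise ValueError("need at least one candidate FDR cutoff")
    rows = []
    for fdr in candidates:
        g = build_network(pair_stats, fdr)
        r2, slope = (np.nan, np.nan)
        if g.number_of_nodes() >= min_nodes:
            r2, slope = scale_free_fit(g, n_bins=n_bins)
        rows.append(
            {
                "fdr": fdr,
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "r_squared": r2,
                "slope": slope,
            }
        )
    report = pd.DataFrame(rows)
    usable = report[
        (report["n_nodes"] >= min_nodes)
        & report["r_squared"].notna()
        & (report["slope"] < 0)
    ]
    if (report["n_nodes"] < min_nodes).all():
        raise InsufficientNetworkError(
            f"all candidates give < {min_nodes} nodes"
        )
    if len(usable) == 0:
        raise InsufficientNetworkError(
            "no candidate yields a decreasing log-log degree fit"
        )
    # stable sort: highest R^2 first, then smaller fdr (stricter) on ties
    best = usable.sort_values(["r_squared", "fdr"], ascending=[False, True]).iloc[0]
    return float(best["fdr"]), report


def detect_modules(
    graph: nx.Graph,
    min_module_size: int = 5,
    max_module_size: int = 1000,
    seed: int = 0,
    resolution: float = 1.0,
) -> dict:
    """Recursive Louvain partition of the network.

    Louvain communities larger than ``max_module_size`` are re-partitioned
    on their induced subgraph (with a derived seed) until no module exceeds
    the bound or the subgraph no longer splits.  Modules smaller than
    ``min_module_size`` are labeled ``UNASSIGNED`` (-1).  Returns a
    gene -> module id dict covering exactly the graph's nodes;
    deterministic for a fixed (graph, seed).
    """
    if graph.number_of_nodes() == 0:
        return {}
    rng = np.random.default_rng(seed)

    def louvain(g):
        s = int(rng.integers(0, 2**31 - 1))
        return [set(c) for c in nx.community.louvain_communities(
            g, seed=s, resolution=resolution
        )]

    final = []
    queue = louvain(graph)
    while queue:
        comm = queue.pop()
        if len(comm) <= max_module_size:
            final.append(comm)
            continue
        sub = graph.subgraph(comm)
        parts = louvain(sub)
        if len(parts) <= 1:  # refuses to split further
            final.append(comm)
            continue
        queue.extend(parts)

    # deterministic module ids: order by size desc, then smallest member
    final.sort(key=lambda c: (-len(c), min(map(str, c))))
    partition = {}
    next_id = 0
    for comm in final:
        if len(comm) < min_module_size:
            mid = UNASSIGNED
        else:
            mid = next_id
            next_id += 1
        for gene in comm:
            partition[gene] = mid
    return partition


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file into a gene -> set-of-terms map."""
    term_to_genes = _read_gmt_terms(str(path))
    gene_to_terms: dict[str, set[str]] = {}
    for term, genes in term_to_genes.items():
        for gene in genes:
            gene_to_terms.setdefault(gene, set()).add(term)
    return gene_to_terms


def annotation_interaction_density(graph: nx.Graph, annotation: dict) -> float:
    """Fraction of annotated edges whose endpoints share >= 1 term.

    An edge counts toward the denominator only when both endpoints appear
    in the annotation map; it counts toward the numerator when their term
    sets intersect.  Raises :class:`UndefinedDensityError` when no edge is
    fully annotated.
    """
    annotated = 0
    sharing = 0
    for u, v in graph.edges():
        tu = annotation.get(u)
        tv = annotation.get(v)
        if not tu or not tv:
            continue
        annotated += 1
        if tu & tv:
            sharing += 1
    if annotated == 0:
        raise UndefinedDensityError("no edge has both endpoints annotated")
    return sharing / annotated


@dataclass
class DensityNullResult:
    observed: float
    null_densities: np.ndarray
    p_value: float
    n_random: int


def density_null_test(
    graph: nx.Graph,
    annotation: dict,
    n_random: int = 100,
    seed: int = 0,
    null: str = "gnm",
) -> DensityNullResult:
    """Compare the observed interaction density with random networks.

    ``null="gnm"`` (default) draws Erdos-Renyi G(n, m) graphs on the same
    node set with the same edge count — the "same genes and interaction
    density" null.  ``null="rewire"`` instead degree-preservingly rewires
    the observed graph (double edge swaps), for sensitivity analysis.
    Empirical p = (1 + #{null >= observed}) / (1 + n_random).
    """
    if n_random < 10:
        raise ValueError("n_random must be >= 10")
    observed = annotation_interaction_density(graph, annotation)
    nodes = list(graph.nodes())
    m = graph.number_of_edges()
    rng = np.random.default_rng(seed)
    null_densities = np.empty(n_random)
    for r in range(n_random):
        s = int(rng.integers(0, 2**31 - 1))
        if null == "gnm":
            g = nx.gnm_random_graph(len(nodes), m, seed=s)
            g = nx.relabel_nodes(g, dict(enumerate(nodes)))
        elif null == "rewire":
            g = graph.copy()
            if m > 1:
                nx.double_edge_swap(g, nswap=5 * m, max_tries=100 * m, seed=s)
        else:
            raise ValueError(f"unknown null model {null!r}")
        try:
            null_densities[r] = annotation_interaction_density(g, annotation)
        except UndefinedDensityError:
            null_densities[r] = 0.0
    p = (1 + int((null_densities >= observed).sum())) / (1 + n_random)
    return DensityNullResult(observed, null_densities, p, n_random)


# ---------------------------------------------------------------------------
# exports


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV: gene_i, gene_j plus any edge attributes present."""
    rows = [{"gene_i": u, "gene_j": v, **d} for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_partition(partition: dict, path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(partition), "module": [partition[g] for g in partition]}
    ).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)
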