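"""Synthetic cohorts and the two proof-of-concept heterogeneity experiments.

The generator emulates the structure of a clone-mixing study: a baseline
(ancestral) expression profile on the log2 scale, per-clone profiles that
deviate from it by independent Gaussian perturbations, a connected random
protein-interaction network, and bulk "tumors" formed by averaging clone
profiles.  Two experiments run on top:

* **mixing experiment** — average k randomly chosen clones and measure the
  nJSD distance of the mixture to the maximally ambiguous state A; as k
  grows the mixture flattens and the distance falls.
* **bulk-vs-cells z-score** — compare one bulk profile's distance to state A
  against the distribution of single-cell (single-clone) distances; a bulk
  mixture of divergent clones sits significantly closer to A (z < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .divergence import NeighborhoodIndex

__all__ = [
    "SyntheticCohort",
    "MixingConfig",
    "generate_synthetic_cohort",
    "generate_gene_sets",
    "mix_profiles",
    "mixing_experiment",
    "mixing_summary",
    "bulk_vs_cells_zscore",
]


@dataclass(frozen=True)
class SyntheticCohort:
    network: nx.Graph
    clones: pd.DataFrame  # genes × clones, log2 scale
    baseline: pd.Series


@dataclass(frozen=True)
class MixingConfig:
    """Conditions of a clone-mixing run.

    Defaults are the desk-scale study conditions: powers of two up to the
    clone-pool size, 100 replicate mixtures per size.
    """

    mixture_sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)
    replicates: int = 100
    seed: int = 0

    def validate(self, pool_size: int) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        for k in self.mixture_sizes:
            if not 1 <= k <= pool_size:
                raise ValueError(f"mixture size {k} exceeds pool of {pool_size} profiles")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_synthetic_cohort(
    n_genes: int = 200,
    n_clones: int = 128,
    network_model: str = "barabasi_albert",
    network_param: float = 3,
    clone_divergence: float = 1.0,
    baseline_logmean: float = 3.0,
    baseline_logsd: float = 2.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a connected random PIN plus clone expression profiles.

    Baseline log2 expression per gene ~ N(baseline_logmean, baseline_logsd)
    clipped at 0; clone c's value = baseline + N(0, clone_divergence), again
    clipped at 0.  ``clone_divergence`` is the s.d. of per-clone log2
    perturbations; 0 makes every clone identical to the baseline.  The
    network is scale-free (Barabási–Albert, ``network_param`` = attachment
    edges) or Erdős–Rényi (``network_param`` = edge probability); the
    largest connected component is retained.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be ≥ 10")
    if n_clones < 1:
        raise ValueError("n_clones must be ≥ 1")
    if clone_divergence < 0:
        raise ValueError("clone_divergence must be ≥ 0")
    rng = np.random.default_rng(seed)
    net_seed = int(rng.integers(2**31 - 1))

    if network_model == "barabasi_albert":
        graph = nx.barabasi_albert_graph(n_genes, int(network_param), seed=net_seed)
    elif network_model == "erdos_renyi":
        graph = nx.gnp_random_graph(n_genes, float(network_param), seed=net_seed)
    else:
        raise ValueError(f"unknown network_model {network_model!r}")
    largest = max(nx.connected_components(graph), key=len)
    graph = nx.Graph(graph.subgraph(largest))
    names = _gene_names(n_genes)
    graph = nx.relabel_nodes(graph, {i: names[i] for i in graph.nodes})

    baseline = np.clip(rng.normal(baseline_logmean, baseline_logsd, n_genes), 0.0, None)
    perturb = rng.normal(0.0, 1.0, (n_genes, n_clones)) * clone_divergence
    clones = np.clip(baseline[:, None] + perturb, 0.0, None)

    clone_ids = [f"clone{c:03d}" for c in range(n_clones)]
    clones_df = pd.DataFrame(clones, index=names, columns=clone_ids)
    baseline_s = pd.Series(baseline, index=names, name="baseline")
    return SyntheticCohort(graph, clones_df, baseline_s)


def generate_gene_sets(
    genes, n_sets: int = 5, set_size: int = 20, seed: int = 0
) -> dict[str, frozenset]:
    """Random gene sets over a gene universe (small synthetic GMT stand-in)."""
    genes = list(genes)
    if set_size > len(genes):
        raise ValueError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    return {
        f"set{i:02d}": frozenset(rng.choice(genes, size=set_size, replace=False))
        for i in range(n_sets)
    }


def mix_profiles(matrix: pd.DataFrame, k: int, rng: np.random.Generator) -> pd.Series:
    """Bulk mixture: per-gene mean of k columns sampled without replacement.

    Averaging on the log2 scale matches mixing the already log-transformed
    profiles; see :func:`mixing_experiment` for a linear-scale option.
    """
    n = matrix.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} profiles")
    cols = rng.choice(n, size=k, replace=False)
    mixture = matrix.iloc[:, cols].mean(axis=1)
    mixture.name = f"mix_k{k}"
    return mixture


def mixing_experiment(
    matrix: pd.DataFrame,
    net: nx.Graph,
    cfg: MixingConfig = MixingConfig(),
    linear_scale: bool = False,
) -> pd.DataFrame:
    """Distance to state A of random k-clone mixtures.

    For each k in ``cfg.mixture_sizes`` and each replicate, draw k clone
    columns without replacement, average them (log2 scale by default;
    ``linear_scale=True`` averages 2**x − 1 and returns to log2, the way
    physical RNA mixes), and record nJSD(mixture, state A).

    Returns a tidy frame with columns ``k``, ``replicate``, ``distance_to_A``.
    """
    cfg.validate(matrix.shape[1])
    rng = np.random.default_rng(cfg.seed)
    universe = set(net.nodes) & set(matrix.index)
    if not universe:
        raise ValueError("network and expression matrix share no genes")
    idx = NeighborhoodIndex(net, universe)
    ones = np.ones(len(idx.universe))

    # linear mode mixes back-transformed abundances (log2(x+1) convention)
    working = (2.0 ** matrix - 1.0) if linear_scale else matrix
    rows = []
    for k in cfg.mixture_sizes:
        for rep in range(cfg.replicates):
            mixture = mix_profiles(working, k, rng)
            if linear_scale:
                mixture = np.log2(mixture + 1.0)
            jsd, defined = idx.per_gene_jsd(idx.expression_vector(mixture), ones)
            rows.append(
                {"k": k, "replicate": rep, "distance_to_A": float(np.nanmean(jsd[defined]))}
            )
    return pd.DataFrame(rows)


def mixing_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-k mean and s.d. of the distance to state A."""
    out = table.groupby("k")["distance_to_A"].agg(["mean", "std"]).reset_index()
    out.columns = ["k", "mean_distance", "sd_distance"]
    return out


def bulk_vs_cells_zscore(
    cells: pd.DataFrame, bulk: pd.Series, net: nx.Graph
) -> tuple[float, float]:
    """Z-score of a bulk sample's distance to state A against single cells.

    d_c = nJSD(cell_c, A) for each single-cell column, d_b likewise for the
    bulk; z = (d_b − mean(d)) / sd(d) with the sample (n−1) standard
    deviation, and the one-sided p-value is the standard-normal lower tail
    (testing whether the bulk is *closer* to state A than the cells).
    """
    if cells.shape[1] < 3:
        raise ValueError("need at least 3 single cells")
    universe = set(net.nodes) & set(cells.index) & set(bulk.index)
    if not universe:
        raise ValueError("network and profiles share no genes")
    idx = NeighborhoodIndex(net, universe)
    ones = np.ones(len(idx.universe))

    def dist(profile: pd.Series) -> float:
        jsd, defined = idx.per_gene_jsd(idx.expression_vector(profile), ones)
        return float(np.nanmean(jsd[defined]))

    d_cells = np.array([dist(cells[c]) for c in cells.columns])
    d_bulk = dist(bulk)
    sd = d_cells.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across single-cell distances; z undefined")
    z = (d_bulk - d_cells.mean()) / sd
    p = float(stats.norm.cdf(z))
    return float(z), p
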