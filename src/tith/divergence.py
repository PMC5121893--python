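"""Network Jensen–Shannon divergence (nJSD) between two expression states.

The model treats each gene's interactions as governed by the law of mass
action: the probability that gene *i* interacts with neighbor *j* is
proportional to *j*'s expression level,

    p_ij = e_j / Σ_{k ∈ J_i} e_k,

where J_i is *i*'s neighbor set in the protein-interaction network.  The
vector PD_i(X) = (p_i1, …, p_in) over *i*'s ordered neighbors is the
neighbor distribution of gene *i* in sample X.  The divergence of gene *i*
between two states N and T is the Jensen–Shannon divergence

    JSD_i = ½·KLD(PD_i(N) ‖ M) + ½·KLD(PD_i(T) ‖ M),   M = ½(PD_i(N)+PD_i(T)),

with base-2 logarithms so that JSD_i ∈ [0, 1], and nJSD(N, T) is the mean
JSD_i over all usable network genes.

Conventions
-----------
* 0·log(0/x) := 0; the mixture M is positive wherever either distribution
  is, so no division by zero can occur inside the JSD.
* Neighbors absent from either expression profile are dropped from *both*
  states' neighbor lists, keeping PD_i(N) and PD_i(T) aligned on a common
  support.
* A gene whose neighbor-expression sum is zero in either state has an
  undefined distribution there; such genes are excluded from the average
  (flagged and counted), never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import rel_entr

__all__ = [
    "NeighborDistribution",
    "GeneDivergence",
    "NJSDResult",
    "NeighborhoodIndex",
    "neighbor_distribution",
    "kld",
    "gene_jsd",
    "njsd",
    "write_gene_divergences",
]

_EPS_NEG = -1e-12  # tolerated float undershoot before clipping JSD at 0


@dataclass(frozen=True)
class NeighborDistribution:
    """Probability vector of one gene over its ordered neighbor list."""

    gene: str
    neighbors: tuple[str, ...]
    probs: np.ndarray
    defined: bool = True


@dataclass(frozen=True)
class GeneDivergence:
    """Per-gene JSD between two states; ``defined`` is False when either
    state's neighbor distribution was degenerate."""

    gene: str
    jsd: float
    defined: bool = True


@dataclass(frozen=True)
class NJSDResult:
    value: float
    per_gene: pd.DataFrame = field(repr=False)
    n_genes_used: int = 0
    n_genes_skipped: int = 0


class NeighborhoodIndex:
    """CSR-style view of a network restricted to a gene universe.

    Precomputes, for the sorted list of universe genes with at least one
    universe neighbor, a flat neighbor-index array plus segment pointers, so
    that per-gene distributions for many profiles can be computed with pure
    array operations.  Build once per (network, universe) pair and reuse.
    """

    def __init__(self, net: nx.Graph, universe) -> None:
        universe = set(universe) & set(net.nodes)
        genes, indptr, nbr = [], [0], []
        order = sorted(universe)
        pos = {g: i for i, g in enumerate(order)}
        for g in order:
            nbrs = sorted(n for n in net.neighbors(g) if n in universe)
            if not nbrs:
                continue
            genes.append(g)
            nbr.extend(pos[n] for n in nbrs)
            indptr.append(len(nbr))
        self.universe: tuple[str, ...] = tuple(order)
        self.genes: tuple[str, ...] = tuple(genes)
        self.indptr = np.asarray(indptr, dtype=np.intp)
        self.nbr_idx = np.asarray(nbr, dtype=np.intp)
        self._counts = np.diff(self.indptr)

    def __len__(self) -> int:
        return len(self.genes)

    def expression_vector(self, profile: pd.Series) -> np.ndarray:
        """Align a profile to the universe gene order."""
        vec = profile.reindex(list(self.universe)).to_numpy(dtype=float)
        if np.isnan(vec).any():
            missing = [g for g, v in zip(self.universe, vec) if math.isnan(v)]
            raise KeyError(f"profile is missing universe gene(s): {missing[:5]}...")
        return vec

    def per_gene_jsd(
        self, ex: np.ndarray, ey: np.ndarray, base: float = 2.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized JSD_i for every indexed gene.

        Parameters
        ----------
        ex, ey
            Expression vectors aligned to ``self.universe``.
        base
            Logarithm base (2 by default, giving JSD ∈ [0, 1]).

        Returns
        -------
        jsd : float array (NaN where undefined)
        defined : bool array
        """
        starts = self.indptr[:-1]
        pv = ex[self.nbr_idx]
        qv = ey[self.nbr_idx]
        sp = np.add.reduceat(pv, starts)
        sq = np.add.reduceat(qv, starts)
        defined = (sp > 0) & (sq > 0)
        # normalise per segment; undefined segments get a harmless dummy sum
        sp_safe = np.where(sp > 0, sp, 1.0)
        sq_safe = np.where(sq > 0, sq, 1.0)
        p = pv / np.repeat(sp_safe, self._counts)
        q = qv / np.repeat(sq_safe, self._counts)
        m = 0.5 * (p + q)
        terms = rel_entr(p, m) + rel_entr(q, m)  # natural log; 0·log0 handled
        jsd = 0.5 * np.add.reduceat(terms, starts) / math.log(base)
        jsd = np.where(jsd > _EPS_NEG, np.maximum(jsd, 0.0), jsd)
        jsd = np.where(defined, jsd, np.nan)
        return jsd, defined


def neighbor_distribution(
    profile: pd.Series, net: nx.Graph, gene: str
) -> NeighborDistribution:
    """Mass-action neighbor distribution of one gene in one sample.

    Neighbors missing from the profile are dropped.  If the remaining
    neighbor-expression sum is zero the distribution is flagged undefined
    (probs all NaN).
    """
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    nbrs = tuple(sorted(n for n in net.neighbors(gene) if n in profile.index))
    if not nbrs:
        raise ValueError(f"gene {gene!r} has no neighbors present in the profile")
    e = profile.loc[list(nbrs)].to_numpy(dtype=float)
    total = e.sum()
    if total <= 0:
        return NeighborDistribution(gene, nbrs, np.full(len(nbrs), np.nan), defined=False)
    return NeighborDistribution(gene, nbrs, e / total, defined=True)


def kld(p, q, base: float = 2.0) -> float:
    """Kullback–Leibler divergence Σ p·log(p/q), with 0·log(0/x) := 0.

    Raises on a support violation (p > 0 where q = 0); the JSD mixture
    never triggers this.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions have different lengths")
    terms = rel_entr(p, q)
    if np.isinf(terms).any():
        raise ValueError("infinite divergence: p has mass where q is zero")
    return float(terms.sum() / math.log(base))


def gene_jsd(
    p: NeighborDistribution, q: NeighborDistribution, base: float = 2.0
) -> GeneDivergence:
    """Jensen–Shannon divergence between two neighbor distributions of the
    same gene (symmetric; bounded by 1 in base 2)."""
    if p.gene != q.gene or p.neighbors != q.neighbors:
        raise ValueError(
            f"mismatched neighbor lists for {p.gene!r}/{q.gene!r}: "
            "distributions must share gene and neighbor ordering"
        )
    if not (p.defined and q.defined):
        return GeneDivergence(p.gene, float("nan"), defined=False)
    m = 0.5 * (p.probs + q.probs)
    value = 0.5 * kld(p.probs, m, base) + 0.5 * kld(q.probs, m, base)
    return GeneDivergence(p.gene, max(value, 0.0), defined=True)


def _as_index(net, x: pd.Series, y: pd.Series) -> NeighborhoodIndex:
    if isinstance(net, NeighborhoodIndex):
        return net
    universe = set(net.nodes) & set(x.index) & set(y.index)
    return NeighborhoodIndex(net, universe)


def njsd(x: pd.Series, y: pd.Series, net, base: float = 2.0) -> NJSDResult:
    """Network JSD between two expression states: mean per-gene JSD over all
    usable genes of ``net`` (nodes ∩ both profiles, with ≥1 usable neighbor
    and defined distributions in both states).

    ``net`` may be a :class:`networkx.Graph` or a prebuilt
    :class:`NeighborhoodIndex` (for repeated calls on one network).
    Symmetric in ``x`` and ``y``; 0 when the profiles agree on the universe.
    """
    idx = _as_index(net, x, y)
    if len(idx) == 0:
        raise ValueError("no usable genes: network and profiles share no connected genes")
    jsd, defined = idx.per_gene_jsd(idx.expression_vector(x), idx.expression_vector(y), base)
    n_used = int(defined.sum())
    if n_used == 0:
        raise ValueError("no gene has a defined neighbor distribution in both states")
    per_gene = pd.DataFrame({"jsd": jsd, "defined": defined}, index=list(idx.genes))
    per_gene.index.name = "gene"
    return NJSDResult(
        value=float(np.nanmean(jsd[defined])),
        per_gene=per_gene,
        n_genes_used=n_used,
        n_genes_skipped=int(len(idx) - n_used),
    )


def write_gene_divergences(result: NJSDResult, path) -> None:
    """Write the per-gene JSD table as TSV: gene, jsd, defined."""
    result.per_gene.to_csv(path, sep="\t")
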