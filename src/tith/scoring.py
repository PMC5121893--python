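"""Transcriptome-based intratumor-heterogeneity (tITH) scores.

A tumor's network state is placed between two references:

* the **normal** state N — a measured normal profile (or a mean of several);
* the **maximally ambiguous** state A — every gene at equal expression, so
  every gene's mass-action neighbor distribution is uniform.

With NT = nJSD(normal, tumor) and TA = nJSD(tumor, A), both averaged over
the *same* restricted gene universe,

    tITH = NT / (NT + TA)  ∈ [0, 1].

A heterogeneous tumor — a bulk mixture of divergent clones — looks flat
across the network and sits close to state A (large NT, small TA, tITH→1);
a tumor transcriptionally close to its normal tissue scores near 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .divergence import NeighborhoodIndex
from .expression import aggregate_reference

__all__ = [
    "TITHResult",
    "ambiguous_reference",
    "combine_nt_ta",
    "tith",
    "tith_cohort",
    "results_frame",
    "TITHScorer",
]


@dataclass(frozen=True)
class TITHResult:
    """Per-sample heterogeneity score.

    ``degenerate`` marks the corner case NT + TA = 0 (the tumor equals both
    the normal reference and state A on the usable universe), where the
    ratio is undefined and reported as 0.
    """

    sample_id: str
    nt: float
    ta: float
    tith: float
    n_genes_used: int
    degenerate: bool = False


def ambiguous_reference(net: nx.Graph, genes: Iterable[str], value: float = 1.0) -> pd.Series:
    """State-A profile: constant expression on ``genes ∩ net nodes``.

    Under mass action a constant profile induces the uniform distribution
    over every gene's (restricted) neighbor set; by scaling invariance any
    positive constant yields the same distributions.
    """
    if value <= 0:
        raise ValueError("state-A constant must be positive")
    keep = sorted(set(genes) & set(net.nodes))
    if not keep:
        raise ValueError("no overlap between requested genes and network nodes")
    return pd.Series(value, index=keep, name="state_A")


def combine_nt_ta(nt: float, ta: float) -> tuple[float, bool]:
    """tITH ratio NT/(NT+TA); returns (value, degenerate flag)."""
    if nt < 0 or ta < 0:
        raise ValueError("NT and TA must be non-negative")
    total = nt + ta
    if total == 0:
        return 0.0, True
    return nt / total, False


def _per_gene_nt_ta(
    normal: pd.Series, tumor: pd.Series, net, base: float = 2.0
) -> tuple[pd.DataFrame, NeighborhoodIndex]:
    """Per-gene JSD tables for NT and TA on the shared gene universe.

    State A is constructed on the same universe as NT so that both averages
    run over identical gene sets; a gene counts only if its distribution is
    defined in the normal state, the tumor state, and state A.
    """
    if isinstance(net, NeighborhoodIndex):
        idx = net
    else:
        universe = set(net.nodes) & set(normal.index) & set(tumor.index)
        if not universe:
            raise ValueError("no usable genes shared by network, normal and tumor")
        idx = NeighborhoodIndex(net, universe)
    if len(idx) == 0:
        raise ValueError("no connected genes on the shared universe")
    e_n = idx.expression_vector(normal)
    e_t = idx.expression_vector(tumor)
    e_a = np.ones_like(e_t)
    jsd_nt, def_nt = idx.per_gene_jsd(e_n, e_t, base)
    jsd_ta, def_ta = idx.per_gene_jsd(e_t, e_a, base)
    table = pd.DataFrame(
        {"jsd_nt": jsd_nt, "jsd_ta": jsd_ta, "defined": def_nt & def_ta},
        index=list(idx.genes),
    )
    table.index.name = "gene"
    return table, idx


def tith(normal: pd.Series, tumor: pd.Series, net, base: float = 2.0) -> TITHResult:
    """tITH of one tumor sample against a normal reference.

    ``net`` may be a :class:`networkx.Graph` or a prebuilt
    :class:`~tith.divergence.NeighborhoodIndex`.  The logarithm base cancels
    in the ratio; it only rescales NT and TA.
    """
    table, _ = _per_gene_nt_ta(normal, tumor, net, base)
    used = table.loc[table["defined"]]
    if used.empty:
        raise ValueError("no gene has defined distributions in all three states")
    nt = float(used["jsd_nt"].mean())
    ta = float(used["jsd_ta"].mean())
    score, degenerate = combine_nt_ta(nt, ta)
    sample_id = tumor.name if tumor.name is not None else "tumor"
    return TITHResult(str(sample_id), nt, ta, score, len(used), degenerate)


def tith_cohort(
    normals: pd.DataFrame,
    tumors: pd.DataFrame,
    net,
    reference_scale: str = "log",
    base: float = 2.0,
) -> list[TITHResult]:
    """tITH for every tumor column against the pooled normal reference.

    The reference is the per-gene mean of all normal samples (the pooled,
    per-cancer-type convention), computed once; tumors are scored in column
    order.
    """
    if normals.shape[1] == 0 or tumors.shape[1] == 0:
        raise ValueError("need at least one normal and one tumor sample")
    reference = aggregate_reference(normals, scale=reference_scale)
    universe = set(net.nodes) & set(reference.index) & set(tumors.index)
    if not universe:
        raise ValueError("no usable genes shared by network, normals and tumors")
    idx = NeighborhoodIndex(net, universe)
    return [tith(reference, tumors[s], idx, base) for s in tumors.columns]


def results_frame(results: Iterable[TITHResult]) -> pd.DataFrame:
    """Tabulate results: sample, NT, TA, tITH, n_genes_used."""
    rows = [
        {
            "sample": r.sample_id,
            "NT": r.nt,
            "TA": r.ta,
            "tITH": r.tith,
            "n_genes_used": r.n_genes_used,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["sample", "NT", "TA", "tITH", "n_genes_used"])


class TITHScorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer computing per-sample tITH scores.

    Parameters
    ----------
    network : networkx.Graph
        Undirected protein-interaction network over gene symbols.
    reference_scale : {"log", "linear"}
        How normal samples are averaged into the reference profile.
    base : float
        Logarithm base for the underlying divergences (the tITH ratio is
        base-invariant).

    Attributes
    ----------
    reference_ : pandas.Series
        Pooled normal reference profile (set by :meth:`fit`).
    n_normal_samples_ : int

    Examples
    --------
    >>> scorer = TITHScorer(network).fit(normals)   # samples × genes
    >>> scores = scorer.transform(tumors)           # NT, TA, tITH per sample

    Input frames follow the sklearn orientation (rows = samples, columns =
    genes); use ``matrix.T`` on a genes × samples table from
    :func:`tith.expression.load_expression`.
    """

    def __init__(self, network=None, reference_scale: str = "log", base: float = 2.0):
        self.network = network
        self.reference_scale = reference_scale
        self.base = base

    def _check_frame(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "expected a pandas DataFrame (samples × genes) with gene-symbol columns"
            )
        if X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("empty expression frame")
        return X

    def fit(self, X, y=None):
        """Build the normal reference from a samples × genes frame."""
        if self.network is None:
            raise ValueError("TITHScorer requires a network")
        X = self._check_frame(X)
        self.reference_ = aggregate_reference(X.T, scale=self.reference_scale)
        self.n_normal_samples_ = X.shape[0]
        return self

    def transform(self, X) -> pd.DataFrame:
        """Score tumor samples; returns a frame indexed by sample with
        columns NT, TA, tITH, n_genes_used."""
        if not hasattr(self, "reference_"):
            raise ValueError("TITHScorer is not fitted; call fit(normals) first")
        X = self._check_frame(X)
        universe = set(self.network.nodes) & set(self.reference_.index) & set(X.columns)
        if not universe:
            raise ValueError("no usable genes shared by network, reference and samples")
        idx = NeighborhoodIndex(self.network, universe)
        results = [tith(self.reference_, X.loc[s], idx, self.base) for s in X.index]
        out = results_frame(results).set_index("sample")
        out.index = X.index
        return out

    def score_samples(self, X) -> pd.Series:
        """Convenience: the tITH column of :meth:`transform`."""
        return self.transform(X)["tITH"]
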