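"""Pathway-level heterogeneity: pathway-tITH and covariate screens.

Pathway-tITH restricts the *averaging* step of tITH to the genes of one
gene set: per-gene divergences are computed with full-network neighborhoods
exactly as for the global score, then NT and TA are averaged only over the
set's usable genes.  An off-by-default ``induced_subgraph`` mode instead
rebuilds neighborhoods within the pathway-induced subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .divergence import NeighborhoodIndex
from .expression import aggregate_reference
from .network import restrict_to_genes
from .scoring import _per_gene_nt_ta, combine_nt_ta

logger = logging.getLogger(__name__)

__all__ = [
    "load_gmt",
    "PathwayTITH",
    "pathway_tith",
    "pathway_tith_table",
    "pathway_screen",
    "PathwayTITHScorer",
]


def load_gmt(path) -> dict[str, frozenset]:
    """Parse a GMT gene-set file: ``name<TAB>description<TAB>gene1<TAB>...``.

    Duplicate genes within a line are deduplicated; duplicate pathway names
    raise.  Returns an insertion-ordered mapping name → frozenset of genes.
    """
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} field(s) found)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


@dataclass(frozen=True)
class PathwayTITH:
    sample_id: str
    pathway: str
    nt: float
    ta: float
    tith: float
    n_genes_used: int
    n_genes_dropped: int  # set members outside the usable universe
    degenerate: bool = False
    skipped: bool = False  # no usable genes at all


def _aggregate_set(
    table: pd.DataFrame, gene_set: frozenset, sample_id: str, pathway: str
) -> PathwayTITH:
    members = table.index.intersection(sorted(gene_set))
    usable = table.loc[members]
    usable = usable.loc[usable["defined"]]
    dropped = len(gene_set) - len(usable)
    if usable.empty:
        return PathwayTITH(
            sample_id, pathway, float("nan"), float("nan"), float("nan"),
            0, dropped, degenerate=False, skipped=True,
        )
    nt = float(usable["jsd_nt"].mean())
    ta = float(usable["jsd_ta"].mean())
    score, degenerate = combine_nt_ta(nt, ta)
    return PathwayTITH(sample_id, pathway, nt, ta, score, len(usable), dropped, degenerate)


def pathway_tith(
    normal: pd.Series,
    tumor: pd.Series,
    net,
    gene_set: Iterable[str],
    pathway: str = "pathway",
    base: float = 2.0,
    induced_subgraph: bool = False,
) -> PathwayTITH:
    """tITH averaged only over one gene set's usable genes.

    With ``induced_subgraph=True`` the neighborhoods themselves are rebuilt
    inside the pathway-induced subgraph (an alternative reading of
    pathway restriction; default keeps full-network neighborhoods).
    """
    gene_set = frozenset(gene_set)
    if induced_subgraph:
        net = restrict_to_genes(net, gene_set)
        if net.number_of_nodes() == 0:
            return PathwayTITH(
                str(tumor.name or "tumor"), pathway, float("nan"), float("nan"),
                float("nan"), 0, len(gene_set), skipped=True,
            )
    table, _ = _per_gene_nt_ta(normal, tumor, net, base)
    row = _aggregate_set(table, gene_set, str(tumor.name or "tumor"), pathway)
    if row.skipped:
        logger.warning("pathway %r: no usable genes; row flagged skipped", pathway)
    return row


def pathway_tith_table(
    normal: pd.Series,
    tumor: pd.Series,
    net,
    collection: Mapping[str, frozenset],
    base: float = 2.0,
) -> pd.DataFrame:
    """Long-format pathway-tITH table for one tumor sample (per-gene
    divergences computed once, then aggregated per pathway)."""
    table, _ = _per_gene_nt_ta(normal, tumor, net, base)
    sample_id = str(tumor.name or "tumor")
    rows = [
        _aggregate_set(table, genes, sample_id, name) for name, genes in collection.items()
    ]
    return pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "pathway": r.pathway,
                "NT": r.nt,
                "TA": r.ta,
                "tITH": r.tith,
                "n_genes_used": r.n_genes_used,
            }
            for r in rows
        ]
    )


def pathway_screen(
    normals: pd.DataFrame,
    tumors: pd.DataFrame,
    net,
    collection: Mapping[str, frozenset],
    covariate: Mapping[str, float],
    reference_scale: str = "log",
    base: float = 2.0,
    qvalues: bool = False,
) -> pd.DataFrame:
    """Screen pathways whose pathway-tITH tracks an external covariate.

    For each pathway, Pearson correlation of per-sample pathway-tITH against
    the covariate (e.g. a genome-based clone count), two-sided p-value,
    sorted by \\|r\\| descending.  Pathways with constant tITH across samples
    get r = NaN and ``flagged=True``.  Raw p-values by default; Benjamini–
    Hochberg q-values with ``qvalues=True``.
    """
    samples = [s for s in tumors.columns if s in covariate]
    if len(samples) < 3:
        raise ValueError(f"need ≥3 samples with covariate values, have {len(samples)}")
    reference = aggregate_reference(normals, scale=reference_scale)
    universe = set(net.nodes) & set(reference.index) & set(tumors.index)
    if not universe:
        raise ValueError("no usable genes shared by network, normals and tumors")
    idx = NeighborhoodIndex(net, universe)

    per_pathway: dict[str, list[float]] = {name: [] for name in collection}
    for s in samples:
        table, _ = _per_gene_nt_ta(reference, tumors[s], idx, base)
        for name, genes in collection.items():
            per_pathway[name].append(_aggregate_set(table, genes, s, name).tith)

    cov = np.asarray([covariate[s] for s in samples], dtype=float)
    rows = []
    for name, values in per_pathway.items():
        vals = np.asarray(values, dtype=float)
        flagged = bool(np.isnan(vals).any() or np.ptp(vals) == 0 or np.ptp(cov) == 0)
        if flagged:
            rows.append({"pathway": name, "r": np.nan, "p": np.nan, "flagged": True})
            continue
        r, p = stats.pearsonr(vals, cov)
        rows.append({"pathway": name, "r": float(r), "p": float(p), "flagged": False})
    out = pd.DataFrame(rows)
    if qvalues:
        from statsmodels.stats.multitest import multipletests

        ok = ~out["p"].isna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["q"] = q
    return out.reindex(out["r"].abs().sort_values(ascending=False, na_position="last").index)


class PathwayTITHScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping samples × genes expression to samples × pathways
    pathway-tITH scores.

    Parameters mirror :class:`~tith.scoring.TITHScorer` plus ``gene_sets``,
    a mapping pathway name → gene set (see :func:`load_gmt`).
    """

    def __init__(
        self,
        network=None,
        gene_sets: Mapping[str, frozenset] | None = None,
        reference_scale: str = "log",
        base: float = 2.0,
    ):
        self.network = network
        self.gene_sets = gene_sets
        self.reference_scale = reference_scale
        self.base = base

    def fit(self, X, y=None):
        if self.network is None or not self.gene_sets:
            raise ValueError("PathwayTITHScorer requires a network and gene_sets")
        if not isinstance(X, pd.DataFrame) or X.empty:
            raise TypeError("expected a non-empty samples × genes DataFrame")
        self.reference_ = aggregate_reference(X.T, scale=self.reference_scale)
        self.n_normal_samples_ = X.shape[0]
        return self

    def transform(self, X) -> pd.DataFrame:
        """Wide samples × pathways frame of pathway-tITH values (NaN where a
        pathway has no usable genes)."""
        if not hasattr(self, "reference_"):
            raise ValueError("PathwayTITHScorer is not fitted; call fit(normals) first")
        universe = set(self.network.nodes) & set(self.reference_.index) & set(X.columns)
        if not universe:
            raise ValueError("no usable genes shared by network, reference and samples")
        idx = NeighborhoodIndex(self.network, universe)
        names = list(self.gene_sets)
        data = {}
        for s in X.index:
            table, _ = _per_gene_nt_ta(self.reference_, X.loc[s], idx, self.base)
            data[s] = [
                _aggregate_set(table, self.gene_sets[name], str(s), name).tith
                for name in names
            ]
        return pd.DataFrame.from_dict(data, orient="index", columns=names).loc[X.index]
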