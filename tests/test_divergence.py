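import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from tith.divergence import (
    NeighborhoodIndex,
    gene_jsd,
    kld,
    neighbor_distribution,
    njsd,
    write_gene_divergences,
)

from naive_oracle import naive_njsd


class TestNeighborDistribution:
    def test_equal_expression_is_uniform(self, star_net):
        profile = pd.Series({"A": 1.0, "B": 2.0, "C": 2.0})
        nd = neighbor_distribution(profile, star_net, "A")
        assert nd.neighbors == ("B", "C")
        np.testing.assert_allclose(nd.probs, [0.5, 0.5])

    def test_mass_action_ratio(self, star_net):
        profile = pd.Series({"A": 1.0, "B": 1.0, "C": 3.0})
        nd = neighbor_distribution(profile, star_net, "A")
        np.testing.assert_allclose(nd.probs, [0.25, 0.75])

    def test_zero_neighbor_sum_flagged_undefined(self, star_net):
        profile = pd.Series({"A": 1.0, "B": 0.0, "C": 0.0})
        nd = neighbor_distribution(profile, star_net, "A")
        assert not nd.defined

    def test_absent_gene_raises(self, star_net):
        with pytest.raises(KeyError):
            neighbor_distribution(pd.Series({"A": 1.0}), star_net, "Z")

    def test_missing_neighbors_dropped(self):
        net = nx.Graph([("A", "B"), ("A", "C"), ("A", "D")])
        profile = pd.Series({"A": 1.0, "B": 1.0, "C": 3.0})  # D unmeasured
        nd = neighbor_distribution(profile, net, "A")
        assert nd.neighbors == ("B", "C")
        np.testing.assert_allclose(nd.probs, [0.25, 0.75])


class TestKLD:
    def test_identity_is_zero(self):
        assert kld([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_point_mass_vs_uniform(self):
        assert kld([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_hand_worked_value(self):
        assert kld([0.25, 0.75], [0.375, 0.625]) == pytest.approx(0.051035, abs=1e-6)

    def test_support_violation_raises(self):
        with pytest.raises(ValueError, match="infinite"):
            kld([0.5, 0.5], [1.0, 0.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            kld([1.0], [0.5, 0.5])


class TestGeneJSD:
    def _nd(self, probs, gene="A", neighbors=("B", "C"), defined=True):
        from tith.divergence import NeighborDistribution

        return NeighborDistribution(gene, neighbors, np.asarray(probs, float), defined)

    def test_identical_distributions(self):
        d = gene_jsd(self._nd([0.3, 0.7]), self._nd([0.3, 0.7]))
        assert d.jsd == 0.0 and d.defined

    def test_disjoint_support_hits_base2_maximum(self):
        d = gene_jsd(self._nd([1.0, 0.0]), self._nd([0.0, 1.0]))
        assert d.jsd == pytest.approx(1.0)

    def test_hand_worked_value(self):
        d = gene_jsd(self._nd([0.5, 0.5]), self._nd([0.25, 0.75]))
        assert d.jsd == pytest.approx(0.048795, abs=1e-6)

    def test_symmetry(self):
        a, b = self._nd([0.9, 0.1]), self._nd([0.2, 0.8])
        assert gene_jsd(a, b).jsd == pytest.approx(gene_jsd(b, a).jsd, abs=1e-15)

    def test_one_side_undefined_propagates(self):
        d = gene_jsd(self._nd([0.5, 0.5]), self._nd([np.nan, np.nan], defined=False))
        assert not d.defined and math.isnan(d.jsd)

    def test_mismatched_neighbors_raise(self):
        with pytest.raises(ValueError, match="neighbor"):
            gene_jsd(self._nd([1.0], neighbors=("B",)), self._nd([1.0], neighbors=("C",)))

    def test_agrees_with_scipy_jensenshannon(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            ours = gene_jsd(
                self._nd(p, neighbors=tuple("vwxyz")), self._nd(q, neighbors=tuple("vwxyz"))
            ).jsd
            ref = jensenshannon(p, q, base=2) ** 2
            assert ours == pytest.approx(ref, abs=1e-12)


class TestNJSD:
    def test_identity(self, star_net, star_profiles):
        normal, _ = star_profiles
        assert njsd(normal, normal, star_net).value == 0.0

    def test_two_gene_path_mean_of_equal_divergences(self):
        net = nx.Graph([("A", "B")])
        x = pd.Series({"A": 2.0, "B": 3.0})
        y = pd.Series({"A": 5.0, "B": 1.0})
        # both genes have a single neighbor → point-mass distributions → 0
        r = njsd(x, y, net)
        assert r.value == 0.0 and r.n_genes_used == 2

    def test_worked_star_example(self, star_net, star_profiles):
        normal, tumor = star_profiles
        r = njsd(normal, tumor, star_net)
        assert r.value == pytest.approx(0.016265, abs=1e-6)
        assert r.per_gene.loc["A", "jsd"] == pytest.approx(0.048795, abs=1e-6)
        assert r.per_gene.loc["B", "jsd"] == 0.0

    def test_symmetry_exact(self, random_instance):
        for seed in range(5):
            net, x, y = random_instance(seed)
            assert njsd(x, y, net).value == njsd(y, x, net).value

    def test_scaling_invariance(self, random_instance):
        net, x, y = random_instance(3)
        base = njsd(x, y, net).value
        assert njsd(x * 37.5, y, net).value == pytest.approx(base, abs=1e-12)
        assert njsd(x, y * 0.001, net).value == pytest.approx(base, abs=1e-12)

    def test_degree_one_genes_contribute_zero(self):
        net = nx.star_graph(["hub", "l1", "l2", "l3"])
        x = pd.Series({"hub": 4.0, "l1": 1.0, "l2": 2.0, "l3": 3.0})
        y = pd.Series({"hub": 9.0, "l1": 3.0, "l2": 2.0, "l3": 1.0})
        per_gene = njsd(x, y, net).per_gene
        for leaf in ("l1", "l2", "l3"):
            assert per_gene.loc[leaf, "jsd"] == 0.0

    def test_skipped_genes_counted(self):
        net = nx.Graph([("A", "B"), ("C", "D")])
        x = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "D": 0.0})
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 1.0, "D": 0.0})
        # C's only neighbor (D) has zero expression in both states
        r = njsd(x, y, net)
        assert r.n_genes_skipped == 1 and r.n_genes_used == 3

    def test_all_undefined_raises(self):
        net = nx.Graph([("A", "B")])
        x = pd.Series({"A": 0.0, "B": 0.0})
        with pytest.raises(ValueError):
            njsd(x, x, net)

    def test_prebuilt_index_matches_graph_route(self, random_instance):
        net, x, y = random_instance(9)
        idx = NeighborhoodIndex(net, set(x.index))
        assert njsd(x, y, idx).value == njsd(x, y, net).value

    def test_matches_naive_oracle_on_random_instances(self, random_instance):
        for seed in range(10):
            net, x, y = random_instance(seed, allow_zeros=True)
            expected = naive_njsd(x.to_dict(), y.to_dict(), net)
            got = njsd(x, y, net).value
            assert got == pytest.approx(expected, abs=1e-12)

    def test_per_gene_table_writer(self, star_net, star_profiles, tmp_path):
        normal, tumor = star_profiles
        path = tmp_path / "jsd.tsv"
        write_gene_divergences(njsd(normal, tumor, star_net), path)
        table = pd.read_csv(path, sep="\t", index_col=0)
        assert list(table.columns) == ["jsd", "defined"]
        assert len(table) == 3


@st.composite
def instance(draw):
    n = draw(st.integers(min_value=2, max_value=8))
    edges = draw(
        st.sets(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                lambda e: e[0] < e[1]
            ),
            min_size=1,
            max_size=n * (n - 1) // 2,
        )
    )
    vals = st.floats(min_value=0.01, max_value=100.0, allow_nan=False)
    x = draw(st.lists(vals, min_size=n, max_size=n))
    y = draw(st.lists(vals, min_size=n, max_size=n))
    net = nx.Graph((f"g{a}", f"g{b}") for a, b in edges)
    genes = [f"g{i}" for i in range(n)]
    return net, pd.Series(x, index=genes), pd.Series(y, index=genes)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(instance())
def test_property_jsd_bounded_and_symmetric(inst):
    """For any simple graph and positive profiles, every per-gene JSD lies in
    [0,1] (base 2) and nJSD is symmetric."""
    net, x, y = inst
    r_xy = njsd(x, y, net)
    r_yx = njsd(y, x, net)
    assert r_xy.value == r_yx.value
    defined = r_xy.per_gene["defined"]
    jsds = r_xy.per_gene.loc[defined, "jsd"]
    assert ((jsds >= 0.0) & (jsds <= 1.0 + 1e-12)).all()
    assert njsd(x, x, net).value == 0.0
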