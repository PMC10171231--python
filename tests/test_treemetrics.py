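import math

import dendropy
import numpy as np
import pytest
from scipy import stats as sps

from locusfilter.phyio import parse_newick
from locusfilter.treemetrics import (
    CladeDefinition,
    clade_support,
    collapse_low_support,
    gene_concordance,
    is_monophyletic,
    n_internal_edges,
    ols_support_regression,
)

from conftest import random_topology_newick


def monophyly_oracle(newick: str, members: set[str]) -> str:
    """Independent oracle via dendropy's bipartition bitmask encoding."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.encode_bipartitions()
    ns = tree.taxon_namespace
    leaves = {t.label for t in ns}
    m = members & leaves
    o = leaves - m
    if len(m) < 2 or len(o) < 2:
        return "not_evaluable"
    mask = ns.taxa_bitmask(labels=m)
    full = ns.all_taxa_bitmask()
    for bip in tree.bipartition_encoding:
        bm = bip.leafset_bitmask
        if bm == mask or bm == (full & ~mask):
            return "yes"
    return "no"


class TestIsMonophyletic:
    def test_yes(self):
        rec = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(rec, CladeDefinition("x", frozenset("AB"))) == "yes"

    def test_no(self):
        rec = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(rec, CladeDefinition("x", frozenset("AC"))) == "no"

    def test_restricted_to_present_members(self):
        rec = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        clade = CladeDefinition("x", frozenset("ABE"))
        assert is_monophyletic(rec, clade) == "yes"

    def test_not_evaluable(self):
        rec = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(
            rec, CladeDefinition("x", frozenset("A"))) == "not_evaluable"
        assert is_monophyletic(
            rec, CladeDefinition("x", frozenset("ABC"))) == "not_evaluable"

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            newick = random_topology_newick(rng, n)
            rec = parse_newick(newick)
            leaves = sorted(rec.leaf_labels())
            k = int(rng.integers(1, n))
            members = frozenset(rng.choice(leaves, size=k, replace=False))
            clade = CladeDefinition("c", members)
            assert is_monophyletic(rec, clade) == monophyly_oracle(
                newick, set(members))


class TestCladeSupport:
    def _tree(self, mono: bool, support: int) -> str:
        if mono:
            return f"((A:1,B:1){support}:1,(C:1,D:1):1,E:1);"
        return f"((A:1,C:1){support}:1,(B:1,D:1):1,E:1);"

    def test_proportions(self):
        trees = []
        for i in range(7):
            trees.append(parse_newick(
                self._tree(True, 95 if i < 4 else 50), f"m{i}"))
        for i in range(3):
            trees.append(parse_newick(self._tree(False, 99), f"n{i}"))
        report = clade_support(trees, CladeDefinition("x", frozenset("AB")))
        assert report.n_evaluable == 10
        assert report.prop_monophyletic == pytest.approx(0.7)
        assert report.prop_strong == pytest.approx(0.4)

    def test_all_identical_full_support(self):
        trees = [parse_newick(self._tree(True, 100), f"m{i}")
                 for i in range(5)]
        report = clade_support(trees, CladeDefinition("x", frozenset("AB")))
        assert report.prop_monophyletic == 1.0
        assert report.prop_strong == 1.0

    def test_zero_evaluable(self):
        trees = [parse_newick("((A:1,B:1):1,(C:1,D:1):1);", "m0")]
        report = clade_support(trees, CladeDefinition("x", frozenset("XY")))
        assert report.n_evaluable == 0
        assert math.isnan(report.prop_monophyletic)

    def test_unlabeled_edge_never_strong(self):
        trees = [parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);", "m0")]
        report = clade_support(trees, CladeDefinition("x", frozenset("AB")))
        assert report.prop_monophyletic == 1.0
        assert report.prop_strong == 0.0

    def test_strong_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        trees = [
            parse_newick(self._tree(True, int(rng.integers(0, 101))), f"m{i}")
            for i in range(40)
        ]
        clade = CladeDefinition("x", frozenset("AB"))
        props = [clade_support(trees, clade, thr).prop_strong
                 for thr in range(0, 101, 10)]
        assert all(b <= a for a, b in zip(props, props[1:]))


class TestCollapseLowSupport:
    def test_all_retained(self):
        rec = parse_newick("((A:1,B:1)50:1,(C:1,D:1)90:1,E:1);")
        out = collapse_low_support(rec, 10)
        assert n_internal_edges(out) == n_internal_edges(rec)

    def test_one_collapsed(self):
        rec = parse_newick("(((A:1,B:1)5:1,C:1)80:1,D:1,E:1);")
        before = n_internal_edges(rec)
        out = collapse_low_support(rec, 10)
        assert n_internal_edges(out) == before - 1

    def test_exactly_at_threshold_retained(self):
        rec = parse_newick("((A:1,B:1)10:1,(C:1,D:1)90:1,E:1);")
        out = collapse_low_support(rec, 10)
        assert n_internal_edges(out) == n_internal_edges(rec)

    def test_unlabeled_never_collapsed(self):
        rec = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        out = collapse_low_support(rec, 10)
        assert n_internal_edges(out) == n_internal_edges(rec)

    def test_idempotent(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            newick = random_topology_newick(rng, 8)
            rec = parse_newick(newick)
            for node in rec.tree.preorder_node_iter():
                if not node.is_leaf() and node is not rec.tree.seed_node:
                    node.edge.support = int(rng.integers(0, 101))
            once = collapse_low_support(rec, 30)
            twice = collapse_low_support(once, 30)
            from locusfilter.supermatrix import _nontrivial_bipartitions
            assert (_nontrivial_bipartitions(twice)
                    == _nontrivial_bipartitions(once))

    def test_survivors_all_at_or_above(self):
        rng = np.random.default_rng(13)
        newick = random_topology_newick(rng, 10)
        rec = parse_newick(newick)
        for node in rec.tree.preorder_node_iter():
            if not node.is_leaf() and node is not rec.tree.seed_node:
                node.edge.support = int(rng.integers(0, 101))
        out = collapse_low_support(rec, 60)
        for node in out.tree.preorder_node_iter():
            sup = getattr(node.edge, "support", None)
            if sup is not None and not node.is_leaf():
                assert sup >= 60


class TestGeneConcordance:
    def test_identical_trees_all_100(self):
        sp = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        trees = [parse_newick(sp.as_newick(), f"m{i}") for i in range(8)]
        table = gene_concordance(sp, trees)
        assert (table["gcf_percent"] == 100.0).all()

    def test_half_concordant(self):
        sp = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        con = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        dis = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        trees = [parse_newick(con, "a"), parse_newick(con, "b"),
                 parse_newick(dis, "c"), parse_newick(dis, "d")]
        table = gene_concordance(sp, trees).set_index("bipartition")
        assert table.loc["A|B", "gcf_percent"] == pytest.approx(50.0)
        assert table.loc["A|B", "n_decisive"] == 4

    def test_nondecisive_excluded(self):
        sp = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        # tree missing B: only one member of {A,B} side remains
        trees = [parse_newick("((A:1,C:1):1,D:1,E:1);", "m0"),
                 parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);", "m1")]
        table = gene_concordance(sp, trees).set_index("bipartition")
        assert table.loc["A|B", "n_decisive"] == 1
        assert table.loc["A|B", "gcf_percent"] == pytest.approx(100.0)

    def test_zero_decisive_is_nan(self):
        sp = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        trees = [parse_newick("((A:1,C:1):1,D:1,E:1);", "m0")]
        table = gene_concordance(sp, trees).set_index("bipartition")
        assert table.loc["A|B", "n_decisive"] == 0
        assert math.isnan(table.loc["A|B", "gcf_percent"])

    def test_random_trees_near_baseline(self):
        rng = np.random.default_rng(55)
        sp = parse_newick(random_topology_newick(rng, 8), "sp")
        trees = [parse_newick(random_topology_newick(rng, 8), f"m{i}")
                 for i in range(150)]
        table = gene_concordance(sp, trees)
        # random resolution: low concordance, wide tolerance
        assert table["gcf_percent"].mean() < 50.0


class TestOlsSupportRegression:
    def test_perfect_fit(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        slope, intercept, r2, p = ols_support_regression(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_y(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        slope, _, _, _ = ols_support_regression(x, np.ones(4))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            ols_support_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_against_normal_equations(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.uniform(0, 2, size=n)
            y = 0.3 * x + rng.normal(0, 0.2, size=n)
            slope, intercept, r2, p = ols_support_regression(x, y)
            # closed-form normal equations
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            s2 = resid @ resid / (n - 2)
            se_slope = math.sqrt(s2 / np.sum((x - x.mean()) ** 2))
            t = beta[1] / se_slope
            p_exp = 2 * sps.t.sf(abs(t), df=n - 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2_exp = 1 - resid @ resid / ss_tot
            assert slope == pytest.approx(beta[1], abs=1e-10)
            assert intercept == pytest.approx(beta[0], abs=1e-10)
            assert r2 == pytest.approx(r2_exp, abs=1e-10)
            assert p == pytest.approx(p_exp, abs=1e-10)


def test_clade_definition_validation():
    with pytest.raises(ValueError):
        CladeDefinition("x", frozenset())
    with pytest.raises(ValueError):
        CladeDefinition("x", frozenset("AB"), frozenset("B"))
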