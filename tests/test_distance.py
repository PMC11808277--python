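"""Distance matrices: patristic, Gower, PCoA, FPDist — against oracles."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

import fpdiv
from fpdiv.containers import TraitType, ValidationError
from fpdiv.distance import FPDistSpec, RetentionRule, rescale_to_unit
from conftest import random_mixed_traits


# ---------------------------------------------------------------- patristic

def brute_force_patristic(tree):
    """Oracle: explicit path sum through the root-ward node chain."""
    pdm = {}
    leaves = list(tree.leaf_node_iter())
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            anc_a = {id(n): n for n in a.ancestor_iter(inclusive=True)}
            node, d_b = b, 0.0
            while id(node) not in anc_a:
                d_b += node.edge.length or 0.0
                node = node.parent_node
            mrca = node
            d_a, node = 0.0, a
            while node is not mrca:
                d_a += node.edge.length or 0.0
                node = node.parent_node
            pdm[frozenset((a.taxon.label, b.taxon.label))] = d_a + d_b
    return pdm


class TestPatristic:
    def test_hand_summed_example(self, small_tree):
        d = fpdiv.patristic_distances(small_tree)
        assert d["A", "B"] == 2.0
        assert d["A", "C"] == 4.0
        assert d["B", "C"] == 4.0

    def test_zero_diagonal_and_symmetry(self, small_tree):
        d = fpdiv.patristic_distances(small_tree)
        assert np.all(np.diag(d.data) == 0)
        np.testing.assert_array_equal(d.data, d.data.T)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_trees(self, seed):
        n = int(np.random.default_rng(seed).integers(4, 13))
        tree = fpdiv.simulate_tree(n, seed=seed)
        d = fpdiv.patristic_distances(tree)
        oracle = brute_force_patristic(tree)
        for pair, expected in oracle.items():
            a, b = sorted(pair)
            assert d[a, b] == pytest.approx(expected, abs=1e-12)

    def test_ultrametric_cross_root_distance(self):
        tree = fpdiv.read_newick("((A:1,B:1):2,(C:2,D:2):1);")
        d = fpdiv.patristic_distances(tree)
        for pair in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
            assert d[pair] == pytest.approx(6.0)  # 2 * depth


# -------------------------------------------------------------------- Gower

def brute_force_gower(traits):
    """Oracle: per-pair, per-trait loop with pairwise deletion."""
    from scipy.stats import rankdata

    sp = traits.species
    cols = {}
    for name, ttype in traits.types.items():
        x = traits.data[name]
        if ttype in (TraitType.CONTINUOUS, TraitType.ORDINAL):
            v = x.to_numpy(float)
            if ttype is TraitType.ORDINAL:
                obs = np.isfinite(v)
                r = np.full(len(v), np.nan)
                r[obs] = rankdata(v[obs])
                v = r
            rng_ = np.nanmax(v) - np.nanmin(v)
            if not np.isfinite(rng_) or rng_ == 0:
                continue
            cols[name] = ("num", v, rng_)
        else:
            v = x.to_numpy(object)
            obs_vals = {u for u in v if u is not None and u == u}
            if len(obs_vals) < 2:
                continue
            cols[name] = ("cat", v, None)
    out = {}
    for i, a in enumerate(sp):
        for j in range(i + 1, len(sp)):
            total = count = 0
            for kind, v, rng_ in cols.values():
                vi, vj = v[i], v[j]
                if kind == "num":
                    if np.isfinite(vi) and np.isfinite(vj):
                        total += abs(vi - vj) / rng_
                        count += 1
                else:
                    if vi == vi and vj == vj and vi is not None and vj is not None:
                        total += float(vi != vj)
                        count += 1
            out[(a, sp[j])] = total / count if count else None
    return out


class TestGower:
    def test_worked_example(self, three_species_traits):
        d = fpdiv.gower_distance(three_species_traits)
        assert d["A", "B"] == pytest.approx(0.75)
        assert d["A", "C"] == pytest.approx(0.5)
        assert d["B", "C"] == pytest.approx(0.75)

    def test_identical_vectors_zero(self):
        tt = fpdiv.TraitTable(
            pd.DataFrame({"m": [1.0, 1.0, 2.0]}, index=["A", "B", "C"]),
            {"m": "continuous"},
        )
        assert fpdiv.gower_distance(tt)["A", "B"] == 0.0

    def test_range_endpoints_give_one(self):
        tt = fpdiv.TraitTable(
            pd.DataFrame({"m": [0.0, 10.0, 5.0]}, index=["A", "B", "C"]),
            {"m": "continuous"},
        )
        assert fpdiv.gower_distance(tt)["A", "B"] == pytest.approx(1.0)

    def test_zero_range_trait_dropped_with_warning(self):
        tt = fpdiv.TraitTable(
            pd.DataFrame({"m": [1.0, 1.0, 1.0], "k": [0.0, 1.0, 2.0]},
                         index=["A", "B", "C"]),
            {"m": "continuous", "k": "continuous"},
        )
        with pytest.warns(UserWarning, match="zero range"):
            d = fpdiv.gower_distance(tt)
        assert d["A", "C"] == pytest.approx(1.0)

    def test_no_shared_traits_pair_is_error(self):
        tt = fpdiv.TraitTable(
            pd.DataFrame({"m": [1.0, np.nan, 2.0], "k": [np.nan, 1.0, 2.0]},
                         index=["A", "B", "C"]),
            {"m": "continuous", "k": "continuous"},
        )
        with pytest.raises(ValidationError, match="shares no observed trait"):
            fpdiv.gower_distance(tt)

    @pytest.mark.parametrize("seed,missing", [(0, 0.0), (1, 0.0), (2, 0.2), (3, 0.3)])
    def test_matches_brute_force(self, seed, missing):
        rng = np.random.default_rng(seed)
        tt = random_mixed_traits(rng, int(rng.integers(5, 13)), missing=missing)
        oracle = brute_force_gower(tt)
        if any(v is None for v in oracle.values()):
            with pytest.raises(ValidationError, match="shares no observed trait"):
                fpdiv.gower_distance(tt)
            return
        d = fpdiv.gower_distance(tt)
        for (a, b), expected in oracle.items():
            assert d[a, b] == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------- PCoA

class TestPcoa:
    def test_equidistant_triple_eigenvalues(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("ABC"))
        res = fpdiv.pcoa(dm)
        np.testing.assert_allclose(sorted(res.eigenvalues, reverse=True), [0.5, 0.5, 0.0], atol=1e-12)
        assert res.retained_axes == 2

    def test_euclidean_input_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(7)])
        res = fpdiv.pcoa(dm, RetentionRule(kind="count", count=6))
        back = fpdiv.fdist_from_axes(res)
        np.testing.assert_allclose(back.data, dm.data, atol=1e-8)

    def test_negative_eigenvalues_excluded_with_warning(self):
        # a non-Euclidean (metric-violating) matrix
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 2.4], [1, 1, 2.4, 0]])
        dm = DistanceMatrix(d, ids=list("ABCD"))
        with pytest.warns(UserWarning, match="negative eigenvalue"):
            res = fpdiv.pcoa(dm, RetentionRule(kind="count", count=10))
        assert (res.eigenvalues[: res.retained_axes] > 0).all()

    def test_matches_skbio_reference(self):
        """Cross-check classical scaling against scikit-bio's PCoA."""
        import skbio.stats.ordination as sko

        rng = np.random.default_rng(3)
        tt = random_mixed_traits(rng, 10)
        dm = fpdiv.gower_distance(tt)
        ours = fpdiv.pcoa(dm, RetentionRule(kind="count", count=3))
        theirs = sko.pcoa(dm, method="eigh")
        ref = theirs.eigvals.to_numpy()
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1][:3], np.sort(ref)[::-1][:3], atol=1e-10
        )
        for k in range(3):
            np.testing.assert_allclose(
                np.abs(ours.coordinates[:, k]),
                np.abs(theirs.samples[f"PC{k + 1}"].to_numpy()),
                atol=1e-8,
            )

    @pytest.mark.parametrize("correction", ["lingoes", "cailliez"])
    def test_corrections_remove_negative_eigenvalues(self, correction):
        rng = np.random.default_rng(5)
        tt = random_mixed_traits(rng, 9)
        dm = fpdiv.gower_distance(tt)
        with pytest.warns(UserWarning, match="negative eigenvalue"):
            uncorrected = fpdiv.pcoa(dm)
        assert (uncorrected.eigenvalues < 0).any()
        res = fpdiv.pcoa(dm, RetentionRule(kind="count", count=8), correction=correction)
        tol = 1e-8 * abs(res.eigenvalues[0])
        assert (res.eigenvalues >= -tol).all()

    def test_degenerate_all_zero_rejected(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("ABC"))
        with pytest.raises(ValidationError, match="degenerate"):
            fpdiv.pcoa(dm)

    def test_retention_rule_cumulative(self):
        rel = np.array([0.5, 0.3, 0.15, 0.05])
        assert RetentionRule(threshold=0.80).n_axes(rel) == 2
        assert RetentionRule(threshold=0.81).n_axes(rel) == 3
        assert RetentionRule(kind="count", count=99).n_axes(rel) == 4


# ------------------------------------------------------------------- FPDist

class TestFpdist:
    @pytest.fixture
    def pair(self, three_species_traits, small_tree):
        fd, _ = fpdiv.functional_distance(three_species_traits)
        pdm = fpdiv.patristic_distances(small_tree)
        return fd, pdm.filter(fd.ids)

    def test_endpoints(self, pair):
        fd, pdm = pair
        a0 = fpdiv.fpdist(fd, pdm, FPDistSpec(a=0.0))
        a1 = fpdiv.fpdist(fd, pdm, FPDistSpec(a=1.0))
        np.testing.assert_allclose(a0.data, rescale_to_unit(fd).data, atol=1e-12)
        np.testing.assert_allclose(a1.data, rescale_to_unit(pdm).data, atol=1e-12)

    def test_direct_formula_value(self):
        fd = DistanceMatrix([[0, 0.6], [0.6, 0]], ids=["A", "B"])
        pdm = DistanceMatrix([[0, 0.8], [0.8, 0]], ids=["A", "B"])
        # maxima are 0.6 / 0.8 so rescaled entries are both 1 -> use 3 species
        fd3 = DistanceMatrix([[0, 0.6, 1], [0.6, 0, 1], [1, 1, 0]], ids=list("ABC"))
        pd3 = DistanceMatrix([[0, 0.8, 1], [0.8, 0, 1], [1, 1, 0]], ids=list("ABC"))
        out = fpdiv.fpdist(fd3, pd3, FPDistSpec(a=0.5, p=2.0))
        assert out["A", "B"] == pytest.approx(np.sqrt(0.5 * 0.64 + 0.5 * 0.36))
        assert out["A", "B"] == pytest.approx(0.70711, abs=1e-5)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValidationError):
            FPDistSpec(a=1.5)

    def test_zero_matrix_rejected(self, pair):
        fd, pdm = pair
        zero = DistanceMatrix(np.zeros_like(fd.data), ids=fd.ids)
        with pytest.raises(ValidationError, match="all-zero"):
            fpdiv.fpdist(zero, pdm, FPDistSpec(a=0.5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a1=st.floats(0, 1), a2=st.floats(0, 1),
        f=st.floats(0.05, 1), p_=st.floats(0.05, 1),
        seed=st.integers(0, 10),
    )
    def test_monotone_in_a(self, a1, a2, f, p_, seed):
        """FPDist increases with a wherever PDist' > FDist' (and vice versa)."""
        lo, hi = sorted((a1, a2))
        fd = DistanceMatrix([[0, f, 1], [f, 0, 1], [1, 1, 0]], ids=list("ABC"))
        pdm = DistanceMatrix([[0, p_, 1], [p_, 0, 1], [1, 1, 0]], ids=list("ABC"))
        d_lo = fpdiv.fpdist(fd, pdm, FPDistSpec(a=lo))["A", "B"]
        d_hi = fpdiv.fpdist(fd, pdm, FPDistSpec(a=hi))["A", "B"]
        if p_ > f:
            assert d_hi >= d_lo - 1e-12
        elif p_ < f:
            assert d_hi <= d_lo + 1e-12
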