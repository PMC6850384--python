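"""Diversity indices: richness counting rules, PCoA embedding geometry,
and the MST-evenness / centroid-dispersion formulas against brute-force
oracles on small Euclidean trait spaces."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from traitflux import (
    SyntheticConfig,
    diversity_series,
    functional_dispersion,
    functional_evenness,
    generate_community,
    ln_transform,
    pcoa_embed,
    species_richness,
    trait_richness,
)
from traitflux.synthetic import generate_trait_matrix

from conftest import make_trait_matrix
from traitflux import TraitBlock


def prim_mst_edges(d: np.ndarray):
    """Independent minimum-spanning-tree oracle (naive Prim's algorithm)."""
    n = d.shape[0]
    in_tree = {0}
    edges = []
    while len(in_tree) < n:
        best = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and (best is None or d[i, j] < best[2]):
                    best = (i, j, d[i, j])
        edges.append(best)
        in_tree.add(best[1])
    return edges


def brute_force_feve(coords: np.ndarray, weights: np.ndarray) -> float:
    present = weights > 0
    x = coords[present]
    w = weights[present] / weights[present].sum()
    s = len(w)
    d = squareform(pdist(x))
    ew = [dist / (w[i] + w[j]) for i, j, dist in prim_mst_edges(d)]
    pew = np.array(ew) / sum(ew)
    thr = 1.0 / (s - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)


def brute_force_fdis(coords: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    centroid = w @ coords
    z = np.linalg.norm(coords - centroid, axis=1)
    return float(w @ z)


class TestRichness:
    def test_species_richness_counts_positive_densities(self):
        assert species_richness([2.3, 0.0, 0.1]) == 2
        assert species_richness([0.0, 0.0]) == 0
        assert species_richness(np.ones(7)) == 7

    def test_trait_richness_counts_expressed_categories(self):
        diet = TraitBlock("diet", ("x", "y", "z"), "fuzzy")
        tm = make_trait_matrix(
            {"t1": [1.0, 0.0, 0.0], "t2": [0.0, 1.0, 0.0], "t3": [0.0, 0.0, 1.0]},
            [diet],
        )
        assert trait_richness([1.0, 2.0, 0.0], tm) == 2
        assert trait_richness([0.0, 0.0, 0.0], tm) == 0

    def test_fractional_affinity_counts_as_expressed(self):
        diet = TraitBlock("diet", ("x", "y"), "fuzzy")
        tm = make_trait_matrix({"t1": [0.5, 0.5], "t2": [0.0, 1.0]}, [diet])
        assert trait_richness([1.0, 0.0], tm) == 2

    def test_trait_richness_monotone_under_adding_taxon(self):
        diet = TraitBlock("diet", ("x", "y", "z"), "fuzzy")
        tm = make_trait_matrix(
            {"t1": [1.0, 0.0, 0.0], "t2": [0.0, 0.5, 0.5]}, [diet]
        )
        assert trait_richness([1.0, 0.0], tm) <= trait_richness([1.0, 1.0], tm)


class TestPcoaEmbedding:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
                            ids=list("abc"))
        emb = pcoa_embed(dm)
        assert emb.coords.shape[1] == 2
        np.testing.assert_allclose(pdist(emb.coords), 1.0, atol=1e-8)
        assert emb.correction == 0.0

    def test_euclidean_input_preserved_and_matches_skbio(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        emb = pcoa_embed(dm)
        assert emb.correction == 0.0
        np.testing.assert_allclose(pdist(emb.coords), pdist(pts), atol=1e-8)
        ref = skbio_pcoa(dm, method="eigh", number_of_dimensions=3)
        np.testing.assert_allclose(
            pdist(ref.samples.to_numpy()), pdist(emb.coords), atol=1e-8
        )

    def test_non_euclidean_input_gets_additive_correction(self):
        # 4-point star metric violating the Euclidean embedding condition
        d = np.array(
            [[0, 2, 2, 1.05], [2, 0, 2, 1.05], [2, 2, 0, 1.05], [1.05, 1.05, 1.05, 0]]
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        emb = pcoa_embed(dm)
        assert emb.correction > 0
        expected = d + emb.correction
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(
            squareform(pdist(emb.coords)), expected, atol=1e-6
        )

    def test_identical_pair_embeds_at_zero_distance(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        emb = pcoa_embed(DistanceMatrix(d, ids=list("abc")))
        assert np.linalg.norm(emb.coords[0] - emb.coords[1]) < 1e-8


class TestFunctionalEvenness:
    def test_equally_spaced_equal_weights_is_one(self):
        for s in (3, 4, 7):
            coords = np.arange(s, dtype=float)[:, None]
            assert functional_evenness(coords, np.ones(s) / s) == pytest.approx(1.0)

    def test_line_with_unequal_weights(self):
        coords = np.array([[0.0], [1.0], [2.0]])
        val = functional_evenness(coords, np.array([0.5, 0.25, 0.25]))
        assert val == pytest.approx(0.8, abs=1e-12)

    def test_fewer_than_three_taxa_undefined(self):
        coords = np.array([[0.0], [1.0]])
        with pytest.warns(UserWarning):
            assert np.isnan(functional_evenness(coords, np.array([0.5, 0.5])))

    def test_matches_brute_force_on_random_euclidean_spaces(self):
        rng = np.random.default_rng(7)
        for s in range(3, 7):
            coords = rng.normal(size=(s, 2))
            w = rng.dirichlet(np.ones(s))
            assert functional_evenness(coords, w) == pytest.approx(
                brute_force_feve(coords, w), abs=1e-8
            )


class TestFunctionalDispersion:
    @staticmethod
    def dm_from_points(pts):
        return DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(len(pts))])

    def test_single_present_taxon_is_zero(self):
        dm = self.dm_from_points(np.array([[0.0], [1.0]]))
        assert functional_dispersion(dm, [1.0, 0.0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_cases(self):
        dm = self.dm_from_points(np.array([[0.0], [1.0]]))
        assert functional_dispersion(dm, [0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
        assert functional_dispersion(dm, [0.75, 0.25]) == pytest.approx(0.375, abs=1e-12)

    def test_weight_rescaling_invariance(self):
        dm = self.dm_from_points(np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]]))
        w = np.array([0.2, 0.5, 0.3])
        assert functional_dispersion(dm, w) == pytest.approx(
            functional_dispersion(dm, 17.0 * w), abs=1e-12
        )

    def test_matches_brute_force_on_random_euclidean_spaces(self):
        rng = np.random.default_rng(11)
        for s in range(2, 7):
            pts = rng.normal(size=(s, 3))
            w = rng.dirichlet(np.ones(s))
            assert functional_dispersion(self.dm_from_points(pts), w) == pytest.approx(
                brute_force_fdis(pts, w), abs=1e-8
            )

    def test_all_zero_weights_rejected(self):
        dm = self.dm_from_points(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            functional_dispersion(dm, [0.0, 0.0])


class TestDiversitySeries:
    def test_permuting_taxon_order_changes_nothing(self):
        cfg = SyntheticConfig(n_taxa=12, seed=21, rare_taxon_fraction=0.0)
        cts, tm, _ = generate_community(cfg)
        cts = ln_transform(cts)
        base = diversity_series(cts, tm)
        perm = list(np.random.default_rng(0).permutation(cts.taxa))
        shuffled = diversity_series(
            cts.with_density(cts.density[perm]), tm.subset(perm)
        )
        for col in ("SRic", "TRic", "FEve", "FDis"):
            np.testing.assert_allclose(
                base[col].to_numpy(), shuffled[col].to_numpy(), atol=1e-9
            )

    def test_integer_indices_and_ranges(self):
        cfg = SyntheticConfig(n_taxa=10, seed=5)
        cts, tm, _ = generate_community(cfg)
        div = diversity_series(ln_transform(cts), tm)
        assert div["SRic"].dtype.kind == "i" and div["TRic"].dtype.kind == "i"
        assert (div["TRic"] <= len(tm.categories)).all()
        feve = div["FEve"].dropna()
        assert ((feve >= 0) & (feve <= 1)).all()
        assert (div["FDis"].dropna() >= 0).all()
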