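"""Gower-Podani dissimilarity: hand oracles, validation, and metric
properties over randomly generated fuzzy-coded trait tables."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from traitflux import (
    SyntheticConfig,
    TraitBlock,
    TraitMatrix,
    gower_distance,
    read_trait_csv,
    validate_trait_matrix,
    write_trait_csv,
)
from traitflux.synthetic import generate_trait_matrix

from conftest import make_trait_matrix


def brute_force_gower(tm: TraitMatrix) -> np.ndarray:
    """Independent per-column oracle: explicit loops, no shared code path."""
    taxa = tm.taxa
    n = len(taxa)
    cols = []  # (values per taxon, weight)
    for b in tm.blocks:
        block = tm.block(b.name)
        if b.kind == "ordinal":
            scores = [
                sum(block.loc[t].iloc[k] * k for k in range(block.shape[1]))
                for t in taxa
            ]
            r = rankdata(scores)
            ties = {v: list(r).count(v) for v in set(r)}
            hi, lo = max(r), min(r)
            denom = (hi - lo) - (ties[hi] - 1) / 2 - (ties[lo] - 1) / 2
            if denom > 0:
                d = np.zeros((n, n))
                for i in range(n):
                    for j in range(n):
                        v = (abs(r[i] - r[j]) - (ties[r[i]] - 1) / 2
                             - (ties[r[j]] - 1) / 2) / denom
                        d[i, j] = max(v, 0.0)
                cols.append((d, 1.0))
        else:
            for cat in block.columns:
                vals = block[cat].to_numpy(dtype=float)
                rng = vals.max() - vals.min()
                if rng > 0:
                    d = np.abs(vals[:, None] - vals[None, :]) / rng
                    cols.append((d, 1.0 / block.shape[1]))
    if not cols:
        return np.zeros((n, n))
    num = sum(w * d for d, w in cols)
    den = sum(w for _, w in cols)
    out = num / den
    np.fill_diagonal(out, 0.0)
    return out


class TestValidation:
    def test_well_formed_matrix_passes(self, two_taxon_contrast):
        assert validate_trait_matrix(two_taxon_contrast) == []

    def test_bad_block_sum_reported(self):
        block = TraitBlock("diet", ("a", "b"), "fuzzy")
        tm = make_trait_matrix({"t1": [0.5, 0.4], "t2": [1.0, 0.0]}, [block])
        report = validate_trait_matrix(tm)
        assert len(report) == 1 and "block sum" in report[0]

    def test_out_of_range_affinity_reported(self):
        block = TraitBlock("diet", ("a", "b"), "fuzzy")
        tm = make_trait_matrix({"t1": [1.2, -0.2], "t2": [1.0, 0.0]}, [block])
        report = validate_trait_matrix(tm)
        assert any("out of [0,1]" in line for line in report)

    def test_duplicate_taxa_rejected(self):
        block = TraitBlock("diet", ("a", "b"), "fuzzy")
        affinity = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]],
            index=["t1", "t1"],
            columns=pd.MultiIndex.from_tuples([("diet", "a"), ("diet", "b")]),
        )
        with pytest.raises(ValueError):
            TraitMatrix(affinity=affinity, blocks=(block,))


class TestGowerHandCases:
    def test_maximal_contrast_pair_has_distance_one(self, two_taxon_contrast):
        dm = gower_distance(two_taxon_contrast)
        assert dm["t1", "t2"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_profiles_have_distance_zero(self):
        block = TraitBlock("diet", ("a", "b", "c"), "fuzzy")
        tm = make_trait_matrix(
            {"t1": [0.2, 0.3, 0.5], "t2": [0.2, 0.3, 0.5], "t3": [1.0, 0.0, 0.0]},
            [block],
        )
        assert gower_distance(tm)["t1", "t2"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_trait_leaves_distance_to_varying_trait(self):
        diet = TraitBlock("diet", ("a", "b"), "fuzzy")
        size = TraitBlock("size", ("s", "l"), "fuzzy")
        tm = make_trait_matrix(
            {
                "t1": [1.0, 0.0, 0.5, 0.5],
                "t2": [0.0, 1.0, 0.5, 0.5],
                "t3": [0.5, 0.5, 0.5, 0.5],
            },
            [diet, size],
        )
        dm = gower_distance(tm)
        np.testing.assert_allclose(dm.data, brute_force_gower(tm), atol=1e-12)
        # size is constant: the distance comes from diet alone
        assert dm["t1", "t2"] == pytest.approx(1.0, abs=1e-12)
        assert dm["t1", "t3"] == pytest.approx(0.5, abs=1e-12)

    def test_ordinal_block_uses_podani_tied_ranks(self):
        size = TraitBlock("size", ("s", "m", "l"), "ordinal")
        tm = make_trait_matrix(
            {"t1": [1, 0, 0], "t2": [1, 0, 0], "t3": [0, 1, 0], "t4": [0, 0, 1]},
            [size],
        )
        dm = gower_distance(tm)
        np.testing.assert_allclose(dm.data, brute_force_gower(tm), atol=1e-12)
        # tied pair is at distance 0; ties shrink the extreme-to-middle gap
        assert dm["t1", "t2"] == 0.0
        assert dm["t1", "t4"] == pytest.approx(1.0, abs=1e-12)

    def test_single_taxon_rejected(self):
        block = TraitBlock("diet", ("a", "b"), "fuzzy")
        tm = make_trait_matrix({"t1": [1.0, 0.0]}, [block])
        with pytest.raises(ValueError):
            gower_distance(tm)


class TestGowerProperties:
    @given(st.integers(0, 10_000))
    def test_random_matrices_match_brute_force_and_are_metric_like(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SyntheticConfig(
            n_taxa=int(rng.integers(3, 9)),
            trait_blocks=(
                ("size", 3, "ordinal"),
                ("feeding", int(rng.integers(2, 5)), "fuzzy"),
                ("habitat", 2, "nominal"),
            ),
            seed=seed,
        )
        tm = generate_trait_matrix(cfg, rng)
        dm = gower_distance(tm)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, brute_force_gower(tm), atol=1e-10)

    def test_adding_constant_block_cannot_increase_distances(self):
        rng = np.random.default_rng(42)
        cfg = SyntheticConfig(n_taxa=6, trait_blocks=(("feeding", 3, "fuzzy"),), seed=1)
        tm = generate_trait_matrix(cfg, rng)
        base = gower_distance(tm).data
        extra = TraitBlock("extra", ("x", "y"), "fuzzy")
        aff = tm.affinity.copy()
        aff[("extra", "x")] = 0.5
        aff[("extra", "y")] = 0.5
        tm2 = TraitMatrix(affinity=aff, blocks=tm.blocks + (extra,))
        grown = gower_distance(tm2).data
        assert (grown <= base + 1e-12).all()
        iu = np.triu_indices_from(base, k=1)
        assert np.array_equal(np.argsort(base[iu]), np.argsort(grown[iu]))


class TestTraitIO:
    def test_round_trip_preserves_matrix(self, tmp_path):
        rng = np.random.default_rng(3)
        tm = generate_trait_matrix(SyntheticConfig(n_taxa=5, seed=3), rng)
        path = tmp_path / "traits.csv"
        write_trait_csv(tm, path)
        back = read_trait_csv(path)
        pd.testing.assert_frame_equal(tm.affinity, back.affinity, check_names=False)
        assert [b.kind for b in back.blocks] == [b.kind for b in tm.blocks]
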