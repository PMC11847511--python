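import numpy as np
import pytest

from deca import ContactList, build_patches, extract_attention
from deca.interpretability import (
    AttentionMap,
    categorize_attention,
    contacts_to_patch_pairs,
    overlap_permutation_test,
)


def make_map(W_by_chrom):
    per = {}
    idx = 0
    for chrom, W in W_by_chrom.items():
        W = np.asarray(W, float)
        ids = list(range(idx, idx + W.shape[0]))
        idx += W.shape[0]
        per[chrom] = (ids, 0.5 * (W + W.T))
    return AttentionMap(per_chrom=per)


class TestExtractAttention:
    def test_symmetric_per_chromosome(self, tiny_model, small_layout, rng):
        x = rng.uniform(0, 1, 60)
        att = extract_attention(tiny_model, x, small_layout)
        for chrom, (ids, W) in att.per_chrom.items():
            np.testing.assert_allclose(W, W.T, atol=1e-9)

    def test_head_averaged_rows_sum_to_one_before_symmetrization(self, tiny_model, x=None):
        from deca.model import forward
        rng = np.random.default_rng(4)
        out = forward(tiny_model, rng.uniform(0, 1, (1, 60)), capture_attention=True)
        head_avg = out["attentions"][-1][0].mean(axis=0)
        np.testing.assert_allclose(head_avg.sum(axis=1), 1.0, atol=1e-6)

    def test_single_patch_chromosome_gives_1x1(self, small_atlas):
        layout = build_patches(small_atlas.peaks, 30)  # 30 peaks/chrom -> 1 patch each
        from deca import ModelConfig
        from deca.model import DecaModel
        cfg = ModelConfig(k=3, n_peaks=60, patch_size=30, d=16, L=1, h=2,
                          decoder_dims=[4, 4, 4, 4], seed=0)
        model = DecaModel(cfg, layout)
        att = extract_attention(model, np.zeros(60), layout)
        assert all(W.shape == (1, 1) for _, W in att.per_chrom.values())

    def test_depth0_model_rejected(self, small_layout):
        from deca import ModelConfig
        from deca.model import DecaModel
        cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=0, h=2,
                          decoder_dims=[4, 4, 4, 4], seed=0)
        model = DecaModel(cfg, small_layout)
        with pytest.raises(ValueError):
            extract_attention(model, np.zeros(60), small_layout)


class TestCategorize:
    def test_nine_distinct_values_three_per_tertile(self):
        # symmetric 4x4 with 6 distinct pair values is too few; use 5x5 -> 10 pairs
        rng = np.random.default_rng(0)
        p = 5
        vals = np.arange(1.0, 11.0)  # 10 distinct pair values
        W = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        W[iu] = vals
        att = make_map({"chr1": W})
        cats = categorize_attention(att)["chr1"]
        counts = {c: 0 for c in ("Low", "Median", "High")}
        for a, b in zip(*iu):
            counts[cats[a, b]] += 1
        # 10 = 4 + 3 + 3 with remainder going Low first
        assert counts == {"Low": 4, "Median": 3, "High": 3}

    def test_all_equal_is_all_median_with_warning(self):
        W = np.ones((4, 4))
        att = make_map({"chr1": W})
        cats = categorize_attention(att)["chr1"]
        off = ~np.eye(4, dtype=bool)
        assert set(cats[off]) == {"Median"}

    def test_invariance_to_monotone_transform(self, rng):
        W = rng.uniform(size=(6, 6))
        att1 = make_map({"chr1": W})
        att2 = make_map({"chr1": np.exp(3 * (0.5 * (W + W.T)))})
        c1 = categorize_attention(att1)["chr1"]
        c2 = categorize_attention(att2)["chr1"]
        np.testing.assert_array_equal(c1, c2)

    def test_diagonal_excluded(self, rng):
        W = rng.uniform(size=(5, 5))
        cats = categorize_attention(make_map({"chr1": W}))["chr1"]
        assert all(cats[i, i] == "" for i in range(5))


class TestContactsToPatches:
    def test_mapping_and_accumulation(self, small_atlas):
        layout = build_patches(small_atlas.peaks, 10)  # chr1: 30 peaks -> 3 patches
        # peaks on chr1 at 0,5000,10000,... width 500; patch 0 holds peaks 0..9,
        # patch 2 holds peaks 20..29 -> positions 250 and 110250
        contacts = ContactList(pairs=(
            ("chr1", 250, 110250, 2.0),
            ("chr1", 250, 110250, 3.0),
            ("chrZ", 10, 20, 1.0),  # chromosome absent: dropped
        ))
        mats = contacts_to_patch_pairs(contacts, layout)
        assert mats["chr1"][0, 2] == 5.0 and mats["chr1"][2, 0] == 5.0

    def test_position_outside_span_dropped(self, small_atlas):
        layout = build_patches(small_atlas.peaks, 10)
        far = ContactList(pairs=(("chr1", 10_000_000, 10_100_000, 1.0),))
        mats = contacts_to_patch_pairs(far, layout)
        assert mats["chr1"].sum() == 0

    def test_between_peak_position_maps_to_nearest(self, small_atlas):
        layout = build_patches(small_atlas.peaks, 10)
        # 600 is just past peak0 (0-500); nearest is peak0 (patch 0)
        c = ContactList(pairs=(("chr1", 600, 110250, 1.0),))
        mats = contacts_to_patch_pairs(c, layout)
        assert mats["chr1"][0, 2] == 1.0


class TestOverlapPermutationTest:
    def test_planted_overlap_gives_minimal_pvalue(self, rng):
        p = 20
        W = rng.uniform(size=(p, p))
        W = 0.5 * (W + W.T)
        att = make_map({"chr1": W})
        # contacts exactly equal attention: top sets coincide
        res = overlap_permutation_test(att, {"chr1": att.per_chrom["chr1"][1]},
                                       top_fraction=0.05, n_permutations=200, seed=1)
        assert res.n_overlap == res.n_attention_selected
        assert res.p_value == pytest.approx(1 / 201)

    def test_null_pvalues_roughly_uniform(self):
        # contacts independent of attention: fraction of p<0.05 in [0.01, 0.10]
        reps, hits = 200, 0
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            p = 24
            W = rng.uniform(size=(p, p))
            C = rng.uniform(size=(p, p))
            att = make_map({"chr1": W})
            res = overlap_permutation_test(att, {"chr1": 0.5 * (C + C.T)},
                                           top_fraction=0.1, n_permutations=500,
                                           seed=2000 + r)
            if res.p_value < 0.05:
                hits += 1
        assert 0.01 <= hits / reps <= 0.10

    def test_zero_permutations_rejected(self, rng):
        W = rng.uniform(size=(5, 5))
        att = make_map({"chr1": W})
        with pytest.raises(ValueError):
            overlap_permutation_test(att, {"chr1": W}, 0.2, n_permutations=0)

    def test_observed_overlap_rank_invariant(self, rng):
        p = 15
        W = rng.uniform(size=(p, p))
        C = rng.uniform(size=(p, p))
        att1 = make_map({"chr1": W})
        att2 = make_map({"chr1": np.exp(2 * (0.5 * (W + W.T)))})
        r1 = overlap_permutation_test(att1, {"chr1": 0.5 * (C + C.T)}, 0.1, 50, seed=3)
        r2 = overlap_permutation_test(att2, {"chr1": 0.5 * (C + C.T)}, 0.1, 50, seed=3)
        assert r1.n_overlap == r2.n_overlap and r1.p_value == r2.p_value

    def test_pvalue_never_zero_and_overlap_bounded(self, rng):
        for _ in range(10):
            p = 10
            att = make_map({"chr1": rng.uniform(size=(p, p))})
            C = rng.uniform(size=(p, p))
            res = overlap_permutation_test(att, {"chr1": 0.5 * (C + C.T)}, 0.2, 30,
                                           seed=int(rng.integers(1 << 30)))
            assert 0 < res.p_value <= 1
            assert res.n_overlap <= min(res.n_attention_selected, res.n_contact_selected)
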