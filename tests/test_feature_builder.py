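import numpy as np
import pytest

from lncboost.data_io import EntityIndex, InteractionMatrix, SimilarityMatrix
from lncboost.feature_builder import (
    FeatureLayout,
    LabeledPairSet,
    assemble_pair_features,
    balanced_pair_set,
    feature_dim,
    fuse_similarity,
    get_layout,
    layout_presets,
    sample_negative_pairs,
)


def _sim(values, labels, kind="custom"):
    return SimilarityMatrix(values=np.asarray(values, dtype=float), labels=labels, kind=kind)


class TestFuseSimilarity:
    def test_semantic_average_wins_for_mapped_pair(self):
        s1 = _sim([[1.0, 0.4], [0.4, 1.0]], ["a", "b"])
        s2 = _sim([[1.0, 0.6], [0.6, 1.0]], ["a", "b"])
        gip = _sim([[1.0, 0.9], [0.9, 1.0]], ["a", "b"])
        assert fuse_similarity(s1, s2, gip).values[0, 1] == pytest.approx(0.5)

    def test_unmapped_entity_falls_back_to_kernel(self):
        # second entity has no semantic information (all-zero row incl. diagonal)
        s1 = _sim([[1.0, 0.0], [0.0, 0.0]], ["a", "b"])
        s2 = _sim([[1.0, 0.0], [0.0, 0.0]], ["a", "b"])
        gip = _sim([[1.0, 0.8], [0.8, 1.0]], ["a", "b"])
        fused = fuse_similarity(s1, s2, gip)
        assert fused.values[0, 1] == pytest.approx(0.8)
        assert fused.values[1, 1] == pytest.approx(1.0)

    def test_true_semantic_zero_kept_for_mapped_pair(self):
        # both entities mapped but with disjoint ancestry: 0 is information
        s1 = _sim([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        s2 = _sim([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        gip = _sim([[1.0, 0.8], [0.8, 1.0]], ["a", "b"])
        assert fuse_similarity(s1, s2, gip).values[0, 1] == 0.0

    def test_entry_presence_replaces_semantic_zeros(self):
        s1 = _sim([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        s2 = _sim([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        gip = _sim([[1.0, 0.8], [0.8, 1.0]], ["a", "b"])
        assert fuse_similarity(s1, s2, gip, presence="entry").values[0, 1] == pytest.approx(0.8)

    def test_diagonal_always_one(self):
        s1 = _sim([[1.0, 0.0], [0.0, 0.0]], ["a", "b"])
        s2 = _sim([[1.0, 0.0], [0.0, 0.0]], ["a", "b"])
        gip = _sim([[1.0, 0.5], [0.5, 1.0]], ["a", "b"])
        assert np.allclose(np.diag(fuse_similarity(s1, s2, gip).values), 1.0)

    def test_shape_mismatch(self):
        s = _sim(np.eye(2), ["a", "b"])
        g = _sim(np.eye(3), ["a", "b", "c"])
        with pytest.raises(ValueError, match="shape"):
            fuse_similarity(s, s, g)


class TestSampleNegativePairs:
    def test_reproducible_for_fixed_seed(self, toy_interaction):
        a = sample_negative_pairs(toy_interaction, 3, seed=0)
        b = sample_negative_pairs(toy_interaction, 3, seed=0)
        assert a.pairs == b.pairs
        assert len(set(a.pairs)) == 3
        assert all(toy_interaction.values[i, j] == 0 for i, j in a.pairs)

    def test_all_zero_cells(self, toy_interaction):
        n_zero = int((toy_interaction.values == 0).sum())
        got = sample_negative_pairs(toy_interaction, n_zero, seed=1)
        assert len(got) == n_zero

    def test_too_many_requested(self, toy_interaction):
        n_zero = int((toy_interaction.values == 0).sum())
        with pytest.raises(ValueError):
            sample_negative_pairs(toy_interaction, n_zero + 1, seed=0)

    def test_balanced_set_is_half_positive(self, toy_interaction):
        ps = balanced_pair_set(toy_interaction, seed=0)
        assert ps.labels.mean() == pytest.approx(0.5)
        assert len(ps) == 2 * toy_interaction.values.sum()


class TestLayouts:
    def test_fifteen_presets(self):
        presets = layout_presets()
        assert len(presets) == 15
        names = {p.name for p in presets}
        assert names == {"FHN"} | {f"THN{i}" for i in range(1, 5)} \
            | {f"TriHN{i}" for i in range(1, 7)} | {f"DHN{i}" for i in range(1, 5)}

    def test_fhn_has_all_five_blocks(self):
        fhn = get_layout("FHN")
        assert set(fhn.blocks) == {"DISSS", "LNCFS", "LNCGS", "DISGS", "LNCDIS"}

    def test_preset_sizes(self):
        for p in layout_presets():
            expected = {"F": 5, "T": 4 if p.name.startswith("THN") else 3, "D": 2}
            assert len(p.blocks) == expected[p.name[0]]

    def test_custom_layout_parsed(self):
        lay = get_layout("DISSS+LNCDIS")
        assert lay.name == "custom" and lay.blocks == ("DISSS", "LNCDIS")

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError, match="unknown blocks"):
            FeatureLayout(name="bad", blocks=("NOPE",))

    def test_empty_blocks_rejected(self):
        with pytest.raises(ValueError):
            FeatureLayout(name="bad", blocks=())


class TestAssemblePairFeatures:
    def _matrices(self, n_d=4, n_l=6, seed=0):
        rng = np.random.default_rng(seed)
        index = EntityIndex(diseases=[f"d{i}" for i in range(n_d)],
                            lncrnas=[f"l{j}" for j in range(n_l)])
        inter = InteractionMatrix(values=(rng.random((n_d, n_l)) < 0.4).astype(np.int8),
                                  index=index)

        def sym(n):
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            return v

        mats = dict(
            disss=_sim(sym(n_d), index.diseases, "DISSS"),
            disgs=_sim(sym(n_d), index.diseases, "DISGS"),
            diss=_sim(sym(n_d), index.diseases, "DISS"),
            lncfs=_sim(sym(n_l), index.lncrnas, "LNCFS"),
            lncgs=_sim(sym(n_l), index.lncrnas, "LNCGS"),
            lncs=_sim(sym(n_l), index.lncrnas, "LNCS"),
        )
        return inter, mats

    def test_fhn_dimension(self):
        inter, mats = self._matrices()
        pairs = LabeledPairSet(pairs=[(0, 0), (1, 2)], labels=np.array([1, 0]))
        feats = assemble_pair_features(pairs, get_layout("FHN"), inter, **mats)
        assert feats.dim == 4 + 6 + 6 + 4

    def test_two_block_dimension(self):
        inter, mats = self._matrices()
        pairs = LabeledPairSet(pairs=[(0, 0)], labels=np.array([1]))
        feats = assemble_pair_features(pairs, get_layout("DHN1"), inter, **mats)
        assert feats.dim == 4 + 6

    @pytest.mark.parametrize("name", ["FHN", "THN1", "THN2", "TriHN2", "TriHN5", "DHN2"])
    def test_dimension_formula_holds_for_presets(self, name):
        inter, mats = self._matrices(n_d=5, n_l=7, seed=2)
        pairs = LabeledPairSet(pairs=[(0, 0)], labels=np.array([1]))
        layout = get_layout(name)
        feats = assemble_pair_features(pairs, layout, inter, **mats)
        assert feats.dim == feature_dim(layout, 5, 7)

    def test_mask_target_zeroes_own_cell(self):
        inter, mats = self._matrices()
        i, j = np.argwhere(inter.values == 1)[0]
        pairs = LabeledPairSet(pairs=[(int(i), int(j))], labels=np.array([1]))
        feats = assemble_pair_features(pairs, get_layout("FHN"), inter, **mats,
                                       mask_target=True)
        n_d, n_l = 4, 6
        d_profile = feats.rows[0, n_d + n_l : n_d + 2 * n_l]
        l_profile = feats.rows[0, n_d + 2 * n_l :]
        assert d_profile[j] == 0.0 and l_profile[i] == 0.0
        assert d_profile.sum() == inter.values[i].sum() - 1
        assert l_profile.sum() == inter.values[:, j].sum() - 1

    def test_unmasked_profiles_keep_own_cell(self):
        inter, mats = self._matrices()
        i, j = np.argwhere(inter.values == 1)[0]
        pairs = LabeledPairSet(pairs=[(int(i), int(j))], labels=np.array([1]))
        feats = assemble_pair_features(pairs, get_layout("FHN"), inter, **mats,
                                       mask_target=False)
        assert feats.rows[0, 4 + 6 + j] == 1.0

    def test_missing_matrix_errors(self):
        inter, mats = self._matrices()
        pairs = LabeledPairSet(pairs=[(0, 0)], labels=np.array([1]))
        with pytest.raises(ValueError, match="fused disease"):
            assemble_pair_features(pairs, get_layout("FHN"), inter,
                                   lncs=mats["lncs"], diss=None)

    def test_repeated_pair_rejected(self):
        with pytest.raises(ValueError, match="repeated"):
            LabeledPairSet(pairs=[(0, 0), (0, 0)], labels=np.array([1, 0]))
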