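import numpy as np
import pytest

from lncboost.evaluation import (
    ConfusionCounts,
    confusion_metrics,
    counts_from_scores,
    holdout_eval,
    kfold_eval,
    loocv_eval,
    rank_candidates,
    repeated_f1_ttest,
    roc_auc,
)

from tests.oracles import auc_concordance_oracle


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert (rep.acc, rep.sen, rep.spe, rep.pre, rep.mcc) == (1, 1, 1, 1, 1)

    def test_hand_computed_case(self):
        rep = confusion_metrics(ConfusionCounts(tp=8, fn=2, tn=6, fp=4))
        assert rep.acc == pytest.approx(0.7)
        assert rep.sen == pytest.approx(0.8)
        assert rep.spe == pytest.approx(0.6)
        assert rep.pre == pytest.approx(2 / 3)
        assert rep.mcc == pytest.approx(0.40824829, abs=1e-6)

    def test_degenerate_margin_flagged_zero(self):
        rep = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert rep.pre == 0.0 and rep.mcc == 0.0
        assert rep.flags

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_counts_match_independent_formulas(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, size=4))
        if tp + fp + tn + fn == 0:
            return
        rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert rep.acc == pytest.approx((tp + tn) / (tp + fp + tn + fn))
        if tp + fn:
            assert rep.sen == pytest.approx(tp / (tp + fn))
        denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
        if denom:
            assert rep.mcc == pytest.approx((tp * tn - fp * fn) / np.sqrt(denom))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.3], [1, 1, 0]).auc == pytest.approx(1.0)

    def test_three_of_four_concordant(self):
        assert roc_auc([0.9, 0.2, 0.6, 0.4], [1, 0, 0, 1]).auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # deliberate ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_concordance_oracle(scores, labels), abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        curve = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()


def test_counts_from_scores_threshold():
    counts = counts_from_scores(np.array([0.9, 0.4, 0.6, 0.1]), np.array([1, 1, 0, 0]), 0.5)
    assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)


class TestProtocols:
    def test_holdout_deterministic_for_seed(self, tiny_dataset, fast_config):
        r1 = holdout_eval(tiny_dataset, fast_config, seed=0)
        r2 = holdout_eval(tiny_dataset, fast_config, seed=0)
        assert r1.to_dict() == r2.to_dict()

    def test_holdout_test_size(self, tiny_dataset, fast_config):
        rep = holdout_eval(tiny_dataset, fast_config, ratio=0.8, seed=0)
        assert rep.counts.total == pytest.approx(0.2 * len(tiny_dataset.pairs), abs=1)

    def test_kfold_folds_disjoint_exhaustive_stratified(self, tiny_dataset, fast_config):
        cv = kfold_eval(tiny_dataset, fast_config, k=5, seed=0)
        totals = sum(r.counts.total for r in cv.fold_reports)
        assert totals == len(tiny_dataset.pairs)
        pos_per_fold = [r.counts.tp + r.counts.fn for r in cv.fold_reports]
        n_pos = int(tiny_dataset.pairs.labels.sum())
        assert all(abs(p - n_pos / 5) <= 1 for p in pos_per_fold)

    def test_kfold_mean_is_fold_mean(self, tiny_dataset, fast_config):
        cv = kfold_eval(tiny_dataset, fast_config, k=5, seed=0)
        assert cv.means["auc"] == pytest.approx(
            np.mean([r.auc for r in cv.fold_reports]))

    def test_kfold_more_folds_than_samples(self, tiny_dataset, fast_config):
        with pytest.raises(ValueError):
            kfold_eval(tiny_dataset, fast_config, k=10_000)

    def test_loocv_pools_one_score_per_sample(self, fast_config):
        from lncboost.pipeline import dataset_from_bundle
        from lncboost.synthetic import SyntheticSpec, generate_bundle
        import dataclasses

        spec = SyntheticSpec(n_diseases=6, n_lncrnas=8, n_clusters=2, p_in=0.9,
                             p_out=0.05, seed=11)
        ds = dataset_from_bundle(generate_bundle(spec), negative_seed=0)
        cfg = dataclasses.replace(fast_config)
        rep = loocv_eval(ds, cfg)
        assert rep.protocol == "loocv"
        assert rep.counts.total == len(ds.pairs)

    def test_loocv_needs_ten_samples(self, fast_config, tiny_dataset):
        small = tiny_dataset.pairs.subset(np.arange(4))
        import dataclasses
        ds = dataclasses.replace(tiny_dataset, pairs=small)
        with pytest.raises(ValueError):
            loocv_eval(ds, fast_config)

    def test_ttest_identical_configs_flagged(self, tiny_dataset, fast_config):
        out = repeated_f1_ttest(tiny_dataset, fast_config, fast_config, n_rep=3, seed=0)
        assert out["f1_mean_a"] == out["f1_mean_b"]
        assert out["p_value"] == 1.0
        assert out["flags"]

    def test_ttest_low_rep_warns(self, tiny_dataset, fast_config, caplog):
        repeated_f1_ttest(tiny_dataset, fast_config, fast_config, n_rep=2, seed=0)
        assert any("low power" in r.message for r in caplog.records)


class TestRankCandidates:
    def test_unknown_disease(self, tiny_dataset, fast_config):
        with pytest.raises(KeyError):
            rank_candidates("nope", tiny_dataset, fast_config)

    def test_ranking_covers_all_lncrnas_descending(self, tiny_dataset, fast_config):
        disease = tiny_dataset.interaction.index.diseases[0]
        ranking = rank_candidates(disease, tiny_dataset, fast_config, seed=0)
        assert len(ranking) == tiny_dataset.interaction.index.n_lncrnas
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)

    def test_disease_with_no_links_still_ranked(self, fast_config):
        import dataclasses
        import numpy as np
        from lncboost.pipeline import dataset_from_bundle
        from lncboost.synthetic import SyntheticSpec, generate_bundle

        ds = dataset_from_bundle(generate_bundle(
            SyntheticSpec(n_diseases=8, n_lncrnas=10, n_clusters=2, p_in=0.8,
                          p_out=0.05, seed=2)), negative_seed=0)
        deg = ds.interaction.values.sum(axis=1)
        if deg.min() > 0:  # force an isolated disease
            vals = ds.interaction.values.copy()
            vals[0, :] = 0
            from lncboost.data_io import InteractionMatrix
            from lncboost.feature_builder import balanced_pair_set
            inter = InteractionMatrix(values=vals, index=ds.interaction.index)
            ds = dataclasses.replace(ds, interaction=inter,
                                     pairs=balanced_pair_set(inter, seed=0))
        disease = ds.interaction.index.diseases[int(np.argmin(ds.interaction.values.sum(axis=1)))]
        ranking = rank_candidates(disease, ds, fast_config, seed=0)
        assert len(ranking) == ds.interaction.index.n_lncrnas
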