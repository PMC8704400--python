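"""Confusion-matrix metrics, LOSO folds, label merging, personalization."""

import numpy as np
import pytest

from trampohar import (
    ConfusionMatrix,
    EvalReport,
    MotionLabel,
    PersonalizationScheme,
    TrainConfig,
    WindowingConfig,
    loso_split,
    merge_labels,
    metrics,
    personalize,
    render_table,
    round_half_up,
    run_loso,
    segment_all,
    train,
    build,
)
from oracles import metrics_oracle

LABELS = tuple(l.code for l in MotionLabel)


def random_cm(rng):
    return ConfusionMatrix(rng.integers(0, 50, (6, 6)))


class TestMetrics:
    def test_matches_per_cell_summation_oracle(self, rng):
        for _ in range(20):
            cm = random_cm(rng)
            got = metrics(cm)
            exp = metrics_oracle(cm.counts.tolist())
            for i, label in enumerate(LABELS):
                assert got.precision[label] == pytest.approx(exp["precision"][i])
                assert got.recall[label] == pytest.approx(exp["recall"][i])
                assert got.f_measure[label] == pytest.approx(exp["f"][i])
            assert got.accuracy == pytest.approx(exp["accuracy"])

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(np.diag([10] * 6)))
        assert all(v == 100.0 for v in m.precision.values())
        assert all(v == 100.0 for v in m.f_measure.values())
        assert m.accuracy == 100.0

    def test_zero_row_imputes_zero(self):
        counts = np.diag([10] * 6)
        counts[0] = 0
        m = metrics(ConfusionMatrix(counts))
        assert m.precision["ST"] == 0.0 and m.f_measure["ST"] == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(ConfusionMatrix(np.zeros((6, 6), int)))

    def test_round_half_up(self):
        assert round_half_up(98.45) == 98.5
        assert round_half_up(98.4449) == 98.4


class TestMergeLabels:
    def test_merge_conserves_total(self, rng):
        cm = random_cm(rng)
        merged = merge_labels(cm, [["ST"], ["WL"], ["MR"], ["TJ"], ["LJ", "RJ"]])
        assert merged.total == cm.total
        assert merged.labels == ("ST", "WL", "MR", "TJ", "LJ+RJ")

    def test_merge_never_decreases_accuracy(self, rng):
        for _ in range(10):
            cm = random_cm(rng)
            merged = merge_labels(cm, [["ST"], ["WL"], ["MR", "LJ", "RJ"], ["TJ"]])
            assert merged.accuracy_pct() >= cm.accuracy_pct()

    def test_merging_everything_is_perfect(self, rng):
        merged = merge_labels(random_cm(rng), [list(LABELS)])
        assert merged.accuracy_pct() == 100.0

    def test_non_partition_rejected(self, rng):
        with pytest.raises(ValueError, match="partition"):
            merge_labels(random_cm(rng), [["ST", "WL"], ["MR"]])
        with pytest.raises(ValueError, match="partition"):
            merge_labels(random_cm(rng), [list(LABELS), ["ST"]])


class TestLosoSplit:
    def test_folds_partition_subjects(self, tiny_cohort):
        folds = loso_split(tiny_cohort)
        subjects = {r.subject_id for r in tiny_cohort}
        assert len(folds) == len(subjects)
        assert {t for _, t in folds} == subjects
        for train_subjects, test_subject in folds:
            assert test_subject not in train_subjects
            assert set(train_subjects) | {test_subject} == subjects

    def test_no_test_windows_leak_into_training(self, tiny_cohort):
        windows = segment_all(tiny_cohort)
        for train_subjects, test_subject in loso_split(windows):
            train_ids = {w.subject_id for w in windows if w.subject_id in train_subjects}
            assert test_subject not in train_ids

    def test_single_subject_rejected(self, tiny_cohort):
        one = [r for r in tiny_cohort if r.subject_id == "A"]
        with pytest.raises(ValueError, match="2 subjects"):
            loso_split(one)


class TestEvalReport:
    def test_pooled_is_sum_and_avg_is_mean(self, rng):
        cms = {s: random_cm(rng) for s in "ABC"}
        report = EvalReport(per_subject=cms)
        np.testing.assert_array_equal(
            report.pooled.counts, sum(cm.counts for cm in cms.values())
        )
        assert report.avg_accuracy == pytest.approx(
            np.mean([cm.accuracy_pct() for cm in cms.values()])
        )

    def test_run_loso_conserves_window_counts(self, tiny_cohort):
        report = run_loso(
            tiny_cohort, "depth:1", config=TrainConfig(epochs=3, seed=0)
        )
        n_windows = len(segment_all(tiny_cohort))
        assert report.pooled.total == n_windows
        d = report.to_dict()
        assert set(d["per_subject"]) == {r.subject_id for r in tiny_cohort}

    def test_run_loso_rf(self, tiny_cohort):
        report = run_loso(tiny_cohort, "rf", config=TrainConfig(epochs=1, seed=0),
                          rf_estimators=25)
        assert report.pooled.total == len(segment_all(tiny_cohort))
        assert report.avg_accuracy > 100 / 6  # above chance on synthetic classes

    def test_render_table_layout(self, rng):
        text = render_table(random_cm(rng))
        lines = text.splitlines()
        assert lines[0].startswith("Pre.\\Cor.") and "Precision" in lines[0]
        assert lines[-2].startswith("Recall")
        assert lines[-1].startswith("F [%]")


@pytest.fixture(scope="module")
def setting(tiny_cohort):
    cfg = TrainConfig(epochs=4, seed=3)
    windows = segment_all(tiny_cohort)
    others = [w for w in windows if w.subject_id != "A"]
    base = train(build("depth:1"), others, cfg)
    return tiny_cohort, base, cfg


class TestPersonalization:

    def test_none_scheme_is_a_no_op(self, setting):
        cohort, base, cfg = setting
        before = base.net.get_weights()
        res = personalize(cohort, "A", PersonalizationScheme("None"),
                          base_model=base, model_kind="depth:1", config=cfg)
        probe = segment_all([r for r in cohort if r.subject_id == "A"])
        np.testing.assert_array_equal(res.model.predict(probe), base.predict(probe))
        for a, b in zip(base.net.get_weights(), before):
            np.testing.assert_array_equal(a, b)

    def test_ft_classifier_freezes_extractor(self, setting):
        cohort, base, cfg = setting
        res = personalize(cohort, "A", PersonalizationScheme("FT-Classifier"),
                          base_model=base, model_kind="depth:1", config=cfg,
                          ft_config=TrainConfig(epochs=3, seed=5))
        w_base, w_ft = base.net.get_weights(), res.model.net.get_weights()
        for a, b in zip(w_base[:-2], w_ft[:-2]):  # all but the softmax layer
            np.testing.assert_array_equal(a, b)
        assert any((a != b).any() for a, b in zip(w_base[-2:], w_ft[-2:]))

    def test_ft_updates_extractor(self, setting):
        cohort, base, cfg = setting
        res = personalize(cohort, "A", PersonalizationScheme("FT"),
                          base_model=base, model_kind="depth:1", config=cfg,
                          ft_config=TrainConfig(epochs=3, seed=5))
        w_base, w_ft = base.net.get_weights(), res.model.net.get_weights()
        assert any((a != b).any() for a, b in zip(w_base[:-2], w_ft[:-2]))

    def test_evaluation_uses_only_heldout_sets(self, setting):
        cohort, base, cfg = setting
        res = personalize(cohort, "A", PersonalizationScheme("None"),
                          base_model=base, model_kind="depth:1", config=cfg)
        user = [r for r in cohort if r.subject_id == "A"]
        heldout = segment_all([r for r in user if r.set_index > 3])
        assert res.cm.total == len(heldout)

    def test_rotate_sets_covers_all_choices(self, setting):
        cohort, base, cfg = setting
        results = personalize(cohort, "A", PersonalizationScheme("None"),
                              base_model=base, model_kind="depth:1", config=cfg,
                              rotate_sets=True)
        assert len(results) == 10  # C(5,3) adaptation-set choices

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            PersonalizationScheme("FineTuneAll")

    def test_too_few_sets_rejected(self, setting):
        cohort, base, cfg = setting
        short = [r for r in cohort if r.set_index <= 3]
        with pytest.raises(ValueError, match="sets"):
            personalize(short, "A", PersonalizationScheme("None"),
                        base_model=base, model_kind="depth:1", config=cfg)
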