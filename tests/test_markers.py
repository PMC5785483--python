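import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oralmia.io_tables import OtuTable, ValidationError, metadata_frame
from oralmia.markers import (
    MarkerEntry,
    MarkerRanking,
    MiaPanel,
    best_panel,
    classify,
    cv_error_curve,
    enumerate_panels,
    mia_score,
    mia_scores,
    rf_rank,
    roc,
    split_evaluate,
    youden_cutoff,
)
from oralmia.synthdata import SynthConfig, generate_study


def _planted_table(rng, n_otus=30, n_per=15, planted="o0"):
    """Noise counts plus one OTU that perfectly separates the classes."""
    counts = rng.integers(10, 100, size=(n_otus, 2 * n_per))
    idx = int(planted.lstrip("o"))
    counts[idx, :n_per] = rng.integers(5, 15, n_per)       # control: low
    counts[idx, n_per:] = rng.integers(400, 500, n_per)    # ASD: high
    table = OtuTable(
        [f"o{i}" for i in range(n_otus)],
        [f"s{j}" for j in range(2 * n_per)],
        counts,
    )
    labels = np.array(["control"] * n_per + ["ASD"] * n_per)
    return table, labels


class TestRfRank:
    def test_planted_separator_first(self):
        firsts = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            table, labels = _planted_table(rng)
            ranking = rf_rank(table, labels, n_top=10, seed=seed, n_estimators=100)
            firsts += ranking.entries[0].otu_id == "o0"
        assert firsts >= 9

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(0)
        table, labels = _planted_table(rng)
        shuffled = rng.permutation(labels)
        ranking = rf_rank(table, shuffled, n_top=30, seed=0, n_estimators=100)
        importances = {e.otu_id: e.importance for e in ranking.entries}
        others = [v for k, v in importances.items() if k != "o0"]
        assert importances["o0"] <= np.quantile(others, 0.95)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        table, _ = _planted_table(rng, n_per=3)
        with pytest.raises(ValidationError):
            rf_rank(table, ["ASD"] * 6, seed=0, n_estimators=10)

    def test_determinism_and_direction(self):
        rng = np.random.default_rng(2)
        table, labels = _planted_table(rng)
        r1 = rf_rank(table, labels, n_top=5, seed=3, n_estimators=50)
        r2 = rf_rank(table, labels, n_top=5, seed=3, n_estimators=50)
        assert [e.otu_id for e in r1.entries] == [e.otu_id for e in r2.entries]
        directions = {e.otu_id: e.direction for e in r1.entries}
        assert directions["o0"] == "ASD-enriched"

    def test_external_directions_override(self):
        rng = np.random.default_rng(3)
        table, labels = _planted_table(rng)
        ranking = rf_rank(table, labels, n_top=3, seed=0, n_estimators=50,
                          directions={"o0": "control-enriched"})
        assert {e.otu_id: e.direction for e in ranking.entries}["o0"] == "control-enriched"

    def test_ranking_invariants(self):
        with pytest.raises(ValidationError):
            MarkerRanking(
                [MarkerEntry("a", 0.1, None), MarkerEntry("b", 0.5, None)], n_top=2
            )
        with pytest.raises(ValidationError):
            MarkerRanking([MarkerEntry("a", 0.1, None)], n_top=2)


class TestCvErrorCurve:
    def test_determinism(self):
        rng = np.random.default_rng(4)
        table, labels = _planted_table(rng, n_per=10)
        ranking = rf_rank(table, labels, n_top=4, seed=0, n_estimators=30)
        c1 = cv_error_curve(table, labels, ranking, folds=5, trials=2, seed=1,
                            n_estimators=30)
        c2 = cv_error_curve(table, labels, ranking, folds=5, trials=2, seed=1,
                            n_estimators=30)
        assert c1.errors == c2.errors and c1.selected_k == c2.selected_k

    def test_planted_recovery_low_error(self):
        rng = np.random.default_rng(5)
        table, labels = _planted_table(rng, n_otus=50, n_per=15)
        ranking = rf_rank(table, labels, n_top=15, seed=0, n_estimators=50)
        curve = cv_error_curve(table, labels, ranking, folds=5, trials=2, seed=0,
                               n_estimators=50)
        assert curve.selected_error <= 0.1
        assert curve.selected_k <= 15
        assert curve.errors[curve.ks.index(curve.selected_k)] == curve.selected_error

    def test_null_error_near_chance(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(10, 100, size=(20, 30))
        table = OtuTable([f"o{i}" for i in range(20)], [f"s{j}" for j in range(30)],
                         counts)
        labels = np.array(["control"] * 12 + ["ASD"] * 18)
        ranking = rf_rank(table, labels, n_top=5, seed=0, n_estimators=30)
        curve = cv_error_curve(table, labels, ranking, folds=5, trials=2, seed=0,
                               n_estimators=30)
        minority = 12 / 30
        assert all(abs(e - minority) < 0.35 for e in curve.errors)

    def test_selected_k_smallest_on_ties(self):
        rng = np.random.default_rng(7)
        table, labels = _planted_table(rng, n_per=10)
        ranking = rf_rank(table, labels, n_top=5, seed=0, n_estimators=30)
        curve = cv_error_curve(table, labels, ranking, folds=5, trials=1, seed=0,
                               n_estimators=30)
        best = min(curve.errors)
        assert curve.selected_k == curve.ks[curve.errors.index(best)]

    def test_bad_k_grid(self):
        rng = np.random.default_rng(8)
        table, labels = _planted_table(rng, n_per=5)
        ranking = rf_rank(table, labels, n_top=3, seed=0, n_estimators=10)
        with pytest.raises(ValidationError):
            cv_error_curve(table, labels, ranking, k_grid=[0, 1], n_estimators=10)


class TestMiaScore:
    def test_worked_example(self):
        panel = MiaPanel(("a1", "a2"), ("c1",))
        sample = {"a1": 10, "a2": 20, "c1": 30}
        assert mia_score(sample, panel) == pytest.approx(-15.0)

    def test_control_only_panel(self):
        panel = MiaPanel((), ("c1", "c2", "c3"))
        sample = {"c1": 6, "c2": 9, "c3": 15}
        assert mia_score(sample, panel) == pytest.approx(-10.0)

    def test_asd_only_panel(self):
        panel = MiaPanel(("a1",), ())
        assert mia_score({"a1": 7}, panel) == pytest.approx(7.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValidationError):
            MiaPanel((), ())

    def test_missing_otu_named(self):
        panel = MiaPanel(("zzz",), ())
        with pytest.raises(ValidationError, match="zzz"):
            mia_score({"a": 1}, panel)

    def test_random_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            m, n = rng.integers(0, 4, size=2)
            if m + n == 0:
                continue
            otus = [f"x{i}" for i in range(m + n)]
            panel = MiaPanel(tuple(otus[:m]), tuple(otus[m:]))
            values = {o: float(rng.normal()) for o in otus}
            expected = (sum(values[o] for o in otus[:m]) / m if m else 0.0) - (
                sum(values[o] for o in otus[m:]) / n if n else 0.0
            )
            assert mia_score(values, panel) == pytest.approx(expected, abs=1e-12)

    def test_table_scores_match_per_sample(self, tiny_table):
        panel = MiaPanel(("OTU001",), ("OTU003",))
        scores = mia_scores(tiny_table, panel, scale="counts")
        for sid in tiny_table.sample_ids:
            expected = mia_score(dict(tiny_table.sample_counts(sid)), panel)
            assert scores[sid] == pytest.approx(expected)

    def test_relative_scale(self, tiny_table):
        panel = MiaPanel(("OTU001",), ())
        scores = mia_scores(tiny_table, panel, scale="relative")
        assert scores["S1"] == pytest.approx(0.2)

    def test_unknown_scale(self, tiny_table):
        with pytest.raises(ValidationError):
            mia_scores(tiny_table, MiaPanel(("OTU001",), ()), scale="log")


class TestRoc:
    def test_perfect_separation(self):
        curve = roc([1, 2, 3, 10, 11, 12], ["control"] * 3 + ["ASD"] * 3)
        assert curve.auc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "ASD", "control")
        assert abs(roc(scores, labels).auc - 0.5) < 0.05

    def test_u_statistic_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n2 = rng.integers(3, 20, size=2)
            scores = np.concatenate(
                [rng.integers(0, 8, n1), rng.integers(0, 8, n2)]
            ).astype(float)  # integer scores force ties
            labels = np.array(["ASD"] * n1 + ["control"] * n2)
            u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                                   alternative="two-sided").statistic
            assert roc(scores, labels).auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.4, "ASD", "control")
        a1 = roc(scores, labels).auc
        a2 = roc(np.exp(scores * 3), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc([1, 2], ["ASD", "ASD"])

    def test_curve_monotone(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, "ASD", "control")
        curve = roc(scores, labels)
        assert (np.diff(curve.tpr) >= -1e-12).all()
        assert (np.diff(curve.fpr) >= -1e-12).all()


class TestYoudenCutoff:
    def test_separated_classes(self):
        curve = roc([0, 1, 2, 10, 11], ["control"] * 3 + ["ASD"] * 2)
        cutoff, sens, spec = youden_cutoff(curve)
        assert sens == 1.0 and spec == 1.0
        assert 2 <= cutoff < 10

    def test_single_pair(self):
        curve = roc([3.0, 7.0], ["control", "ASD"])
        cutoff, sens, spec = youden_cutoff(curve)
        assert sens == spec == 1.0

    def test_confusion_matrix_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            scores = rng.normal(size=30)
            labels = np.where(rng.random(30) < 0.5, "ASD", "control")
            if len(set(labels)) < 2:
                continue
            curve = roc(scores, labels)
            cutoff, sens, spec = youden_cutoff(curve)
            predicted = classify(scores, cutoff)
            pos = labels == "ASD"
            assert sens == pytest.approx(np.mean(predicted[pos] == "ASD"))
            assert spec == pytest.approx(np.mean(predicted[~pos] == "control"))


class TestClassify:
    def test_boundary_is_control(self):
        assert classify([5.0], 5.0)[0] == "control"

    def test_above_boundary_is_asd(self):
        assert classify([5.0 + 1e-9], 5.0)[0] == "ASD"


@pytest.fixture(scope="module")
def marker_study():
    config = SynthConfig(
        n_otus=100,
        group_sizes={("control", "saliva"): 27, ("ASD", "saliva"): 32},
        depth_mean=8000,
        depth_sd=500,
        n_diff_per_habitat=10,
        asd_enriched_fraction=0.4,
        log2_fold_change=3.0,
        seed=21,
    )
    table, records, _, truth = generate_study(config)
    meta = metadata_frame(records)
    labels = meta.loc[table.sample_ids, "group"].to_numpy()
    return table, labels, truth


class TestEnumeratePanels:
    def test_grid_count_identity(self):
        entries = [
            MarkerEntry(f"a{i}", 1.0 - 0.01 * i, "ASD-enriched") for i in range(7)
        ] + [
            MarkerEntry(f"c{i}", 0.5 - 0.01 * i, "control-enriched") for i in range(13)
        ]
        entries.sort(key=lambda e: -e.importance)
        ranking = MarkerRanking(entries, n_top=20)
        counts = np.random.default_rng(0).integers(1, 50, size=(20, 8))
        table = OtuTable([e.otu_id for e in entries], [f"s{j}" for j in range(8)],
                         counts)
        labels = ["ASD"] * 4 + ["control"] * 4
        panels = enumerate_panels(ranking, table, labels, mode="grid")
        assert len(panels) == (7 + 1) * (13 + 1) - 1 == 111

    def test_powerset_refused_when_large(self):
        entries = [MarkerEntry(f"a{i}", 1.0 - 0.01 * i, "ASD-enriched") for i in range(17)]
        ranking = MarkerRanking(entries, n_top=17)
        counts = np.random.default_rng(1).integers(1, 50, size=(17, 6))
        table = OtuTable([e.otu_id for e in entries], [f"s{j}" for j in range(6)],
                         counts)
        with pytest.raises(ValidationError, match="powerset"):
            enumerate_panels(ranking, table, ["ASD"] * 3 + ["control"] * 3,
                             mode="powerset")

    def test_grid_dominated_by_powerset(self):
        rng = np.random.default_rng(2)
        entries = (
            [MarkerEntry(f"a{i}", 0.9 - 0.1 * i, "ASD-enriched") for i in range(2)]
            + [MarkerEntry(f"c{i}", 0.4 - 0.1 * i, "control-enriched") for i in range(2)]
        )
        ranking = MarkerRanking(entries, n_top=4)
        counts = rng.integers(1, 100, size=(4, 12))
        table = OtuTable([e.otu_id for e in entries], [f"s{j}" for j in range(12)],
                         counts)
        labels = ["ASD"] * 6 + ["control"] * 6
        grid_best = best_panel(enumerate_panels(ranking, table, labels, mode="grid"))
        power_best = best_panel(
            enumerate_panels(ranking, table, labels, mode="powerset")
        )
        assert power_best.auc >= grid_best.auc - 1e-12

    def test_powerset_count(self):
        entries = (
            [MarkerEntry("a0", 0.9, "ASD-enriched")]
            + [MarkerEntry("c0", 0.4, "control-enriched")]
        )
        ranking = MarkerRanking(entries, n_top=2)
        counts = np.random.default_rng(3).integers(1, 50, size=(2, 8))
        table = OtuTable(["a0", "c0"], [f"s{j}" for j in range(8)], counts)
        panels = enumerate_panels(ranking, table, ["ASD"] * 4 + ["control"] * 4,
                                  mode="powerset")
        assert len(panels) == 2 * 2 - 1

    def test_planted_panel_auc_high(self, marker_study):
        table, labels, truth = marker_study
        from oralmia.difftax import diff_frame, differential_screen
        ranking = rf_rank(table, labels, n_top=20, seed=0, n_estimators=100)
        panels = enumerate_panels(ranking, table, labels, mode="grid")
        best = best_panel(panels)
        assert best.auc >= 0.9
        # every planted marker in the best panel keeps its planted direction
        direction_of = {t.otu_id: t.direction for t in truth}
        for otu in best.asd_otus:
            assert direction_of.get(otu, "ASD-enriched") == "ASD-enriched"
        for otu in best.control_otus:
            assert direction_of.get(otu, "control-enriched") == "control-enriched"

    def test_sorted_by_auc(self, marker_study):
        table, labels, _ = marker_study
        ranking = rf_rank(table, labels, n_top=6, seed=0, n_estimators=50)
        panels = enumerate_panels(ranking, table, labels, mode="grid")
        aucs = [p.auc for p in panels]
        assert aucs == sorted(aucs, reverse=True)

    def test_reported_metrics_self_consistent(self, marker_study):
        table, labels, _ = marker_study
        ranking = rf_rank(table, labels, n_top=6, seed=0, n_estimators=50)
        best = best_panel(enumerate_panels(ranking, table, labels, mode="grid"))
        predicted = classify(best.scores.to_numpy(), best.cutoff)
        pos = np.asarray(labels) == "ASD"
        assert best.sensitivity == pytest.approx(np.mean(predicted[pos] == "ASD"))
        assert best.specificity == pytest.approx(np.mean(predicted[~pos] == "control"))


class TestSplitEvaluate:
    def test_honest_generalization(self):
        config = SynthConfig(
            n_otus=100,
            group_sizes={("control", "saliva"): 100, ("ASD", "saliva"): 100},
            depth_mean=8000,
            depth_sd=500,
            n_diff_per_habitat=10,
            asd_enriched_fraction=0.4,
            log2_fold_change=2.0,
            seed=5,
        )
        table, records, _, _ = generate_study(config)
        meta = metadata_frame(records)
        labels = meta.loc[table.sample_ids, "group"].to_numpy()
        result = split_evaluate(table, labels, n_top=15, seed=0, n_estimators=100)
        assert result["train_auc"] - 0.15 <= result["test_auc"] <= result["train_auc"] + 0.05
        assert result["test_auc"] > 0.75
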