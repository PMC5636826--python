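import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hexgram.evaluate as ev
from hexgram import quipt
from hexgram.alphabets import BEST_ENCODING
from hexgram.classify import ModelConfig
from hexgram.evaluate import (
    CVPlan,
    EvaluationReport,
    auc,
    benchmark,
    confusion_metrics,
    crossvalidate,
    rank_encodings,
)
from hexgram.peptides import PeptideRecord, PeptideSet
from hexgram.synthdata import MotifSpec, SynthConfig, default_motif, generate_peptide_set


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics(2, 0, 2, 0)
        assert (m["sensitivity"], m["specificity"], m["mcc"]) == (1.0, 1.0, 1.0)

    def test_chance(self):
        m = confusion_metrics(1, 1, 1, 1)
        assert (m["sensitivity"], m["specificity"], m["mcc"]) == (0.5, 0.5, 0.0)

    def test_matches_direct_arithmetic(self):
        tp, fp, tn, fn = 57, 11, 170, 32
        m = confusion_metrics(tp, fp, tn, fn)
        assert m["sensitivity"] == pytest.approx(tp / (tp + fn))
        assert m["specificity"] == pytest.approx(tn / (tn + fp))
        assert m["mcc"] == pytest.approx(
            (tp * tn - fp * fn)
            / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        )

    def test_undefined_denominator_flagged_not_zeroed(self):
        m = confusion_metrics(0, 0, 5, 5)
        assert m["sensitivity"] == 0.0
        assert m["mcc"] is None

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auc([0.3] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        scores = rng.choice([0.1, 0.2, 0.3, 0.4], size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        total = wins = 0
        for sp, lp in zip(scores, labels):
            if lp != 1:
                continue
            for sn, ln in zip(scores, labels):
                if ln != 0:
                    continue
                total += 1
                wins += (sp > sn) + 0.5 * (sp == sn)
        assert auc(scores, labels) == pytest.approx(wins / total)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    @given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, raw):
        # quantize so the transform is strictly increasing at float precision
        raw = [round(x, 3) for x in raw]
        labels = [i % 2 for i in range(len(raw))]
        transformed = [math.exp(2 * x) - 0.5 for x in raw]
        assert auc(raw, labels) == pytest.approx(auc(transformed, labels))


@pytest.fixture(scope="module")
def cv_setup():
    cfg = SynthConfig(
        seed=5, n_pos=50, n_neg=50,
        motifs=(MotifSpec(default_motif(), p_pos=1.0, p_neg=0.0),),
    )
    ps, _ = generate_peptide_set(cfg)
    plan = CVPlan(seed=3, n_repeats=1)
    model_cfg = ModelConfig(seed=3, n_trees=60)
    return ps, plan, model_cfg


class TestCrossValidation:
    def test_deterministic_given_seed(self, cv_setup):
        ps, plan, cfg = cv_setup
        r1 = crossvalidate(ps, BEST_ENCODING, plan, cfg)
        r2 = crossvalidate(ps, BEST_ENCODING, plan, cfg)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_strong_signal_high_auc(self, cv_setup):
        ps, plan, cfg = cv_setup
        report = crossvalidate(ps, BEST_ENCODING, plan, cfg)
        assert report.mean_auc("all") >= 0.9

    def test_null_labels_auc_near_half(self):
        # one shuffled dataset retains a chance association shared by all
        # of its folds, so average over independent shuffles and use the
        # between-shuffle standard error
        means = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            cfg = SynthConfig(seed=100 + seed, n_pos=30, n_neg=30,
                              motifs=(MotifSpec(default_motif(), 0.5, 0.5),))
            ps, _ = generate_peptide_set(cfg)
            labels = rng.permutation([r.label for r in ps])
            ps = PeptideSet(
                [PeptideRecord(r.id, r.sequence, int(l)) for r, l in zip(ps, labels)]
            )
            report = crossvalidate(
                ps, BEST_ENCODING, CVPlan(seed=seed, n_repeats=1),
                ModelConfig(seed=seed, n_trees=40),
            )
            means.append(report.mean_auc("all"))
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) <= 3 * se + 0.02

    def test_selection_never_sees_test_fold(self, cv_setup, monkeypatch):
        ps, plan, cfg = cv_setup
        captured = []
        original = quipt.select_features

        def spy(fm, **kwargs):
            captured.append(set(fm.provenance["parent_id"]))
            return original(fm, **kwargs)

        monkeypatch.setattr("hexgram.evaluate.quipt.select_features", spy)
        report = crossvalidate(ps, BEST_ENCODING, plan, cfg)
        folds = sorted(report.fold_assignments)  # (repeat, fold) in call order
        assert len(captured) == len(folds)
        for train_ids, key in zip(captured, folds):
            assert train_ids.isdisjoint(report.fold_assignments[key])

    def test_long_set_evaluated_in_long_stratum(self, cv_setup):
        ps, plan, cfg = cv_setup
        long_cfg = SynthConfig(
            seed=13, n_pos=10, n_neg=10,
            motifs=(MotifSpec(default_motif(), p_pos=1.0, p_neg=0.0),),
            length_distribution={16: 0.5, 20: 0.5},
        )
        long_ps, _ = generate_peptide_set(long_cfg)
        long_ps = PeptideSet(
            [PeptideRecord(f"L{r.id}", r.sequence, r.label) for r in long_ps]
        )
        report = crossvalidate(ps, BEST_ENCODING, plan, cfg, long_set=long_ps)
        assert "16-25" in set(report.records["stratum"])

    def test_single_class_input_errors(self, cv_setup):
        ps, plan, cfg = cv_setup
        pos_only = PeptideSet([r for r in ps if r.label == 1])
        with pytest.raises(ValueError, match="both classes"):
            crossvalidate(pos_only, BEST_ENCODING, plan, cfg)


def report_from_aucs(stratum_aucs):
    """Build a minimal EvaluationReport from {stratum: [aucs]}."""
    rows = []
    for stratum, aucs in stratum_aucs.items():
        for i, a in enumerate(aucs):
            rows.append(
                {
                    "repeat": 0, "fold": i, "stratum": stratum,
                    "n_pos": 5, "n_neg": 5, "degenerate": False,
                    "auc": a, "mcc": 0.0, "sensitivity": 0.5, "specificity": 0.5,
                }
            )
    return EvaluationReport(pd.DataFrame(rows))


class TestRanking:
    def test_dominant_encoding_wins_with_minimal_rank_sum(self):
        reports = {
            "good": report_from_aucs({"6": [0.9], "7-10": [0.8]}),
            "bad": report_from_aucs({"6": [0.6], "7-10": [0.5]}),
        }
        ranking = rank_encodings(reports)
        assert ranking.winner == "good"
        assert ranking.table.loc["good", "rank_sum"] == 2  # one per stratum

    def test_hand_computed_rank_sums(self):
        reports = {
            "e1": report_from_aucs({"6": [0.9], "7-10": [0.5]}),
            "e2": report_from_aucs({"6": [0.8], "7-10": [0.7]}),
            "e3": report_from_aucs({"6": [0.7], "7-10": [0.6]}),
        }
        ranking = rank_encodings(reports)
        # stratum 6 ranks: e1=1 e2=2 e3=3; stratum 7-10: e2=1 e3=2 e1=3
        assert ranking.table.loc["e1", "rank_sum"] == 4
        assert ranking.table.loc["e2", "rank_sum"] == 3
        assert ranking.table.loc["e3", "rank_sum"] == 5
        assert ranking.winner == "e2"

    def test_ties_get_midranks_and_grand_mean_breaks(self):
        reports = {
            "x": report_from_aucs({"6": [0.8], "7-10": [0.6]}),
            "y": report_from_aucs({"6": [0.8], "7-10": [0.6]}),
            "z": report_from_aucs({"6": [0.5], "7-10": [0.5]}),
        }
        ranking = rank_encodings(reports)
        assert ranking.table.loc["x", "6"] == 1.5
        assert ranking.table.loc["y", "6"] == 1.5
        assert ranking.table.loc["x", "rank_sum"] == ranking.table.loc["y", "rank_sum"]
        ranks = ranking.table["6"]
        assert sorted(ranks) == [1.5, 1.5, 3.0]

    def test_missing_stratum_errors(self):
        reports = {
            "a": report_from_aucs({"6": [0.9], "7-10": [0.8]}),
            "b": report_from_aucs({"6": [0.7]}),
        }
        with pytest.raises(ValueError, match="lacks stratum"):
            rank_encodings(reports, strata=["6", "7-10"])

    def test_fewer_than_two_encodings_error(self):
        with pytest.raises(ValueError, match="two encodings"):
            rank_encodings({"only": report_from_aucs({"6": [0.9]})})


@pytest.fixture
def labelled_ten():
    seqs = ["KLVFFA", "ILVILV", "FYWFYW", "IIVVLL", "LVLVLV",
            "DDDDDD", "KPRKPR", "SSTTNN", "DEDEDE", "QQNNSS"]
    labels = [1] * 5 + [0] * 5
    return PeptideSet(
        [PeptideRecord(f"p{i}", s, l) for i, (s, l) in enumerate(zip(seqs, labels))]
    )


class TestBenchmark:
    def test_scores_equal_labels_auc_one(self, labelled_ten):
        scores = {pid: float(l) for pid, l in zip(labelled_ten.ids, labelled_ten.labels)}
        table = benchmark({"oracle": scores}, labelled_ten)
        assert table.loc["oracle", "auc"] == 1.0

    def test_affine_transform_preserves_auc(self, labelled_ten, rng):
        raw = {pid: float(rng.random()) for pid in labelled_ten.ids}
        affine = {pid: 7.5 * v - 3.0 for pid, v in raw.items()}
        table = benchmark({"a": raw, "b": affine}, labelled_ten)
        assert table.loc["a", "auc"] == pytest.approx(table.loc["b", "auc"])

    def test_lower_is_amyloid_orientation(self, labelled_ten):
        # energies: more negative = more amyloidogenic
        energies = {
            pid: (-10.0 if l == 1 else -1.0)
            for pid, l in zip(labelled_ten.ids, labelled_ten.labels)
        }
        table = benchmark(
            {"energy": energies}, labelled_ten,
            thresholds={"energy": -5.0}, lower_is_amyloid=["energy"],
        )
        assert table.loc["energy", "auc"] == 1.0
        assert table.loc["energy", "sensitivity"] == 1.0
        assert table.loc["energy", "specificity"] == 1.0

    def test_threshold_metrics_match_hand_confusion(self, labelled_ten):
        scores = dict(zip(labelled_ten.ids, [0.9, 0.8, 0.4, 0.7, 0.6,
                                             0.3, 0.55, 0.2, 0.1, 0.0]))
        table = benchmark({"tool": scores}, labelled_ten, thresholds={"tool": 0.5})
        # normalized threshold (0.5 - 0)/0.9; calls: scores >= 0.5 raw
        # tp = 4 (0.9,0.8,0.7,0.6), fn = 1 (0.4), fp = 1 (0.55), tn = 4
        assert table.loc["tool", "sensitivity"] == pytest.approx(4 / 5)
        assert table.loc["tool", "specificity"] == pytest.approx(4 / 5)

    def test_missing_score_names_peptide_and_tool(self, labelled_ten):
        scores = {pid: 0.5 for pid in labelled_ten.ids[:-1]}
        with pytest.raises(ValueError, match="mytool.*p9"):
            benchmark({"mytool": scores}, labelled_ten)
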