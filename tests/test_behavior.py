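"""Selectivity scoring: printed-example exactness, edge cases, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdrdti.behavior import (
    RecallRecord,
    StudyDesign,
    UndefinedSelectivityError,
    one_sample_t,
    paired_t,
    read_behavior_tsv,
    score_list,
    selectivity_index,
    subject_summary,
    write_summary_tsv,
)

from conftest import worked_example_record


class TestScoreList:
    def test_worked_example(self, design):
        score = score_list(worked_example_record(design), design)
        assert score.actual == 45
        assert score.chance == 26
        assert score.ideal == 48
        assert round(selectivity_index(score), 2) == 0.86

    def test_zero_recall(self, design):
        rec = RecallRecord(design.list_values(), np.zeros(24, bool))
        score = score_list(rec, design)
        assert (score.actual, score.chance, score.ideal) == (0, 0, 0)
        assert score.selectivity is None
        with pytest.raises(UndefinedSelectivityError):
            selectivity_index(score)

    def test_full_recall_undefined(self, design):
        rec = RecallRecord(design.list_values(), np.ones(24, bool))
        score = score_list(rec, design)
        assert score.actual == score.chance == score.ideal == 156
        assert score.selectivity is None

    def test_low_value_recall_negative_selectivity(self, design):
        values = design.list_values()
        recalled = np.zeros(24, bool)
        for v in (1, 2, 3):
            recalled[np.flatnonzero(values == v)[0]] = True
        score = score_list(RecallRecord(values, recalled), design)
        assert score.actual == 6 and score.chance == 19.5 and score.ideal == 36
        assert selectivity_index(score) == pytest.approx(-0.818, abs=5e-4)

    def test_perfect_selectivity(self, design):
        values = design.list_values()
        recalled = values == 12
        score = score_list(RecallRecord(values, recalled), design)
        assert selectivity_index(score) == 1.0
        assert score.n_high_recalled == 4 and score.n_low_recalled == 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            RecallRecord(np.array([]), np.array([], bool))

    @settings(derandomize=True, max_examples=50)
    @given(perm_seed=st.integers(0, 10**6), subset_seed=st.integers(0, 10**6))
    def test_word_order_invariance(self, design, perm_seed, subset_seed):
        """Permuting word order changes no ListScore field."""
        values = design.list_values()
        rng = np.random.default_rng(subset_seed)
        recalled = rng.random(24) < 0.4
        base = score_list(RecallRecord(values, recalled), design)
        perm = np.random.default_rng(perm_seed).permutation(24)
        other = score_list(RecallRecord(values[perm], recalled[perm]), design)
        assert other == base


class TestSelectivityInvariants:
    def test_selectivity_at_most_one_exhaustive(self):
        """SI <= 1 over every recall subset of a 6-word toy list, against a
        brute-force maximum-score oracle."""
        values = np.array([10.0, 12, 10, 1, 2, 1])  # 6-word toy list
        for bits in itertools.product([False, True], repeat=6):
            recalled = np.array(bits)
            score = score_list(RecallRecord(values, recalled))
            # oracle: best achievable total for this many recalled words
            best = max(
                values[list(c)].sum()
                for c in itertools.combinations(range(6), int(recalled.sum()))
            ) if recalled.any() else 0.0
            assert score.ideal == best
            assert score.actual <= score.ideal
            if score.selectivity is not None:
                assert score.selectivity <= 1.0 + 1e-12

    def test_chance_score_is_random_assignment_expectation(self, design):
        """Chance = 6.5 * n_recalled equals the Monte-Carlo mean of the actual
        score under random value assignment."""
        values = design.list_values()
        rng = np.random.default_rng(0)
        recalled = np.zeros(24, bool)
        recalled[:7] = True
        score = score_list(RecallRecord(values, recalled), design)
        assert score.chance == 6.5 * 7
        draws = np.array([
            values[rng.permutation(24)][recalled].sum() for _ in range(20000)
        ])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - score.chance) < 3 * se

    def test_random_subset_selectivity_mean_zero(self, design):
        """A uniformly random recalled subset has expected SI ~ 0."""
        values = design.list_values()
        rng = np.random.default_rng(1)
        sels = []
        while len(sels) < 10000:
            recalled = rng.random(24) < rng.uniform(0.1, 0.9)
            s = score_list(RecallRecord(values, recalled), design)
            if s.selectivity is not None:
                sels.append(s.selectivity)
        sels = np.asarray(sels)
        se = sels.std(ddof=1) / np.sqrt(sels.size)
        assert abs(sels.mean()) < 3 * se


class TestSubjectSummary:
    def test_identical_perfect_lists(self, design):
        values = design.list_values()
        rec = RecallRecord(values, values == 12)
        s = subject_summary([rec] * 5, design)
        assert s.mean_high_recall == 4 and s.mean_low_recall == 0
        assert s.mean_selectivity == 1.0
        assert s.n_lists_scored == 5

    def test_undefined_lists_excluded_from_selectivity_mean(self, design):
        s = subject_summary(
            [worked_example_record(design),
             RecallRecord(design.list_values(), np.zeros(24, bool))],
            design,
        )
        assert s.mean_selectivity == pytest.approx(19 / 22)
        assert s.mean_high_recall == 2.0  # recall means keep every list

    def test_all_lists_undefined(self, design):
        recs = [RecallRecord(design.list_values(), np.zeros(24, bool))] * 3
        s = subject_summary(recs, design)
        assert s.mean_selectivity is None
        assert s.mean_high_recall == 0 and s.mean_low_recall == 0


class TestTTests:
    def test_paired_zero_mean_difference(self):
        t, df, _ = paired_t([1.0, 2, 3, 4], [2.0, 1, 4, 3])
        assert t == 0 and df == 3

    def test_paired_hand_example(self):
        t, df, p = paired_t([2.0, 4, 6], [1.0, 2, 3])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-12)
        assert df == 2
        from scipy import stats as sps
        assert p == pytest.approx(2 * sps.t.sf(3.4641016, 2), rel=1e-5)

    def test_df_convention_n19(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=19)
        assert paired_t(x, rng.normal(size=19))[1] == 18
        assert one_sample_t(x)[1] == 18

    def test_one_sample_hand_example(self):
        t, df, _ = one_sample_t([0.5, 0.6, 0.7], 0.0)
        assert t == pytest.approx(0.6 / (0.1 / np.sqrt(3)), rel=1e-12)

    def test_zero_variance_signals_infinite_t(self):
        t, _, p = paired_t([2.0, 3, 4], [1.0, 2, 3])
        assert np.isinf(t) and t > 0 and p == 0.0


class TestTSVRoundTrip:
    def test_read_validates_and_scores(self, tmp_path, design):
        import pandas as pd

        values = design.list_values()
        rows = []
        rec = worked_example_record(design)
        for lst in range(2):
            for w in range(24):
                rows.append(
                    {"subject_id": "s1", "list_id": lst, "word_idx": w,
                     "value": int(values[w]), "recalled": int(rec.recalled[w])}
                )
        path = tmp_path / "behavior.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        records = read_behavior_tsv(path, design)
        assert set(records) == {"s1"} and len(records["s1"]) == 2
        summary = subject_summary(records["s1"], design)
        assert summary.mean_selectivity == pytest.approx(19 / 22)
        out = tmp_path / "summary.tsv"
        write_summary_tsv(out, {"s1": summary})
        back = pd.read_csv(out, sep="\t")
        assert back.loc[0, "mean_selectivity"] == pytest.approx(19 / 22)

    def test_bad_value_rejected(self, tmp_path, design):
        import pandas as pd

        df = pd.DataFrame(
            {"subject_id": "s", "list_id": 0, "word_idx": range(24),
             "value": [7] * 24, "recalled": 0}
        )
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="value"):
            read_behavior_tsv(p, design)
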