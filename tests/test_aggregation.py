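"""Consensus aggregation scoring: binarization rules, score, segments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fibriltools.aggregation import (
    DEFAULT_RULES,
    PREDICTORS,
    ConsensusProfile,
    PredictorRule,
    binarize,
    consensus,
    consensus_from_table,
    load_predictions,
    segments_with_score,
)


def brute_force_segments(scores, target, k):
    """Independent oracle: per-residue scan for maximal target-score runs."""
    hit = [s >= target if target == k else s == target for s in scores]
    out, start = [], None
    for i, h in enumerate(hit):
        if h and start is None:
            start = i
        if not h and start is not None:
            out.append((start + 1, i))
            start = None
    if start is not None:
        out.append((start + 1, len(scores)))
    return out


class TestBinarize:
    def test_threshold_is_strict(self):
        # values exactly at the threshold are NOT flagged
        flags = binarize([0.0, 0.0, 0.1], DEFAULT_RULES["tango"])
        np.testing.assert_array_equal(flags, [0, 0, 1])

    def test_below_rule(self):
        flags = binarize([-3.0, -2.8, -2.0], DEFAULT_RULES["pasta"])
        np.testing.assert_array_equal(flags, [1, 0, 0])

    def test_short_run_is_erased(self):
        values = [0.07] * 4 + [0.05] * 6
        flags = binarize(values, DEFAULT_RULES["foldamyloid"])
        assert flags.sum() == 0

    def test_qualifying_run_is_kept_whole(self):
        values = [0.07] * 5 + [0.05] * 5
        flags = binarize(values, DEFAULT_RULES["foldamyloid"])
        np.testing.assert_array_equal(flags, [1] * 5 + [0] * 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        values=arrays(float, 30, elements=st.floats(-1, 1)),
        bump=st.floats(0.01, 2.0),
        idx=st.integers(0, 29),
    )
    def test_monotone_before_run_filter(self, values, bump, idx):
        rule = PredictorRule("tango", "above", 0.0)
        before = binarize(values, rule)
        values2 = values.copy()
        values2[idx] += bump
        after = binarize(values2, rule)
        assert np.all(after >= before)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(values=arrays(float, 40, elements=st.floats(-0.2, 0.2)))
    def test_run_filter_never_adds_flags(self, values):
        plain = binarize(values, PredictorRule("foldamyloid", "above", 0.062))
        filtered = binarize(values, DEFAULT_RULES["foldamyloid"])
        assert np.all(filtered <= plain)


class TestConsensus:
    def test_all_zero_and_all_one(self):
        zeros = {p: np.zeros(20, dtype=int) for p in PREDICTORS}
        ones = {p: np.ones(20, dtype=int) for p in PREDICTORS}
        assert consensus(zeros).scores.sum() == 0
        assert np.all(consensus(ones).scores == 5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(matrix=arrays(np.int8, (5, 20), elements=st.integers(0, 1)))
    def test_equals_brute_force_column_count(self, matrix):
        flags = {p: matrix[i] for i, p in enumerate(PREDICTORS)}
        profile = consensus(flags)
        expected = [sum(int(matrix[i, j]) for i in range(5)) for j in range(20)]
        np.testing.assert_array_equal(profile.scores, expected)

    def test_length_mismatch_rejected(self):
        flags = {"tango": np.zeros(10), "waltz": np.zeros(11)}
        with pytest.raises(ValueError, match="mismatch"):
            consensus(flags)


class TestSegments:
    def test_top_score_runs(self):
        profile = ConsensusProfile("p", [5, 5, 5, 0, 0, 5], PREDICTORS)
        assert segments_with_score(profile, 5) == [(1, 3), (6, 6)]

    def test_no_top_score(self):
        profile = ConsensusProfile("p", [0] * 6, PREDICTORS)
        assert segments_with_score(profile, 5) == []

    def test_zero_score_runs(self):
        profile = ConsensusProfile("p", [0, 0, 1, 0], PREDICTORS)
        assert segments_with_score(profile, 0) == [(1, 2), (4, 4)]

    def test_min_len_filter(self):
        profile = ConsensusProfile("p", [5, 5, 5, 0, 0, 5], PREDICTORS)
        assert segments_with_score(profile, 5, min_len=2) == [(1, 3)]

    def test_target_outside_range_rejected(self):
        profile = ConsensusProfile("p", [0, 1], PREDICTORS)
        with pytest.raises(ValueError):
            segments_with_score(profile, 6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(scores=st.lists(st.integers(0, 5), min_size=1, max_size=50))
    def test_matches_brute_force_and_disjointness(self, scores):
        profile = ConsensusProfile("p", scores, PREDICTORS)
        top = segments_with_score(profile, 5)
        zero = segments_with_score(profile, 0)
        assert top == brute_force_segments(scores, 5, 5)
        assert zero == brute_force_segments(scores, 0, 5)
        covered_top = {i for s, e in top for i in range(s, e + 1)}
        covered_zero = {i for s, e in zero for i in range(s, e + 1)}
        assert not covered_top & covered_zero


def make_table(values_by_predictor, protein_id="prot"):
    rows = []
    for pred, values in values_by_predictor.items():
        for i, v in enumerate(values, start=1):
            rows.append((protein_id, pred, i, v))
    return pd.DataFrame(rows, columns=["protein_id", "predictor", "residue_index", "value"])


class TestFromTable:
    def test_full_pipeline_on_synthetic_values(self):
        n = 10
        hot = slice(2, 7)  # residues 3..7 aggregation-prone for every program
        values = {
            "tango": np.full(n, -1.0),
            "waltz": np.full(n, -1.0),
            "foldamyloid": np.full(n, 0.05),
            "aggrescan": np.full(n, -1.0),
            "pasta": np.full(n, 0.0),
        }
        values["tango"][hot] = 5.0
        values["waltz"][hot] = 1.0
        values["foldamyloid"][hot] = 0.08
        values["aggrescan"][hot] = 0.5
        values["pasta"][hot] = -5.0
        profile = consensus_from_table(make_table(values), "prot")
        assert segments_with_score(profile, 5) == [(3, 7)]
        assert segments_with_score(profile, 0) == [(1, 2), (8, 10)]

    def test_waltz_whole_sequence_mode(self):
        values = {"waltz": np.array([-1.0, -1.0, 5.0])}  # sum = 3 > 0
        table = make_table(values)
        per_res = consensus_from_table(table, "prot")
        whole = consensus_from_table(table, "prot", waltz_mode="whole_sequence")
        np.testing.assert_array_equal(per_res.scores, [0, 0, 1])
        np.testing.assert_array_equal(whole.scores, [1, 1, 1])

    def test_gap_in_residue_indices_rejected(self, tmp_path):
        df = make_table({"tango": [0.1, 0.2, 0.3]})
        df = df[df["residue_index"] != 2]
        path = tmp_path / "pred.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="contiguous"):
            load_predictions(path)

    def test_unknown_predictor_rejected(self, tmp_path):
        df = make_table({"tango": [0.1]})
        df.loc[0, "predictor"] = "zipper"
        path = tmp_path / "pred.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="unknown predictor"):
            load_predictions(path)
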