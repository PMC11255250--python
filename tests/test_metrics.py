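import numpy as np
import pytest

from tcnss.metrics import (MetricsReport, Segment, accuracy, evaluate, miauc,
                           segments, sov99, state_counts)
from tcnss.seqdata import ProteinRecord, Q3, Q8, reduce_to_q3

from .conftest import random_labels
from .oracles import auc_pairwise, sov99_bruteforce


class TestSegments:
    def test_runs(self):
        assert segments("HHHCC") == [Segment("H", 0, 3), Segment("C", 3, 5)]

    def test_singletons(self):
        assert len(segments("HEHEH")) == 5

    def test_empty(self):
        assert segments("") == []

    def test_concatenation_reproduces_input(self):
        rng = np.random.default_rng(0)
        s = random_labels(rng, "HGIEBTSC", 40)
        assert "".join(seg.state * seg.length for seg in segments(s)) == s


class TestSov99:
    def test_worked_case(self):
        """H pair: (3+1)/6*6 = 4; C pair: (2+1)/5*2 = 1.2; N = 8 -> 65.0."""
        assert sov99("HHHHHHCC", "HHHCCCCC") == pytest.approx(65.0)

    def test_perfect_prediction_scores_100(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = random_labels(rng, "HEC", int(rng.integers(1, 40)))
            assert sov99(s, s) == pytest.approx(100.0)

    def test_fully_disjoint_scores_zero(self):
        assert sov99("HHHH", "CCCC") == 0.0

    def test_range_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            L = int(rng.integers(1, 30))
            a = random_labels(rng, "HEC", L)
            b = random_labels(rng, "HEC", L)
            assert 0.0 <= sov99(a, b) <= 100.0

    @pytest.mark.parametrize("alphabet", ["HEC", "HGIEBTSC"])
    def test_agrees_with_bruteforce(self, alphabet):
        rng = np.random.default_rng(hash(alphabet) % 2 ** 31)
        for _ in range(100):
            L = int(rng.integers(1, 61))
            a = random_labels(rng, alphabet, L)
            b = random_labels(rng, alphabet, L)
            assert sov99(a, b) == pytest.approx(sov99_bruteforce(a, b),
                                                abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sov99("HH", "HHH")

    def test_boundary_tolerance_rewards_near_miss(self):
        """A one-residue boundary shift within delta still scores 100."""
        assert sov99("HHHHCCCC", "HHHCCCCC") == pytest.approx(100.0)


class TestAccuracy:
    def test_identical(self):
        assert accuracy("HEC", "HEC") == 100.0

    def test_worked_case(self):
        assert accuracy("HHHHHHCC", "HHHCCCCC") == 62.5

    def test_disjoint(self):
        assert accuracy("HHHH", "EEEE") == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = random_labels(rng, "HEC", 30)
        b = random_labels(rng, "HEC", 30)
        assert accuracy(a, b) == accuracy(b, a)

    def test_state_decomposed_counts(self):
        counts = state_counts("HHEC", "HHCC")
        assert counts == {"H": 2, "C": 1}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy("", "")

    def test_merge_monotonicity(self):
        """Reducing both strings to Q3 can only keep or gain matches."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            L = int(rng.integers(1, 50))
            obs = random_labels(rng, "HGIEBTSC", L)
            pred = random_labels(rng, "HGIEBTSC", L)
            assert accuracy(reduce_to_q3(obs), reduce_to_q3(pred)) >= \
                accuracy(obs, pred)


class TestMiauc:
    def test_perfect_scores(self):
        obs = "HHEEC"
        scores = np.zeros((5, 3))
        scores[np.arange(5), Q3.encode(obs)] = 1.0
        assert miauc(obs, scores, Q3) == 1.0

    def test_constant_scores_give_half(self):
        assert miauc("HHEE", np.full((4, 3), 0.2), Q3) == pytest.approx(0.5)

    def test_agrees_with_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = int(rng.integers(2, 25))
            obs = random_labels(rng, "HEC", L)
            scores = rng.random((L, 3))
            y = np.zeros((L, 3))
            y[np.arange(L), Q3.encode(obs)] = 1.0
            assert miauc(obs, scores, Q3) == pytest.approx(
                auc_pairwise(y, scores), abs=1e-12)

    def test_two_class_worked_example(self):
        obs = "HHEE"
        h_scores = np.array([0.9, 0.8, 0.7, 0.1])
        scores = np.column_stack([h_scores, 1 - h_scores])
        from tcnss.seqdata import StateAlphabet
        he = StateAlphabet(("H", "E"))
        y = np.zeros((4, 2))
        y[np.arange(4), he.encode(obs)] = 1.0
        assert miauc(obs, scores, he) == pytest.approx(auc_pairwise(y, scores))

    def test_nonfinite_scores_rejected(self):
        scores = np.full((2, 3), np.nan)
        with pytest.raises(ValueError):
            miauc("HE", scores, Q3)


class TestEvaluate:
    @staticmethod
    def _probs_for(labels, alphabet=Q3, correct=True):
        L = len(labels)
        p = np.full((L, alphabet.size), 0.05)
        idx = alphabet.encode(labels)
        if correct:
            p[np.arange(L), idx] = 0.9
        else:
            p[np.arange(L), [(i + 1) % alphabet.size for i in idx]] = 0.9
        return p / p.sum(axis=1, keepdims=True)

    def test_perfect_prediction(self):
        rec = ProteinRecord("a", "ACDEFGHI", labels3="HHHEECCC")
        report = evaluate([rec], {"a": self._probs_for("HHHEECCC")}, Q3)
        assert report.pooled["accuracy"] == 100.0
        assert report.pooled["sov99"] == 100.0
        assert report.pooled["miauc"] == 1.0

    def test_sov_pooling_is_length_weighted(self):
        r1 = ProteinRecord("a", "ACDE", labels3="HHHH")
        r2 = ProteinRecord("b", "ACDE", labels3="HHHH")
        probs = {"a": self._probs_for("HHHH"),
                 "b": self._probs_for("EEEE")}  # no overlap with observed H
        report = evaluate([r1, r2], probs, Q3)
        assert report.per_record["a"]["sov99"] == 100.0
        assert report.per_record["b"]["sov99"] == 0.0
        assert report.pooled["sov99"] == pytest.approx(50.0)

    def test_pooled_accuracy_is_residue_weighted(self):
        r1 = ProteinRecord("a", "AC", labels3="HH")
        r2 = ProteinRecord("b", "ACDEFG", labels3="EEEEEE")
        probs = {"a": self._probs_for("HH"),
                 "b": self._probs_for("EEEEEE", correct=False)}
        report = evaluate([r1, r2], probs, Q3)
        assert report.pooled["accuracy"] == pytest.approx(100.0 * 2 / 8)
        weighted = sum(report.per_record[i]["accuracy"] *
                       report.per_record[i]["length"] for i in ("a", "b")) / 8
        assert report.pooled["accuracy"] == pytest.approx(weighted)

    def test_missing_prediction_names_record(self):
        rec = ProteinRecord("a", "AC", labels3="HH")
        with pytest.raises(KeyError, match="a"):
            evaluate([rec], {}, Q3)

    def test_report_serialization(self, tmp_path):
        rec = ProteinRecord("a", "ACDE", labels3="HHEE")
        report = evaluate([rec], {"a": self._probs_for("HHEE")}, Q3)
        report.to_json(tmp_path / "metrics.json")
        report.to_csv(tmp_path / "metrics.csv")
        import json
        data = json.loads((tmp_path / "metrics.json").read_text())
        assert data["pooled"]["accuracy"] == 100.0
        lines = (tmp_path / "metrics.csv").read_text().strip().splitlines()
        assert len(lines) == 3  # header, one record, pooled row
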