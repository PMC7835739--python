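import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from splice_prognosis import (
    RiskSignatureClassifier,
    SignatureModel,
    classify_risk,
    derive_signature,
    evaluate_signature,
    logrank_test,
)
from splice_prognosis.survival import CutoffScanResult

from conftest import make_clinical


def scan_stub(tid, cutoff, direction):
    return CutoffScanResult(
        feature_id=tid,
        candidate_cutoffs=np.array([cutoff]),
        candidate_pvalues=np.array([0.01]),
        cutoff=cutoff,
        p_value=0.01,
        direction=direction,
        n_high=10,
        n_low=10,
    )


@pytest.fixture()
def printed_model():
    """Signature with the four cutoffs derived on the discovery cohort:
    two favorable transcripts (risk below 476.35 / 0.69) and two
    unfavorable ones (risk above 18.18 / 13.74)."""
    return SignatureModel(
        transcript_ids=["PKM2", "PKM-609", "PKM-093", "PKM-883"],
        cutoffs=[476.35, 0.69, 18.18, 13.74],
        risk_sides=["below", "below", "above", "above"],
        vote_threshold=2,
    )


class TestSignatureModel:
    def test_validation(self):
        with pytest.raises(ValueError, match="align"):
            SignatureModel(["a"], [1.0, 2.0], ["below"])
        with pytest.raises(ValueError, match="risk sides"):
            SignatureModel(["a"], [1.0], ["sideways"])
        with pytest.raises(ValueError, match="vote threshold"):
            SignatureModel(["a"], [1.0], ["below"], vote_threshold=5)
        with pytest.raises(ValueError, match="positive"):
            SignatureModel(["a"], [0.0], ["below"])

    def test_derive_maps_directions_to_sides(self):
        scans = {
            "fav": scan_stub("fav", 5.0, "favorable"),
            "unfav": scan_stub("unfav", 2.0, "unfavorable"),
        }
        model = derive_signature(scans)
        sides = dict(zip(model.transcript_ids, model.risk_sides))
        assert sides == {"fav": "below", "unfav": "above"}
        assert dict(zip(model.transcript_ids, model.cutoffs)) == {"fav": 5.0, "unfav": 2.0}

    def test_missing_scan_rejected(self):
        with pytest.raises(ValueError, match="missing scan"):
            derive_signature({"t": None})


class TestClassifyRisk:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["PKM2", "PKM-609", "PKM-093", "PKM-883"],
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_vote_rule_on_printed_cutoffs(self, printed_model):
        X = self._frame([
            (400.0, 0.5, 10.0, 10.0),   # two below-votes -> high risk
            (500.0, 1.0, 10.0, 10.0),   # no votes -> low risk
            (400.0, 0.5, 20.0, 20.0),   # four votes -> high risk
        ])
        calls = classify_risk(printed_model, X)
        assert list(calls["votes"]) == [2, 0, 4]
        assert list(calls["risk_class"]) == ["high", "low", "high"]

    def test_values_equal_to_cutoff_never_vote(self, printed_model):
        X = self._frame([(476.35, 0.69, 18.18, 13.74)])
        calls = classify_risk(printed_model, X)
        assert list(calls["votes"]) == [0]
        assert list(calls["risk_class"]) == ["low"]

    def test_vote_threshold_is_a_parameter(self, printed_model):
        X = self._frame([(400.0, 0.5, 10.0, 10.0)])
        strict = SignatureModel(
            printed_model.transcript_ids, printed_model.cutoffs,
            printed_model.risk_sides, vote_threshold=3,
        )
        assert list(classify_risk(strict, X)["risk_class"]) == ["low"]

    def test_missing_transcript_column_rejected(self, printed_model):
        X = pd.DataFrame({"PKM2": [1.0]}, index=["s0"])
        with pytest.raises(KeyError, match="PKM-609"):
            classify_risk(printed_model, X)


class TestEvaluateSignature:
    def test_matches_direct_logrank_and_is_order_invariant(self, rng):
        n = 40
        calls = pd.DataFrame({
            "sample_id": [f"s{i + 1}" for i in range(n)],
            "votes": rng.integers(0, 4, n),
        })
        calls["risk_class"] = np.where(calls["votes"] >= 2, "high", "low")
        times = rng.exponential(100, n)
        events = rng.integers(0, 2, n)
        events[:5] = 1
        clin = make_clinical(times, events)
        res = evaluate_signature(calls, clin)
        hi = calls["risk_class"] == "high"
        ref = logrank_test(times[hi], events[hi], times[~hi], events[~hi])
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        shuffled = calls.sample(frac=1.0, random_state=2).reset_index(drop=True)
        assert evaluate_signature(shuffled, clin).statistic == pytest.approx(
            res.statistic, rel=1e-12
        )

    def test_single_class_rejected(self):
        calls = pd.DataFrame({
            "sample_id": ["s1", "s2"], "votes": [3, 3],
            "risk_class": ["high", "high"],
        })
        clin = make_clinical([10, 20], [1, 1])
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_signature(calls, clin)

    def test_random_labels_are_null(self):
        """Random risk classes give a uniform-ish p over replicates."""
        rng = np.random.default_rng(17)
        n = 80
        hits = 0
        reps = 200
        for _ in range(reps):
            times = rng.exponential(50, n)
            events = rng.integers(0, 2, n)
            events[0] = 1
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            r = logrank_test(times[labels], events[labels],
                             times[~labels], events[~labels])
            hits += r.p_value < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 0.04


class TestEstimatorInterface:
    def test_clone_and_from_model_predict(self, printed_model):
        est = RiskSignatureClassifier(vote_threshold=2)
        assert clone(est).get_params() == est.get_params()
        applied = RiskSignatureClassifier.from_model(printed_model)
        X = pd.DataFrame(
            [(400.0, 0.5, 10.0, 10.0), (500.0, 1.0, 10.0, 10.0)],
            columns=printed_model.transcript_ids, index=["s0", "s1"],
        )
        np.testing.assert_array_equal(applied.predict(X), ["high", "low"])

    def test_fit_derives_cutoffs_from_scans(self, rng):
        n = 200
        x_fav = rng.lognormal(3, 0.6, n)
        x_unfav = rng.lognormal(1, 0.6, n)
        z_fav = (np.log(x_fav) - np.log(x_fav).mean()) / np.log(x_fav).std()
        z_unfav = (np.log(x_unfav) - np.log(x_unfav).mean()) / np.log(x_unfav).std()
        t = rng.exponential(1.0 / (0.01 * np.exp(-1.0 * z_fav + 1.0 * z_unfav)))
        X = pd.DataFrame({"fav": x_fav, "unfav": x_unfav},
                         index=[f"s{i}" for i in range(n)])
        est = RiskSignatureClassifier(vote_threshold=1).fit(X, np.c_[t, np.ones(n)])
        sides = dict(zip(est.model_.transcript_ids, est.model_.risk_sides))
        assert sides == {"fav": "below", "unfav": "above"}
        assert set(est.predict(X)) == {"high", "low"}
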