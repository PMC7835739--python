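"""Multi-transcript majority-vote risk signature.

Each signature transcript carries an expression cutoff (taken from its
individual optimal-cutoff survival scan) and a risk side: for a
favorable transcript (high expression protective) values strictly below
the cutoff vote high-risk, for an unfavorable transcript values strictly
above the cutoff vote high-risk. A sample is called high-risk when at
least ``vote_threshold`` transcripts (default 2) vote high-risk. Values
exactly equal to a cutoff never vote high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import ClinicalTable
from .survival import CutoffScanResult, LogRankResult, logrank_test, scan_optimal_cutoff

__all__ = [
    "SignatureModel",
    "RiskSignatureClassifier",
    "derive_signature",
    "classify_risk",
    "evaluate_signature",
]

_SIDES = ("below", "above")


@dataclass
class SignatureModel:
    """Per-transcript cutoffs, risk sides and the vote threshold."""

    transcript_ids: list[str]
    cutoffs: list[float]
    risk_sides: list[str]  # "below" or "above": which side votes high-risk
    vote_threshold: int = 2

    def __post_init__(self) -> None:
        k = len(self.transcript_ids)
        if not (len(self.cutoffs) == len(self.risk_sides) == k):
            raise ValueError("transcript ids, cutoffs and risk sides must align")
        if len(set(self.transcript_ids)) != k:
            raise ValueError("duplicate transcript ids in signature")
        bad = set(self.risk_sides) - set(_SIDES)
        if bad:
            raise ValueError(f"unknown risk sides: {sorted(bad)}")
        if any(c <= 0 for c in self.cutoffs):
            raise ValueError("cutoffs must be positive expression values")
        if not 1 <= self.vote_threshold <= k:
            raise ValueError("vote threshold must be between 1 and the number of transcripts")


class RiskSignatureClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style classifier applying the majority-vote signature.

    ``fit(X, y)`` derives one cutoff per transcript by running the
    optimal-cutoff survival scan on each column of ``X`` (samples x
    transcripts) against the survival outcome ``y`` (an (n, 2) array of
    time and event); the risk side is ``below`` for transcripts whose
    high expression is favorable and ``above`` otherwise. ``predict``
    returns ``"high"`` / ``"low"`` risk classes.

    A pre-specified signature (e.g. cutoffs printed for an external
    cohort) can be applied without fitting via :meth:`from_model`.
    """

    def __init__(self, vote_threshold: int = 2, lo_pct: float = 10.0, hi_pct: float = 90.0):
        self.vote_threshold = vote_threshold
        self.lo_pct = lo_pct
        self.hi_pct = hi_pct

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float))
        y = np.asarray(y, float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of (time, event)")
        scans = {
            str(col): scan_optimal_cutoff(
                X[col].to_numpy(float),
                times=y[:, 0],
                events=y[:, 1].astype(int),
                lo_pct=self.lo_pct,
                hi_pct=self.hi_pct,
                feature_id=str(col),
            )
            for col in X.columns
        }
        self.model_ = derive_signature(scans, vote_threshold=self.vote_threshold)
        self.scans_ = scans
        self.classes_ = np.array(["high", "low"])
        return self

    @classmethod
    def from_model(cls, model: SignatureModel) -> "RiskSignatureClassifier":
        est = cls(vote_threshold=model.vote_threshold)
        est.model_ = model
        est.classes_ = np.array(["high", "low"])
        return est

    def vote_counts(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        m = self.model_
        missing = [t for t in m.transcript_ids if t not in X.columns]
        if missing:
            raise KeyError(f"expression matrix lacks signature transcripts: {missing}")
        votes = np.zeros(len(X), dtype=int)
        for tid, cutoff, side in zip(m.transcript_ids, m.cutoffs, m.risk_sides):
            x = X[tid].to_numpy(float)
            votes += (x < cutoff) if side == "below" else (x > cutoff)
        return pd.Series(votes, index=X.index, name="votes")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        votes = self.vote_counts(X)
        return np.where(votes >= self.model_.vote_threshold, "high", "low")


def derive_signature(
    scans: Mapping[str, CutoffScanResult], vote_threshold: int = 2
) -> SignatureModel:
    """Build a signature from per-transcript optimal-cutoff scans.

    Favorable transcripts risk-vote below their cutoff, unfavorable ones
    above it.
    """
    if not scans:
        raise ValueError("no scans supplied")
    ids, cutoffs, sides = [], [], []
    for tid, scan in scans.items():
        if scan is None:
            raise ValueError(f"missing scan for transcript {tid!r}")
        ids.append(tid)
        cutoffs.append(scan.cutoff)
        sides.append("below" if scan.direction == "favorable" else "above")
    return SignatureModel(ids, cutoffs, sides, vote_threshold=vote_threshold)


def classify_risk(model: SignatureModel, expression: pd.DataFrame) -> pd.DataFrame:
    """Apply the vote rule to a samples x transcripts expression frame.

    Returns a table with ``sample_id``, ``votes`` and ``risk_class``.
    """
    clf = RiskSignatureClassifier.from_model(model)
    votes = clf.vote_counts(expression)
    return pd.DataFrame(
        {
            "sample_id": expression.index.astype(str),
            "votes": votes.to_numpy(),
            "risk_class": np.where(votes.to_numpy() >= model.vote_threshold, "high", "low"),
        }
    )


def evaluate_signature(calls: pd.DataFrame, clinical: ClinicalTable) -> LogRankResult:
    """Log-rank test of overall survival between risk classes."""
    if not {"sample_id", "risk_class"} <= set(calls.columns):
        raise ValueError("calls must have sample_id and risk_class columns")
    high_ids = calls.loc[calls["risk_class"] == "high", "sample_id"]
    low_ids = calls.loc[calls["risk_class"] == "low", "sample_id"]
    if high_ids.empty or low_ids.empty:
        raise ValueError("both risk classes must be non-empty")
    t_high, e_high = clinical.aligned(high_ids)
    t_low, e_low = clinical.aligned(low_ids)
    return logrank_test(t_high, e_high, t_low, e_low)
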