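"""scikit-learn estimator surface over the scoring and classification layer.

`ConsecutiveRunScorer` turns candidate sequences into (cG, cC, cG/cC)
features; `ThresholdFoldClassifier` applies — or calibrates by midpoint-
threshold ROC — the strict-inequality fold call.  Both compose with sklearn
pipelines and model selection; they are thin over the module functions in
:mod:`g4context.score` and :mod:`g4context.evaluate`.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core_seq import normalize_residues
from .evaluate import (
    FOLDING,
    NON_FOLDING,
    THRESHOLD_SENSITIVE,
    EvalCandidate,
    midpoint_thresholds,
    sens_spec,
)
from .score import cc_score, cg_score, cgcc_ratio

_FEATURE_FUNCS = {"cg": cg_score, "cc": cc_score, "ratio": cgcc_ratio}


def _as_sequences(X) -> list[str]:
    arr = np.asarray(X, dtype=object)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("expected a 1-D array-like of sequence strings")
    return [normalize_residues(str(s))[0] for s in arr]


class ConsecutiveRunScorer(TransformerMixin, BaseEstimator):
    """Transform candidate sequences into consecutive-run score features.

    Parameters
    ----------
    features : tuple of {"cg", "cc", "ratio"}
        Columns of the output matrix, in order.  The ratio column may contain
        ``inf`` (no C at all) or ``nan`` (neither G nor C).
    """

    def __init__(self, features: tuple[str, ...] = ("cg", "cc", "ratio")):
        self.features = features

    def fit(self, X, y=None):
        for name in self.features:
            if name not in _FEATURE_FUNCS:
                raise ValueError(f"unknown feature {name!r}")
        self.n_features_in_ = 1
        self.feature_names_out_ = np.asarray(self.features, dtype=object)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        seqs = _as_sequences(X)
        funcs = [_FEATURE_FUNCS[name] for name in self.features]
        return np.array([[float(f(s)) for f in funcs] for s in seqs])

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return self.feature_names_out_


class ThresholdFoldClassifier(ClassifierMixin, BaseEstimator):
    """Strict-threshold fold classifier on a single predictive score.

    Predicts folding when the score is strictly above the threshold (strictly
    below, for ``lower_is_folding`` metrics such as total loop length).  With
    ``calibrate=True``, ``fit`` scans the midpoint thresholds of the training
    scores and keeps the one maximizing sensitivity + specificity (ties to
    the lowest threshold); otherwise ``fit`` simply adopts ``threshold``.
    """

    def __init__(
        self,
        threshold: float = THRESHOLD_SENSITIVE,
        calibrate: bool = False,
        lower_is_folding: bool = False,
    ):
        self.threshold = threshold
        self.calibrate = calibrate
        self.lower_is_folding = lower_is_folding

    @staticmethod
    def _scores(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected a single score column")
        return arr

    @staticmethod
    def _labels(y) -> np.ndarray:
        raw = np.asarray(y, dtype=object)
        as_bool = []
        for v in raw:
            if isinstance(v, str):
                if v not in (FOLDING, NON_FOLDING):
                    raise ValueError(f"unknown label {v!r}")
                as_bool.append(v == FOLDING)
            else:
                as_bool.append(bool(v))
        return np.asarray(as_bool)

    def fit(self, X, y):
        scores = self._scores(X)
        labels = self._labels(y)
        if scores.shape[0] != labels.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_ = np.array([NON_FOLDING, FOLDING], dtype=object)
        self.n_features_in_ = 1
        if self.calibrate:
            adj = -scores if self.lower_is_folding else scores
            finite = np.isfinite(adj)
            cands = [
                EvalCandidate(str(i), float(s), bool(l))
                for i, (s, l) in enumerate(zip(adj[finite], labels[finite]))
            ]
            best = None
            for t in midpoint_thresholds([c.score for c in cands]):
                sens, spec = sens_spec(cands, t)
                key = (sens + spec, -t)
                if best is None or key > best[0]:
                    best = (key, t)
            assert best is not None
            self.threshold_ = -best[1] if self.lower_is_folding else best[1]
        else:
            self.threshold_ = self.threshold
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        scores = self._scores(X)
        adj = -scores if self.lower_is_folding else scores
        t = -self.threshold_ if self.lower_is_folding else self.threshold_
        with np.errstate(invalid="ignore"):
            margin = adj - t
        margin[np.isposinf(adj)] = math.inf
        return margin

    def predict(self, X) -> np.ndarray:
        margin = self.decision_function(X)
        if np.isnan(margin).any():
            raise ValueError(
                "undefined score (sequence with neither G nor C); no call possible"
            )
        return np.where(margin > 0, FOLDING, NON_FOLDING).astype(object)
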