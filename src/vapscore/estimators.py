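"""scikit-learn-style estimators wrapping the scoring pipeline.

``ScoreTransformer`` appends score columns to a cohort frame (a stateless
transform), ``ThresholdClassifier`` dichotomizes one score at a cutoff, and
:class:`vapscore.derivation.LogOddsScorer` (re-exported here) derives a
point table from a labelled cohort.  All three follow the estimator
protocol (``get_params``/``set_params``, ``fit`` returning ``self``, fitted
attributes with a trailing underscore) so they compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .derivation import LogOddsScorer
from .io import score_frame
from .records import ValidationError
from .scores import Comparison, ThresholdRule, classify

__all__ = ["ScoreTransformer", "ThresholdClassifier", "LogOddsScorer"]


class ScoreTransformer(BaseEstimator, TransformerMixin):
    """Append the five score variants to a cohort DataFrame.

    Parameters
    ----------
    lus_table : mapping, optional
        Lung-ultrasound point table; defaults to the published one.  Pass
        ``LogOddsScorer().fit(cohort).score_table_.points`` to score with a
        data-derived table.
    rules : sequence of ThresholdRule, optional
        When given, one prediction column per rule is appended too.
    """

    def __init__(self, lus_table=None, rules: Optional[Sequence[ThresholdRule]] = None):
        self.lus_table = lus_table
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None) -> "ScoreTransformer":
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("ScoreTransformer expects a cohort DataFrame")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return score_frame(X, rules=self.rules, lus_table=self.lus_table)


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Dichotomize one score variant at a cutoff.

    ``predict`` returns ``"positive"`` / ``"negative"`` /
    ``"undetermined"`` (the last for patients whose score is undefined);
    ``decision_function`` exposes the underlying score so ROC analyses can
    use the continuous value.
    """

    def __init__(self, score_name: str = "cpis_plus", cutoff: int = 12,
                 comparison: str = "ge"):
        self.score_name = score_name
        self.cutoff = cutoff
        self.comparison = comparison

    def _rule(self) -> ThresholdRule:
        return ThresholdRule(self.score_name, self.cutoff, Comparison(self.comparison))

    def fit(self, X, y=None) -> "ThresholdClassifier":
        self.rule_ = self._rule()  # validates name and cutoff range
        self.classes_ = np.array(["negative", "positive"])
        return self

    def _scores(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            col = "lus_score" if self.score_name == "lus" else self.score_name
            if col not in X.columns:
                raise ValidationError(f"column {col!r} not found; score the cohort first")
            return pd.to_numeric(X[col], errors="coerce").to_numpy(dtype=float)
        return np.asarray(X, dtype=float).ravel()

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        rule = getattr(self, "rule_", None) or self._rule()
        return np.array([classify(v, rule) for v in self._scores(X)], dtype=object)
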