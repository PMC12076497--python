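"""scikit-learn-compatible front end.

In few-shot prediction the "training set" handed to ``fit`` *is* the
support set: ``FewShotClassifier.fit(X, y)`` conditions a meta-trained
backbone on a handful of labeled molecules (no weight updates), and
``predict_proba`` scores query feature rows.  The estimator therefore
plugs into sklearn pipelines and model-selection utilities exactly like
any other classifier, while the expensive episodic meta-training lives
in :mod:`fewshotmol.training`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import EmptySupportClass
from .model import FewShotModel, load_model


class FewShotClassifier(ClassifierMixin, BaseEstimator):
    """Few-shot classifier conditioned on a support set at ``fit`` time.

    Parameters
    ----------
    model : FewShotModel or str
        A meta-trained backbone, or a path to a saved checkpoint.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Always ``[0, 1]``; both classes must appear in ``y``.
    support_X_, support_y_ : the stored support set.
    """

    def __init__(self, model=None):
        self.model = model

    def _backbone(self) -> FewShotModel:
        if isinstance(self.model, (str, bytes)) or hasattr(self.model, "__fspath__"):
            return load_model(self.model)
        if self.model is None:
            raise ValueError("FewShotClassifier requires a meta-trained model")
        return self.model

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) != {0, 1}:
            raise EmptySupportClass(
                "support labels must contain both classes (0 and 1)"
            )
        self.backbone_ = self._backbone()
        self.support_X_ = np.asarray(X, dtype=np.float64)
        self.support_y_ = y
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "backbone_")
        X = check_array(X)
        p1 = self.backbone_.predict_scores(self.support_X_, self.support_y_, X)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
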