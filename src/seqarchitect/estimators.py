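"""scikit-learn estimator wrapper around a single architecture configuration.

:class:`SequenceClassifier` turns one point of the search space into a
fit/predict classifier over one-hot encoded DNA windows, so a single
configuration composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .build import build_plan, instantiate
from .errors import InvalidInputError
from .nn import make_optimizer
from .space import HyperparamConfig, define_search_space, from_unit_vector


def default_config(space) -> HyperparamConfig:
    """The mid-point of the space (centre of the unit cube), a serviceable
    small default architecture."""
    return from_unit_vector(space, np.full(space.encoding_dim, 0.5))


class SequenceClassifier(BaseEstimator, ClassifierMixin):
    """Classifier over (n, L, 4) one-hot DNA windows from one configuration.

    Parameters
    ----------
    config : dict or None
        Hyperparameter values (a point in the search space).  ``None``
        uses the space mid-point.
    sequence_length, model_family, residual, overrides
        Search-space conditioning for interpreting ``config``.
    n_steps, batch_size
        Training budget: number of minibatch gradient steps and their size.
    random_state
        Seed for weight initialization, batch order and dropout.
    """

    def __init__(
        self,
        config=None,
        sequence_length: int = 150,
        model_family: str = "gap",
        residual: bool = False,
        overrides=None,
        n_steps: int = 200,
        batch_size: int = 32,
        random_state: int = 0,
    ):
        self.config = config
        self.sequence_length = sequence_length
        self.model_family = model_family
        self.residual = residual
        self.overrides = overrides
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 4:
            raise InvalidInputError("X must be an (n, L, 4) one-hot array")
        if X.shape[1] != self.sequence_length:
            raise InvalidInputError(
                f"X windows have length {X.shape[1]}, expected {self.sequence_length}"
            )
        return X

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise InvalidInputError("need at least 2 classes")
        space = define_search_space(
            self.sequence_length, self.model_family, self.residual, self.overrides
        )
        cfg = (
            HyperparamConfig(dict(self.config))
            if self.config is not None
            else default_config(space)
        )
        self.space_ = space
        self.plan_ = build_plan(cfg, space, len(self.classes_))
        self.model_ = instantiate(self.plan_, seed=self.random_state)
        self.n_parameters_ = self.model_.trainable_count

        opt = make_optimizer(cfg["optimizer"], self.model_)
        lr = cfg["learning_rate"]
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        for _ in range(self.n_steps):
            idx = rng.choice(n, size=bs, replace=False)
            self.model_.fit_step(X[idx], y_idx[idx], opt, lr)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._validate_X(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
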