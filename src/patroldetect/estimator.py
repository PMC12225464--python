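"""scikit-learn-style front end for the conditional detection model.

``ConditionalDetectionClassifier`` wraps the whole pipeline — category scheme
handling, min-max covariate scaling, collinearity screening, treatment-coded
design construction, MCMC posterior sampling, convergence diagnostics, WAIC
and posterior-predictive classification — behind fit/predict_proba/predict,
so it composes with sklearn model-selection tooling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import evaluation, records, reporting, sampling
from .records import CategoryScheme, build_design, collinearity_screen, scale_continuous
from .sampling import SamplerConfig


class ConditionalDetectionClassifier(BaseEstimator, ClassifierMixin):
    """Bayesian two-stage Bernoulli classifier for patrol outcomes.

    Parameters
    ----------
    detection_terms, violation_terms
        Predictor assignment for the two logit submodels.
    n_chains, n_warmup, n_samples
        MCMC settings (defaults: 3 chains, 600 warmup, 2400 sampling draws).
    threshold
        Classification threshold on the posterior-mean probability v*p.
    tune_threshold
        If True, replace ``threshold`` after fitting by the in-sample
        F1-optimal threshold from a grid sweep with ``grid_step``.
    collinearity_action
        What to do with predictor pairs whose |r| exceeds 0.7: ``"drop"``
        removes the later column of each flagged pair, ``"warn"`` keeps it,
        ``"error"`` raises.
    scheme
        Fixed :class:`CategoryScheme`; inferred from the training data when None.
    random_state
        Master seed for the sampler.

    Attributes (after ``fit``)
    --------------------------
    scheme_, scaling_, design_ : preprocessing state reused at predict time.
    draws_ : :class:`~patroldetect.sampling.PosteriorDraws`.
    rhat_report_ : convergence diagnostics (all split-Rhat < 1.1 to pass).
    waic_ : WAIC of the fitted model.
    threshold_ : operative classification threshold.
    dropped_columns_ : design columns removed by the collinearity screen.
    """

    def __init__(
        self,
        detection_terms=records.DETECTION_TERMS,
        violation_terms=records.VIOLATION_TERMS,
        n_chains: int = 3,
        n_warmup: int = 600,
        n_samples: int = 2400,
        threshold: float = 0.5,
        tune_threshold: bool = False,
        grid_step: float = 0.01,
        collinearity_action: str = "drop",
        scheme: CategoryScheme | None = None,
        store_loglik: bool = True,
        random_state: int = 0,
    ):
        self.detection_terms = detection_terms
        self.violation_terms = violation_terms
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_samples = n_samples
        self.threshold = threshold
        self.tune_threshold = tune_threshold
        self.grid_step = grid_step
        self.collinearity_action = collinearity_action
        self.scheme = scheme
        self.store_loglik = store_loglik
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of patrol-record columns")
        missing = [c for c in records.REQUIRED_COLUMNS if c != "outcome" and c not in X.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        return X

    def fit(self, X: pd.DataFrame, y=None):
        X = self._validate_frame(X)
        if y is None:
            if "outcome" not in X.columns:
                raise ValueError("pass y or include an 'outcome' column")
            frame = X.copy()
        else:
            frame = X.copy()
            frame["outcome"] = np.asarray(y, dtype=int)
        if len(frame) == 0:
            raise ValueError("cannot fit on an empty dataset")

        self.scheme_ = self.scheme or CategoryScheme.from_frame(frame)
        design = build_design(
            frame, self.scheme_,
            detection_terms=self.detection_terms,
            violation_terms=self.violation_terms,
        )
        self.scaling_ = design.scaling

        cols = pd.DataFrame(
            np.column_stack([design.X_det, design.X_viol]) if design.X_det.size or design.X_viol.size
            else np.empty((len(frame), 0)),
            columns=design.det_names + design.viol_names,
        )
        self.dropped_columns_ = []
        if len(cols.columns):
            flagged = collinearity_screen(cols)
            if flagged:
                if self.collinearity_action == "error":
                    raise ValueError(f"collinear predictor pairs: {flagged}")
                msg = "; ".join(f"{a} ~ {b} (r={r:.2f})" for a, b, r in flagged)
                if self.collinearity_action == "drop":
                    order = list(cols.columns)
                    drop = {max(a, b, key=order.index) for a, b, _ in flagged}
                    self.dropped_columns_ = sorted(drop, key=order.index)
                    warnings.warn(f"collinearity screen dropped {self.dropped_columns_}: {msg}")
                    design = design.drop_columns(drop)
                else:
                    warnings.warn(f"collinear predictor pairs kept: {msg}")

        self.design_ = design
        cfg = SamplerConfig(
            n_chains=self.n_chains, n_warmup=self.n_warmup, n_samples=self.n_samples,
            seed=self.random_state, store_loglik=self.store_loglik,
        )
        self.draws_ = sampling.sample_posterior(design, cfg)
        self.rhat_report_ = sampling.compute_rhat(self.draws_)
        self.waic_ = (
            sampling.compute_waic(self.draws_.pointwise_loglik)
            if self.draws_.pointwise_loglik is not None else None
        )

        self.threshold_ = self.threshold
        if self.tune_threshold:
            probs = evaluation.posterior_predict(self.draws_, design)
            sweep = evaluation.threshold_sweep(probs, design.y, step=self.grid_step)
            if sweep.best_threshold is not None:
                self.threshold_ = sweep.best_threshold
            self.sweep_ = sweep
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(records.REQUIRED_COLUMNS) - 1
        return self

    # ------------------------------------------------------------------
    def _design_for(self, X: pd.DataFrame):
        X = self._validate_frame(X)
        frame = X.copy()
        if "outcome" not in frame.columns:
            frame["outcome"] = 0
        return build_design(
            frame, self.scheme_, scaling=self.scaling_,
            detection_terms=self.detection_terms,
            violation_terms=self.violation_terms,
        ).drop_columns(self.dropped_columns_)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        vp = evaluation.posterior_predict(self.draws_, self._design_for(X))
        return np.column_stack([1.0 - vp, vp])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return evaluation.classify(self.predict_proba(X)[:, 1], self.threshold_)

    # ------------------------------------------------------------------
    def evaluate(self, X: pd.DataFrame, y=None):
        """Confusion matrix and scores at the operative threshold."""
        self._check_fitted()
        if y is None:
            y = np.asarray(X["outcome"], dtype=int)
        return evaluation.confusion_and_scores(self.predict(X), y)

    def headline_summary(self):
        self._check_fitted()
        return reporting.headline_summary(self.draws_, self.design_)

    def summarize_factor(self, frame: pd.DataFrame, factor: str):
        self._check_fitted()
        return reporting.summarize_categories(self.draws_, frame, self.scheme_, factor)

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise RuntimeError("estimator is not fitted; call fit first")


def fit_detection_model(frame: pd.DataFrame, **kwargs) -> ConditionalDetectionClassifier:
    """Convenience wrapper: fit the classifier on a record frame that
    includes the outcome column."""
    return ConditionalDetectionClassifier(**kwargs).fit(frame)
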