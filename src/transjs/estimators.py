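"""Scikit-learn style estimator interface to the POPAN model families.

The estimators wrap :func:`transjs.inference.fit_mle`:

>>> est = TranslocationJollySeber(phi="constant", p="constant")
>>> est.fit(capture_data)                       # doctest: +SKIP
>>> est.abundance_, est.aic_                    # doctest: +SKIP

``fit`` accepts a :class:`~transjs.data.CaptureData` (or a
``(design, histories)`` pair) instead of a feature matrix — capture
histories are the sample unit of mark-recapture inference — but the
estimators follow the scikit-learn contract otherwise: constructor
arguments are stored verbatim, ``get_params``/``set_params``/``clone``
work, and every fitted attribute carries a trailing underscore.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .data import CaptureData, StudyDesign
from .inference import (
    FitOptions,
    ModelSpec,
    bootstrap_ci,
    fit_mle,
)


def _as_data(X, design):
    if isinstance(X, CaptureData):
        return X
    if design is not None:
        return CaptureData(design, list(X))
    if isinstance(X, tuple) and len(X) == 2 and isinstance(X[0], StudyDesign):
        return CaptureData(X[0], list(X[1]))
    raise TypeError(
        "fit expects a CaptureData, a (StudyDesign, histories) pair, or "
        "histories plus design=..."
    )


class JollySeberPopan(BaseEstimator):
    """Maximum-likelihood POPAN Jolly-Seber estimator.

    Parameters
    ----------
    model : {"translocation", "standard"}
        Likelihood family.  ``"translocation"`` conditions on the known
        released animals (certain detection at release, no entry before
        ``tau``); ``"standard"`` is the unconstrained POPAN model.
    n, phi, p : str or tuple of str
        Effect structure per parameter family (see
        :class:`~transjs.inference.ModelSpec`).
    phi_timescale : {"monthly", "interval"}
        Scale on which survival coefficients live; ``"monthly"`` raises
        the linked value to each interval's length in months.
    n_starts, maxiter, seed
        Multi-start optimizer settings.

    Attributes
    ----------
    result_ : FitResult
        Full fit record.
    params_ : dict of str -> ParameterSet
        Natural-scale parameters per group.
    coef_ : ndarray
        Link-scale coefficient vector at the optimum.
    loglik_, aic_, n_params_, converged_ : float, float, int, bool
    abundance_ : ndarray of shape (T,)
        Derived abundance trajectory (summed over groups).
    """

    def __init__(
        self,
        model: str = "translocation",
        n: str = "constant",
        phi="constant",
        p="constant",
        phi_timescale: str = "monthly",
        p_fixed: tuple = (),
        n_starts: int = 5,
        maxiter: int = 500,
        seed: int = 0,
    ):
        self.model = model
        self.n = n
        self.phi = phi
        self.p = p
        self.phi_timescale = phi_timescale
        self.p_fixed = p_fixed
        self.n_starts = n_starts
        self.maxiter = maxiter
        self.seed = seed

    def _spec(self) -> ModelSpec:
        phi = tuple(self.phi) if isinstance(self.phi, (list, tuple)) else self.phi
        p = tuple(self.p) if isinstance(self.p, (list, tuple)) else self.p
        return ModelSpec(
            n=self.n, phi=phi, p=p, p_fixed=tuple(self.p_fixed),
            phi_timescale=self.phi_timescale,
        )

    def _options(self) -> FitOptions:
        return FitOptions(
            n_starts=self.n_starts, maxiter=self.maxiter, seed=self.seed
        )

    def fit(self, X, y=None, design: StudyDesign | None = None):
        """Fit the model to capture histories.

        ``X`` is a :class:`CaptureData`, a ``(design, histories)`` pair,
        or a history sequence with ``design=`` given; ``y`` is ignored
        (scikit-learn signature compatibility).
        """
        data = _as_data(X, design)
        result = fit_mle(
            data.histories, data.design, self._spec(), self.model,
            self._options(),
        )
        self.data_ = data
        self.result_ = result
        self.coef_ = result.theta
        self.params_ = result.params
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.n_params_ = result.k
        self.abundance_ = result.abundance
        self.converged_ = result.converged
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise NotFittedError("call fit before using this estimator")

    def predict(self, X=None):
        """Derived abundance trajectory N_1..N_T of the fitted model."""
        self._check_fitted()
        return np.asarray(self.abundance_)

    def score(self, X=None, y=None):
        """Maximized log-likelihood (on the training data)."""
        self._check_fitted()
        return float(self.loglik_)

    def bootstrap(self, B: int = 999, seed: int = 0, level: float = 0.95):
        """Nonparametric bootstrap intervals for the fitted model."""
        self._check_fitted()
        return bootstrap_ci(
            self.data_.histories, self.data_.design, self._spec(),
            self.model, B=B, seed=seed, level=level, options=self._options(),
        )


class TranslocationJollySeber(JollySeberPopan):
    """POPAN model with a separate likelihood component for the known
    number of released individuals (entry and release detection known)."""

    def __init__(self, n="constant", phi="constant", p="constant",
                 phi_timescale="monthly", p_fixed=(), n_starts=5,
                 maxiter=500, seed=0):
        super().__init__(
            model="translocation", n=n, phi=phi, p=p,
            phi_timescale=phi_timescale, p_fixed=p_fixed,
            n_starts=n_starts, maxiter=maxiter, seed=seed,
        )


class StandardJollySeber(JollySeberPopan):
    """Unconstrained POPAN Jolly-Seber model (origin labels ignored)."""

    def __init__(self, n="constant", phi="constant", p="constant",
                 phi_timescale="monthly", p_fixed=(), n_starts=5,
                 maxiter=500, seed=0):
        super().__init__(
            model="standard", n=n, phi=phi, p=p,
            phi_timescale=phi_timescale, p_fixed=p_fixed,
            n_starts=n_starts, maxiter=maxiter, seed=seed,
        )
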