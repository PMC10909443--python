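"""Joint Jolly-Seber (POPAN) likelihoods with a translocation component.

The translocation model splits the observed animals into ``n0`` translocated
individuals — whose number and release occasion are known, and whose capture
probability at the release occasion is 1 — and wild-born recruits drawn from
a superpopulation of size ``N`` that enters the population from occasion
``tau`` onwards with per-occasion entry proportions ``beta``.  The joint
likelihood is

    L(N, phi, p, beta) ∝ N! / (N - D_w)!  ·  prod_i Pr(h*_i)
                         · prod_i Pr(h_i) · Pr(h_0)^(N - D_w),

where ``D_w`` is the number of *observed* wild individuals, ``Pr(h*_i)`` the
probability of a translocated history (entry known, release detection
certain), ``Pr(h_i)`` that of a wild history (summing over unknown entry and
death occasions), and ``Pr(h_0)`` the probability a wild superpopulation
member is never detected.

The standard, unconstrained POPAN likelihood — the comparison baseline — is
the same construction with every individual treated identically: entry
allowed from occasion 1, ``beta`` free over all occasions, and the
superpopulation including the translocated animals.

A history's probability sums over the latent entry occasion ``b`` and last
occasion alive ``d``:

    Pr(h) = sum_b sum_d  beta_b · prod_{j=b}^{d-1} phi_j · death(d)
                        · prod_{j=b}^{d} p_j^{x_j} (1 - p_j)^{1 - x_j},

with ``death(d) = 1 - phi_d`` for ``d < T`` and 1 for ``d = T`` (an animal
may outlive the study; this convention is what makes history probabilities
sum to one).  ``phi_j`` is the survival probability over interval ``j``,
already on the interval scale (uneven intervals are handled upstream by
raising a monthly survival to the interval length in months).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .data import (
    ORIGIN_TRANSLOCATED,
    ORIGIN_WILD,
    CaptureHistory,
    StudyDesign,
)

#: additive sentinel for log(0); optimizers recover from it instead of crashing
LOG_ZERO = -1e300

_BETA_TOL = 1e-10


class ContractError(ValueError):
    """A likelihood was called outside its mathematical preconditions."""


@dataclass
class ParameterSet:
    """Natural-scale POPAN parameters for one group.

    Attributes
    ----------
    n_super : float
        Superpopulation size N.  Wild-born individuals only under the
        translocation model; every individual under the standard model.
        Continuous (need not be integer): factorials are evaluated through
        log-gamma.
    phi : ndarray, shape (T-1,)
        Apparent survival probability over each inter-survey interval.
    p : ndarray, shape (T,)
        Capture probability per occasion.
    beta : ndarray, shape (T,)
        Entry proportions by entry occasion; zero before ``tau`` under the
        translocation model, summing to 1 over the free entry occasions.
    """

    n_super: float
    phi: np.ndarray
    p: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)

    @property
    def n_occasions(self) -> int:
        return self.p.size

    def validate(self, tau: int | None = None) -> None:
        T = self.n_occasions
        if self.phi.shape != (T - 1,) or self.beta.shape != (T,):
            raise ContractError("phi must have length T-1 and beta length T")
        if self.n_super < 0:
            raise ContractError("N must be nonnegative")
        for name, arr in (("phi", self.phi), ("p", self.p), ("beta", self.beta)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ContractError(f"{name} must lie in [0, 1]")
        if abs(self.beta.sum() - 1.0) > _BETA_TOL:
            raise ContractError("beta must sum to 1 over entry occasions")
        if tau is not None and np.any(self.beta[: tau - 1] != 0):
            raise ContractError(f"beta must be 0 before tau={tau}")


@dataclass(frozen=True)
class HistoryProbability:
    """A history probability carried on both natural and log scales."""

    value: float
    log_value: float

    @classmethod
    def from_value(cls, value: float) -> "HistoryProbability":
        return cls(value, float(np.log(value)) if value > 0 else LOG_ZERO)


def _history_prob_sum(
    x: np.ndarray,
    params: ParameterSet,
    b_min: int,
    use_beta: bool,
    release_detection: bool,
) -> float:
    """Direct double sum over entry and last-alive occasions (reference path)."""
    T = x.size
    ones = np.flatnonzero(x) + 1
    f = int(ones[0]) if ones.size else 1
    delta = int(ones[-1]) if ones.size else b_min
    phi, p, beta = params.phi, params.p, params.beta
    total = 0.0
    b_hi = f if ones.size else T
    for b in range(b_min, b_hi + 1):
        for d in range(max(delta, b), T + 1):
            w = beta[b - 1] if use_beta else 1.0
            for j in range(b, d):
                w *= phi[j - 1]
            if d < T:
                w *= 1.0 - phi[d - 1]
            for j in range(b, d + 1):
                if release_detection and j == 1:
                    continue  # p_1 = 1 at the release; x_1 = 1 contributes 1
                w *= p[j - 1] if x[j - 1] else 1.0 - p[j - 1]
            total += w
    return total


def prob_history_wild(
    history: CaptureHistory, params: ParameterSet, design: StudyDesign
) -> HistoryProbability:
    """Probability of a wild-born individual's capture history.

    Sums over entry occasions ``b`` in ``[tau, f_i]`` and last-alive
    occasions ``d`` in ``[delta_i, T]``.
    """
    if history.origin != ORIGIN_WILD:
        raise ContractError("history is not of wild origin")
    if history.first_capture < design.tau:
        raise ContractError(
            f"wild history first captured at {history.first_capture} "
            f"before tau={design.tau}"
        )
    value = _history_prob_sum(
        history.detections, params, design.tau, use_beta=True,
        release_detection=False,
    )
    return HistoryProbability.from_value(value)


def prob_history_translocated(
    history: CaptureHistory, params: ParameterSet, design: StudyDesign
) -> HistoryProbability:
    """Probability of a translocated individual's history.

    Entry is known to be the release occasion, so there is no ``beta``
    term; the release detection is certain (``p_1`` treated as 1).
    """
    if history.origin != ORIGIN_TRANSLOCATED:
        raise ContractError("history is not of translocated origin")
    if history.detections[0] != 1:
        raise ContractError("translocated history must be detected at release")
    T = history.detections.size
    phi, p = params.phi, params.p
    x = history.detections
    delta = history.last_capture
    total = 0.0
    for d in range(delta, T + 1):
        w = 1.0
        for j in range(1, d):
            w *= phi[j - 1]
        if d < T:
            w *= 1.0 - phi[d - 1]
        for j in range(2, d + 1):
            w *= p[j - 1] if x[j - 1] else 1.0 - p[j - 1]
        total += w
    return HistoryProbability.from_value(total)


def prob_never_seen(
    params: ParameterSet, design: StudyDesign, entry_min: int | None = None
) -> HistoryProbability:
    """Probability a wild superpopulation member is never detected."""
    b_min = design.tau if entry_min is None else entry_min
    x = np.zeros(design.n_occasions, dtype=np.int8)
    value = _history_prob_sum(
        x, params, b_min, use_beta=True, release_detection=False
    )
    return HistoryProbability.from_value(value)


# ---------------------------------------------------------------------------
# vectorized evaluator used for fitting


class PopanEvaluator:
    """Precompiled joint log-likelihood for one dataset and model family.

    Aggregates identical histories into frequency classes and precomputes
    the (entry, last-alive) pair grid and its per-history admissibility
    masks, so that one evaluation costs a handful of small dense array
    operations; detection products are formed as ratios of cumulative
    products, with an automatic log-space fallback when a capture
    probability sits exactly on {0, 1} or the products underflow.
    """

    def __init__(
        self,
        design: StudyDesign,
        histories: Sequence[CaptureHistory],
        model: str = "translocation",
    ):
        if model not in ("translocation", "standard"):
            raise ValueError(f"unknown model family {model!r}")
        self.model = model
        self.design = design
        T = design.n_occasions
        self.T = T
        X = np.array([h.detections for h in histories], dtype=np.int8)
        if X.size == 0:
            X = X.reshape(0, T)
        origin = np.array(
            [h.origin == ORIGIN_TRANSLOCATED for h in histories], dtype=bool
        )
        self.n_total_obs = len(histories)
        self.n0 = int(origin.sum())
        if model == "translocation":
            trans, wild = X[origin], X[~origin]
            self.b_min = design.tau
            self.n_open = self.n_total_obs - self.n0  # observed draws from N
        else:
            trans, wild = X[:0], X
            self.b_min = 1
            self.n_open = self.n_total_obs

        self.Xw, self.cw = _unique_rows(wild)
        self.Xt, self.ct = _unique_rows(trans)

        # (entry b, last-alive d) pair grid, 1-based, b <= d
        B, D = np.meshgrid(np.arange(1, T + 1), np.arange(1, T + 1), indexing="ij")
        keep = (B <= D) & (B >= self.b_min)
        self.pair_b = B[keep]
        self.pair_d = D[keep]

        fw, dw = _first_last(self.Xw)
        self.mask_w = (self.pair_b[None, :] <= fw[:, None]) & (
            self.pair_d[None, :] >= dw[:, None]
        )
        _, dt = _first_last(self.Xt)
        self.mask_t = np.arange(1, T + 1)[None, :] >= dt[:, None]

    # -- pieces -----------------------------------------------------------

    def _pair_weights(self, params: ParameterSet) -> np.ndarray:
        """beta_b * survival(b..d-1) * death(d) over the pair grid."""
        T = self.T
        phi = params.phi
        lphi = np.concatenate(([0.0], np.cumsum(np.log(np.maximum(phi, 1e-300)))))
        surv = np.exp(lphi[self.pair_d - 1] - lphi[self.pair_b - 1])
        death = np.ones_like(surv)
        interior = self.pair_d < T
        death[interior] = 1.0 - phi[self.pair_d[interior] - 1]
        return params.beta[self.pair_b - 1] * surv * death

    def _trans_weights(self, params: ParameterSet) -> np.ndarray:
        T = self.T
        phi = params.phi
        lphi = np.concatenate(([0.0], np.cumsum(np.log(np.maximum(phi, 1e-300)))))
        death = np.concatenate((1.0 - phi, [1.0]))
        return np.exp(lphi[:T]) * death

    def _detection_ratio(
        self, X: np.ndarray, p: np.ndarray, skip_first: bool
    ) -> np.ndarray | None:
        """prod_{j in (b, d]} p-term, via cumulative-product ratios.

        Returns None when the fast path is numerically unsafe (exact 0/1
        capture probabilities or underflow), signalling the caller to use
        the per-history reference sum instead.
        """
        terms = np.where(X == 1, p[None, :], 1.0 - p[None, :])
        if skip_first:
            terms = terms.copy()
            terms[:, 0] = 1.0
        if terms.size and terms.min() <= 0.0:
            return None
        Q = np.concatenate(
            (np.ones((X.shape[0], 1)), np.cumprod(terms, axis=1)), axis=1
        )
        if Q.size and Q[:, -1].min() < 1e-250:
            return None
        return Q

    # -- public -----------------------------------------------------------

    def history_probs(self, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities of the unique wild and translocated history classes."""
        pw = self._pair_weights(params)
        Q = self._detection_ratio(self.Xw, params.p, skip_first=False)
        if Q is None:
            prob_w = np.array(
                [
                    _history_prob_sum(
                        x, params, self.b_min, use_beta=True,
                        release_detection=False,
                    )
                    for x in self.Xw
                ]
            )
        else:
            R = Q[:, self.pair_d] / Q[:, self.pair_b - 1]
            prob_w = (R * self.mask_w) @ pw

        tw = self._trans_weights(params)
        Qt = self._detection_ratio(self.Xt, params.p, skip_first=True)
        if Qt is None:
            prob_t = np.array(
                [
                    _history_prob_sum(
                        x, params, 1, use_beta=False, release_detection=True
                    )
                    for x in self.Xt
                ]
            )
        else:
            prob_t = (Qt[:, 1:] * self.mask_t) @ tw
        return prob_w, prob_t

    def prob_never_seen(self, params: ParameterSet) -> float:
        miss = 1.0 - params.p
        if miss.min() <= 0.0 or np.cumprod(miss)[-1] < 1e-250:
            # a certain-detection occasion breaks the cumprod ratio; fall
            # back to the direct double sum (grid is tiny)
            return _history_prob_sum(
                np.zeros(self.T, dtype=np.int8), params, self.b_min,
                use_beta=True, release_detection=False,
            )
        pw = self._pair_weights(params)
        q = np.concatenate(([1.0], np.cumprod(miss)))
        return float(pw @ (q[self.pair_d] / q[self.pair_b - 1]))

    def loglik(self, params: ParameterSet) -> float:
        """Joint log-likelihood; LOG_ZERO-bounded instead of raising on 0s."""
        N = params.n_super
        if N < self.n_open - 1e-9:
            raise ContractError(
                f"N={N} smaller than the {self.n_open} observed individuals "
                "it must account for"
            )
        unseen = max(N - self.n_open, 0.0)
        prob_w, prob_t = self.history_probs(params)
        ll = 0.0
        for probs, counts in ((prob_w, self.cw), (prob_t, self.ct)):
            if probs.size:
                if probs.min() <= 0.0:
                    return LOG_ZERO
                ll += float(counts @ np.log(probs))
        ll += float(gammaln(N + 1.0) - gammaln(unseen + 1.0))
        if unseen > 0.0:
            p0 = self.prob_never_seen(params)
            if p0 <= 0.0:
                return LOG_ZERO
            ll += unseen * float(np.log(p0))
        return ll


def _unique_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if X.shape[0] == 0:
        return X, np.zeros(0, dtype=np.int64)
    uniq, counts = np.unique(X, axis=0, return_counts=True)
    return uniq, counts


def _first_last(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-based first and last detection occasions per row."""
    if X.shape[0] == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    first = np.argmax(X, axis=1) + 1
    last = X.shape[1] - np.argmax(X[:, ::-1], axis=1)
    return first, last


# ---------------------------------------------------------------------------
# module-level likelihoods


def log_likelihood_translocation(
    params: ParameterSet,
    design: StudyDesign,
    histories: Sequence[CaptureHistory],
) -> float:
    """Log of the joint translocation likelihood for one group.

    ``params.n_super`` is the wild-born superpopulation and must be at
    least the number of observed wild individuals.
    """
    params.validate(tau=design.tau)
    return PopanEvaluator(design, histories, model="translocation").loglik(params)


def log_likelihood_standard_popan(
    params: ParameterSet,
    design: StudyDesign,
    histories: Sequence[CaptureHistory],
) -> float:
    """Log-likelihood of the unconstrained POPAN model.

    Origin labels are ignored: every individual can enter from occasion 1
    and ``params.n_super`` counts the full superpopulation, translocated
    animals included.
    """
    params.validate()
    return PopanEvaluator(design, histories, model="standard").loglik(params)


def log_likelihood_groups(
    params_per_group: Mapping[str, ParameterSet],
    design: StudyDesign,
    histories: Sequence[CaptureHistory],
) -> float:
    """Group-structured translocation likelihood: product over groups.

    Each group contributes an independent translocation likelihood with its
    own parameters; the total superpopulation is the sum of the per-group
    ``n_super`` values.
    """
    total = 0.0
    labels = set(params_per_group)
    for h in histories:
        if h.group not in labels:
            raise ContractError(f"history {h.individual_id} has unknown group "
                                f"{h.group!r}")
    for g, params in params_per_group.items():
        sub = [h for h in histories if h.group == g]
        total += log_likelihood_translocation(params, design, sub)
        if total <= LOG_ZERO:
            return LOG_ZERO
    return total
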