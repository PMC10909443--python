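"""Model specification, link functions, maximum-likelihood fitting,
derived abundance, bootstrap confidence intervals and AIC selection.

Parameters are estimated on an unconstrained link scale: log for the
superpopulation N (shifted so that N always exceeds the number of observed
individuals it must account for), logit for survival ``phi`` and capture
``p``, and a multinomial logit over the free entry occasions for ``beta``
(reference category: the last free occasion).  Survival is parameterized
per month by default and raised to each interval's length in months, which
is how uneven survey spacing enters the likelihood.

Fixed constraints — ``p = 1`` at the release occasion and ``beta = 0``
before the first possible entry occasion under the translocation model —
are applied structurally and never consume a coefficient, so the AIC
parameter count ``k`` covers free coefficients only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import (
    ORIGIN_TRANSLOCATED,
    ORIGIN_WILD,
    CaptureHistory,
    StudyDesign,
)
from .likelihood import LOG_ZERO, ContractError, ParameterSet, PopanEvaluator

_N_SHIFT_EPS = 1e-8
_POOLED = "_all"


@dataclass(frozen=True)
class ModelSpec:
    """Which effects each parameter family carries.

    ``phi`` and ``p`` accept ``"constant"``, ``"time"``, ``"group"`` or a
    tuple of occasion-covariate names (logit-linear with intercept);
    ``n`` is ``"constant"`` (single superpopulation) or ``"group"``
    (one N per group, totals summed); ``beta`` is always time dependent.
    ``p_fixed`` pins capture probabilities at given occasions (1-based);
    the translocation family adds ``p_1 = 1`` automatically.
    """

    n: str = "constant"
    phi: str | tuple[str, ...] = "constant"
    p: str | tuple[str, ...] = "constant"
    beta: str = "time"
    p_fixed: tuple[tuple[int, float], ...] = ()
    phi_timescale: str = "monthly"
    name: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.phi, list):
            object.__setattr__(self, "phi", tuple(self.phi))
        if isinstance(self.p, list):
            object.__setattr__(self, "p", tuple(self.p))
        if self.beta != "time":
            raise ValueError("beta is always time dependent in POPAN models")
        if self.phi_timescale not in ("monthly", "interval"):
            raise ValueError("phi_timescale must be 'monthly' or 'interval'")

    @property
    def label(self) -> str:
        if self.name:
            return self.name

        def fam(v):
            return "+".join(v) if isinstance(v, tuple) else v

        return f"N~{self.n}, phi~{fam(self.phi)}, p~{fam(self.p)}, beta~time"


def parse_spec(config: Mapping[str, str], **kwargs) -> ModelSpec:
    """Build a :class:`ModelSpec` from formula strings.

    ``{"phi": "~time", "p": "~effort + airtemp + moon_sin"}`` gives a
    time-dependent survival and a covariate model for capture; ``~1``
    means constant.  Unlisted families default to constant.
    """

    def term(text: str):
        rhs = text.strip().lstrip("~").strip()
        if rhs in ("1", "constant", ""):
            return "constant"
        if rhs in ("time", "group"):
            return rhs
        return tuple(t.strip() for t in rhs.split("+"))

    fields = {}
    for key in ("n", "phi", "p"):
        if key in config:
            value = term(config[key])
            if key == "n" and value not in ("constant", "group"):
                raise ValueError("N supports only ~1 or ~group")
            fields[key] = value
    return ModelSpec(**fields, **kwargs)


# ---------------------------------------------------------------------------
# coefficient-to-parameter mapping


class ParameterMap:
    """Layout of the link-scale coefficient vector for one model fit."""

    def __init__(self, spec: ModelSpec, design: StudyDesign, model: str):
        if model not in ("translocation", "standard"):
            raise ValueError(f"unknown model family {model!r}")
        self.spec = spec
        self.design = design
        self.model = model
        self.group_mode = spec.n == "group"
        if self.group_mode and not design.groups:
            raise ValueError("spec requests group effects but the design "
                             "defines no groups")
        self.groups: tuple[str, ...] = (
            design.groups if self.group_mode else (_POOLED,)
        )
        T = design.n_occasions
        self.tau_eff = design.tau if model == "translocation" else 1
        self.free_entry = tuple(range(self.tau_eff, T + 1))

        p_fixed = dict(spec.p_fixed)
        if model == "translocation":
            p_fixed.setdefault(1, 1.0)
        self.p_fixed = p_fixed

        self._slices: dict[str, slice] = {}
        start = 0
        start += self._alloc("n", len(self.groups), start)
        start += self._alloc("phi", self._family_size(spec.phi, T - 1), start)
        n_free_p = (
            sum(1 for j in range(1, T + 1) if j not in p_fixed)
            if spec.p == "time"
            else self._family_size(spec.p, T)
        )
        start += self._alloc("p", n_free_p, start)
        start += self._alloc("beta", len(self.free_entry) - 1, start)
        self.k = start

    def _alloc(self, name: str, size: int, start: int) -> int:
        self._slices[name] = slice(start, start + size)
        return size

    def _family_size(self, kind, n_rows: int) -> int:
        if kind == "constant":
            return 1
        if kind == "time":
            return n_rows
        if kind == "group":
            return len(self.groups)
        return 1 + len(kind)  # intercept + covariates

    def _family_values(self, kind, theta_block, n_rows: int, group_idx: int,
                       covariate_rows) -> np.ndarray:
        """Link-scale values for one family in one group."""
        if kind == "constant":
            return np.full(n_rows, theta_block[0])
        if kind == "time":
            return np.asarray(theta_block, dtype=float)
        if kind == "group":
            eta = theta_block[0]
            if group_idx > 0:
                eta = eta + theta_block[group_idx]
            return np.full(n_rows, eta)
        Z = np.column_stack(
            [np.ones(n_rows)] + [covariate_rows(c) for c in kind]
        )
        return Z @ np.asarray(theta_block, dtype=float)

    def expand(
        self, theta: np.ndarray, n_lower: Mapping[str, float] | None = None
    ) -> dict[str, ParameterSet]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(f"theta has length {theta.size}, expected {self.k}")
        design, spec = self.design, self.spec
        T = design.n_occasions
        months = design.interval_months
        if n_lower is None:
            n_lower = {}
        out: dict[str, ParameterSet] = {}

        def phi_cov(c):
            return design.covariate(c)[: T - 1]

        def p_cov(c):
            return design.covariate(c)

        for gi, g in enumerate(self.groups):
            # N: log link shifted by the observed-count floor
            n_super = n_lower.get(g, 0.0) + np.exp(theta[self._slices["n"]][gi if
                self.group_mode else 0])

            eta_phi = self._family_values(
                spec.phi, theta[self._slices["phi"]], T - 1, gi, phi_cov
            )
            phi_unit = expit(eta_phi)
            phi = (
                phi_unit ** months if spec.phi_timescale == "monthly" else phi_unit
            )

            block = theta[self._slices["p"]]
            if spec.p == "time":
                p = np.empty(T)
                it = iter(block)
                for j in range(1, T + 1):
                    p[j - 1] = (
                        self.p_fixed[j] if j in self.p_fixed else expit(next(it))
                    )
            else:
                p = expit(
                    self._family_values(spec.p, block, T, gi, p_cov)
                )
                for j, v in self.p_fixed.items():
                    p[j - 1] = v

            eta_b = np.concatenate([theta[self._slices["beta"]], [0.0]])
            eta_b = eta_b - eta_b.max()
            w = np.exp(eta_b)
            beta = np.zeros(T)
            beta[np.array(self.free_entry) - 1] = w / w.sum()

            out[g] = ParameterSet(n_super=float(n_super), phi=phi, p=p, beta=beta)
        return out


def expand_parameters(
    theta: np.ndarray,
    spec: ModelSpec,
    design: StudyDesign,
    model: str = "translocation",
    n_lower: Mapping[str, float] | None = None,
) -> dict[str, ParameterSet]:
    """Map a link-scale coefficient vector to natural-scale parameters.

    Returns one :class:`ParameterSet` per group (key ``"_all"`` when the
    spec has no group structure).  With ``n_lower`` omitted the N link is
    a plain log link.
    """
    return ParameterMap(spec, design, model).expand(theta, n_lower)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    n_starts: int = 5
    seed: int = 0
    maxiter: int = 500
    perturb_scale: float = 0.5
    method: str = "L-BFGS-B"


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: str
    spec: ModelSpec
    theta: np.ndarray
    params: dict[str, ParameterSet]
    loglik: float
    k: int
    aic: float
    abundance: np.ndarray
    abundance_by_group: dict[str, np.ndarray]
    converged: bool
    boundary: bool
    n_failed_starts: int
    message: str = ""

    @property
    def n_super_total(self) -> float:
        return float(sum(ps.n_super for ps in self.params.values()))


def _group_data(
    pmap: ParameterMap, histories: Sequence[CaptureHistory]
) -> dict[str, list[CaptureHistory]]:
    if not pmap.group_mode:
        return {_POOLED: list(histories)}
    out: dict[str, list[CaptureHistory]] = {g: [] for g in pmap.groups}
    for h in histories:
        if h.group not in out:
            raise ContractError(
                f"history {h.individual_id} has group {h.group!r} not in "
                f"design groups {pmap.groups}"
            )
        out[h.group].append(h)
    return out


def _initial_theta(pmap: ParameterMap, by_group, n_lower) -> np.ndarray:
    theta = np.zeros(pmap.k)
    T = pmap.design.n_occasions
    D = sum(len(v) for v in by_group.values())
    det_total = sum(h.n_detections for v in by_group.values() for h in v)
    p0 = np.clip(det_total / max(D * T, 1), 0.05, 0.8)
    theta[pmap._slices["p"]] = logit(p0)
    phi0 = 0.97 if pmap.spec.phi_timescale == "monthly" else 0.8
    theta[pmap._slices["phi"]] = logit(phi0)
    n_block = pmap._slices["n"]
    for gi, g in enumerate(pmap.groups):
        lower = n_lower.get(g, 0.0)
        theta[n_block][gi] = np.log(0.5 * lower + 10.0)
    return theta


def fit_mle(
    histories: Sequence[CaptureHistory],
    design: StudyDesign,
    spec: ModelSpec,
    model: str = "translocation",
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the joint log-likelihood by multi-start quasi-Newton search.

    The best local optimum over ``options.n_starts`` perturbed starting
    points is returned; a fit that converges nowhere is flagged
    (``converged=False``), never silently reported as an answer.
    """
    opts = options or FitOptions()
    pmap = ParameterMap(spec, design, model)
    by_group = _group_data(pmap, histories)
    evaluators = {
        g: PopanEvaluator(design, v, model=model) for g, v in by_group.items()
    }
    if model == "translocation":
        n_lower = {
            g: sum(h.origin == ORIGIN_WILD for h in v) + _N_SHIFT_EPS
            for g, v in by_group.items()
        }
    else:
        n_lower = {g: len(v) + _N_SHIFT_EPS for g, v in by_group.items()}

    def objective(theta: np.ndarray) -> float:
        params = pmap.expand(theta, n_lower)
        ll = 0.0
        for g, ev in evaluators.items():
            ll += ev.loglik(params[g])
            if ll <= LOG_ZERO:
                break
        if not np.isfinite(ll) or ll <= LOG_ZERO:
            return 1e12
        return min(-ll, 1e12)

    rng = np.random.default_rng(opts.seed)
    theta0 = _initial_theta(pmap, by_group, n_lower)
    best = None
    n_failed = 0
    for s in range(max(opts.n_starts, 1)):
        start = theta0 if s == 0 else theta0 + rng.normal(
            0.0, opts.perturb_scale, size=pmap.k
        )
        try:
            res = minimize(
                objective, start, method=opts.method,
                options={"maxiter": opts.maxiter},
            )
        except Exception:
            n_failed += 1
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            n_failed += 1
            continue
        if not res.success:
            n_failed += 1
        if best is None or res.fun < best.fun:
            best = res

    if best is None:
        return FitResult(
            model=model, spec=spec, theta=theta0,
            params=pmap.expand(theta0, n_lower), loglik=-np.inf, k=pmap.k,
            aic=np.inf, abundance=np.full(design.n_occasions, np.nan),
            abundance_by_group={}, converged=False, boundary=False,
            n_failed_starts=n_failed, message="all starts failed",
        )

    theta_hat = best.x
    params = pmap.expand(theta_hat, n_lower)
    loglik = -float(best.fun)
    aic = 2 * pmap.k - 2 * loglik
    boundary = False
    abundance_by_group = {}
    for g, ps in params.items():
        n0_g = sum(h.origin == ORIGIN_TRANSLOCATED for h in by_group[g])
        abundance_by_group[g] = derive_abundance(ps, design, model, n0=n0_g)
        free_p = [j for j in range(1, design.n_occasions + 1)
                  if j not in pmap.p_fixed]
        probs = np.concatenate([ps.phi, ps.p[np.array(free_p) - 1]])
        if probs.size and (probs.min() < 1e-4 or probs.max() > 1 - 1e-4):
            boundary = True
        if ps.n_super - n_lower[g] < 1e-3:
            boundary = True
    abundance = np.sum(list(abundance_by_group.values()), axis=0)
    converged = n_failed < max(opts.n_starts, 1)
    return FitResult(
        model=model, spec=spec, theta=theta_hat, params=params,
        loglik=loglik, k=pmap.k, aic=aic, abundance=abundance,
        abundance_by_group=abundance_by_group, converged=converged,
        boundary=boundary, n_failed_starts=n_failed,
        message=str(getattr(best, "message", "")),
    )


def derive_abundance(
    params: ParameterSet,
    design: StudyDesign,
    model: str = "translocation",
    n0: int | float = 0,
) -> np.ndarray:
    """Abundance trajectory by the entry/survival recursion.

    ``N_1 = n0`` (translocation) or ``N_hat * beta_1`` (standard);
    ``N_{t+1} = N_t * phi_t + N_hat * beta_{t+1}`` with ``phi_t`` the
    interval-scale survival.
    """
    T = design.n_occasions
    nt = np.empty(T)
    nt[0] = float(n0) if model == "translocation" else params.n_super * params.beta[0]
    for t in range(1, T):
        nt[t] = nt[t - 1] * params.phi[t - 1] + params.n_super * params.beta[t]
    return nt


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    level: float
    intervals: dict[str, tuple[float, float]]
    abundance_low: np.ndarray
    abundance_high: np.ndarray
    replicates: pd.DataFrame
    n_failed: int


def _flatten_fit(fit: FitResult) -> dict[str, float]:
    row: dict[str, float] = {"n_super_total": fit.n_super_total}
    for g, ps in fit.params.items():
        tag = "" if g == _POOLED else f"{g}:"
        row[f"{tag}N"] = ps.n_super
        for t, v in enumerate(ps.phi, start=1):
            row[f"{tag}phi[{t}]"] = v
        for j, v in enumerate(ps.p, start=1):
            row[f"{tag}p[{j}]"] = v
        for j, v in enumerate(ps.beta, start=1):
            row[f"{tag}beta[{j}]"] = v
    for t, v in enumerate(fit.abundance, start=1):
        row[f"Nt[{t}]"] = v
    return row


def bootstrap_ci(
    histories: Sequence[CaptureHistory],
    design: StudyDesign,
    spec: ModelSpec,
    model: str = "translocation",
    B: int = 999,
    seed: int = 0,
    level: float = 0.95,
    options: FitOptions | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap percentile intervals.

    Individuals are resampled with replacement, stratified by origin so
    every resample keeps exactly ``n0`` translocated and ``D - n0`` wild
    individuals; each resample is refitted starting from the base fit's
    coefficients.  More than 20% refit failures aborts with diagnostics.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    base_opts = options or FitOptions()
    base = fit_mle(histories, design, spec, model, base_opts)
    if not base.converged:
        raise RuntimeError("base fit did not converge; cannot bootstrap")
    rng = np.random.default_rng(seed)
    trans = [h for h in histories if h.origin == ORIGIN_TRANSLOCATED]
    wild = [h for h in histories if h.origin == ORIGIN_WILD]
    refit_opts = dataclasses.replace(base_opts, n_starts=1)
    rows = []
    n_failed = 0
    for b in range(B):
        sample: list[CaptureHistory] = []
        for pool in (trans, wild):
            if pool:
                idx = rng.integers(0, len(pool), size=len(pool))
                sample.extend(pool[i] for i in idx)
        refit_opts = dataclasses.replace(
            refit_opts, seed=int(rng.integers(0, 2**31 - 1))
        )
        fit = _refit_from(sample, design, spec, model, refit_opts, base.theta)
        if fit is None or not np.isfinite(fit.loglik):
            n_failed += 1
            continue
        rows.append(_flatten_fit(fit))
    if n_failed > 0.2 * B:
        raise RuntimeError(
            f"bootstrap unreliable: {n_failed}/{B} refits failed"
        )
    reps = pd.DataFrame(rows)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    intervals = {
        c: (float(reps[c].quantile(lo_q)), float(reps[c].quantile(hi_q)))
        for c in reps.columns
    }
    T = design.n_occasions
    ab_lo = np.array([intervals[f"Nt[{t}]"][0] for t in range(1, T + 1)])
    ab_hi = np.array([intervals[f"Nt[{t}]"][1] for t in range(1, T + 1)])
    return BootstrapResult(
        level=level, intervals=intervals, abundance_low=ab_lo,
        abundance_high=ab_hi, replicates=reps, n_failed=n_failed,
    )


def _refit_from(histories, design, spec, model, opts, theta_start):
    """Single-start refit warm-started at ``theta_start``."""
    pmap = ParameterMap(spec, design, model)
    by_group = _group_data(pmap, histories)
    evaluators = {
        g: PopanEvaluator(design, v, model=model) for g, v in by_group.items()
    }
    if model == "translocation":
        n_lower = {
            g: sum(h.origin == ORIGIN_WILD for h in v) + _N_SHIFT_EPS
            for g, v in by_group.items()
        }
    else:
        n_lower = {g: len(v) + _N_SHIFT_EPS for g, v in by_group.items()}

    def objective(theta):
        params = pmap.expand(theta, n_lower)
        ll = sum(ev.loglik(params[g]) for g, ev in evaluators.items())
        if not np.isfinite(ll) or ll <= LOG_ZERO:
            return 1e12
        return min(-ll, 1e12)

    try:
        res = minimize(
            objective, theta_start, method=opts.method,
            options={"maxiter": opts.maxiter},
        )
    except Exception:
        return None
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        return None
    params = pmap.expand(res.x, n_lower)
    abundance_by_group = {}
    for g, ps in params.items():
        n0_g = sum(h.origin == ORIGIN_TRANSLOCATED for h in by_group[g])
        abundance_by_group[g] = derive_abundance(ps, design, model, n0=n0_g)
    return FitResult(
        model=model, spec=spec, theta=res.x, params=params,
        loglik=-float(res.fun), k=pmap.k, aic=2 * pmap.k + 2 * float(res.fun),
        abundance=np.sum(list(abundance_by_group.values()), axis=0),
        abundance_by_group=abundance_by_group, converged=bool(res.success),
        boundary=False, n_failed_starts=0,
    )


# ---------------------------------------------------------------------------
# model selection


def aic_select(
    candidates: Sequence[ModelSpec],
    histories: Sequence[CaptureHistory],
    design: StudyDesign,
    model: str = "translocation",
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit every candidate spec and rank by AIC.

    Failed fits appear as flagged rows (``converged=False``, infinite
    AIC) rather than raising.  Ties break toward smaller ``k``, then
    registration order.
    """
    if not candidates:
        raise ValueError("need at least one candidate spec")
    rows = []
    fits = []
    for order, spec in enumerate(candidates):
        fit = fit_mle(histories, design, spec, model, options)
        fits.append(fit)
        rows.append(
            {
                "spec": spec.label,
                "k": fit.k,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "converged": fit.converged,
                "_order": order,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["aic", "k", "_order"], kind="stable"
    ).reset_index(drop=True)
    best = table.loc[table["converged"], "aic"].min()
    table["delta_aic"] = table["aic"] - best
    table.attrs["fits"] = fits
    return table.drop(columns="_order")
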