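"""Simulation of translocated-population capture histories.

Twelve scenarios cross the number of released animals (15 or 30), the
total superpopulation (500 or 2000, released animals included) and the
capture-probability regime (low 0.1-0.3, mid 0.4-0.6, high 0.7-0.9).
Every scenario runs over 10 survey occasions spaced 6 months apart;
occasion 1 is the release, at which detection is certain.  Wild-born
recruits cannot appear before occasion 4: the entry proportion for
occasion 1 equals the released fraction N1/N, occasions 2-3 carry zero
entry mass, and occasions 4-10 receive uniform draws on (0.1, 0.2)
rescaled to make the full entry vector sum to one.

Survival is drawn per interval as a *monthly* probability on
(0.94, 0.99) and raised to the interval length (6 months); capture
probabilities are drawn per occasion from the scenario's regime.  Draws
are shared by all individuals (between-survey stochasticity, no
individual heterogeneity).  Presence histories assign each
superpopulation member an entry occasion (categorical over the entry
proportions) and a death process (per-interval Bernoulli survival);
capture histories then sample detection at each alive occasion, and
individuals never detected are dropped from the observed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ORIGIN_TRANSLOCATED,
    ORIGIN_WILD,
    CaptureData,
    CaptureHistory,
    StudyDesign,
)
from .likelihood import ParameterSet

#: scenario id -> (released N1, total superpopulation N, capture regime)
TABLE1: dict[int, tuple[int, int, tuple[float, float]]] = {
    1: (15, 500, (0.1, 0.3)),
    2: (15, 500, (0.4, 0.6)),
    3: (15, 500, (0.7, 0.9)),
    4: (30, 500, (0.1, 0.3)),
    5: (30, 500, (0.4, 0.6)),
    6: (30, 500, (0.7, 0.9)),
    7: (15, 2000, (0.1, 0.3)),
    8: (15, 2000, (0.4, 0.6)),
    9: (15, 2000, (0.7, 0.9)),
    10: (30, 2000, (0.1, 0.3)),
    11: (30, 2000, (0.4, 0.6)),
    12: (30, 2000, (0.7, 0.9)),
}

LOW_P_SCENARIOS = (1, 4, 7, 10)
MID_P_SCENARIOS = (2, 5, 8, 11)
HIGH_P_SCENARIOS = (3, 6, 9, 12)


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: design constants plus parameter ranges."""

    scenario_id: int
    n1: int
    n_total: int
    p_range: tuple[float, float]
    beta_range: tuple[float, float] = (0.1, 0.2)
    phi_range: tuple[float, float] = (0.94, 0.99)
    n_occasions: int = 10
    interval_months: float = 6.0
    tau: int = 4
    replicates: int = 250
    phi_scale: str = "monthly"  # "monthly" | "interval" | "annual"

    def design(self) -> StudyDesign:
        times = np.arange(self.n_occasions) * self.interval_months
        return StudyDesign(
            n_occasions=self.n_occasions, occasion_times=times, tau=self.tau
        )


def scenario(scenario_id: int, **overrides) -> ScenarioSpec:
    """The scenario with the given id (1-12)."""
    try:
        n1, n_total, p_range = TABLE1[scenario_id]
    except KeyError:
        raise ValueError(f"scenario_id must be 1..12, got {scenario_id}")
    return ScenarioSpec(
        scenario_id=scenario_id, n1=n1, n_total=n_total, p_range=p_range,
        **overrides,
    )


def all_scenarios(**overrides) -> list[ScenarioSpec]:
    return [scenario(s, **overrides) for s in TABLE1]


def replicate_seed(base_seed: int, scenario_id: int, replicate: int) -> int:
    """Deterministic per-replicate seed; independent across the study grid."""
    return int(base_seed + 1000 * scenario_id + replicate) % (2**31 - 1)


@dataclass
class TruthRecord:
    """Realized truth for one simulated replicate."""

    params: ParameterSet          # interval-scale phi, per-occasion p, beta
    phi_unit: np.ndarray          # survival on the drawn (monthly) scale
    entry: np.ndarray             # entry occasion per superpopulation member
    last_alive: np.ndarray        # last occasion alive per member
    true_n: np.ndarray            # individuals alive per occasion

    @property
    def wild_beta(self) -> np.ndarray:
        """Entry proportions renormalized over the wild-born superpopulation."""
        b = self.params.beta.copy()
        wild_mass = 1.0 - b[0]
        b[0] = 0.0
        return b / wild_mass


def draw_scenario_parameters(
    spec: ScenarioSpec, rng: np.random.Generator
) -> tuple[ParameterSet, np.ndarray]:
    """Draw one replicate's true parameters.

    Returns the interval-scale :class:`ParameterSet` (``p_1 = 1``;
    ``beta_1 = N1/N``; zero entry at occasions 2..tau-1) together with the
    survival values on their drawn scale.
    """
    T = spec.n_occasions
    p = np.empty(T)
    p[0] = 1.0
    p[1:] = rng.uniform(*spec.p_range, size=T - 1)
    phi_unit = rng.uniform(*spec.phi_range, size=T - 1)
    if spec.phi_scale == "monthly":
        phi = phi_unit ** spec.interval_months
    elif spec.phi_scale == "annual":
        phi = phi_unit ** (spec.interval_months / 12.0)
    else:
        phi = phi_unit.copy()
    beta = np.zeros(T)
    beta[0] = spec.n1 / spec.n_total
    raw = rng.uniform(*spec.beta_range, size=T - spec.tau + 1)
    beta[spec.tau - 1:] = raw / raw.sum() * (1.0 - beta[0])
    params = ParameterSet(
        n_super=float(spec.n_total), phi=phi, p=p, beta=beta
    )
    return params, phi_unit


def simulate_presence(
    params: ParameterSet, spec: ScenarioSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Entry occasion, last-alive occasion and true abundance per occasion.

    Each of the N superpopulation members draws an entry occasion from the
    entry proportions, then survives each subsequent interval with the
    interval survival probability.
    """
    T = spec.n_occasions
    N = spec.n_total
    entry = rng.choice(np.arange(1, T + 1), size=N, p=params.beta)
    last = entry.copy()
    alive = np.ones(N, dtype=bool)
    for t in range(1, T):
        at_risk = alive & (entry <= t)
        survives = rng.random(N) < params.phi[t - 1]
        died = at_risk & ~survives
        alive[died] = False
        last[alive & (entry <= t + 1)] = np.maximum(
            last[alive & (entry <= t + 1)], t + 1
        )
    true_n = np.array(
        [(entry <= t) & (last >= t) for t in range(1, T + 1)]
    ).sum(axis=1)
    return entry, last, true_n


def simulate_captures(
    entry: np.ndarray,
    last: np.ndarray,
    params: ParameterSet,
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> CaptureData:
    """Sample detections for every alive occasion and build observed data.

    Occasion-1 entrants are the translocated animals (detected with
    certainty at release); later entrants are wild-born.  Individuals with
    all-zero histories are dropped from the observed set.
    """
    T = spec.n_occasions
    N = entry.size
    occ = np.arange(1, T + 1)
    alive = (entry[:, None] <= occ[None, :]) & (last[:, None] >= occ[None, :])
    det = (rng.random((N, T)) < params.p[None, :]) & alive
    det[:, 0] = alive[:, 0]  # release detection certain
    seen = det.any(axis=1)
    histories = []
    for i in np.flatnonzero(seen):
        origin = ORIGIN_TRANSLOCATED if entry[i] == 1 else ORIGIN_WILD
        histories.append(
            CaptureHistory(f"sim{i:05d}", origin, det[i].astype(np.int8))
        )
    return CaptureData(spec.design(), histories)


def simulate_dataset(
    spec: ScenarioSpec, seed_or_rng: int | np.random.Generator
) -> tuple[CaptureData, TruthRecord]:
    """One full replicate: parameter draw, presence and capture histories."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    params, phi_unit = draw_scenario_parameters(spec, rng)
    entry, last, true_n = simulate_presence(params, spec, rng)
    data = simulate_captures(entry, last, params, spec, rng)
    truth = TruthRecord(
        params=params, phi_unit=phi_unit, entry=entry, last_alive=last,
        true_n=true_n,
    )
    return data, truth


def truth_frame(truth: TruthRecord) -> pd.DataFrame:
    """Per-occasion truth sidecar table (written next to simulated data)."""
    T = truth.params.p.size
    return pd.DataFrame(
        {
            "occasion": np.arange(1, T + 1),
            "true_n": truth.true_n,
            "beta": truth.params.beta,
            "p": truth.params.p,
            "phi_interval": np.append(truth.params.phi, np.nan),
            "phi_drawn": np.append(truth.phi_unit, np.nan),
        }
    )
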