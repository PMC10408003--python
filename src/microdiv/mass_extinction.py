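"""Mass-extinction-perturbed diversification model.

Six dated events perturb the exponential birth-death expectation: the
Great Oxidation Event (~2450 Mya, the only event striking free-living
microbes directly) and the "Big Five" macroorganismal extinctions,
modeled as host-associated.  Each event is an instantaneous one-time
reduction: a fraction ``p`` (intensity) of the vulnerable fraction
``q`` of taxa is removed, so the surviving proportion per event is
``1 - p * q_eff`` with ``q_eff = q`` at host-associated events and 1 at
the GOE.  Present-day richness at the default schedule is therefore

    S_4000 = exp((lambda - mu) * 4000) * (1 - p) * (1 - p q)^5.

Events are placed at integer-My model times (``t_origin - age``); the
model acknowledges that real extinction pulses spanned longer intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import LN10, Contour, DiversificationParams, RichnessValue

__all__ = [
    "ExtinctionEvent",
    "ExtinctionSchedule",
    "DiversityTrajectory",
    "CladeScenario",
    "DEFAULT_EVENTS",
    "default_schedule",
    "load_schedule",
    "survival_factor",
    "richness_with_extinction",
    "trajectory",
    "epsilon_contour_me",
    "MassExtinctionModel",
    "clade_vulnerability_scenario",
]


@dataclass(frozen=True)
class ExtinctionEvent:
    """A single dated mass-extinction event.

    ``age_mya`` is measured back from the present; ``host_associated``
    marks membership in the host-extinction set (vulnerable fraction q
    applies there; everywhere else all taxa are exposed).  Per-event
    ``p``/``q`` overrides support sensitivity analysis; ``None`` defers
    to the schedule-wide scalars.
    """

    name: str
    age_mya: float
    host_associated: bool
    p_override: float | None = None
    q_override: float | None = None

    def __post_init__(self) -> None:
        if not self.age_mya >= 0:
            raise ValueError(f"age_mya must be non-negative, got {self.age_mya}")
        for label, v in (("p_override", self.p_override), ("q_override", self.q_override)):
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{label} must lie in [0, 1], got {v}")


# GOE ~2450 Mya plus the Big Five (O-S, Devonian, P-Tr, Tr-J, K-T).
DEFAULT_EVENTS: tuple[ExtinctionEvent, ...] = (
    ExtinctionEvent("GOE", 2450.0, host_associated=False),
    ExtinctionEvent("O-S", 445.0, host_associated=True),
    ExtinctionEvent("D", 375.0, host_associated=True),
    ExtinctionEvent("P-Tr", 252.0, host_associated=True),
    ExtinctionEvent("Tr-J", 201.0, host_associated=True),
    ExtinctionEvent("K-T", 66.0, host_associated=True),
)


@dataclass(frozen=True)
class ExtinctionSchedule:
    """An ordered set of extinction events with global intensity scalars.

    ``p`` is the fraction of vulnerable taxa removed per event; ``q`` the
    fraction of all taxa vulnerable at host-associated events.  The
    removal fraction at an event is thus ``p*q`` (host-associated) or
    ``p`` (non-host).  ``t_origin`` anchors model time: an event at age
    A Mya occurs at model time ``round(t_origin - A)``.
    """

    events: tuple[ExtinctionEvent, ...] = DEFAULT_EVENTS
    p: float = 0.0
    q: float = 1.0
    t_origin: float = 4000.0

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not 0 <= self.q <= 1:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not self.t_origin > 0:
            raise ValueError(f"t_origin must be positive, got {self.t_origin}")
        for ev in self.events:
            if ev.age_mya > self.t_origin:
                raise ValueError(
                    f"event {ev.name!r} at {ev.age_mya} Mya predates origin {self.t_origin}"
                )
        times = [self.model_time(ev) for ev in self.events]
        if times != sorted(times):
            raise ValueError("events must be ordered oldest-first (increasing model time)")

    def model_time(self, event: ExtinctionEvent) -> float:
        """Integer model timestep (My since origin) of an event."""
        return float(round(self.t_origin - event.age_mya))

    def event_survival(self, event: ExtinctionEvent) -> float:
        """Proportion of all taxa surviving one event, 1 - p * q_eff."""
        p = self.p if event.p_override is None else event.p_override
        if event.host_associated:
            q_eff = self.q if event.q_override is None else event.q_override
        else:
            q_eff = 1.0
        surv = 1.0 - p * q_eff
        if surv <= 0.0:
            raise ValueError(
                f"event {event.name!r} removes every taxon (p*q = 1); "
                "richness is undefined after total annihilation"
            )
        return surv


def default_schedule(p: float = 0.0, q: float = 1.0, t_origin: float = 4000.0) -> ExtinctionSchedule:
    """The GOE + Big Five schedule with given intensity scalars."""
    return ExtinctionSchedule(DEFAULT_EVENTS, p=p, q=q, t_origin=t_origin)


def load_schedule(path: str | Path) -> ExtinctionSchedule:
    """Read a schedule from YAML/JSON.

    Expected shape::

        p: 0.9
        q: 1.0
        t_origin: 4000
        events:
          - {name: GOE, age_mya: 2450, host_associated: false}
          - {name: K-T, age_mya: 66, host_associated: true, q: 0.5}

    Per-event ``p``/``q`` keys override the schedule scalars.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    events = tuple(
        ExtinctionEvent(
            name=str(ev["name"]),
            age_mya=float(ev["age_mya"]),
            host_associated=bool(ev["host_associated"]),
            p_override=None if ev.get("p") is None else float(ev["p"]),
            q_override=None if ev.get("q") is None else float(ev["q"]),
        )
        for ev in raw["events"]
    )
    return ExtinctionSchedule(
        events=events,
        p=float(raw.get("p", 0.0)),
        q=float(raw.get("q", 1.0)),
        t_origin=float(raw.get("t_origin", 4000.0)),
    )


def survival_factor(schedule: ExtinctionSchedule, up_to_t: float | None = None) -> float:
    """Product of per-event surviving proportions over events by time t."""
    return math.exp(log_survival_factor(schedule, up_to_t))


def log_survival_factor(schedule: ExtinctionSchedule, up_to_t: float | None = None) -> float:
    """ln of the survival factor; the log-space primitive everything uses."""
    if up_to_t is None:
        up_to_t = schedule.t_origin
    total = 0.0
    for ev in schedule.events:
        if schedule.model_time(ev) <= up_to_t:
            total += math.log(schedule.event_survival(ev))
    return total


def richness_with_extinction(
    params: DiversificationParams, schedule: ExtinctionSchedule
) -> RichnessValue:
    """Expected present richness after all events by ``params.t``.

    The birth-death expectation multiplied by the survival factor; at
    the default schedule and t = t_origin this is the closed form
    ``exp((lam - mu) t) (1 - p) (1 - p q)^5``.
    """
    log10_s = params.net_rate * params.t / LN10 + log_survival_factor(schedule, params.t) / LN10
    return RichnessValue(log10_s)


@dataclass(frozen=True)
class DiversityTrajectory:
    """Richness through time, log10 internally; piecewise exponential
    with drops only at event model times."""

    times: np.ndarray
    log10_richness: np.ndarray

    @property
    def richness(self) -> np.ndarray:
        return 10.0 ** self.log10_richness


def trajectory(
    params: DiversificationParams, schedule: ExtinctionSchedule, step: float = 1.0
) -> DiversityTrajectory:
    """Evaluate S(t) on a regular grid from origin to ``schedule.t_origin``.

    ``step`` must divide the horizon; with the default 1-My step every
    integer event time falls on the grid, so drops land exactly at the
    event timesteps (the post-event value is reported there).
    """
    if not step > 0:
        raise ValueError(f"step must be positive, got {step}")
    n = schedule.t_origin / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} does not divide the time horizon {schedule.t_origin}")
    times = np.arange(round(n) + 1) * step
    growth = params.net_rate * times / LN10
    log_surv = np.zeros_like(times)
    for ev in schedule.events:
        log_surv[times >= schedule.model_time(ev)] += math.log(schedule.event_survival(ev))
    return DiversityTrajectory(times, growth + log_surv / LN10)


def epsilon_contour_me(lam: float, s_target: float, schedule: ExtinctionSchedule) -> Contour:
    """ME-model contour: eps at which perturbed S_{t_origin} = s_target.

    Inverts the closed form: the survival factor shifts the effective
    target, ``eps = 1 - ln(s_target / V) / (t_origin lam)`` where V is
    the full-schedule survival.  Reduces to the pure birth-death contour
    at p = 0.  Out-of-[0,1] values are flagged, including targets below
    the survival-adjusted minimum (contour above 1).
    """
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if not s_target >= 1:
        raise ValueError(f"s_target must be >= 1, got {s_target}")
    slope = (math.log(s_target) - log_survival_factor(schedule)) / schedule.t_origin
    eps = 1.0 - slope / lam
    return Contour(eps, 0.0 <= eps <= 1.0)


class MassExtinctionModel:
    """Richness surface of the perturbed model, for area integration.

    Same contract as :class:`microdiv.core.BirthDeathModel`; the whole
    perturbation enters as one additive log-survival constant, so all
    parameter-space machinery applies unchanged.
    """

    def __init__(self, schedule: ExtinctionSchedule):
        self.schedule = schedule
        self.t = float(schedule.t_origin)
        self._log_surv = log_survival_factor(schedule)

    def log10_richness(self, lam, eps):
        return np.asarray(lam) * (1.0 - np.asarray(eps)) * self.t / LN10 + self._log_surv / LN10

    def log_survival(self) -> float:
        return self._log_surv

    def contour_slope(self, s_target: float) -> float:
        if not s_target > 0:
            raise ValueError(f"s_target must be positive, got {s_target}")
        return (math.log(s_target) - self._log_surv) / self.t

    def epsilon_contour(self, lam: float, s_target: float) -> Contour:
        eps = 1.0 - self.contour_slope(s_target) / lam
        return Contour(eps, 0.0 <= eps <= 1.0)


@dataclass(frozen=True)
class CladeScenario:
    """Clade-resolved trajectories plus their share-weighted total."""

    shares: tuple[float, ...]
    clades: tuple[DiversityTrajectory, ...]
    total: DiversityTrajectory


def clade_vulnerability_scenario(
    params: DiversificationParams,
    schedule: ExtinctionSchedule,
    clade_shares: "list[float]",
    vulnerable_flags: "list[list[bool]]",
    step: float = 1.0,
) -> CladeScenario:
    """Diversity when only some clades are exposed to each event.

    Each clade starts with its share of the single ancestral lineage,
    diversifies independently at the common (lambda, eps), and suffers
    an event's reduction only where flagged vulnerable (the schedule's
    q still applies at host-associated events).  The total is the
    share-weighted sum; with every clade vulnerable to every event it
    collapses to :func:`richness_with_extinction`'s trajectory.
    """
    shares = [float(s) for s in clade_shares]
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValueError(f"clade shares must sum to 1, got {sum(shares)}")
    if len(vulnerable_flags) != len(shares):
        raise ValueError("need one flag row per clade")
    n_events = len(schedule.events)
    clades = []
    total_linear = None
    for share, flags in zip(shares, vulnerable_flags):
        if len(flags) != n_events:
            raise ValueError(f"flag row must have {n_events} entries, got {len(flags)}")
        sub = ExtinctionSchedule(
            events=tuple(ev for ev, f in zip(schedule.events, flags) if f),
            p=schedule.p,
            q=schedule.q,
            t_origin=schedule.t_origin,
        )
        traj = trajectory(params, sub, step)
        with np.errstate(divide="ignore"):
            log10 = traj.log10_richness + math.log10(share) if share > 0 else np.full_like(traj.log10_richness, -np.inf)
        clades.append(DiversityTrajectory(traj.times, log10))
    # share-weighted sum accumulated in log space
    stacked = np.stack([c.log10_richness for c in clades])
    peak = stacked.max(axis=0)
    total_log10 = peak + np.log10(np.sum(10.0 ** (stacked - peak), axis=0))
    total = DiversityTrajectory(clades[0].times, total_log10)
    return CladeScenario(tuple(shares), tuple(clades), total)
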