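"""Feasibility integration over the (lambda, epsilon) parameter rectangle.

The question answered here: over a uniform measure on the speciation /
relative-extinction rectangle, what fraction of parameter combinations
leads to a given present-day richness outcome?  The feasible band is
bounded below by the number of described 16S OTUs (1e6) and above by a
neutral-drift ceiling (1e23, half-open); richness cannot exceed the
1e30 global cell count in any case.

Because the richness surface is ``exp(lam (1 - eps) t) * V`` for a
constant survival factor V, every iso-richness contour has the form
``eps = 1 - a / lam`` with ``a = ln(S/V) / t``.  Areas between clipped
contours therefore integrate in closed form (the integrand is linear in
1/lam on each clip piece); that exact piecewise integral is the
reference method, with a midpoint-grid sum kept as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterDomain",
    "FeasibilityBounds",
    "OutcomeBin",
    "ConditionalOutcome",
    "band_area",
    "band_area_grid",
    "feasible_fraction",
    "infeasible_low_fraction",
    "infeasible_high_fraction",
    "outcome_probabilities",
    "conditional_probability_at_lambda",
    "lambda_threshold_for",
]


@dataclass(frozen=True)
class ParameterDomain:
    """The (lambda, eps) rectangle over which outcomes are weighed.

    Defaults are the study conditions: speciation rates 0.004-0.03 My^-1
    (endosymbiont-calibrated, lower endpoint discounted for free-living
    lineages), the full relative-extinction interval, and t = 4000 My
    since the last universal common ancestor.
    """

    lam_range: tuple[float, float] = (0.004, 0.03)
    eps_range: tuple[float, float] = (0.0, 1.0)
    t: float = 4000.0

    def __post_init__(self) -> None:
        l0, l1 = self.lam_range
        e0, e1 = self.eps_range
        if not 0 < l0 < l1:
            raise ValueError(f"lam_range must be a nonempty interval in (0, inf), got {self.lam_range}")
        if not 0 <= e0 < e1 <= 1:
            raise ValueError(f"eps_range must be a nonempty subinterval of [0, 1], got {self.eps_range}")
        if not self.t > 0:
            raise ValueError(f"t must be positive, got {self.t}")

    @property
    def area(self) -> float:
        (l0, l1), (e0, e1) = self.lam_range, self.eps_range
        return (l1 - l0) * (e1 - e0)


@dataclass(frozen=True)
class FeasibilityBounds:
    """Richness bounds defining feasible parameter space.

    ``s_low``: hard floor from described OTUs. ``s_high``: soft ceiling
    from neutral drift (the feasible interval is half-open,
    [s_low, s_high)). ``s_hard_max``: the global abundance ceiling,
    kept for documentation only — no computation uses it.
    """

    s_low: float = 1e6
    s_high: float = 1e23
    s_hard_max: float = 1e30

    def __post_init__(self) -> None:
        if not 1 <= self.s_low < self.s_high <= self.s_hard_max:
            raise ValueError(
                f"need 1 <= s_low < s_high <= s_hard_max, got "
                f"({self.s_low}, {self.s_high}, {self.s_hard_max})"
            )


@dataclass(frozen=True)
class OutcomeBin:
    """A half-open richness interval [lower, upper) with its area weight."""

    lower: float
    upper: float
    area: float
    probability: float


@dataclass(frozen=True)
class ConditionalOutcome:
    """Per-bin fractions of the eps interval at one fixed lambda.

    ``feasible_width`` is the eps-length mapping into the feasible band;
    when it is zero no outcome is reachable at this lambda and ``bins``
    is empty.
    """

    lam: float
    bins: tuple[OutcomeBin, ...]
    feasible_width: float


def _check_monotone(model, domain: ParameterDomain) -> None:
    """Contract probe: richness must strictly decrease in eps."""
    l0, l1 = domain.lam_range
    e0, e1 = domain.eps_range
    for lam in (l0, 0.5 * (l0 + l1), l1):
        lo = model.log10_richness(lam, e0 + 0.75 * (e1 - e0))
        hi = model.log10_richness(lam, e0 + 0.25 * (e1 - e0))
        if not lo < hi:
            raise ValueError(
                "richness function is not decreasing in eps on probe points; "
                "the contour-based area integration does not apply"
            )


def _area_above_level(model, domain: ParameterDomain, s: float) -> float:
    """Exact area of {(lam, eps) in domain : richness >= s}.

    The region is {eps <= g(lam)} with g(lam) = 1 - a/lam; the clipped
    width integrates piecewise in closed form, with breakpoints where g
    crosses the eps bounds.
    """
    if s == math.inf:
        return 0.0
    a = model.contour_slope(s)
    (l0, l1), (e0, e1) = domain.lam_range, domain.eps_range

    breakpoints = {l0, l1}
    if a > 0:
        for e in (e0, e1):
            if e < 1.0:
                lb = a / (1.0 - e)
                if l0 < lb < l1:
                    breakpoints.add(lb)
    knots = sorted(breakpoints)

    total = 0.0
    for la, lb in zip(knots[:-1], knots[1:]):
        mid = 0.5 * (la + lb)
        g = 1.0 - a / mid
        if g <= e0:
            continue
        if g >= e1:
            total += (e1 - e0) * (lb - la)
        else:
            # integral of (1 - a/lam - e0)
            total += (1.0 - e0) * (lb - la) - a * math.log(lb / la)
    return total


def band_area(domain: ParameterDomain, s_lo: float, s_hi: float, model) -> float:
    """Exact area where ``s_lo <= richness < s_hi`` (lambda x eps units).

    Reference method: difference of two closed-form clipped-contour
    integrals.  ``s_hi = inf`` gives the area above ``s_lo``.
    """
    if not s_lo < s_hi:
        raise ValueError(f"need s_lo < s_hi, got ({s_lo}, {s_hi})")
    _check_monotone(model, domain)
    return _area_above_level(model, domain, s_lo) - _area_above_level(model, domain, s_hi)


def band_area_grid(
    domain: ParameterDomain, s_lo: float, s_hi: float, model, resolution: int = 2000
) -> float:
    """Midpoint-grid estimate of the same band area (cross-check method)."""
    if not s_lo < s_hi:
        raise ValueError(f"need s_lo < s_hi, got ({s_lo}, {s_hi})")
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    (l0, l1), (e0, e1) = domain.lam_range, domain.eps_range
    lam = l0 + (np.arange(resolution) + 0.5) * (l1 - l0) / resolution
    eps = e0 + (np.arange(resolution) + 0.5) * (e1 - e0) / resolution
    logs = model.log10_richness(lam[:, None], eps[None, :])
    lo = -math.inf if s_lo <= 0 else math.log10(s_lo)
    hi = math.inf if s_hi == math.inf else math.log10(s_hi)
    inside = (logs >= lo) & (logs < hi)
    return float(inside.mean()) * domain.area


def feasible_fraction(domain: ParameterDomain, bounds: FeasibilityBounds, model) -> float:
    """Fraction of the rectangle with richness in [s_low, s_high)."""
    return band_area(domain, bounds.s_low, bounds.s_high, model) / domain.area


def infeasible_low_fraction(domain: ParameterDomain, bounds: FeasibilityBounds, model) -> float:
    """Fraction of the rectangle with richness below the s_low floor."""
    _check_monotone(model, domain)
    below = domain.area - _area_above_level(model, domain, bounds.s_low)
    return below / domain.area


def infeasible_high_fraction(domain: ParameterDomain, bounds: FeasibilityBounds, model) -> float:
    """Fraction of the rectangle with richness at or above s_high."""
    _check_monotone(model, domain)
    return _area_above_level(model, domain, bounds.s_high) / domain.area


def _bin_edges(bounds: FeasibilityBounds, bin_width_decades: int) -> list[tuple[float, float]]:
    lo_dec = math.log10(bounds.s_low)
    hi_dec = math.log10(bounds.s_high)
    if abs(lo_dec - round(lo_dec)) > 1e-9 or abs(hi_dec - round(hi_dec)) > 1e-9:
        raise ValueError("bin edges require power-of-10 feasibility bounds")
    lo_dec, hi_dec = round(lo_dec), round(hi_dec)
    edges = []
    for d in range(lo_dec, hi_dec, bin_width_decades):
        upper = min(d + bin_width_decades, hi_dec)
        # exact integer power first so edges equal literals like 1e23
        edges.append((float(10 ** d), float(10 ** upper)))
    return edges


def outcome_probabilities(
    domain: ParameterDomain,
    bounds: FeasibilityBounds,
    model,
    bin_width_decades: int = 1,
) -> list[OutcomeBin]:
    """Probability of each diversity-outcome bin over the feasible band.

    Partitions [s_low, s_high) into power-of-10 bins of the requested
    decade width (the last bin is truncated at s_high if the width does
    not divide evenly), computes each bin's exact area, and normalizes
    by the feasible-band area so probabilities sum to 1 by construction.
    """
    if bin_width_decades < 1:
        raise ValueError(f"bin_width_decades must be >= 1, got {bin_width_decades}")
    feas = band_area(domain, bounds.s_low, bounds.s_high, model)
    if feas <= 0:
        raise ValueError("empty feasible area: no parameter combination lies in bounds")
    bins = []
    for lower, upper in _bin_edges(bounds, bin_width_decades):
        area = band_area(domain, lower, upper, model)
        bins.append(OutcomeBin(lower, upper, area, area / feas))
    return bins


def conditional_probability_at_lambda(
    lam: float,
    domain: ParameterDomain,
    bounds: FeasibilityBounds,
    model,
    bin_width_decades: int = 1,
) -> ConditionalOutcome:
    """Outcome probabilities conditional on one speciation rate.

    At fixed lambda the probability of a bin is the length of the eps
    interval mapping into it, normalized by the length mapping into the
    feasible band.  Above ``lam ~ ln(s_high)/t`` every contour lies in
    (0, 1), the lambda factor cancels, and the fractions become
    lambda-invariant.  An empty feasible interval is returned flagged
    (``feasible_width == 0``) rather than raising.
    """
    l0, l1 = domain.lam_range
    if not l0 <= lam <= l1:
        raise ValueError(f"lam={lam} outside domain {domain.lam_range}")
    e0, e1 = domain.eps_range

    def width(s_lo: float, s_hi: float) -> float:
        g_lo = 1.0 - model.contour_slope(s_lo) / lam
        g_hi = (1.0 - model.contour_slope(s_hi) / lam) if s_hi != math.inf else -math.inf
        return max(0.0, min(g_lo, e1) - e0) - max(0.0, min(g_hi, e1) - e0)

    feas = width(bounds.s_low, bounds.s_high)
    if feas <= 0:
        return ConditionalOutcome(lam, (), 0.0)
    bins = tuple(
        OutcomeBin(lower, upper, w, w / feas)
        for lower, upper in _bin_edges(bounds, bin_width_decades)
        for w in (width(lower, upper),)
    )
    return ConditionalOutcome(lam, bins, feas)


def lambda_threshold_for(s_target: float, t: float, eps_floor: float = 0.0) -> float:
    """Minimum speciation rate at which ``s_target`` is attainable.

    With extinction no lower than ``eps_floor``, richness at a given
    lambda is maximized at that floor, so the threshold solves
    ``lam (1 - eps_floor) t = ln(s_target)``.
    """
    if not s_target >= 1:
        raise ValueError(f"s_target must be >= 1, got {s_target}")
    if not 0 <= eps_floor < 1:
        raise ValueError(f"eps_floor must lie in [0, 1), got {eps_floor}")
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    return math.log(s_target) / ((1.0 - eps_floor) * t)
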