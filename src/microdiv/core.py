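"""Closed-form birth-death diversification model for global microbial richness.

Species are 97%-similarity 16S rRNA OTUs.  A speciation event is the
accumulation of 3% sequence divergence, so the speciation rate lambda
follows directly from a 16S substitution rate.  Expected richness after
time t from a single ancestral lineage is exponential,
``E[S_t] = exp((lambda - mu) t)``, with extinction expressed through the
relative extinction rate ``eps = mu / lambda`` in [0, 1].

All richness arithmetic is carried in log10 space: unclipped expectations
over the default parameter domain reach ~1e52, far beyond what should be
materialized as a linear float until display time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

LN10 = math.log(10.0)

__all__ = [
    "SubstitutionRate",
    "DiversificationParams",
    "RichnessValue",
    "Contour",
    "BirthDeathModel",
    "speciation_rate_from_substitution",
    "speciation_rate_range",
    "expected_richness",
    "epsilon_contour",
]


@dataclass(frozen=True)
class SubstitutionRate:
    """A 16S rRNA substitution rate.

    Parameters
    ----------
    k16s
        Divergence per nucleotide site per million years
        (e.g. ``0.00025`` for 0.025%/nt/My).
    divergence_threshold
        Fractional sequence divergence treated as a speciation event
        under the OTU species definition (default 3%).
    seq_length
        16S gene length in nucleotides.  Optional: it cancels from the
        speciation-rate formula and is accepted only to make that
        cancellation testable.
    """

    k16s: float
    divergence_threshold: float = 0.03
    seq_length: float | None = None

    def __post_init__(self) -> None:
        if not self.k16s > 0:
            raise ValueError(f"k16s must be positive, got {self.k16s}")
        if not 0 < self.divergence_threshold < 1:
            raise ValueError(
                f"divergence_threshold must lie in (0, 1), got {self.divergence_threshold}"
            )
        if self.seq_length is not None and not self.seq_length > 0:
            raise ValueError(f"seq_length must be positive, got {self.seq_length}")


@dataclass(frozen=True)
class DiversificationParams:
    """Coordinates of one birth-death model evaluation.

    ``lam`` is the speciation rate (new species per extant species per
    My), ``eps`` the relative extinction rate mu/lambda, and ``t`` the
    elapsed time in My.  The extinction rate ``mu`` is always derived as
    ``eps * lam`` and never stored independently.
    """

    lam: float
    eps: float
    t: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not 0 <= self.eps <= 1:
            raise ValueError(f"eps must lie in [0, 1], got {self.eps}")
        if not self.t >= 0:
            raise ValueError(f"t must be non-negative, got {self.t}")

    @property
    def mu(self) -> float:
        """Extinction rate, species extinctions per extant species per My."""
        return self.eps * self.lam

    @property
    def net_rate(self) -> float:
        """Net diversification rate lambda - mu = lambda (1 - eps)."""
        return self.lam * (1.0 - self.eps)


@dataclass(frozen=True)
class RichnessValue:
    """A species count held as its base-10 logarithm.

    The linear value ``s`` is materialized on demand and may overflow to
    ``inf`` for log10_s beyond ~308; the log representation is the one
    every computation should use.
    """

    log10_s: float

    @property
    def s(self) -> float:
        return 10.0 ** self.log10_s

    @classmethod
    def from_linear(cls, s: float) -> "RichnessValue":
        if not s > 0:
            raise ValueError(f"richness must be positive, got {s}")
        return cls(math.log10(s))


@dataclass(frozen=True)
class Contour:
    """An epsilon-contour evaluation.

    ``in_range`` is False when the contour value falls outside the
    admissible relative-extinction interval [0, 1] at this lambda, i.e.
    the requested richness level is unattainable (or exceeded even at
    eps = 1) there.  The raw value is kept so callers can clip
    deliberately rather than silently.
    """

    epsilon: float
    in_range: bool


def speciation_rate_from_substitution(rate: SubstitutionRate) -> float:
    """Speciation rate (My^-1) implied by a 16S substitution rate.

    The number of substitutions accumulated per My, ``seq_length * k16s``,
    divided by the number needed for the OTU divergence threshold,
    ``divergence_threshold * seq_length``; the gene length cancels.
    """
    return rate.k16s / rate.divergence_threshold


def speciation_rate_range(
    k_min: float,
    k_max: float,
    free_living_discount: float = 0.5,
    divergence_threshold: float = 0.03,
) -> tuple[float, float]:
    """Speciation-rate range from a substitution-rate range.

    Endosymbiont substitution rates can run up to twice those of
    free-living relatives, so the lower endpoint is discounted by
    ``free_living_discount`` (0.5 halves it; 1.0 keeps the raw range).

    Returns ``(lam_min, lam_max)`` unrounded; presentation rounding is
    the caller's concern.
    """
    if not 0 < k_min <= k_max:
        raise ValueError(f"need 0 < k_min <= k_max, got ({k_min}, {k_max})")
    if not 0 < free_living_discount <= 1:
        raise ValueError(
            f"free_living_discount must lie in (0, 1], got {free_living_discount}"
        )
    lam_min = free_living_discount * speciation_rate_from_substitution(
        SubstitutionRate(k_min, divergence_threshold)
    )
    lam_max = speciation_rate_from_substitution(
        SubstitutionRate(k_max, divergence_threshold)
    )
    return lam_min, lam_max


def expected_richness(params: DiversificationParams) -> RichnessValue:
    """Unconditional expected richness E[S_t] = exp(lambda (1 - eps) t).

    Starts from a single ancestral lineage; extinct realizations count
    as zero, so no survival conditioning is applied.
    """
    return RichnessValue(params.net_rate * params.t / LN10)


def epsilon_contour(lam: float, s_target: float, t: float) -> Contour:
    """Relative extinction rate at which E[S_t] equals ``s_target``.

    Inverts the exponential expectation:
    ``eps(lam) = 1 - ln(s_target) / (lam t)``.  Values outside [0, 1]
    are returned flagged rather than clipped, so that area integration
    can distinguish truncation from genuine contour intersection.
    """
    if not lam > 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if not s_target >= 1:
        raise ValueError(f"s_target must be >= 1, got {s_target}")
    if not t > 0:
        raise ValueError(f"t must be positive, got {t}")
    eps = 1.0 - math.log(s_target) / (lam * t)
    return Contour(eps, 0.0 <= eps <= 1.0)


class BirthDeathModel:
    """The pure birth-death expectation surface over (lambda, eps).

    Exposes the vectorized log-richness surface and the linear-in-1/lam
    contour coefficient used by the exact area integrator.  Serves as
    the ``p = 0`` reduction of the mass-extinction model.
    """

    def __init__(self, t: float = 4000.0):
        if not t > 0:
            raise ValueError(f"t must be positive, got {t}")
        self.t = float(t)

    def log10_richness(self, lam, eps):
        """log10 E[S_t]; accepts scalars or numpy arrays."""
        return np.asarray(lam) * (1.0 - np.asarray(eps)) * self.t / LN10

    def log_survival(self) -> float:
        """ln of the mass-extinction survival factor (1 for this model)."""
        return 0.0

    def contour_slope(self, s_target: float) -> float:
        """Coefficient a such that the s_target contour is eps = 1 - a/lam."""
        if not s_target > 0:
            raise ValueError(f"s_target must be positive, got {s_target}")
        return (math.log(s_target) - self.log_survival()) / self.t

    def epsilon_contour(self, lam: float, s_target: float) -> Contour:
        eps = 1.0 - self.contour_slope(s_target) / lam
        return Contour(eps, 0.0 <= eps <= 1.0)
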