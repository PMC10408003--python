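"""Synthetic EMP-like incidence tables and parameter-grid fixtures.

The generator produces an OTU x sample presence/absence table together
with sample habitat metadata and ground-truth niche labels, with the
mixture of obligate-host, preferential-host, tied, preferential-free,
and obligate-free OTUs under exact control.  Only incidence structure
is emulated — no read counts, chimeras, or sequencing noise — because
the host-association analysis consumes presence/absence alone.

By default category counts are deterministic quotas (largest-remainder
apportionment of weights * n_otus), so a classification run recovers
the specified mixture exactly; a multinomial mode is available when
sampling variability is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .host_association import CATEGORIES, OtuTable, SampleMetadata

__all__ = ["MixtureSpec", "generate_table", "parameter_grid_fixture"]

_HOST_HABITATS = ("Animal gut", "Animal surface", "Plant rhizosphere", "Plant corpus")


@dataclass(frozen=True)
class MixtureSpec:
    """Specification of a synthetic OTU mixture.

    ``weights`` maps the five niche categories to fractions summing to
    1.  ``occurrence_range`` is the inclusive range of per-OTU total
    occurrences; the default (2, 10) keeps exact ties constructible.
    """

    n_otus: int = 1000
    n_host_samples: int = 40
    n_free_samples: int = 40
    weights: tuple[float, float, float, float, float] = (0.093, 0.106, 0.021, 0.258, 0.522)
    occurrence_range: tuple[int, int] = (2, 10)
    seed: int | None = None
    quota_mode: bool = True

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError(f"n_otus must be >= 1, got {self.n_otus}")
        if len(self.weights) != len(CATEGORIES):
            raise ValueError(f"need {len(CATEGORIES)} weights {CATEGORIES}, got {self.weights}")
        if any(w < 0 for w in self.weights):
            raise ValueError(f"weights must be non-negative, got {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        lo, hi = self.occurrence_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid occurrence_range {self.occurrence_range}")
        active = {c for c, w in zip(CATEGORIES, self.weights) if w > 0}
        if active & {"obligate_host", "preferential_host", "tied", "preferential_free"}:
            if self.n_host_samples < 1:
                raise ValueError("host-occurring categories need n_host_samples >= 1")
        if active & {"obligate_free", "preferential_free", "tied", "preferential_host"}:
            if self.n_free_samples < 1:
                raise ValueError("free-occurring categories need n_free_samples >= 1")

    @property
    def weight_map(self) -> dict[str, float]:
        return dict(zip(CATEGORIES, self.weights))


def _largest_remainder(weights, n: int) -> np.ndarray:
    """Apportion n among categories by weights, largest remainder."""
    raw = np.asarray(weights, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    counts[order[:short]] += 1
    return counts


def _feasible_splits(category: str, spec: MixtureSpec) -> list[tuple[int, int, int]]:
    """All feasible (total, host_min, host_max) for a category.

    Splits are constrained so the classified category equals the truth
    label: preferential OTUs keep at least one occurrence on the minor
    side (otherwise they would be obligate), ties are exactly even.
    """
    lo, hi = spec.occurrence_range
    nh, nf = spec.n_host_samples, spec.n_free_samples
    out = []
    for total in range(lo, hi + 1):
        if category == "obligate_host":
            if total <= nh:
                out.append((total, total, total))
        elif category == "obligate_free":
            if total <= nf:
                out.append((total, 0, 0))
        elif category == "tied":
            if total % 2 == 0 and total // 2 <= nh and total // 2 <= nf:
                out.append((total, total // 2, total // 2))
        elif category == "preferential_host":
            h_min = max(total // 2 + 1, total - nf)
            h_max = min(total - 1, nh)
            if total >= 3 and h_min <= h_max:
                out.append((total, h_min, h_max))
        elif category == "preferential_free":
            h_min = max(1, total - nf)
            h_max = min((total - 1) // 2, nh)
            if total >= 3 and h_min <= h_max:
                out.append((total, h_min, h_max))
    return out


def generate_table(
    spec: MixtureSpec,
) -> tuple[OtuTable, SampleMetadata, pd.Series]:
    """Generate (table, metadata, truth labels) for a mixture spec.

    Category counts are quotas (default) or one multinomial draw; each
    OTU then draws a total occurrence count and a host/free split that
    force its category by construction, and occupies uniformly chosen
    samples on each side.  Byte-identical outputs for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.quota_mode:
        counts = _largest_remainder(spec.weights, spec.n_otus)
    else:
        counts = rng.multinomial(spec.n_otus, np.asarray(spec.weights) / sum(spec.weights))

    feasible = {}
    for cat, k in zip(CATEGORIES, counts):
        if k > 0:
            feasible[cat] = _feasible_splits(cat, spec)
            if not feasible[cat]:
                raise ValueError(
                    f"category {cat!r} has no feasible occurrence split with "
                    f"occurrence_range={spec.occurrence_range}, "
                    f"n_host_samples={spec.n_host_samples}, n_free_samples={spec.n_free_samples}"
                )

    host_ids = [f"host_s{i:04d}" for i in range(spec.n_host_samples)]
    free_ids = [f"free_s{i:04d}" for i in range(spec.n_free_samples)]
    otu_ids = [f"otu_{i:06d}" for i in range(spec.n_otus)]

    incidence = np.zeros((spec.n_otus, spec.n_host_samples + spec.n_free_samples), dtype=bool)
    labels = np.empty(spec.n_otus, dtype=object)
    row = 0
    for cat, k in zip(CATEGORIES, counts):
        for _ in range(k):
            total, h_min, h_max = feasible[cat][rng.integers(len(feasible[cat]))]
            h = int(rng.integers(h_min, h_max + 1))
            f = total - h
            if h:
                cols = rng.choice(spec.n_host_samples, size=h, replace=False)
                incidence[row, cols] = True
            if f:
                cols = rng.choice(spec.n_free_samples, size=f, replace=False)
                incidence[row, spec.n_host_samples + cols] = True
            labels[row] = cat
            row += 1

    table = OtuTable(
        pd.DataFrame(
            incidence,
            index=pd.Index(otu_ids, name="otu_id"),
            columns=host_ids + free_ids,
        )
    )
    habitats = pd.Series(
        [_HOST_HABITATS[i % len(_HOST_HABITATS)] for i in range(spec.n_host_samples)]
        + ["Free-living"] * spec.n_free_samples,
        index=pd.Index(host_ids + free_ids, name="sample_id"),
    )
    meta = SampleMetadata(habitats)
    truth = pd.Series(labels, index=table.otu_ids, name="category")
    return table, meta, truth


def parameter_grid_fixture(
    domain=None,
    resolution: int = 100,
    seed: int | None = None,
    jitter: float = 0.0,
    schedule=None,
) -> pd.DataFrame:
    """Regular (lambda, eps) grid with closed-form richness columns.

    Returns one row per grid point with ``log10_s_bd`` and, when a
    schedule is given, ``log10_s_me``.  ``jitter`` (fraction of a cell)
    perturbs interior points reproducibly for grid-robustness tests;
    resolution 2 gives exactly the four domain corners.
    """
    from .core import BirthDeathModel
    from .mass_extinction import MassExtinctionModel
    from .parameter_space import ParameterDomain

    if domain is None:
        domain = ParameterDomain()
    if resolution < 2:
        raise ValueError(f"resolution must be >= 2, got {resolution}")
    (l0, l1), (e0, e1) = domain.lam_range, domain.eps_range
    lam = np.linspace(l0, l1, resolution)
    eps = np.linspace(e0, e1, resolution)
    ll, ee = np.meshgrid(lam, eps, indexing="ij")
    ll, ee = ll.ravel(), ee.ravel()
    if jitter > 0:
        rng = np.random.default_rng(seed)
        dl = (l1 - l0) / (resolution - 1) * jitter
        de = (e1 - e0) / (resolution - 1) * jitter
        ll = np.clip(ll + rng.uniform(-dl, dl, ll.size), l0, l1)
        ee = np.clip(ee + rng.uniform(-de, de, ee.size), e0, e1)
    out = pd.DataFrame({"lam": ll, "eps": ee})
    out["log10_s_bd"] = BirthDeathModel(domain.t).log10_richness(ll, ee)
    if schedule is not None:
        out["log10_s_me"] = MassExtinctionModel(schedule).log10_richness(ll, ee)
    return out
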