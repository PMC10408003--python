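# Methods

## Diversification model

Richness dynamics are a constant-rate, universal birth–death process:
every extant OTU speciates at rate λ and goes extinct at rate μ, with
no clade, niche, or time dependence. Starting from a single ancestral
lineage, the *unconditional* expectation is E[S_t] = e^{(λ−μ)t}; extinct
realizations count as zero, and no survival conditioning is applied
anywhere (a survival-conditioned mean is systematically larger and must
not be compared to this closed form — the stochastic oracle documents
the same convention).

Parameters, units, defaults:

| parameter | meaning | default | why |
|---|---|---|---|
| K₁₆S | 16S substitution rate, divergence/nt/My | 0.00025–0.00091 | endosymbiont calibrations against dated insect fossils |
| divergence threshold | divergence counted as speciation | 0.03 | the 97% OTU species definition; configurable for sensitivity analysis |
| λ | speciation rate, My⁻¹ | domain 0.004–0.03 | K₁₆S/0.03, lower endpoint halved because endosymbiont substitution rates can be ~2× free-living rates |
| ε = μ/λ | relative extinction | domain [0, 1] | extinction is not directly estimable without circularity; the full ratio range is scanned |
| t | time since origin, My | 4000 | approximate age of the last universal common ancestor |
| S bounds | feasible richness | [10⁶, 10²³), hard cap 10³⁰ | described OTUs below; neutral-drift ceiling above; global cell count as absolute cap |

ε is the canonical extinction coordinate; μ is always derived as ελ and
never stored, because the analysis lives on the (λ, ε) rectangle. All
richness values are carried as log10 internally — unclipped
expectations reach ~10⁵² at the domain corner — and converted to linear
numbers only for display.

## Area integration

Both richness surfaces have the form e^{λ(1−ε)t}·V with a constant
survival factor V (V = 1 without mass extinction), so every
iso-richness contour is ε(λ) = 1 − a/λ with a = ln(S/V)/t. The area
with richness in [S₁, S₂) is the integral over λ of the difference of
the two contours clipped to the ε interval. The reference integrator
is exact: it splits the λ range at the points where a contour crosses
an ε bound (λ = a/(1−ε_bound)) and applies the antiderivative
(1−ε₀)λ − a ln λ on each piece. A midpoint-grid sum
(`band_area_grid`) exists purely as an independent cross-check; the
acceptance script refuses to report an area value when the two methods
disagree by more than 0.2 percentage points of the domain.

Outcome probabilities normalize per-bin areas by the feasible-band
area, so any decade partition sums to 1 by construction. Feasibility
intervals and bins are half-open [lower, upper). Bin edges are exact
integer powers of 10; when the requested decade width does not divide
the 17-decade feasible band (e.g. 3-decade display bins), the last bin
is truncated at 10²³. λ integration limits are the configured domain
endpoints exactly, no padding.

Contour evaluations outside ε ∈ [0, 1] are returned as flagged values
(`Contour.in_range = False`), never silently clipped: the integrator
must distinguish "the contour leaves the admissible range here"
(clipping is correct) from "a caller asked for an unattainable level"
(the flag is the answer).

One published sentence reports the parameter-space share "leading to
>10⁶ species" moving from 26.7% to 50.2% under mass extinction, which
contradicts its own direction; both numbers equal the *below*-10⁶
share analytically (26.77% and 50.20%), so the quantity is implemented
as the below-threshold fraction and the sentence treated as a sign
slip. Published area percentages (50.6%, 36.5%) differ from the exact
integrals (50.42%, 36.26%) by ≲0.2 pp, consistent with an unstated
discretization in the original scheme; the exact values are reported.

## Mass-extinction model

Events are instantaneous one-time reductions placed at integer model
times round(t_origin − age): GOE at 2450 Mya (configurable), then the
Big Five at 445, 375, 252, 201, 66 Mya. Intensity p and vulnerable
fraction q are global scalars matching the "equal magnitude" modeling
choice (presets p ∈ {0, 0.5, 0.9}, q ∈ {0.1, 0.5, 1}); per-event
overrides exist in the schedule format for sensitivity work. q is the
fraction of *all* extant taxa exposed, so an event removes p·q of
standing richness — not a within-host-taxa intensity. The GOE is the
one non-host event: q does not apply there, even in scenarios framed
as "only obligate host-associated taxa vulnerable" — its survival
factor is always (1 − p). A p·q_eff = 1 event (total annihilation) is
rejected rather than propagated as zero richness.

The clade-vulnerability scenario generalizes this: clades holding
shares of the ancestral lineage diversify independently at the common
(λ, ε) and suffer only the events they are flagged for; the total is
the share-weighted sum (accumulated in log space). With one fully
vulnerable clade it reduces exactly to the closed form. The exact
clade groupings behind the published supplementary scenario are not
printed anywhere, so the mechanism is exposed generically rather than
hard-coding one configuration.

Not modeled, deliberately: multi-My extended extinction pulses,
post-extinction adaptive radiation, and event-specific empirical
magnitudes from the marine invertebrate record.

## Stochastic oracle

The simulator tracks only the species count — no event-time genealogy —
which keeps the moments being validated while avoiding the memory
blow-up that makes genealogical simulation of ≥10¹² species
intractable. Schemes: exact Gillespie (waiting time exponential at
rate S(λ+μ), speciation with probability λ/(λ+μ)) and a binomial
tau-leap (births ~ Bin(S, λ·dt), deaths ~ Bin(S, μ·dt) per step,
enforced dt(λ+μ) ≤ 0.1). The tau-leap per-step growth factor
1 + (λ−μ)dt undershoots e^{(λ−μ)dt} by ~((λ−μ)dt)²/2 per step, so dt
must be chosen with the horizon in mind; validation runs at the 4000-My
horizon use dt = 2 My (relative mean bias ~2.5%, well inside Monte
Carlo noise at the replicate counts used). Mass extinctions are
binomial thinning of extant lineages at event times. Replicates
hitting the cap (default 10⁷) are frozen there and flagged; >1% capped
sets a warning because moments are then biased low. Validation designs
keep λt ≤ 10 so expectations stay far below the cap.

## Host-association classification

Occurrence means presence in a sample (count > 0); read abundances are
never weighted, matching the use of observation tables as presence
evidence. A sample is host-derived unless its habitat label equals the
free-living designation (default "Free-living", matched
case-insensitively after trimming) — every other label counts as host.
Obligate = all occurrences on one side; preferential = strictly more
than half (an exact 50% tie is preferential for neither side, which is
why the two preferential proportions sum below 100%). No
minimum-prevalence filter is applied; OTUs observed in zero samples
are rejected unless explicitly dropped, since the source subsetting
convention is not documented. The obligate-host and any-host
proportions bracket the mass-extinction model's q.

Input formats: TSV (OTU × sample counts) and BIOM 1.0 JSON (sparse or
dense). The BIOM reader/writer is a minimal JSON adapter covering the
observation-matrix core of the format, not a full BIOM implementation
(no HDF5/BIOM 2.x, no embedded metadata).

## Synthetic data

The generator emulates only the incidence structure the classifier
consumes: per-OTU totals uniform on [2, 10] (ties need an even total,
hence the floor of 2), splits drawn to force the intended category
(preferential OTUs keep ≥1 occurrence on the minor side so they cannot
collapse into obligate), and uniformly chosen sample subsets per side.
Category counts are deterministic largest-remainder quotas by default,
so classification recovers the specified mixture *exactly* and
round-trip tests are sharp; a multinomial mode adds sampling
variability when wanted. Real data differ in every dimension the
analysis ignores — read depth, compositionality, habitat structure,
OTU co-occurrence — so passing round-trip tests shows the classifier
implements its definitions correctly, not that those definitions are
robust to survey artifacts.

## Numerical conventions and limitations

- Exact equality of the p = 0 mass-extinction model with the plain
  birth–death model is maintained bit-for-bit (identical evaluation
  order, log-survival exactly 0.0).
- Contour/richness round-trips hold to 10 significant digits in log10.
- The published ε bound for 10¹² species is the contour value 0.7697
  at λ = 0.03, printed as "< 0.78"; the ≤ comparison is used since the
  rounding convention behind the printed 0.78 is unstated.
- Monte-Carlo checks use a 3-standard-error band with fixed seeds;
  they are reproducible, not distribution-free.
- The model is a feasibility instrument, not an estimator: constant
  universal rates over 4000 My can inflate expectations by orders of
  magnitude, so outputs bound what is possible rather than predict
  what is.
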