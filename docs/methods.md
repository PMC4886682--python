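# Methods

This note documents the models, numerical choices and study conditions
behind `pelletmix`, and what the synthetic data do and do not establish.

## The germling-aggregation simulator

`synthetic_data.simulate_germling_aggregation` is an agent-based
coalescence model of a shaken liquid culture inoculated with a
green:red mix of spores.

**State.** Each particle carries founder counts per color, a diameter (µm),
and a germination time. Spores start at 1 µm.

**Germination.** Times are drawn from Normal(`germ_mean`, `germ_sd`)
truncated at zero; defaults 4 ± 1 h. The 4-h center reflects when spores of
this organism visibly germinate; the 1-h spread is a modelling choice that
staggers entry into the aggregation-competent state.

**Growth.** After germination the diameter grows linearly at `growth_rate`
(default 2 µm/h). Linear diameter growth is a deliberate simplification; it
implies the *relative* size advantage of early aggregates shrinks with
time, which is why particle sizes are measured at an early harvest (below).

**Encounters and adhesion.** Particle pairs meet as well-mixed random pairs
at a total rate of `collision_rate · n/2` per hour — a constant
per-particle encounter rate (default 1/h), not mass-action in the particle
concentration. The constant-rate kernel is what keeps late-mixed cultures
able to aggregate: cultures combined after 8 h of separate growth still
produce almost exclusively dual-colored pellets, which a density-decaying
kernel cannot reproduce because most particles have already coalesced by
then. An encounter merges the pair with probability `adhesion` (the glycan
genotype: 1 for wild type, ≪ 1 for synthase mutants), but only if **both**
partners are germinated and the time is inside the aggregation window. A
diameter-weighted kernel and a maximum-diameter eligibility cap are
available as options (`size_proportional_kernel`, `max_merge_diameter`).

**Window.** Aggregation shuts off after `aggregation_t_max` (default
11.5 h). A hard window is the simplest mechanism consistent with the
observed time restriction of aggregation. The default was calibrated once
against the observed mixing time course: combined cultures remain >90%
dual-pelleted when mixed at 8 h and drop to zero by 12 h; a window ending
exactly at 10 h would zero out the 10-h mixing point, which experimentally
still shows ~30% dual pellets.

**Merging.** Merges are volume-additive, `d = (d₁³ + d₂³)^{1/3}`, treating
pellets as roughly spherical with additive biomass. Founder counts add;
total founders and (at zero growth) total biovolume are conserved, which
the test suite asserts as invariants.

**Integration.** Fixed step `dt` (default 0.1 h). Encounter counts per step
are Poisson-thinned by adhesion up front; pairs are drawn uniformly from
the currently alive particles, and same-step merge chains are resolved with
a union-find redirect so a particle absorbed earlier in the step passes
subsequent encounters to its absorber. Coarser steps systematically
overshoot merge counts (the attempt rate uses the particle count from the
step start), which is why the default step is 0.1 h.

**Seeding.** Every generator takes one explicit seed; identical seeds give
bit-identical output. Because the simulator consumes randomness strictly in
time order, rerunning with a shorter `t_end` and the same seed reproduces
the exact earlier state of the same realization — used to harvest sizes at
12 h from the same culture whose flow events are read at 24 h.

## Flow gating

Events below extinction 25 are debris and discarded. Compensation is
subtract-only on the raw signals — green′ = max(0, green − 0.04·red),
red′ = max(0, red − 0.05·green) — with both coefficients applied to the raw
values, not sequentially; the clamp at zero prevents negative intensities
and undefined ratios. (Subtract-only compensation inverts the generator's
bleed model only to first order; the residual is ~c₁·c₂ ≈ 0.2%, well below
the gate widths.) The dual gate is derived from single-color controls after
filtering and compensation: the upper boundary is the lowest green:red
ratio in the green-only control, the lower boundary the highest ratio in
the red-only control, and an event is dual iff its ratio falls strictly
between the boundaries. With this strictness, control events can never fall
inside a gate derived from themselves. Compensated red of zero gives an
infinite ratio (a green event); a fully dark event is counted on the red
side so the green/red/dual classes always partition the events.

## Imaging quantification

The two channels are averaged and rescaled to 8-bit; this merged picture is
used **only** to detect regions (Otsu global threshold, connected
components, regions under `min_area` = 20 px dropped as speckle — the
detection method and area filter are package choices, standard and
parameter-light for well-separated particles). Mean green and red are then
measured per region **on the raw channels**, and the region is classified
by its ratio: strictly above 1.2 → green, strictly below 0.15 → red,
otherwise (boundaries included) → aggregated. Replicate class lists are
summarized as mean ± sample sd of the aggregated fraction, with a warning
when a replicate holds fewer than 500 particles.

## Size-distribution analysis

Maximum Feret diameters are normalized by the sample maximum, mapping into
(0, 1] and keeping the divisor so results can be mapped back to µm.

**Fit.** The five parameters (p, μ₁, μ₂, σ₁, σ₂) are estimated by maximum
likelihood with EM. The E-step runs in log space; convergence is declared
when the log-likelihood changes by less than `tol · max(1, |ℓ|)`
(default `tol` 1e-8; the relative form is scale-free in the sample size),
capped at 500 iterations. A floor of 1e-4 (normalized units) on both σ's
guards the unbounded-likelihood collapse of Gaussian mixtures. Components
are always relabeled so μ₁ ≤ μ₂; p refers to the small-particle component.

**Starts.** Multi-start (default 10) with a deliberately diverse
deterministic prefix: quantile splits at 0.5/0.1/0.9/0.3/0.7 and an
equal-mean unequal-variance start, then random two-point starts. The
extreme-quantile starts matter on mis-specified (unimodal) data: the
highest-likelihood solutions there are often "bulk plus vestigial tail"
fits with p near 0 or 1, which is exactly the signature the decision rule
uses to reject a second population; a start set of interior splits only
never finds them.

**Oracle.** `loglik_grid_oracle` maximizes the same likelihood by
exhaustive grid search (small samples only); the suite asserts EM never
falls below it, and separately cross-checks the fit against an independent
library implementation.

**Bootstrap.** Nonparametric case resampling; every replicate is refit
from fresh multi-starts (a reduced set of 4) and relabeled before pooling.
Replicates are *not* warm-started from the full-sample fit: warm starts
anchor every replicate in one local optimum and artificially shrink the
intervals of weakly identified fits. Replicate refits use a looser relative
tolerance (1e-6), to which the intervals are insensitive. Non-converged or
degenerate replicates are excluded and counted; >20% failures raises a
reliability warning.

**CI type.** The default interval is the bootstrap standard-error (normal
approximation) interval, mean ± 1.96·sd of the replicate draws, clipped to
the parameter domain; percentile intervals are available via
`ci_type="percentile"`. The SE interval is the package's choice because the
μ₁ ≤ μ₂ relabeling makes the *percentile* intervals of the two means
disjoint almost by construction whenever the components are weakly
separated — every admissible EM solution places μ₁ just below and μ₂ just
above the bulk center, so the order statistics of the pooled draws never
cross it. Under that artifact the overlap rule would call homogeneous
cultures bimodal about half the time; with SE intervals the operating
characteristics are correct (verdict ONE on 20/20 unimodal datasets, TWO on
20/20 five-sigma-separated mixtures, 92% coverage of the generative p —
all recomputed by the test suite).

**Decision.** TWO iff the CIs of μ₁ and μ₂ are disjoint **and** the point
estimate satisfies 0.025 < p̂ < 0.975 (the bound applies to the point
estimate, not its CI). Reports always carry both booleans alongside the
verdict.

## Study conditions for the end-to-end demonstrations

The bundled configurations fix the synthetic study conditions:

- **Wild type:** 200,000 spores, adhesion 1, collision rate 1/h →
  ≈ 6000 particles at 24 h. Flow events use `gain_ext` = 0.4, so the
  extinction threshold of 25 corresponds to 62.5 µm: the flow instrument
  sees pellets, not small stray mycelia, mirroring the physical detection
  limit of large-particle flow cytometry. Sizes are measured on the 12-h
  harvest of the same realization (2000 of ≈ 6000 particles), before
  linear growth compresses the aggregate/single size contrast.
- **Mutant:** as wild type but adhesion 0.003, calibrated to the few-percent
  dual fractions measured for glycan-synthase deletion strains in rich
  medium. No particle reaches the flow detection limit (reported as a null
  flow result); aggregation is quantified by imaging, as it is done
  experimentally for these strains.
- **Time course:** 100,000 spores per run; the dual fraction is computed
  over flow-detectable (≥ 62.5 µm) particles, because the reference
  measurement is flow-based.
- Demo configs run 200 bootstrap replicates for speed; the package default
  is 1000.

## What the synthetic data do not show

The generator emulates the *statistical shape* of the real assays — mixed
fluorescent populations with bleed-through, debris, a time-restricted
coalescence process, and one- or two-component size distributions — not
their biology or optics. It has no hydrodynamics, shear fragmentation,
nutrient limitation, death, spatial structure inside pellets, out-of-focus
artifacts or mosaic stitching. Passing tests therefore demonstrate that the
quantification pipeline is correct and well-calibrated on data whose ground
truth is known, not that the simulator is an accurate model of any
particular culture. Real micrographs and flow streams enter through the
same CSV/TIFF interfaces.

## Known limitations

- The uniform-kernel coalescence produces a right-skewed continuum of
  aggregate sizes rather than two cleanly separated modes; the
  two-population verdict on wild-type-like runs rests on the small/large
  contrast of that continuum and needs ≈ 2000 measured sizes to be stable
  across seeds.
- Subtract-only compensation is first-order; strong bleed-through would
  need the full matrix inverse.
- The Otsu-based detector assumes well-separated particles on a uniform
  background; overlapping or touching particles are not split.
- With `ci_type="percentile"` the decision rule loses specificity on
  homogeneous samples, for the relabeling reason documented above.
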