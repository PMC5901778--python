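# Methods

## Model

Two strains, identical except for a neutral color label c ∈ {1 (blue),
2 (red)}, compete for space on an L×L square lattice with periodic
boundaries in both axes (cells washed past one border re-enter at the
opposite side, which also removes the anisotropy a directional flow would
otherwise imprint on a finite field of view). Each lattice site holds at
most one cell; with a cell cross-section of ~1 μm², one site represents
1 μm² of substratum and L = 60 mimics a 60 μm × 60 μm microscopy tile.

State updates are stochastic and occur in discrete steps. Each step
executes **one birth attempt then one detachment attempt**, each on an
independently and uniformly chosen occupied cell (the two sub-steps may
select the same cell; the ordering is a fixed convention — results depend
only on the relative frequency of detachments to births, which is set by
p_d, not on the sub-step order).

**Birth.** With probability p_b the chosen cell divides. The newborn
inherits the parent's color and takes a uniformly chosen empty site of the
parent's Moore neighborhood (8 surrounding sites, periodic wrap). If the
neighborhood is full, the newborn attempts to shove one uniformly chosen
resident neighbor. The resident is displaced with probability

    p_s = (1 − σ)/2 ,

so maximally adhesive residents (σ = 1) are never displaced and
non-adhesive residents (σ = 0) face a fair contest (p_s = 1/2). The shove
loser (displaced resident, or the newborn) moves to a uniformly chosen
empty Moore neighbor of the resident's original site; if that neighborhood
is also full the loser is removed from the system with the outflow. Shove
cascades are truncated: one shove per birth, at most.

**Detachment and relocation.** The chosen cell is first checked for
drafting: if its directly upstream site ((x − 1) mod L, y) is occupied the
cell is hydrodynamically shielded and cannot detach. An exposed cell
detaches with probability

    p_d = f (1 − σ) ,

where f ∈ [0, 1] is the non-dimensional flow intensity (f = 0: no flow,
no transport; f = 1: cells can be carried up to a full lattice length).
A detached cell is relocated downstream: Δx is a uniform integer on
{0, …, ⌊fL⌋} and Δy a uniform integer on {−Δx, …, Δx} (transverse drift
bounded by downstream travel, as in a laminar profile). The landing site
is evaluated after the origin is vacated, so the degenerate draw
Δx = Δy = 0 self-lands harmlessly. If the landing site is occupied the
cell is removed from the system (loss with the outflow).

**Initialization and stopping.** round(ρ₀·L²) founders are placed
uniformly without replacement, each independently blue or red with
probability ½ (a 1:1 inoculation mixture on average). Runs stop once 95%
of sites are occupied (configurable): near-complete coverage is dominated
by shove churn that no longer changes the pattern. A `max_steps` bound
(default 10⁷) is a safety net only.

A consequence of these rules worth stating: total extinction is
impossible once at least one cell is present. Removal requires either an
occupied relocation landing site (needs a second cell) or a failed shove
placement (which always accompanies a birth). The EXTINCT run status
exists and is excluded from ensembles, but is defensive.

## Parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| L | lattice lateral length (sites; 1 site = 1 μm) | ≥ 2 | 60 |
| σ | adhesiveness (matrix investment) | [0, 1] | 1.0 |
| ρ₀ | founder density (fraction of sites) | [0, 1] | 0.01 |
| f | flow intensity | [0, 1] | 1.0 |
| p_b | per-step birth-attempt probability | (0, 1] | 1.0 |
| occupancy_threshold | stopping fraction | (0, 1] | 0.95 |

p_b defaults to 1 (one guaranteed birth attempt per step): the final
pattern is insensitive to the absolute birth rate, since only the ratio
of detachment to birth events matters and that ratio is governed by p_d.
p_b is exposed for sensitivity studies.

## Engines

The rules are implemented twice: a readable pure-Python reference
(`biofilmca.model`, operating through per-event functions that also expose
telemetry for tests) and a numba-jitted kernel (`biofilmca._kernel`) with
an O(1) occupied-site index, used by ensembles and sweeps (~1–3 ms per
L = 60 run). The engines share counter semantics and the bookkeeping
invariant `final = founders + births − shove_removals −
relocation_removals`; they consume different random streams, so they agree
in distribution (tested) rather than trajectory-by-trajectory. Runs are
exactly reproducible given (config, seed, engine).

## Pattern statistics

**Autocorrelation.** For occupied sites with colors c ∈ {1, 2}, the
radially averaged autocorrelation in the unit-width annulus
[k − ½, k + ½) of ordered-pair Euclidean separations is

    C(k) = ( E[c_i c_j] − E[c_i] E[c_j] ) / ( E[c_i²] − E[c_i]² ),

with expectations over the pairs in the annulus; empty sites are excluded
(patterns are analyzed at ≥ 95% occupancy, where exclusion and imputation
are indistinguishable, and exclusion is the only option with a clean
definition of c). The denominator is the variance of the annulus's own
pair-endpoint color distribution, making each C(k) a Pearson coefficient:
C(0) = 1 by construction and |C(k)| ≤ 1 always (Cauchy–Schwarz). Under
periodic sampling every site enters every annulus equally and this equals
the conventional global-variance normalization; in bounded mode it is the
variant that preserves the bounds. The result is invariant under affine
relabeling, hence under swapping the two colors.

Two pair-distance modes exist: **bounded** (default; pairs confined to the
field of view, as in finite experimental tiles) and **periodic**
(minimal-image distances, natural for simulation lattices). The default
r_max is L/2, avoiding annuli dominated by few long-distance pairs.

The fast path computes the per-displacement pair sums with FFT
cross-correlograms of the occupancy and color indicator arrays and pools
them into annuli. All sums are integers, so FFT round-off is removed
exactly by rounding: the fast path reproduces the O(N²) brute-force
enumeration (kept as `autocorrelation_reference`, the test oracle)
bit-for-bit at the 1e-12 level.

**Correlation length.** ξ is the first zero of C(r): the linearly
interpolated radius at the first sign change from positive to ≤ 0.
Profiles that never cross zero within r_max are censored at r_max;
single-color patterns (one lineage fixed, common at very low founder
densities) are perfectly correlated at every r and are likewise recorded
as censored. Censored and extinct runs are counted separately and
excluded from ensemble moments.

Calibration on patterns of known structure: for stripes of width w the
cross-stripe correlation is a triangle wave and its angular average is
C(r) ≈ 1 − 4r/(πw) near the origin, so the first zero sits at **πw/4**,
not at w — the along-stripe direction never decorrelates and drags the
radial average upward. The measured ξ matches πw/4 within one annulus for
w ∈ {2, 4, 5, 10} and matches the brute-force oracle exactly. Random 1:1
patterns give ξ ≈ 1 (median), with a noise tail: individual random
patterns can show spurious short-range correlation, so ensemble tests
anchor the median, and seeded fixtures anchor exact values.

**Ensemble summaries.** Mean, sample standard deviation (n − 1), median
and adjusted Fisher–Pearson skewness (the convention under which |g₁| in
[0.5, 1] reads "moderately skewed"). Degenerate-variance ensembles report
skewness 0 with a flag.

**Adaptive KDE.** ξ distributions are asymmetric with a fat tail, so
densities are estimated with Abramson variable bandwidths: a pilot
Gaussian KDE with Silverman bandwidth h₀ = 0.9·min(sd, IQR/1.34)·n^(−1/5)
is evaluated at the sample points, and each sample receives
h_i = h₀·(f_pilot(x_i)/g)^(−1/2), g the geometric mean of pilot
densities. Positive-valued data are reflected at 0 to correct boundary
bias (`lower_bound=None` disables this for unbounded data). The default
evaluation grid spans [0, max + 5·max(h₀, max h_i)], on which the
estimate integrates to 1 within 1e-3.

## Experiments

`run_ensemble` executes independent replicates with per-replicate
generators spawned from `SeedSequence([base_seed, bits(f), bits(ρ₀),
bits(σ), rep])` — byte-reproducible, independent across grid points, and
identical for duplicated parameter values (a sweep over σ ∈ {1, 1} yields
Δξ ≡ 0 exactly). `sweep` fills an (f, ρ₀, σ) grid and tabulates the
adhesion payoff Δξ = mean ξ(σ_max) − mean ξ(σ_min);
`variability_surface` adds percentile-bootstrap CIs on std(ξ);
`compare_distributions` overlays adaptive KDEs and reports overlap
coefficients ∫min(f, g).

Desk-scale replica counts are 200 for trend statistics and 500 for Δξ
sign tests (with bootstrap CIs), against published ensembles of 5×10⁴ to
2×10⁶ realizations: at these counts the monotone trends and the Δξ sign
structure are stable, but individual means carry sampling error of order
std(ξ)/√n ≈ 0.2–0.3, and exact figure values are not a target. Trend
significance uses Spearman correlation on the pooled (ρ₀, ξ) replicate
pairs rather than on the handful of grid means.

## What the generator does and does not emulate

The synthetic study conditions reproduce the experimental geometry
(60 μm tiles, one cell per μm² site), the 1:1 random inoculation, and the
confluence stopping rule. They do not emulate: planktonic motility or
surface exploration before attachment, cell death, nutrient limitation,
3D growth above the monolayer, adhesion costs, or hydrodynamics beyond
the drafting rule and the f-bounded relocation kernel. Passing tests
therefore validate the lattice model's internal predictions — not
quantitative agreement with any particular experimental system, for which
the flow parameter f would first need calibration against images.

## Numerical choices and edge cases

- ⌊fL⌋ and the stopping count use a 1e-9 epsilon guard against binary
  fraction noise (0.1·60 evaluating just above 6).
- Annulus assignment uses `rint` on exact pair distances; distances of
  the form k + ½ cannot occur on an integer lattice (k² + k + ¼ is never
  an integer), so the half-open annulus convention is unambiguous.
- Annuli with zero endpoint variance (pathological, e.g. all endpoints of
  one color) report C = nan and are skipped by the first-zero walk.
- Image binarization is deliberately minimal: per-channel threshold
  (Otsu when unspecified) then brighter-channel argmax, ties to blue.
- Founder counts round half-up; the spec of a density, not a count,
  makes any consistent rounding acceptable.

## Limitations

- The shove rule truncates displacement cascades; dense-packing pressure
  is resolved by removal rather than long-range rearrangement.
- ξ censoring at r_max biases low-density ensemble moments slightly
  downward (the largest single-cluster outcomes are excluded); censored
  counts are always reported alongside moments.
- The per-bin Pearson normalization differs from the global-variance form
  in bounded mode by edge effects of order 1/L.
- numba compiles the kernel on first use (~4 s per process); pass
  `engine="python"` for compile-free single runs.
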