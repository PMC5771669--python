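# Methods

`budneck` implements the quantitative procedures used to study how budding
yeast confine age-promoting DNA circles in the mother cell: the FLIP-based
Barrier Index, the circle propagation-frequency statistic, stage-resolved
passage flux, circle–NPC colocalization, and a stochastic model of ERC
accumulation and replicative lifespan. This note records the models, their
assumptions, the defaults, and the numerical choices.

## FLIP and the Barrier Index (`budneck.flip`)

**Model.** In fluorescence loss in photobleaching, a spot in the mother part
of a dividing nucleus is bleached at every frame while integrated intensity
is recorded in the mother compartment, the bud compartment, and 3–5
unbleached neighbouring control cells. Processing follows the standard
protocol: subtract a scalar background, divide mother and bud frame-wise by
the control mean (removing acquisition photobleaching), rescale each trace to
start at 100%, average the single-cell profiles into one pooled profile per
compartment, and fit

    Y(t) = P + (100 − P)·exp(−K·t),   Y(0) ≡ 100,

by unweighted least squares (`scipy.optimize.curve_fit`, trust-region with
bounds K ≥ 0, P < 100). The time to lose 25% of the signal is the closed
form t75 = (1/K)·ln((100 − P)/(75 − P)), and the Barrier Index is
BI = t75(bud)/t75(mother). Standard errors propagate by the delta method
(∂t/∂K = −t/K, ∂t/∂P = (1/K)(100 − 75′)/((100 − P)(75′ − P)) for threshold
75′), including the plateau–K covariance whenever the fitter returns a finite
covariance matrix; the BI standard error combines the two t75 relative errors
in quadrature (the two fits are independent).

**Choices.**
- *Pool-then-fit is the default.* The pooled mean profile is fit once per
  compartment; per-cell fitting and averaging is possible with the same
  primitives but is not the default path, since the pooled profile is what
  the protocol fits.
- *Censoring.* If the fitted plateau is at or above the threshold (or K = 0),
  the compartment never loses 25% and t75 is undefined. A censored bud yields
  a censored BI reported as "n.d.", never as infinity; a censored mother is an
  error, because the bleached compartment must decay if the experiment worked.
- *Background* is a per-movie scalar supplied by the caller; the package does
  not estimate it.
- *Weighting.* Unweighted least squares; the pooled profile has roughly
  homoscedastic noise when cohort sizes per frame are constant.
- *Cross-instrument normalization.* When one condition is acquired on a
  different microscope, `cross_run_normalize` rescales its BI by the ratio of
  a shared reference strain's BI on the baseline instrument to its BI on the
  same run, with the SE propagated over the triple ratio.
- *Flat traces.* A constant-100 profile makes P and K jointly unidentifiable;
  the fit is returned with `converged=False` or with a curve indistinguishable
  from 100, and downstream t75 is censored. Nothing is raised silently.

## Propagation frequency and passage flux (`budneck.segregation`)

**Propagation frequency.** Anaphase cells carrying 1, 2 or 4 model circles
(cells whose circles sit on the spindle pole bodies are excluded upstream)
are scored for circles retained in the mother. With nᵢ cells of class i and
pᵢ the per-circle retention fraction of class i, the statistic is
1 − Σᵢ i·nᵢ·pᵢ / Σᵢ i·nᵢ. We read pᵢ as circles retained over total circles
of class-i cells (partial retention counts fractionally); under this reading
the statistic equals the circle-weighted bud fraction, it equals 1 − p when
every circle passes independently with probability p, and an empty class
simply contributes zero weight. Replicate experiments give a mean ± SEM over
experiments alongside the pooled value.

**Stage flux.** Early anaphase runs from the entry of a nuclear lobe into
the bud until the dumbbell-shaped nucleus forms; late anaphase from the
dumbbell to karyokinesis. The flux in a stage is the number of passage
events (first appearance of a circle in the daughter compartment) divided by
the summed stage duration over all cells, in cell·minutes. Per-cell
averaging of rates is a possible alternative denominator; pooled
cell·minutes was chosen because it weights cells by observation time and is
the maximum-likelihood denominator for a constant hazard. An event recorded
on the frame that ends early anaphase is attributed to early anaphase:
passage events are logged at the first frame on which the circle is visible
in the daughter, so an event at exactly t_dumbbell occurred before the
boundary.

## Colocalization (`budneck.coloc`)

Per cell, a two-channel intensity profile along the nuclear rim (NPC marker
in GFP, circle in mCherry; SPB region excluded) is background-subtracted, and
the GFP trace is re-indexed so the brightest mCherry pixel sits at offset 0
(ties take the first occurrence in scan order and are logged; an
all-background mCherry trace rejects the cell). Profiles are circular by
default and wrap; the linear mode, which matches real traces interrupted by
the SPB gap, truncates out-of-range offsets. Aligned GFP values are averaged
per offset and reported only where more than 10 cells contribute — the mask
is a strict inequality. The fold change at the circle is the aligned mean at
offset 0 divided by the rim-wide mean GFP over all positions and cells
(normalized to 1). The statistic is invariant to global GFP rescaling and to
per-cell rotation of the rim, both tested. An optional filter drops cells
whose circle lies within a configurable number of positions of a recorded
SPB index.

## ERC accumulation and lifespan (`budneck.erc`)

**Model.** One mother lineage carries an integer ERC load L, starting at 0.
Per division, in order: each resident circle duplicates with probability f
(independent Bernoulli; no copy-number dependence); Poisson(e) newly excised
circles join the pool; every copy independently stays in the mother with
probability r; the mother dies when the retained load reaches the threshold
T. The mean load obeys the exact recursion E[L_{g+1}] = (1+f)·r·E[L_g] + r·e,
used as the simulator's oracle — for r = 0.96, f = 0.6 an established load
grows ≈1.536-fold per generation. Newly excised circles replicate only from
the following cycle, which is what makes the recursion exact and reflects
excision occurring during or after S phase.

**Parameters.** r (retention) is the biologically measured quantity: 0.96
under optimal growth, 0.83 under heat stress. f defaults to 0.6, the
reported rDNA origin-firing efficiency. The de-novo excision rate e and
lethal load T are not experimentally pinned down; they default to
e = 0.1/division and T = 1000 (old mothers carry up to a thousand ERCs) and
are exposed in `ErcConfig`. The threshold-death rule was chosen over a
load-dependent hazard for testability; daughters are not simulated as new
mothers (a lineage is one mother), though per-division exported counts are
recorded and conservation (copies created = kept + exported) holds exactly.

**Survival.** The survival curve is the fraction of lineages alive after g
divisions; the median lifespan is the sample median of uncensored lifespans
(midpoint rule on even splits) and is reported as undefined when half or
more of the lineages are censored at `max_generations`. With the defaults
the simulated load at 16 generations is several-fold larger at r = 0.96 than
at r = 0.83, qualitatively mirroring the measured several-fold ERC difference
between aged cohorts — the exact fold depends on the unpinned e and T, so no
numeric value is asserted. Southern-blot densitometry is summarized as the
ratio of summed band intensities between lanes.

## Synthetic cohorts (`budneck.synthetic`)

The generators produce already-extracted tabular quantities (no images) with
the statistical structure each analysis assumes; all are deterministic given
their seed, and noise enters observations only, so latent dynamics admit
exact oracles.

- **FLIP** (`gen_flip_traces`): discrete per-frame update — bleach pulse on
  the mother (fraction b removed), linear exchange of a fraction x of the
  inter-compartment difference across the bud neck, then global acquisition
  decay a on every cell including controls; background is added and Gaussian
  noise applied to reported values. Defaults: 4 s frames, 70 frames
  (≈4.7 min), b = 0.05, x = 0.01, a = 0.002, 4 controls, initial latent
  signal 1000 a.u. The discrete update (rather than a continuous ODE)
  matches pulses iterated at every frame and keeps a hand-iterable
  recurrence. x is capped at 0.5 because beyond that the linear step
  overshoots equilibration. Mother/bud volumes are equal by default; the
  `volume_ratio` knob ρ moves the exchange equilibrium to equal
  concentration (flux x·(B − M/ρ)) and conserves total latent signal for any
  ρ when a = b = 0.
- **Segregation** (`gen_circle_observations`): class mix (0.6, 0.3, 0.1)
  over 1/2/4-circle cells, independent per-circle bud passage with
  probability p_pass (default 0.04, the optimal-growth frequency), cells
  split round-robin over 3 replicate experiments.
- **Timelines** (`gen_timelines`): truncated-normal (>0) stage durations,
  defaults early 3.9 ± 1.0 min and late 14.5 ± 3.0 min (means as measured;
  the spreads are SEM-scale-compatible SDs chosen to give realistic per-cell
  variation), hazards 0.03 and 0.004 per circle·minute, one circle per cell,
  1-minute frames. Stage boundaries snap to the grid first (≥1 frame per
  stage); each circle's first passage runs on a continuous exponential clock
  within the snapped stages and is recorded at the ceiling frame, making
  stage attribution exact. At most one passage per circle (the assay scores
  first appearance), so the events/cell·minutes flux slightly underestimates
  the hazard — by (1 − e^{−hD})/(hD) ≈ 6% at the defaults, well inside the
  3-SE recovery band tested.
- **Rim profiles** (`gen_rim_profiles`): 64 positions, 8 quasi-regular NPC
  punctae (per-punctum jitter keeps inter-punctum offsets incoherent across
  cells so only the circle offset aligns), punctum amplitude 2× the baseline,
  Gaussian peak widths σ = 1.5 positions; an attached circle sits on a
  punctum, a detached one at the true midpoint between two punctae.

**What the generators do not emulate:** cell-to-cell variability of FLIP
kinetics (all dividing cells share one latent trajectory), circle return
from daughter to mother, copy-number-dependent replication, SPB signal in
the rim profiles, and any optics (PSF, pixel saturation). Passing tests
therefore demonstrate estimator correctness under the assumed data-generating
process, not robustness to real-microscopy artifacts.

## Problem sizes

Consistency checks use 10,000 cells (propagation frequency), 5,000 timelines
(flux recovery), 30 cells per point on a 5-point exchange-rate grid (BI
monotonicity), and 20,000 lineages over 16 generations (ERC recursion);
the full suite and the acceptance script each complete in seconds on one
core.

## Known limitations

- The BI standard error ignores correlation between mother and bud fits
  induced by shared controls; with 3–5 controls this term is small relative
  to fit uncertainty.
- The one-phase-decay fit can be poorly identified when the true curve is
  nearly flat over the movie; such fits surface through `converged`,
  large standard errors, or censoring rather than being rejected outright.
- The ERC simulator's e and T are free parameters; absolute lifespans and
  load ratios depend on them, so only qualitative orderings (monotonicity in
  r, growth factor (1+f)·r) are asserted.
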