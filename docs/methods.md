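# Model and methods

## The model

`hextumour` simulates the earliest stage of tumorigenesis as a discrete-time
cellular automaton on a bounded two-dimensional hexagonal lattice.  Space is a
hexagon-shaped canvas of radius *R* in axial coordinates `(q, r)` (so
`3R(R+1)+1` sites); every site has six direct neighbours and holds at most one
agent.  Three agent types exist:

* **cancer cells**, carrying a clone identity (1 or 2), an oncoprotein
  expression level, a base division rate *b* (divisions/hour) and a death
  rate *d* (deaths/hour);
* **cancer stem cells**, identical except that they are exempt from
  spontaneous death and their daughters remain stem cells only with a fixed
  symmetric-division probability `p_symmetric_division` (default 0.1);
* **immune cells**, which carry no oncoprotein and never die.

One step represents `dt = 1` hour, so rates act directly as per-step
Bernoulli probabilities (valid through the studied range `b ≤ 0.1`).  A cell
that divides places its daughter on the empty neighbouring site closest to
the canvas centre, ties broken uniformly at random; a cell with no empty
neighbour forfeits the attempt (no pushing).  Division is strictly local to
the parent's 6-neighbourhood and the canvas boundary is absorbing in the
sense that nothing can be placed beyond it — a large tumour eventually runs
out of space, and its per-step increment ΔN falls.

### Initialisation

Two clones are seeded as compact clusters of `n_cancer_per_clone + 
n_stem_per_clone` cells (default 10 + 2) whose centres sit
`clone_separation` sites apart (default 28), symmetric about the canvas
centre.  Oncoprotein is initialised with spatial autocorrelation by an MCMC
(Gibbs-style) sampler: for `oncoprotein_sweeps` sweeps, every occupied site
redraws its value from a normal law centred on the mean value of its
already-assigned occupied neighbours (the global prior `N(μ0, σ0)` when it
has none), truncated at zero.  Defaults `μ0 = 3.0`, `σ0 = 1.5`, 10 sweeps.
Because the sweep kernel re-centres on neighbour means, the stationary
marginal spread is wider than σ0; combined with the 1.25× oncoprotein
increment on mutualism (below), boosted cells usually cross the advantage
threshold of 4.

### Ecological rules

**Contact mutualism.**  Whenever a cancer cell of one clone is adjacent to a
cancer cell of the other clone, each not-yet-boosted member of the pair
gains, exactly once, a 1.25× increase of its instantaneous proliferation
rate and a 1.25× increase of its oncoprotein level.  The boost is per-cell,
never compounds, and is not inherited by daughters.  Contacts are resolved
simultaneously each step; boosting is monotone so the result does not depend
on iteration order.

**Random mutualism (null control).**  Instead of requiring contact, each
not-yet-boosted cancer cell converts independently with a per-step
probability — either a constant (3% mirrors the prevalence measured in the
contact model) or a per-step schedule replayed from a paired contact run
(the fraction of cells that are boosted with oncoprotein > 4 at each step).

**Immune predation.**  With predation enabled, every site of the lattice
ring at `immune_ring_radius` (default 40, i.e. 240 cells) holds an immune
cell.  All immune cells are inactive until the total cancer-cell count first
reaches `activation_threshold` (default 3000); activation is global and
irreversible.  Active, unattached immune cells step onto the empty neighbour
that reduces their distance to the (unweighted) centroid of the cancer
cells, if any.  An active immune cell adjacent to cancer attaches to one
uniformly chosen untargeted neighbour with probability 0.99 and is then
immobile; on any later step it kills the held target with probability 0.99,
after which it re-enters the movement/targeting pool.  A cancer cell is held
by at most one immune cell, and targeting and killing never occur in the
same step: each step executes the fixed phase order (1) activation check,
(2) kills, (3) immune movement, (4) new attachments, (5) spontaneous cancer
death, (6) division, (7) mutualism resolution, (8) statistics recording.
Within a phase, agents are visited in a seeded-shuffled order.

### Geostatistics

At every step the oncoprotein values on the occupied cancer-cell sites
(stem cells included, immune cells excluded) form a spatial field with
binary, non-row-standardised 6-neighbour adjacency weights `w_ij`:

* Getis-Ord general `G = Σ_{i≠j} w_ij x_i x_j / Σ_{i≠j} x_i x_j`, in
  `[0, 1]` for binary weights;
* Moran's `I = (n/S0) Σ w_ij z_i z_j / Σ z_i²` with `z = x − x̄`,
  `S0 = Σ w_ij`;
* Geary's `C = ((n−1)/(2 S0)) Σ w_ij (x_i − x_j)² / Σ z_i²`.

Undefined cases (fewer than two sites, zero variance for I and C, zero
cross-product for G, no adjacent pairs) are recorded as explicit NA, never
as 0.  The idealised Moran bound ±1 holds only approximately on finite
lattices; on contiguous tumour masses the package's property tests allow
±1.05, and arbitrarily sparse site subsets can exceed it (the spectral bound
grows like `n/S0`).

### Randomness and reproducibility

Each run derives nine independent child RNG streams (initial placement,
oncoprotein field, death, division, mutualism, random mutualism, immune
movement, targeting, killing) from the scenario seed via `SeedSequence`
spawning.  Disabling one behaviour therefore does not perturb the draws of
the others, which is what makes seed-paired comparisons exact under the
null.  `(config, seed)` fully determines a trajectory; CLI outputs are
byte-identical across repeats and carry a JSON manifest with config snapshot
and SHA-256 checksums.

## The experiment harness

Growth trajectories (per-step cancer counts) are compared with the
two-sample Kolmogorov-Smirnov statistic; p > 0.05 is read as "statistically
similar", matching the convention that the comparison of interest is
seed-paired (identical under the null).  Group comparisons use the
tie-corrected Kruskal-Wallis test (scipy) with Dunn's post-hoc pairwise z
tests (implemented here, with tie-corrected pooled variance and Bonferroni
multiplication over all pairs).  The sensitivity sweep runs, per division
rate and replicate, the ±mutualism × ±predation factorial and records the KS
distance of each predation/no-predation pair.  Replicate seeds derive from a
master seed and the (rate, replicate) key; the paired conditions of one
replicate share the seed for variance reduction.  "Higher growth trajectory"
is scored by the final cancer count (area under the curve available as an
alternative).

## Default parameters

| parameter | default | unit / meaning |
|---|---|---|
| `canvas_radius` | 50 | lattice radius (7651 sites); free parameter, undocumented in the source study |
| `division_rate` | 0.0461 | divisions/hour; experimentally grounded reference for NSCLC lines; swept 0.01–0.1 |
| `death_rate` | 0.005 | deaths/hour; half the smallest swept division rate |
| `dt` | 1.0 | hours per step |
| `max_steps` | 340 | steps (490 for the long-horizon malignant scenario) |
| `n_cancer_per_clone`, `n_stem_per_clone` | 10, 2 | seed cells per clone |
| `clone_separation` | 28 | sites between clone centres; calibrated so clones first touch around division rate 0.03 within 340 steps (no contact at ≤ 0.02, marginal at 0.025–0.03) |
| `mutualism_boost` | 1.25 | one-time proliferation multiplier |
| `oncoprotein_boost` | 1.25 | one-time oncoprotein multiplier (magnitude unstated in the source; mirrors the rate boost) |
| `oncoprotein_advantage_threshold` | 4.0 | boosted cells above this count as "advantaged" |
| `activation_threshold` | 3000 | cancer cells; immune activation gate |
| `target_probability`, `kill_probability` | 0.99, 0.99 | per adjacency / per held target per step |
| `immune_ring_radius` | 40 | ring sites hold one immune cell each (240); encloses the tumour at activation size (3000 cells ≈ radius 32) |

## What the simulations do and do not show

All experiments are self-generated: there is no external data, and the
"synthetic data" are the simulation runs themselves under the defaults
above.  The model is 2D, on-lattice and cell-scale: no molecular signalling,
diffusion, angiogenesis, cell morphology or off-lattice mechanics, and the
coupling of oncoprotein to birth/death rates is left as identity (rates are
set per scenario; oncoprotein is a tracked, spatially structured label whose
only dynamic role is the mutualism-advantage classification).  Passing tests
therefore demonstrate internal consistency of the rules and reproduction of
the study-scale summary statistics, not predictions about real tumours.

Two quantitative behaviours deserve explicit caveats:

* Because division is local and the seed clusters are small, growth is
  perimeter-limited and the 3000-cell activation gate is reached within 340
  steps only at division rates ≳ 0.07 (or at 0.1, around step 230).  At
  lower rates predation-on and predation-off runs coincide exactly.  The
  mutualistic compensation of predation at intermediate rates is accordingly
  a very small effect here, of the order of the replicate noise of the KS
  distance (±0.02); larger seed populations would activate the immune system
  earlier and amplify it.
* Activated immune cells contain the tumour partly by killing and partly by
  physically occupying boundary sites (single occupancy).  Even with
  targeting and killing probabilities set to 0, an activated immune shell
  measurably slows growth by crowding.

## Numerical and design choices

* Axial coordinates on a hexagon-shaped canvas; integer hex distance
  `(|dq|+|dr|+|dq+dr|)/2`, extended fractionally for centroid seeking.
* Ties (division placement, immune movement, target choice) broken uniformly
  at random from the owning phase stream.
* Truncation at zero throughout oncoprotein handling (rejection sampling).
* Division/death draws are vectorised per phase over the shuffled agent
  list; this is distributionally identical to per-agent sequential draws and
  deterministic given the seed.
* The acceptance script sizes its problems exactly at the defaults above:
  10 paired replicates across rates 0.03–0.08 for the mutualism-advantage
  fraction, one default contact-mutualism run for the advantaged-cell
  prevalence, a two-cell constellation for the boost ratio, and 100 random
  fields (n = 10–300) for the general-G bound.
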