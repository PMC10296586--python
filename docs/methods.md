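# Methods

This note documents the models implemented in `cortexmodes`, the choices
made where the underlying ideas leave the design open, and what the
package's synthetic experiments do and do not demonstrate.

## 1. Architecture: a network of networks

The cortex is modelled at two levels.

**Inner networks (columns).** A column is a directed graph of `n`
excitable–refractory neurons.  Every ordered pair `(i, j)`, `i ≠ j`, is an
edge independently with probability `density`; each edge carries a weight
(membrane-kick amplitude) and a *real-valued* transmission delay drawn
uniformly on `[τ_min, τ_max]` (default `[0.5, 2.0]` model time units).
Uniform delays are a modelling choice — the essential property is only
that delays are generic reals: with probability one no two are equal and
no integer combination vanishes, so distinct directed loops have
incommensurate periods.

**Outer network (cortex sheet).** Columns sit on a flat 2-D integer grid.
An ordered pair of columns at Euclidean distance `d` is connected with
probability `min(1, β·exp(−d/λ))`.  The exponential kernel is our choice
(a single interpretable length scale `λ`); a hard cutoff radius is
available as an option.  A `NetworkOfNetworks` attaches one column per
grid node and samples neuron-level bridges along outer edges with
probability `bridge_density`; bridge delays default to 2× the intra-column
range, reflecting longer axonal paths.  Both the kernel and the bridge
rule are stated defaults, not derived facts.

## 2. Spiking tier: exact event-driven leaky integrate-and-fire

Neurons are leaky integrate-and-fire with an absolute refractory period —
the simplest dynamics that are excitable and refractory without being
intrinsically oscillatory.  Membrane potential decays exponentially
toward rest with time constant `leak_tau`; an arriving kick adds the edge
weight instantaneously; crossing `threshold` emits a spike, resets the
potential and silences the neuron for `refractory` time units.  Kicks
delivered during the refractory period are discarded (not queued): the
simplest absolute-refractory semantics.

Integration is exactly event-driven.  Potentials are updated lazily in
closed form at event times; every spike schedules one delivery per
outgoing edge at emission time + delay, with no time grid.  The event
queue is ordered by `(time, edge id)`, externally forced kicks winning
ties; this tie-break is load-bearing for the unit-delay experiment, where
coincident arrivals ("dead heats") are the object of study.  The inner
loop is compiled with numba; a simulation with ~10⁶ deliveries takes on
the order of a second.

## 3. Clock tier: generalised Kuramoto with delayed phase-resetting maps

A column is abstracted as a *k-dimensional clock*: `k` phases in
`[0, 2π)` winding at constant positive rates, i.e. a linear flow on a
k-torus.  Clocks are coupled by directed edges with three attributes:

* **trigger** — a designated sender phase and crossing value; each upward
  crossing emits a signal.  A single-phase upward crossing is the
  simplest edge-parameterisable condition with closed-form next-crossing
  times.
* **delay** — real-valued transmission time.
* **PRM** — an additive phase-kick vector applied to the receiver's
  phases on arrival (mod 2π): the simplest instantaneous map on the
  torus.  The PRM is isolated behind one function so richer maps can be
  substituted.

Integration is again exact and event-driven: phases wind in closed form
between events; emission times are computed analytically; after an
emission, the next crossing of the same trigger is exactly one revolution
later (computing it from the floating-point phase can round to a zero
advance, so the period is added directly).  Stale emissions caused by
intervening kicks are invalidated by per-clock version counters.

External stimulation acts through the same mechanism as internal
signals: a forced spike applies a kick of `ext_kick` radians to every
phase of the target clock.  The default is 1.0 rad, deliberately
*incommensurate with 2π*: a kick that divides 2π evenly (π/2, say) makes
an entire periodic forcing history sum to full turns and vanish from the
state, erasing exactly the memory the preconditioning analysis measures.

Winding rates default to log-uniform in `[0.5, 2.0]` rad/unit so that no
single rate scale dominates.  `build_clock_network(shared_rates=True)`
gives every clock the same rate vector; relative phase patterns imprinted
by a stimulus are then preserved indefinitely by free winding, which is
the configuration used for preconditioning (where the state must carry
memory).  `k` defaults to 10 per clock, the order of magnitude expected
for full-size (n ≈ 10⁴) columns; desk-scale fixtures use k = 3.

## 4. Estimating k: correlation dimension of recorded activity

`estimate_k` measures the number of dynamical degrees of freedom in a
recording:

1. reduce the channels × bins rate matrix to its first principal
   component (one generic scalar observable suffices for embedding);
2. z-score (making the estimate affine-invariant by construction) and
   delay-embed with `embed_dim` coordinates; the lag defaults to the 1/e
   autocorrelation time;
3. compute Theiler-excluded pairwise distances (default window: 10× the
   embedding lag — large enough that consecutive trajectory segments,
   which look one-dimensional, never enter the pair statistics);
4. extract the Grassberger–Procaccia correlation-dimension slope by the
   Takens maximum-likelihood form over the automatically selected
   scaling range `r ≤ r0`, where `r0` is the radius at which the
   correlation sum reaches `c_cut = 0.01`.  The ML form uses every pair
   below `r0` rather than a handful of grid points, which matters at
   desk-scale data sizes;
5. `k_hat` is the slope rounded to the nearest integer, clipped at 0.

When more points are available than `max_points` (3000), a seeded
*random* subsample is used: a uniform stride aliases against the winding
frequencies of quasi-periodic signals and visibly distorts small-distance
statistics.

Ground truth for the estimator is the `torus_signal` family: sums of
`j ∈ {1, 2, 3}` unit sines at frequencies (1, √2, √5) with random phases.
Records of 400 time units at dt = 0.05 suffice for j ≤ 2; j = 3 uses
1200 time units because torus filling, and hence the data requirement,
grows exponentially with dimension.  This same data requirement is why
estimating k ≈ 10 directly (n = 10⁴ columns) is out of desk-scale reach,
and why the scaling study below runs at n ≤ 800 where true k is small.

## 5. The column studies: operating regime

A desk-scale column cannot be run at n = 10⁴ with realistic density, so
the studies use a regime chosen to make k well-defined, resolvable, and
mechanistically transparent:

* mean out-degree 1.2 (density `1.2/(n−1)`), single-kick suprathreshold
  weight 1.1, threshold 1, `leak_tau` 0.5, refractory 2.0;
* stimulation: half the neurons kicked during `[0, 3)`, then 5% of the
  neurons re-kicked every 250 time units ("sustained stimulation" that
  re-seeds activity which has died out, at deterministic seeded times,
  without injecting continuous noise; the count scales with n so the
  per-capita drive is size-invariant);
* recordings of 4200 time units, binned at 0.5 with a 0.75 Gaussian
  kernel; the first 300 units (transient) are discarded; a column's k is
  the median of three disjoint-window estimates, which suppresses
  single-window estimator noise.

In this near-critical sparse regime, sustained activity consists of spike
packets circulating on directed loops.  Each surviving loop contributes
one phase-like degree of freedom with period equal to its real-valued
delay sum; distinct loops are incommensurate, so the collective dynamics
is a torus winding whose dimension counts the active independent loops.
This is exactly the structure the clock abstraction posits, and it is the
regime where "k counts the longish, mutually independent cycles" is a
literal description of the attractor.  The number of such loops in a
sparse random digraph grows with n (at fixed mean degree), producing the
logarithmic-like growth of mean k̂ with n that the scaling study
measures.  Dense columns driven hard at desk scale either die or
saturate into noise-like microstates whose correlation dimension pins at
the embedding capacity — they do not exhibit a resolvable low-dimensional
attractor at these sizes, which is why the studies run in the sparse
regime.

Caveats: per-column k̂ has substantial seed-to-seed dispersion (loop
counts of near-critical random digraphs are highly variable), so the
study reports means over 10 replicates per size; with four sizes the
monotonicity of the mean curve can occasionally be broken by an unlucky
ensemble.

**Unit-delay quench.** The same column is simulated twice per seed —
once as generated, once with every delay forced to 1.0.  Under unit
delays every loop period is an integer: all frequency ratios are
rational, equal-hop parallel walks arrive coincidentally, and the torus
collapses toward a periodic orbit; k̂ drops sharply (typically from 2–4
to 0–1).  Coincidence itself is quantified by
`count_distinct_arrival_times`, which counts distinct delivery
timestamps per neuron (rounded at 1e−9) — on the two-parallel-path
fixture the count at the junction is exactly 2 under real delays and 1
under unit delays.

## 6. Mode discovery

**Batteries.** `run_experiment_battery` simulates `reps` runs of each
stimulus regime with sub-seeds derived from (master seed, regime, rep).
Clock responses are recorded as sin-of-phase channels; spiking responses
as smoothed rates.  The clock battery fixture records the *steady-state*
window `[48, 98]` of a 98-unit run, so that a record contains the
regime's sustained response (including in-flight internal signals) rather
than the rest-to-driven transient; this matters for preconditioning,
where primed responses must be comparable to the battery's records.

**Dissimilarity.** `d = 1 − max_ℓ corr(r1, shift(r2, ℓ))` over integer
bin lags `|ℓ| ≤ max_lag`, Pearson correlation of the flattened
units × time matrices on the overlapping window.  Offset tolerance
implements the principle that relative firing patterns matter, not
absolute time.  Zero-variance windows correlate 0 (distance 1) unless
the raw windows are identical (distance 0), preserving identity while
avoiding 0/0.  The matrix assembly standardises all records per lag and
uses one matrix product per lag — identical to the pairwise definition
(tested to 1e−10) but fast enough for permutation nulls.

**Hierarchy.** Average-linkage agglomerative clustering (scipy) of the
dissimilarity matrix; requested levels are dendrogram cuts, so coarser
clusters are exactly unions of finer ones.  Each cluster's *medoid* is
its member with minimal summed within-cluster dissimilarity.

**Significance.** Because hierarchical clustering always "finds"
clusters, mode structure is tested against surrogates: each record's time
axis is independently circularly shifted by a uniform random offset,
which destroys cross-record relative timing while preserving each
record's marginal distribution and autocorrelation.  The statistic is the
between-minus-within cluster contrast at the chosen cut, recomputed from
scratch (including re-clustering) per surrogate;
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`.  On iid-noise batteries the
rejection rate at α = 0.05 is nominal (≈ 0.04 with 49 permutations).

**Competition.** `mode_exclusivity` maps a windows × modes activation
distribution to `1 − mean(H/log M)`: 1 when exactly one mode is active
per window, 0 under uniform co-activation.  Exclusivity is *measured*,
not enforced — no mechanism in the model forbids co-activation.

**Preconditioning.** The operational question: does priming the network
with mode A's stimulus bias the interpretation of a subsequent ambiguous
stimulus toward mode A?  Both arms run as one continuous simulation —
priming regime (or silence) during `[0, t_prime)`, then the ambiguous
stimulus (by default the union of two regimes' forcings) — and only the
response window is scored, by nearest-medoid assignment under the same
dissimilarity.  A continuous run, rather than restarting from a copied
phase state, keeps priming-era signals still in flight on delayed edges.
The effect is carried by the phase state: with shared winding rates and
an external kick incommensurate with 2π, a clock's phase encodes its
forcing history, so primed-A runs reproduce the A-records' channel
waveforms almost exactly while unprimed runs match them only at chance.
The report gives assignment distributions, the mean
`P(assigned = primed mode | primed)` (the exclusivity index, in [0, 1]),
and the entropy reduction in bits (negative values reported as-is).
Weak internal coupling (`kick_scale = 0.1`) is used in the
preconditioning fixture because strong recurrent kicks amplify
trial-to-trial jitter chaotically and wash out the state's imprint.

## 7. What the synthetic experiments do and do not show

The generators emulate the *architecture* (dense-in-sparse-out
connectivity, range dependence, generic real delays) and the *protocols*
(observed-unit recordings, stimulation batteries, reverse-engineering by
clustering).  They do not emulate biological neuron diversity, synaptic
plasticity, conductance dynamics, or cortex-scale sizes; passing tests
show that the package's machinery measures what it claims on systems
where ground truth is constructible — not that any specific k or mode
count holds for a real cortex.  Full-scale configuration arithmetic (10⁶
clocks × 10 phases = 10⁷ state variables; 10¹⁰ neurons at one phase
each) is reproduced as arithmetic, not simulated.

## 8. Numerical conventions

* Continuous time, dimensionless model units throughout.
* Event ties broken by `(time, edge id, kind)`; external events first.
* Delivery exactness: arrival = emission + delay to float precision;
  tests assert ≤ 1e−9.
* Phases always reduced mod 2π on storage; sampled phases in `[0, 2π)`.
* Dead-heat timestamp comparison after rounding to 1e−9 time units.
* Times serialised with 17 significant digits (`%.17g`) and parsed in
  round-trip mode, so CSV/JSON round trips are bit-exact.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; batteries and studies derive per-cell
  sub-seeds from (master, cell indices).
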