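# Methods

## Model

`chimeranet` simulates two intra-connected networks of identical
FitzHugh–Nagumo (FHN) oscillators — layers A and B, standing for the two
cortical hemispheres — joined by a sparse set of inter-layer links that
stands for the corpus callosum.  Node `i` of layer A obeys

    eps * du_i/dt = u_i - u_i^3/3 - v_i
                    + (lambda_in / k_in,i)  * sum_j A_ij  [d_uu (u_j - u_i) + d_uv (v_j - v_i)]
                    + (lambda_out / k_out,i) * sum_j AB_ij [d_uu (u_j^b - u_i) + d_uv (v_j^b - v_i)]
        dv_i/dt = u_i + a
                    + (lambda_in / k_in,i)  * sum_j A_ij  [d_vu (u_j - u_i) + d_vv (v_j - v_i)]
                    + (lambda_out / k_out,i) * sum_j AB_ij [d_vu (u_j^b - u_i) + d_vv (v_j^b - v_i)]

with the mirrored equations for layer B.  The coupling mixes fast- and
slow-variable differences through the rotational matrix

    D(alpha) = [[cos alpha, sin alpha], [-sin alpha, cos alpha]],

parameterized by the coupling phase `alpha`; values near `pi/2` make the
coupling nearly cross-diagonal, the regime known to destabilize uniform
synchrony and favor chimera states.  Coupling input is averaged over
neighbors (division by the intra-/inter-degree); a node without neighbors
of one kind receives no input of that kind — the empty average is null
input, not a division by zero.

Parameters and defaults:

| parameter   | meaning                               | default       |
|-------------|---------------------------------------|---------------|
| eps         | fast/slow timescale separation        | 0.05          |
| a           | excitability; oscillatory iff \|a\|<1 | 0.5           |
| alpha       | coupling phase (rad), in (-pi, pi]    | scenario-set  |
| lambda_in   | intra-layer coupling strength         | scenario-set  |
| lambda_out  | inter-layer coupling strength         | scenario-set  |

All time is dimensionless model time.

## Numerics

Integration is fixed-step classical RK4.  The default step `dt = 0.01`
resolves the fast timescale (eps = 0.05) with ~20 steps; halving the step
changes sampled trajectories by well under 1e-4 RMS on test problems (this
is asserted in the suite).  The integrator is fully deterministic; the only
randomness in a run is the seeded initial condition, i.i.d. uniform on
[-2, 2] for every u_i and v_i, a range that brackets the FHN limit cycle
(u-amplitude about ±2).  Integration aborts with a diagnostic naming the
step if any |u| exceeds 1e3.

A run discards a transient `t_trans` before measuring for `t_measure`,
sampling every `sample_every` time units (defaults 1000 / 2000 / 0.5).  The
simulation-heavy tests and the acceptance script use `t_trans = 500` and
`t_measure = 1000`, sizes at which mean firing counts are still in the
hundreds per node and a full inter-link ladder completes in minutes; the
reported regime structure was checked to be unchanged at the longer
defaults.

## Observables

**Firing count and mean phase velocity.** A firing is an upward crossing of
u through a threshold (default 0; FHN spikes traverse about -2 to +2, so
any mid-range threshold counts the same events).  The mean phase velocity
of node `i` is `omega_i = 2*pi*M_i / DT` with `M_i` the firing count over
the window `DT`.  A warning is raised when the mean count falls below 50,
the point where omega profiles become visibly quantized.

**Velocity-sorted index.** A complex network has no spatial embedding, so
each layer's nodes are re-indexed by ascending omega (stable sort, layers
sorted independently) before any profile or "spatial" coherence is read.
The permutation is computed once per run and frozen across snapshots.  In a
chimera state the frequency-locked subpopulation then appears as an omega
plateau adjacent to a spread of drifting frequencies.

**Spatial coherence g0 / g1.** For one snapshot of one layer, the discrete
curvature `d_i = u_{i+1} - 2 u_i + u_{i-1}` is taken along the sorted index
(endpoints excluded) and `g0` is the fraction of interior nodes with
`|d_i| < delta_rel * D_max`, `delta_rel = 0.01`.  For the standalone
single-snapshot function, `D_max = 4 * (max u - min u)` of that snapshot.
When scoring a run, `D_max` is instead fixed from the layer's u range over
the *whole* measurement window — the attractor amplitude.  The distinction
matters only for states whose spatial spread collapses far below the
oscillation amplitude: a per-snapshot scale would re-amplify the numerical
residue of a fully synchronized state and score it incoherent, while the
run-level scale correctly gives g0 = 1.  `g1` is the time average of g0 and
classifies the layer: synchronized for g1 > 0.95, disordered for g1 < 0.05,
otherwise "partial synchronization" — a deliberately neutral term that does
not distinguish chimera states from cluster synchronization, since the
binarized curvature measure cannot separate the two when many small
synchronized clusters create many incoherent boundary nodes.  The
thresholds are configurable; the limiting values (1 for full synchrony,
near 0 for incoherence) are the model-independent anchors.

The binarized measure has a combinatorial noise floor: for independent
random phases on the FHN cycle, about 4–5% of interior triples happen to
have small curvature, so even an ideally disordered state scores g1 of
roughly 0.05 rather than exactly 0, and weak coupling raises this floor
further (measured ~0.07 at lambda_in = 0.1, lambda_out = 0.3 on the
synthetic network).  "Disordered" labels at the 0.05 threshold are
correspondingly conservative.

## Synthetic modular networks

Each subnetwork starts as an Erdos–Renyi G(n, m) graph with n = 200 nodes
and m = 1000 edges (mean degree 10) and is rewired by degree-preserving
double-edge swaps: a proposed swap is accepted only if it keeps the graph
simple and strictly increases the average local (Watts–Strogatz) clustering
coefficient, until C reaches the target 0.7.  Acceptance is monotone by
construction, the degree sequence is conserved exactly, and the walk is
seeded and reproducible.  Near the target the acceptance rate drops
sharply, so the default proposal budget is generous (5e6; reaching C = 0.7
from C ≈ 0.05 takes about 1e6 proposals and ~10 s).  Connectivity is not
enforced during rewiring; a post-check warns if the giant component covers
less than 95% of nodes (the shipped seeds stay connected).  The two layers
are then joined by exactly `l_out` inter-layer links chosen uniformly
without replacement among all cross pairs.  For sweeps along the `l_out`
axis the link sets are nested (a larger count contains the smaller one,
drawn from one seeded permutation of all cross pairs), so the axis is not
confounded by independent link realizations; this can be switched off.

What the generator does and does not emulate: it reproduces the high local
clustering (C = 0.7) and sparse inter-layer bridging of cortical
connectivity, but not the degree heterogeneity, spatial geometry, weighted
fibers or hemispheric asymmetry of a real connectome.  Greedy clustering
maximization also produces strongly modular graphs (communities of ~10–40
nodes; Newman modularity ~0.7 for the shipped seeds).  Consequences for
transferability are discussed below.

## Synchronization borderline theory

At the border of the synchronized region the state differences
`du = u_j - u_i`, `dv = v_j - v_i` are treated as non-zero constants, giving
the total-coupling constant `y = (lambda_in + lambda_out) *
[cos(alpha) du + sin(alpha) dv]` and the borderline

    lambda_out(alpha) = y / (cos(alpha) du + sin(alpha) dv) - lambda_in.

Over alpha the curve is a strictly convex arc on the branch where the
denominator is positive, with minimum at `alpha* = arctan(dv/du)`; at fixed
alpha it decreases linearly in lambda_in with slope -1; scaling (du, dv, y)
together leaves it unchanged.  `du`, `dv` and `y` are free inputs (defaults
3.0, 0.5 and the family 1.0/1.5/2.0 with lambda_in = 0.1); the theory is
not closed against simulation, which also means no procedure is provided to
fit y to an observed boundary.  The default alpha grid spans the
positive-denominator branch clipped to (-pi/2, pi/2); the singular
direction `alpha = arctan(-du/dv)` raises an error rather than being
clipped.

## Design choices made where the design was open

- **Firing definition**: upward zero-crossing of u.  Any threshold between
  the FHN branches gives identical counts; configurable.
- **Sorted-index curvature**: g0 is computed along the omega-sorted index
  (not the raw index, not all pairs).  This affects the magnitude of g0 in
  partial states but not its limiting values.
- **Snapshot variable**: u (the fast variable) is used for coherence; v
  gives qualitatively identical classifications in spot checks.
- **Classification thresholds** 0.05 / 0.95: symmetric about the limiting
  values, configurable.
- **Sweep resumption**: completed grid points are keyed by grid indices and
  replicate number in the output CSV and skipped on restart; an interrupted
  and resumed sweep is asserted to equal an uninterrupted one.
- **Tie-breaks**: equal-omega nodes keep their original relative order
  (stable sort), so permutations are deterministic.

## Known limitations

- The model is unweighted and undirected; chemical synapses, transmission
  delays, noise, and mean-field (population) node models are out of scope.
- The coherence measure saturates: states with many small synchronized
  clusters and states with one large coherent core can give similar mid-range
  g1.
- Quantitative regime boundaries on *synthetic* networks are sensitive to
  the topology realization.  On the shipped N = 200, C = 0.7 realizations,
  inter-layer links stabilize the synchronized state exactly as the theory
  predicts (the transverse growth rate of a perturbation off the
  synchronized manifold falls by orders of magnitude between l_out = 100
  and 300), but capture from random initial conditions into full synchrony
  at lambda_in = 0.6, lambda_out = 0.5 occurs at a few hundred inter-links
  more than on the cortical network the canonical value of ~200 was read
  from.  Likewise, at l_out = 100 only ~40% of nodes carry any inter-link,
  so the strong-inter-coupling chimera scenario (lambda_in = 0.1,
  lambda_out = 1.8) leaves most nodes effectively uncoupled and produces a
  low-coherence partial state without a broad frequency plateau, unlike on
  the densely bridged cortex network.  Tests assert the mechanisms
  (stability trend, existence of the transition, strong-coupling synchrony)
  and report the realization-dependent boundary locations as measured.
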