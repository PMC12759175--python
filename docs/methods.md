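# Methods

## Model

A riverscape is a forest of dendritic trees. Reaches are nodes carrying a
positive length (km) and a catchment id; flow direction is encoded by a
single downstream pointer per reach, and the one reach per catchment without
a pointer is the outlet. Edges are either confluences (passability 1 both
ways) or barriers — natural waterfalls or anthropogenic dams, existing or
planned — with independent upstream and downstream passabilities in [0, 1].
Braided channels, lateral floodplain connectivity and hydrodynamic routing
are out of scope: the graph must be a tree per catchment, which is what
next-down river topologies provide.

Dispersal between reaches *i* and *j* is the product of the passabilities of
the barriers on the unique tree path, each taken in the direction of travel
away from the focal reach (`outgoing` mode). This makes connectivity
asymmetric: a downstream reach sees its upstream neighbours through their
upstream passabilities and vice versa. A `symmetric` mode replaces both
directions of each barrier by the geometric mean √(p_up·p_down).

RCI is the length-weighted mean of these products over all reaches of the
focal reach's catchment, self term included (c_ii = 1), so RCI ∈ (0, 1] and
equals 1 exactly when no barrier intervenes. RCIsuit multiplies RCI by
group-mean habitat suitability. CCI aggregates RCI over a catchment with
suitability weights; dCCI_m is the percent increase in CCI when barrier *m*
alone is made fully passable (topology intact — equivalent to deletion for
these indices, and simpler). Barrier removal candidates default to
anthropogenic barriers: waterfalls remain in the network as natural
fragmentation during every evaluation and can be added to the candidate set
with a flag.

## Algorithm

The production RCI is a two-pass dynamic program on the tree rooted at the
outlet. The downward pass accumulates, per node v, S(v) = Σ_{j∈subtree(v)}
c_vj·w_j via S(v) = w_v + Σ_children p_up(edge)·S(child); the upward pass
propagates the out-of-subtree complement U(v) = p_down(edge)·(F(parent) −
p_up(edge)·S(v)) with F = S + U, giving RCI_v = F(v)/W. This is exactly the
pairwise enumeration factored along the unique tree paths — O(n) instead of
O(n²) — and the test suite requires agreement with a brute-force
path-enumeration oracle to 1e-12. Traversals are iterative (explicit
stacks), so chain-like networks thousands of reaches deep do not hit
recursion limits.

Ranking uses average ranks for ties and is invariant to candidate
enumeration order; mean ranks across scenario cells are reported to two
decimals.

## Parameters

| parameter | default | meaning |
|---|---|---|
| dam passability | 0.1 up / 0.4 down | expert judgment for low fish-passage efficiency at tropical dams; downstream passage also disrupted (reservoir residence, turbine mortality) |
| waterfall passability | 0.1 up / 0.7 down | natural falls are easier to drift down than to climb |
| confluence | 1 / 1 | junctions impose no resistance |
| CCI weight | suitability | literal reading of suitability-weighted aggregation; `suitability_length` option multiplies by reach length, mirroring the RCI weights |
| RCIsuit layer | continuous consensus | mean of retained-model suitabilities; a binary option (fraction of species present) is exposed |
| AUC filter | > 0.8 | ensemble models at or below 0.8 are dropped before consensus; a species with no survivor is excluded with a warning |
| binarization | max sens+spec, rule ≥ t | smallest maximizing threshold on ties |
| consensus | strictly > m/2 of m models | majority rule |

Per-barrier passability overrides take precedence over values in the barrier
table, which take precedence over the kind defaults.

## Sensitivity analysis

Passabilities are expert-elicited, so RCI is recomputed under multiplicative
perturbations of the barrier defaults — the grid {±10%, ±25%} × {up, down,
both}, clipped to [0, 1] — plus a restrictive scenario forcing dam upstream
passability to 0. Suitability is held fixed. Each scenario is compared with
the baseline by Pearson correlation over reaches and a paired two-sided
Wilcoxon signed-rank test with zero differences dropped (the common
default; the Pratt variant was not needed). All-zero-difference scenarios
are flagged degenerate with r = 1, p = 1; a constant RCI vector leaves r
undefined (NaN) and is flagged. The perturbation is multiplicative because
passabilities are ratio-scale quantities near the low end of [0, 1];
additive perturbation would leave the ±0.25 band clipping at zero for the
0.1 defaults.

## Synthetic riverscapes

The generator exists so the whole pipeline runs with no external data. It
emulates, at desk scale, the features the analysis relies on:

- **Topology**: a dendritic tree grown from the outlet; each step extends a
  headwater tip or, with probability 0.35, branches off a reach with one
  upstream neighbour (confluences are binary). Lengths are log-normal
  (meanlog 1.5, sdlog 0.6 km — median ≈ 4.5 km, right-skewed like
  mid-order reach inventories).
- **Barriers**: 5 waterfalls, 30 existing and 25 planned dams per 500
  reaches by default — a deliberately denser portfolio than a whole-basin
  average, matching a heavily developed sub-basin so that fragmentation
  signal is present at small n. Placement is uniform over reaches (interior
  placement splits the host reach at a uniform fraction in [0.2, 0.8]);
  `mainstem_biased` up-weights mainstem reaches tenfold. The optional
  planted "super-barrier" is an impassable dam on the confluence cutting
  total river length most evenly — by the product form of the indices this
  balanced cut, not the largest subtree, is the one that fragments the
  basin most, and exhaustive subtree search locates it.
- **Suitability**: per species, a latent Gaussian field propagated
  outlet-to-headwater with lag-1 autocorrelation 0.8 plus a species offset
  (sd 0.6), squashed by a logistic. Future cells subtract a drift linear in
  epoch index with climate-specific slope (moderate 0.2, pessimistic 0.45
  per step), so mean suitability declines monotonically and fastest under
  the pessimistic scenario. Groups default to 27 migratory + 25 sedentary
  species; the combined group is the mean over all 52.

What the generator does **not** emulate: real basin topology and reach-length
correlation with stream order, spatial clustering of dams in particular
sub-basins, species-specific range boundaries, or any covariance between
suitability and barrier placement. Passing tests therefore demonstrate the
correctness and robustness of the indices and procedures, not basin-specific
numerical results, which require the real network, barrier inventory and
fitted distribution models.

## Numerical choices

- Exact agreement with the oracle is required to 1e-12 (absolute, on indices
  of magnitude ≤ 1); float summation order makes barrier-free RCI equal to
  1 only to machine epsilon, so tests compare with tolerances, never `==`.
- Splitting a reach for an interior barrier conserves total length exactly;
  several barriers on one reach are applied upstream-first with fractions
  renormalized to the shrinking remainder. Two barriers at exactly the same
  fraction are separated by a 1e-9 relative sliver reach so they become
  consecutive links (the passability product is order-independent).
- Reaches missing from a suitability layer contribute weight 0 to CCI
  (unsuitable-by-omission) rather than being dropped.
- dCCI on a multi-catchment network is evaluated for the catchment
  containing the barrier.
- All generators draw from named substreams spawned from one master seed, so
  every output is bit-reproducible given (config, seed).

## Problem sizes

The test suite and the acceptance script run riverscapes of 20–2,000
reaches: 100 networks of ≤ 30 reaches for oracle equality, 300-reach
networks for planted-barrier recovery, 500-reach/35-barrier networks for the
perturbation analysis, and one 2,000-reach, 100-barrier network for the full
24-cell scenario grid with ranking. These sizes exercise every code path,
including deep chains and multi-catchment inputs, while keeping the whole
suite in the low minutes on a single CPU; the linear-time RCI recursion is
the reason basin-scale networks (tens of thousands of reaches) remain
practical.

## Known limitations

- Connectivity is structural: no dispersal kernels, distance decay, or
  time-dependent movement; indices weight by habitat amount (length ×
  suitability), not population dynamics.
- Leave-one-out ranks barriers individually; portfolio effects (two dams in
  series sharing impact) mean the top-k individually ranked barriers are not
  necessarily the optimal k-subset. Joint optimization is out of scope.
- The Wilcoxon test treats reaches as independent paired observations;
  spatial autocorrelation of RCI differences makes its p-values liberal.
  It is used descriptively, as a screening statistic.
- Suitability layers are taken as given (or synthetic); fitting the
  distribution models themselves is out of scope.
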