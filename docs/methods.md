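# Methods

## Generalized modularity with a polymer null model

Communities are found by maximizing

    Q = (1/2m) * sum_{i != j} (A_ij - gamma * P_ij) * delta(g_i, g_j)

over partitions `g`, where `A` is the (usually KR-balanced) contact
matrix, `k_i = sum_j A_ij`, `2m = sum_i k_i`, and `gamma > 0` sets the
scale of the communities (larger `gamma`, smaller communities). `Q` is
bounded in [-1, 1]. Self-contacts are excluded throughout: `A_ii` is
zeroed before balancing and detection, and both null models are defined
and normalized over `i != j` only. For the Newman–Girvan (NG) null
`k_i k_j / 2m` this diagonal-exclusion convention means
`sum_{i != j} P_ij` falls short of `2m` by `sum_i k_i^2 / 2m`; the NG null
is retained only as a baseline. The fractal-globule (FG) null

    P_ij = 2m * k_i k_j |i-j|^(-alpha) / Z,   Z = sum_{i'!=j'} k_i' k_j' |i'-j'|^(-alpha)

sums to `2m` exactly by construction, which gives the useful identity
`Q(single community) = 1 - gamma` for every map — used as a machine-
precision self-test. `alpha` defaults to 1 (the decay seen in megabase-
scale Hi-C and in fractal-globule polymers) but is a free parameter.

Genomic distances `|i - j|` are always computed on original bin indices;
masked (unmappable) bins are removed from all sums and re-inserted with a
sentinel label, never by compacting indices — distance decay is physics,
not an artifact of masking.

## Optimization

A Louvain scheme operates on the dense gain matrix `B = A - gamma*P`
restricted to unmasked bins: seeded-shuffle sweeps of greedy single-node
moves (ties broken toward the lowest community id; a pass that improves
total Q by less than 1e-10 stops the phase) followed by aggregation of `B`
over community blocks. Aggregating `B` itself sidesteps the fact that
`|i - j|` is undefined between super-nodes: the FG null is evaluated once
at the finest level, so `Q` is exact across levels. The best of
`n_restarts` independently seeded runs is returned, and the result is
floored at the all-in-one and all-singletons partitions, so
`Q >= max(1 - gamma, 0)` under the FG null. Runs are deterministic given
the seed. Resolution scans are independent per `gamma`; no hierarchical
nesting is imposed or implied.

On all fixture graphs with <= 10 nodes the returned `Q` is verified in the
test suite against exhaustive enumeration of all set partitions.

## KR balancing

Matrices are balanced with the Knight–Ruiz inner-outer Newton iteration
(conjugate-gradient inner solves, cone safeguards delta = 0.1, Delta = 3),
to residual 2-norm 1e-7, giving row/column sums within 1e-6. Rows that
sum to zero are masked first; failure to converge within 300 outer
iterations or 20000 matrix-vector products raises, which in practice
signals a structurally unbalanceable support. An independent Sinkhorn
alternating-scaling oracle cross-checks the result in the tests.

## Fractal-globule simulator

Growth is a conformation-dependent polymerization on the simple cubic
lattice: each unoccupied neighbour of the head is weighted
`1 + A * n`, where `n` counts its occupied neighbours *excluding the
head* (every candidate touches the head, so including it would reduce the
rule to weak n-proportionality; excluding it makes `A = 1e4` a strong
surface-adhesion bias, which is what produces compact space-filling
growth). Occupied neighbours carry weight `epsilon = 1e-4` and are
rejected-and-resampled when drawn. On trapping the walk backtracks up to
10 monomers, then restarts (at most 100 times). Growth is unconfined by
default; a confining cube is available and fills reliably up to ~0.85
site occupancy (complete filling of an exactly-sized box is not reachable
with this bounded-backtrack rule and raises instead).

Measured at N = 4096 over 20-chain ensembles: end-to-end exponent
~0.35 (space-filling 1/3), contact-probability exponent ~ -0.94 over
s in [8, 512].

## Equilibrium-globule reference

A self-avoiding walk confined to a sphere, sampled by a symmetric-proposal
Monte Carlo mixing slithering-snake reptation (80%) with kink flips and
end rotations (20%), which is uniform over confined self-avoiding walks.
The default budget of `15 N^2` attempted moves spans several reptation
renewal times; fitted exponents are unchanged between `8 N^2` and
`25 N^2`.

The confinement radius defaults to the sphere holding N monomers at
site-filling fraction 0.25. This is a deliberate numerical choice: the
radius-of-gyration-derived conventions (`radius_from_fg`) prescribe fewer
lattice sites than monomers at every N and cannot host an on-lattice
chain, and denser feasible spheres (fill 0.5-0.8) push the confinement
plateau of R(s) into the intermediate-s window, hiding the ideal-chain
`s^(1/2)` regime the reference exists to exhibit (measured fitted
exponents over [8, N^(2/3)] at N = 4096: 0.45 at fill 0.25, 0.39 at 0.5,
~0.33 at 0.8).

## Contact registration and annealing

Off-lattice snapshots are produced by bond-preserving moves: interior
monomers rotate about the axis through their bonded neighbours
(crankshaft), ends rotate about their single neighbour; the rotation
angle is capped so the displacement stays below `displacement_scale`
(default 1 lattice unit) and moves violating a hard-core diameter of
`0.8 * bond_length` are rejected. Each snapshot follows one sweep
(N attempted moves) by default. A pair (i, j) scores one contact per
snapshot with distance strictly below the threshold, default three
lattice spacings (the community structure is insensitive to +/-50%
changes of this threshold). Counts aggregate over snapshots; the diagonal
is zero.

## Fitting conventions

Power-law exponents are least-squares slopes of log-log data restricted
to intermediate separations, default `s in [8, N^(2/3)]` for R(s) (below
8: lattice discreteness; above N^(2/3): finite-size saturation) and
`s in [8, 512]` for P(s) at N = 4096. P(s) points are averaged within
logarithmic bins (8 per decade) before fitting so every scale carries
equal weight. R(s) is evaluated on a log-spaced grid of integer
separations; community-segment curves take one observation per contiguous
segment (distance between its two boundary monomers at s = segment length
in bonds) and are binned onto the same grid. When comparing segment and
all-subchain curves, bins require at least 5 segment observations and
s >= 2, since at s = 1 both distances equal the bond length identically.

## Synthetic data: what it does and does not emulate

The simulator reproduces the contact-decay and end-to-end scaling laws,
compactness and non-contiguity of communities, and the masking/balancing
pipeline of real Hi-C — enough to validate the detection machinery
end-to-end. It does not emulate loop extrusion or CTCF-anchored loops,
cell-population averaging, distance-dependent noise, copy-number or
mappability biases, or inter-chromosomal contacts. Passing tests
therefore certify the algorithmic contracts, not biological discovery on
real data; external matrices, TAD/CTCF BED references and bedGraph tracks
are first-class inputs for that purpose.

## Problem sizes used in validation

Full-scale checks use 20-chain ensembles at N = 4096 with 100 annealed
snapshots per chain; community-level analyses (compactness comparison)
use a 10-chain subset at `gamma = 0.4`, and the resolution-monotonicity
check uses ten N = 512 maps — sizes chosen to keep the suite comfortably
reproducible on a single CPU while leaving the fitted exponents stable.

## Known limitations

* The Louvain optimizer is greedy; only small graphs are verified against
  the global optimum, and on large maps different seeds can return
  different near-optimal partitions (`n_restarts` mitigates).
* The exact-filling lattice limit of the growth model is unreachable (see
  above); free growth reaches internal density ~0.5, not 1.
* Border-overlap analysis uses a +/-1 bin window by default; the matching
  tolerance of published TAD-boundary sets is not standardized.
* Uniformity of the equilibrium-globule sampler relies on mixing of the
  snake/kink dynamics; at site fillings well above 0.8 the dynamics slow
  down and the default budget may under-equilibrate.
* Community segments detected on an equilibrium-globule map still show a
  weak (~8%) end-to-end reduction against random subchains. This is a
  selection effect — communities are detected on a map built from the same
  frozen conformation whose distances are then measured — and it shrinks
  with denser confinement, but dense confinement also hides the
  ideal-chain R(s) regime; at the default fill fraction the effect is
  visible though an order of magnitude weaker than the fractal globule's
  genuine compactness signal.
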