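# Methods

This note documents the models and procedures `modbrain` implements, the
defaults and why, the numerical choices, what the synthetic generator does
and does not emulate, and the known limitations.

## Weight conventions

Input connectivity matrices are Pearson correlation matrices, one per
participant. The pipeline takes the **absolute value** of the correlations —
the quantity of interest is connection strength, not sign — zeroes the
diagonal, and enforces symmetry by averaging with the transpose (a warning
is emitted if the raw asymmetry exceeds 1e−6). All downstream weights
therefore live in [0, 1]. Exact-zero pairs are never promoted to edges, even
at 100% density: the Hadamard masking step would erase them anyway.

## Network construction

Edge density (network cost) is 2T/(N²−N)×100% for T undirected edges over N
nodes. The target edge count for a requested density is ⌊density·(N²−N)/200⌋
— rounding down so the requested cost is never exceeded.

**Global threshold.** The T strongest edges of the whole matrix are kept;
ties are broken by ascending (i, j) node-index pair for determinism. The
cutoff weight τ (the weakest retained edge) is stored on the result.

**Local threshold (k-NNG).** The union k-nearest-neighbour graph keeps an
edge when *either* endpoint ranks the other among its k strongest
neighbours; neighbour rank ties also break by ascending index. The
construction finds the largest k whose union k-NNG does not exceed the
target count (`k_base`), then augments with the candidate edges of the
(k_base+1)-NNG ring, added in descending weight order, until the target is
met. Where the construction literature leaves the augmentation order open
(per-node round-robin vs global order), this implementation chooses
**global descending-weight order**: it preserves the nearest-(strongest)-
neighbour semantics, hits the exact density, and is validated against a
brute-force enumeration oracle on all small graphs in the tests. Every
output contains the 1-NNG, which is also the feasibility floor: requesting a
density below the 1-NNG density raises an error carrying the achievable
minimum. In the saturated regime (every positive edge already included)
several values of k describe the same graph; `k_base` then records the k at
which saturation was detected.

Community statistics are always computed on the **Hadamard product** of the
binary adjacency and the original weighted matrix.

## Community detection

Modularity Q is the Newman–Girvan weighted statistic. Louvain maximisation
(igraph's C implementation of the multilevel algorithm) is stochastic, so
partitions are the best of N independent runs — N = 1000 at the final
density, N = 10 during density scanning, where only the argmax location
matters and one algorithm family throughout avoids behavioural seams. Each
run draws from a child seed of the caller's seed, so results are exactly
reproducible. The resolution parameter is fixed at 1.

**Null modularity.** Q_rand is the mean best-of-N Louvain Q of 40
degree-preserving rewired copies of the thresholded weighted network
(weights travel with their edges). Rewiring performs 10 swap attempts per
edge — the common convention for Maslov–Sneppen rewiring effort. If the
source network is connected, swaps that would disconnect it are reverted;
because a swap (a,b),(c,d)→(a,d),(c,b) always leaves a~d and b~c adjacent,
a single BFS from a to b decides connectedness, which keeps the null cheap.
On a disconnected source only the degree sequence is preserved. Topologies
with no legal swap (stars) fall back to the identity with a logged warning.

**Optimal density.** For each participant and each grid density, Q and
Q_rand are computed and averaged across participants; the optimal density is
the argmax of mean Q − Q_rand, with ties resolved toward the sparsest
density (cheaper networks). Grid conventions by parcellation size: 51
points over 0.08–5% for ~451-node parcellations, 73 over 0.2–10% for
~200–250 nodes, 100 over 0.3–25% for ~100 nodes. Cells below a
participant's local-threshold floor are excluded from the means and logged.

**Consensus.** The Lancichinetti–Fortunato association-matrix procedure:
the node-pair co-assignment fraction is thresholded at the expected
co-assignment of label-permuted (module-size-preserving) null partitions,
re-clustered with replicate Louvain runs, and iterated until all replicates
agree; 50 iterations without convergence raises an error (bootstrap
iterations whose consensus fails are redrawn, up to 5 times, logged). The
permutation-null threshold is a documented choice where the consensus
literature leaves the parameter open. Meta-consensus is the same operation
applied to the per-iteration consensus partitions.

## MV, MD and the group comparison

MV_s(i,j) = 1 − (|X_s(i)∩X_s(j)|/|X_s(i)|)·(|X_s(i)∩X_s(j)|/|X_s(j)|),
computed for all nodes at once from the label contingency table. Singleton
communities are valid node-sets; the formula needs no special casing. MV is
symmetric, label-invariant and confined to [0, 1].

MD runs both constructions at the same density, partitions each masked
network with best-of-N Louvain using the **same seed stream** for both —
isolating the thresholding effect from optimiser stochasticity — and
returns the nodal MV between the two partitions.

**Balanced bootstrap MV.** With unequal group sizes a joint consensus would
be biased toward the larger group, so at each of 500 iterations B
participants (B = the smaller group size) are drawn without replacement
from each group; their joint consensus is estimated and each sampled
participant's nodal MV against it recorded. A participant's summary value
is the mean over the iterations in which it was sampled. Per iteration,
nodal group differences are tested with 5000 label permutations after
covariate residualisation; the per-iteration p and Z are averaged into
meta-results, the direction is the sign of the mean Z, and nodes whose
per-iteration direction flips are flagged. BH-FDR at α = 0.05 is applied to
the meta p-values. MD needs no bootstrap (it is within-participant) and is
tested directly.

**Covariates.** Age, sex, study/site (and optionally mean FD) are regressed
out before permutation. Age is demeaned *within* groups when the groups
differ systematically in age — removing age variance without absorbing the
group effect. A `group` column is never used as a regressor. Zero-variance
columns silently drop (they duplicate the intercept); genuinely collinear
designs raise an error naming the redundant columns.

**MD/OA.** Nodal MD of a group of interest is concatenated with the
reference (older-adult) group per node, residualised on covariates, and
referenced by subtracting the reference residual mean: [R1 R2] − E(R1).
The per-node index is the group mean of the referenced values; referencing
makes the index comparable across cohorts. Globally, a Wilcoxon signed-rank
test over nodes asks whether a group's MD/OA differs from zero; at the
module level, two-sided rank-sum tests compare groups within each consensus
module, nodes treated as independent observations, BH-corrected per family.
Ties are handled by midranks with scipy's normal approximation for larger
samples. Group-mean MD maps use unadjusted means; the covariate-adjusted
values feed the tests.

## Distance–strength model

Edge strength is modelled as
strength ~ β₁·distance + β₂·group + β₃·group×distance + β₄·age + β₅·sex +
β₆·study + intercept, over all surviving edges of the locally thresholded
networks; β₂ and β₃ carry the group intercept and slope differences.
Because |r| weights are not normal, the model is refit by OLS on 20%
subsamples of the pooled edge population, drawn without replacement, for
10,000 bootstrap iterations; a coefficient is significant when 0 falls
outside the central 95% of its bootstrap distribution (percentile rule —
the natural reading of "significantly different from zero" for a bootstrap
histogram), and the reported two-sided p is twice the smaller tail
fraction. Singular subsample fits are redrawn and logged; constant
covariate columns drop with a warning.

## Motion QC

Framewise displacement sums the absolute per-volume deltas of the six
rigid-body parameters, FD_i = |Δx|+|Δy|+|Δz|+|Δa|+|Δb|+|Δc|, with the
rotational deltas (radians) converted to arc length on a **65-mm-radius
sphere** before summation — FD is in mm throughout and linear in the
deltas. Participants with mean FD > 0.5 mm are flagged for exclusion, and
excluded participants appear in no downstream table. Motion files are
six-column text; the column convention (FSL-FLIRT stores rotations first)
is a loader parameter rather than a guess, defaulting to rotations-first.

## Visualisation transforms

For display only, MV and MD map as 100^value and p-values as 100^(1−p),
taking the 0–1 scale to a nonlinear 1–100 scale that spreads the upper
range. These values never feed back into statistics.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
symmetric |r|-like matrices in [0, 1] with zero diagonal; a planted block
partition (default 8 modules over 100 nodes, within-module level 0.6,
between 0.1); linear decay of weight with Euclidean distance between node
coordinates sampled uniformly in a 70-mm ball (brain-scale, consistent with
the 65-mm FD sphere convention), with group-specific slope (defaults
0.0015/mm young, 0.0020/mm older — steeper decay with age) and intercept
0.2; additive Gaussian noise (SD 0.05); participant-level partition jitter
(each node reassigned to a uniformly random other module with probability
0.05 young / 0.08 older), which drives both the participant's block pattern
and the recoverable between-participant MV; ages uniform on 20–40 / 60–80;
and 128-volume motion traces whose random-walk increments are rescaled so
the realised mean FD matches the group target (0.15 / 0.25 mm) exactly.
Validation caps |intercept| + within-level at 0.95 because clipping to
[0, 1] would otherwise distort the planted means.

The additive block + linear-decay + Gaussian model is the simplest one
exhibiting both the distance-decay and the modular structure the pipeline
measures; it is a stand-in, not a characterisation of real |r|
distributions. The generator does **not** simulate BOLD dynamics,
hemodynamics, scanner artifacts beyond rigid-body parameters, negative
correlations (the pipeline consumes |r|), spatially contiguous modules, or
realistic edge-weight marginals. Passing tests therefore demonstrate that
the machinery recovers planted structure under its own assumptions — not
that those assumptions hold in any particular dataset.

## Determinism and problem sizes

A single master seed spawns per-stage child seeds (numpy `SeedSequence`),
igraph's RNG is re-seeded before every Louvain run, and all CSV output uses
a fixed float format, so a fixed config + seed reproduces every output byte
for byte on one machine. Paper-scale defaults (1000 Louvain runs, 40 nulls,
500 bootstrap iterations, 5000 permutations, 10,000 distance–strength
bootstraps) suit full cohorts; the `fast` profile (50/10/50/500/500) and the
test suite's demo sizes (100 nodes, 2×15 participants) are the package's
scaled-down settings for routine verification, chosen so the complete suite
runs in minutes while still exercising every stage at sizes where planted
structure is comfortably recoverable.

## Known limitations

- The density scan uses Louvain throughout; analyses that used a faster
  greedy algorithm for scanning may locate the argmax slightly differently.
  The difference is confined to the argmax location and is validated on
  synthetics with a planted peak.
- The permutation Z normalises by the pooled permutation SD; per-tail SDs
  are not implemented.
- Consensus results depend on the (documented) permutation-null threshold;
  other consensus thresholds are not exposed.
- No time-resolved (sliding-window) MV, no signed-network thresholding, no
  minimum-spanning-tree construction, no multilayer community detection,
  and no imaging I/O — the pipeline starts at correlation matrices.
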