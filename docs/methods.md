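# Methods

## Model and rationale

Tractography-based connectomics faces a thresholding problem: the directed
edge i→k is declared when some seed voxel of ROI i sends more than a
fraction τ of its streamlines to ROI k, and no universally correct τ
exists. This package treats τ as an optimization variable. Because
diffusion MRI cannot observe fiber polarity, a correct reconstruction must
be a symmetric directed network; asymmetry in the thresholded network
G_τ is therefore an error signal. Raw asymmetry ϕ (the fraction of edges
whose reverse is absent) is confounded with density — sparse random
networks are asymmetric by chance, with expectation 1 − ρ for a random
directed network of density ρ whose edges occupy distinct ordered pairs —
so the objective is the normalized asymmetry Φ = ϕ / (1 − ρ), and the
selected threshold is the Φ-minimizer. Φ is undefined for empty (ϕ = 0/0)
and complete (ρ = 1) networks; both are excluded from the optimization,
which also removes the two trivial "perfectly symmetric" solutions.

## Reduction to a strength matrix and the threshold scan

The voxel-level input (one v_i × N matrix of streamline fractions per ROI)
is reduced to an N×N strength matrix S(i,k) = max over seed voxels of the
fraction reaching ROI k. Under the at-least-one-voxel connectivity rule
this reduction is exact: G_τ(i,k) = 1 ⇔ S(i,k) > τ for every τ. The
comparison is strictly greater-than; a voxel at exactly τ does not connect.

The thresholded network only changes when τ crosses a distinct strength
value, so the scan is event-driven: one representative τ per open interval
between consecutive distinct positive strengths (plus the interval above
the maximum, when the maximum is below 1), each taken at the interval
midpoint. This enumerates every achievable network exactly once with no
resolution parameter; a grid scan exists only as a test oracle. When an
interval of thresholds attains the optimum, the reported τ* is the
midpoint of the achieving interval — a convention, since any value in the
interval yields the same network. Equal-Φ records are tied when they agree
within 1e−12 (Φ values along a scan are ratios of small integers, so exact
ties are the norm) and resolved toward the largest density.

Post-symmetrization resolves pairs detected in exactly one direction
(S_ij > τ ≥ S_ji): the undirected edge is kept iff the presence confidence
(S_ij − τ)/(1 − τ) strictly exceeds the absence confidence (τ − S_ji)/τ.
Exact ties drop the edge and are logged. The rule is applied to the
selected network only when Φ_min > 0 (a symmetric optimum is left alone,
on which the rule is the identity anyway). The node-level ratio rule is
applied to the max-over-voxels strengths, consistent with the reduction.

## Edge confidence

As τ decreases, each directed edge α first appears at density
ρ_α = (rank of its strength) / [N(N−1)]; tied strengths enter together and
share the density at which the whole tie class has appeared, and
zero-strength edges sit in the final class at ρ_α = 1. Relative to the
selected density ρ*: present edges score (ρ* − ρ_α)/ρ* ∈ (0, 1], absent
edges (ρ* − ρ_α)/(1 − ρ*) ∈ [−1, 0), marginal edges (ρ_α = ρ*) score 0,
and a node pair scores the mean of its two directed edges. The −1 bound is
attained only in the limit ρ_α = 1, ρ* → 0; no correction is applied.
Confidence expresses how decisively an edge is classified, not connection
strength; the network remains unweighted.

## Group consensus

Each subject contributes a total order over the N(N−1) directed edges
(most confident first). Ties within a ρ_α class are broken by ROI-label
lexicographic order (index order when unlabeled) so every rank vector is a
strict permutation, as the Kemeny distance — the number of pairwise
disagreements — requires. The consensus ordering is computed by randomized
QuickSort: a random pivot edge splits the remainder into edges ranked
before the pivot by a *strict* majority of subjects versus the rest, and
recursion proceeds on both lists; exact majority ties go to the right
(lower-confidence) list, deterministically. The pivot sequence is fully
determined by an explicit seed (default 0). The consensus network is the
top-K prefix of the aggregate ranking minimizing Φ over K = 1 … N(N−1)−1,
largest K on ties. No strengths exist at group level, so
post-symmetrization is not applicable; an asymmetric optimum is returned
as-is with its Φ_min.

## Synthetic data generator

Ground truths are symmetric networks with round(ρ·N(N−1)/2) undirected
edges (half-integers round up) placed uniformly without replacement among
distinct pairs — symmetric because tractography cannot detect polarity.
Each simulated ROI is a single voxel, so the corrupted fraction matrix is
itself a strength matrix. Noise follows the maximum-entropy distribution
on [0, 1] with a mean constraint — the truncated exponential
f(ζ) = α e^{−αζ}/(1 − e^{−α}) — sampled by inverse CDF. Connected ordered
pairs observe 1 − Z1 (mean miss-noise μ1), non-connected pairs observe Z2
(mean spurious-signal μ2); the two directions of a pair are drawn
independently. Intensity is parameterized by the means μ ∈ (0, 1/2),
converted to rates by bracketed root finding on
μ(α) = [1 − (1+α)e^{−α}] / [α(1 − e^{−α})] (residual < 1e−10; a series
expansion handles α → 0). Means above 0.3 make the distribution nearly
uniform and inference hopeless, so studies stay within (0, 0.3].

What the generator does *not* emulate: multi-voxel ROIs, spatial or
distance-dependent error structure (tractography under-detects long
connections and over-detects proximal ones), streamline-count
discretization, and inter-subject registration error. Passing synthetic
benchmarks therefore demonstrates correct behavior under independent,
density-uniform noise — not performance on real diffusion data, where
distance-bias correction is a recommended independent preprocessing step.

## Evaluation studies and replication sizes

Accuracy is measured as a binary classification of ordered pairs: Jaccard
similarity of edge sets, false-positive rate FP/(absent pairs) and
false-negative rate FN/(present pairs); two empty edge sets define J = 1
with a warning, and rates with empty denominators are NaN. An oracle that
knows the ground truth reports the Jaccard-maximizing threshold (all
maximal optimal intervals; representative value the midpoint of the widest
one). Because the final inferred network is post-symmetrized, the oracle
scans post-symmetrized networks too — presence of each unordered pair is
monotone in τ with a per-pair cutoff min(a, b/(1 + b − a)) for strengths
a ≥ b, which keeps the oracle scan event-driven and guarantees it
dominates the selected network instance-wise.

Two designs are provided, with one global seed fanned out to per-replicate
child seeds so every cell is independently reproducible:

- **heat map**: N = 50, ground-truth densities {0.1, 0.5, 0.9}, a 6×6 grid
  of (μ1, μ2) over {0.05 … 0.30}, 200 replicates per cell, cell summaries
  as medians. Expected structure: errors below 5% where μ1 + μ2 < 0.3;
  false negatives dominate for sparse truths, false positives for dense
  ones; the median Jaccard shortfall against the oracle stays within a few
  points even at μ1 = μ2 = 0.3.
- **box plot**: N = 50, 1000 experiments with ρ ~ U(0,1) (redrawn in the
  degenerate cases of zero or all undirected edges) and μ1, μ2 ~ U(0, 0.3),
  paired across methods (the same instances feed every method, for variance
  reduction). Compared are post-symmetrization benefit per method and
  MANIA's paired advantage over fixed thresholds {0.1 … 0.5} (an evenly
  spaced ladder, configurable), with one-sided Mann–Whitney U tests.

At the most extreme simulated noise (μ1 = μ2 = 0.3) and extreme densities,
the median error rate of the dominating error type plateaus near 30%
rather than under 25%: the oracle itself misses ~28% of edges at ρ = 0.1
there, so this is a floor of the noise conditions, not of the algorithm.

## Numerical and degenerate-input choices

- Strength and adjacency matrices are dense; N is tens to hundreds of
  ROIs, never voxels. Self-loops are structurally zeroed.
- All-zero strengths raise a no-signal error; inputs whose only achievable
  networks are empty/complete raise a degenerate-input error naming the
  cause (CLI exit code 3; validation errors exit 2).
- Reports are canonical JSON (sorted keys, floats at 12 significant
  digits), so identical inputs and seed give byte-identical files.
- The simulation loops use a vectorized selection path that skips record
  objects; tests assert it agrees exactly with the full inference.
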