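# Methods

## Model

A differentiating cell population is modelled as a continuous
birth-death (source–sink Fokker–Planck) process for the cell density
c(**x**, t) in expression space:

    ∂c/∂t = ∇·(c ∇F) + D Δc + R c.

The assumptions that matter in practice:

- **Non-equilibrium steady state.** Births balance deaths and the
  population distribution is stationary.  Data sampled from a
  developmental burst that has not equilibrated violates this.
- **Continuous coverage.** The sampled cells must trace the whole
  process; a missing intermediate stage breaks the operator chain.
- **Metastable cell types.** Clusters must correspond to dwelling
  regions of the dynamics, with the cluster count between
  (number of lineages + 2) and the number of metastable wells.

At steady state F decomposes into U = −D log p (diffusion part,
available as `equilibrium_potential`) and the advection potential V
with [∇log p·∇ + Δ] V = −R.  V alone orders cells by developmental
progress; pseudo-time is −V.  Changing D rescales V uniformly and
leaves the order unchanged (tested as an exact gauge), which is why the
pipeline defaults to D = 1 without loss.

## Estimation chain and numerical choices

**Embedding.** PCA (deterministic full SVD, sign fixed by the
largest-magnitude loading).  Default m = 2, which suits the bundled
benchmarks; real data may need more components.  Because every later
step uses only Euclidean geometry, rotating the input coordinates by
any orthogonal matrix leaves V̂ unchanged to 1e-8 (tested).  Note the
invariance is through PCA re-deriving the axes: the net-flow step
itself decomposes over embedding axes and is not invariant to
re-rotating the *embedding*.

**Diffusion operator.** Gaussian kernel K_ε(x,y) =
(4πε)^{−m/2} exp(−‖x−y‖²/4ε) on a kNN graph (default
k = min(n−1, 15)), symmetrised with the union rule (configurable to
intersection); self-loops kept.  Bandwidth: 2ε = median pairwise
distance, i.e. ε = median/2 — the median of Euclidean, not squared,
distances.  Anisotropic normalisation with α = ½ removes the sampling
density to first order, so (P − I)/ε converges to the backward operator
∇log r·∇ + Δ of the underlying diffusion; the suite verifies the
generator value −x for f(x) = x on standard-normal samples with the
error decreasing along the bandwidth ladder ε = 1.6 → 0.2 at n = 2000.
A disconnected kernel graph is an error (the stationary distribution
would not be unique); the advice is to raise k.

**Coarse-graining.** k-means (10 restarts, fixed seed, clusters
relabelled by descending size).  The aggregate
P̂ₛₜ = μ̂ₜ/(nₛnₜ) Σᵢ∈s Σⱼ∈t Pᵢⱼ is only approximately row-stochastic at
finite n, while the potential equation needs constants in the null
space of P̂ − I; we therefore row-normalise (the raw aggregate is kept
for inspection as `P_hat_raw`).

**Net-flow.** Per cluster and axis, a 1-D Gaussian KDE of the cluster's
coordinates with Silverman bandwidth, evaluated at the support
endpoints a = min, b = max (optionally padded by one bandwidth).  The
bandwidth is floored at 5% of the axis range: marginals piled up at a
single value (e.g. expression clipped at zero) would otherwise collapse
the bandwidth and blow up the boundary derivative.  Clusters with ≤ 2
cells or zero spread contribute R̂ = 0 with a warning.  The raw rates
are recentred (R̃ₛ = R̂ₛ − Σ nₛR̂ₛ/N) so that Σ nₛR̃ₛ = 0 holds to
round-off; the per-axis sums are verified against Simpson quadrature of
the KDE Laplacian to 1e-6.

**Potential and paths.** V̂ = −pinv(P̂ − I) R̃ ε is the minimum-norm
least-squares solution (V̂ ⟂ constants when P̂ is irreducible), checked
against a closed form at K = 2 and against random perturbations.
Candidate edges are off-diagonal P̃ entries above a threshold (default
1% of the largest off-diagonal weight), oriented from high to low V̂;
ties orient from the larger cluster with a warning.  For landscapes
expected to be trees, `maximum_weight_tree` extracts the maximum-weight
spanning tree instead — a threshold-free rule that recovers the
root-source/two-sink-leaves topology of the bifurcation benchmark
deterministically, whereas a fixed threshold cannot always separate the
(genuinely touching) branch clusters near the bifurcation.

**Surface.** V(x,y) = a·f + b·g with f a mean of inverted Gaussians of
width σ/p̃ᵢ centred on cells (p̃ᵢ = the diagonal weight of the cell's
cluster; zero diagonals replaced by the smallest positive one, logged)
and g the least-squares plane through the per-cell potentials — the
simplest monotone-in-V̂ trend.  a, b, σ and an optional NaN cap are
user parameters; the surface is illustrative, not quantitative.

**Evaluation.** Pearson correlation against true-time labels
(scipy.stats.pearsonr) and the one-sided Wilcoxon rank-sum test that an
early stage has smaller pseudo-time (scipy.stats.mannwhitneyu: exact
enumeration for small untied samples — p = 1/6 for {1,2} vs {3,4} —
normal approximation with continuity correction otherwise).

## Synthetic benchmarks

The generators produce exactly the data the model assumes — a
stationary population with localised births, potential-driven drift,
isotropic diffusion noise (Euler–Maruyama: x ← x − ∇F Δt + √(D Δt) ξ)
and localised deaths — plus ground-truth labels: per-cell age since
birth, lineage (the sink basin reached by the noise-free flow from the
cell's position; exact separatrix points fall back to the nearest
sink), and early/mid/late stages from age terciles.

**Birth-rate balancing.** Births are a per-step Poisson count placed
uniformly in the source ball; deaths are per-step Bernoulli removals
inside sink balls.  To hold the population near its target without
hand-tuned rates, the engine runs a calibration burn-in with a
provisional rate, measures the mean lifetime T̄ of cells dying in its
second half, then fixes the rate at target_population/T̄ for an
equilibration phase before the snapshot (a user-supplied rate skips the
recalibration).  The long-run mean population stays within 10% of the
target (tested over 20 seeds), and late snapshots of the same chain are
distributionally indistinguishable (KS check).

**Drift-diffusion (2 lineages, 50 dims).** A "tuning-fork" potential on
the first two coordinates — a tilted channel whose single y-well
switches smoothly into a double well — with the source ball at the
channel entrance and one sink at each well end; the other 48
coordinates are pure diffusion noise.  Defaults: dt = 0.01, D = 0.02,
tilt 1, channel length 4, branch half-separation 1.5, snapshot 400 of
~800 cells.  D sets a trade-off observed while designing the benchmark:
much larger noise decouples a cell's position from its age (no
pseudo-time method operating on positions could then score well), while
much smaller noise collapses the cloud to a filament that starves the
KDE net-flow step.

**Gene networks.** Hill-kinetics production minus linear degradation,
negative excursions clipped to zero (events counted).  The two-gene
toggle uses symmetric mutual inhibition with production a = 20,
K = 1, Hill n = 6, degradation 1, D = 0.05; births in a small ball at
the symmetric saddle, deaths in balls (radius 3) around the two
attractors.  The steep Hill curve and strong production are deliberate:
the saddle's unstable eigenvalue (bounded by n − 1 for these kinetics)
controls the randomness of commitment timing, and with a shallow curve
(n = 2) the commitment jitter is so large that cell position carries
little age information — the benchmark would be unlearnable rather
than hard.  The six-gene network stacks three such toggles: g1/g2
mutually inhibit; g1 activates the g3/g4 toggle and g2 the g5/g6 toggle
with activation threshold K_act = 5, midway between the saddle (~1.6)
and committed (~20) levels, so each secondary toggle fires only after
its parent commits.  Two sequential decisions yield four lineages with
exactly two high genes each.

What the generators do **not** emulate: count noise, dropout, library
size variation, batch effects, or doublets — they are continuous-state
dynamics.  Green tests therefore demonstrate correctness of the method
under its own model assumptions, not robustness to scRNA-seq technical
noise.

## Benchmark operating points

Cluster counts follow the topology rule above: K = 4 for the
drift-diffusion process, 7 for the toggle, 9 for the six-gene network;
400-cell snapshots, 10 replicate seeds in the validation suite and the
reproduction script.  These sizes keep a full three-benchmark
validation run to a few minutes on one CPU.

## Known limitations

- Pseudo-time is cluster-constant; there is no within-cluster
  interpolation, so the achievable correlation with a continuous true
  time is capped by within-cluster age variance.
- The potential difference between two branches that communicate only
  through the progenitor cluster is weakly determined (a
  near-null mode of P̂ − I): branch-internal order is reliable, but
  cross-branch cluster rank comparisons can fluctuate between
  replicates even when the overall pseudo-time correlation is high.
- The net-flow estimator's raw magnitude depends on how sharply the
  cluster's density falls at its support boundary; it discriminates
  sources from sinks well when births are localised and deaths are
  spatially spread, and degrades when a cluster mixes the source with
  long transit regions (hence the guidance to keep the progenitor
  region its own cluster).
- The marginal (per-axis) decomposition of the divergence theorem is
  exact only for axis-aligned box domains; for real cluster shapes it
  is an approximation, and it ties the estimate to the embedding axes.
- K must be supplied by the user; there is no automatic model
  selection.
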