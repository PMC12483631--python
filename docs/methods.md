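# Methods

## Model

`tepc` treats a dataset as a spatial network: nodes are data points
r_1…r_N ∈ R^n, and interaction strength decays with Euclidean distance
d_ij = ‖r_i − r_j‖₂ through one of three kernels (off-diagonal
entries; the diagonal is minus the row's off-diagonal sum so that A has
zero row sums):

* cutoff: A_ij = 1 if d_ij ≤ σ else 0;
* generalized exponential: A_ij = exp(−d_ij^κ / (κ σ^κ));
* power law: A_ij = (d_ij/σ)^(−ν), ν > 1.

The exponential exponent is normalized by κ so that A_ij = e^(−d/σ) at
κ = 1, consistent with the flexibility–rigidity kernels this family
generalizes. A single global characteristic distance σ is used; σ = 3
and κ = 1 are the package defaults across modalities. For multichannel
signals the coupling weight is instead |Pearson r| of the two channels
(absolute value, because coupling conductances are non-negative; a
`signed` switch preserves raw correlations for sensitivity analyses).

**Laplacian filtration.** With l_ij = A_ij (i ≠ j), lmin/lmax their
extremes and d = lmax − lmin, scale k ∈ {1…p} keeps edge (i,j) iff
l_ij > (k/p)·d + lmin, assigning off-diagonal −1 and diagonal = degree.
The comparison is exactly `≤` for dropping, so ties at a threshold drop
the edge and scale p is always the empty graph; the k = p threshold is
set to lmax directly rather than lmin + d to avoid a one-ulp rounding
leak. Edge sets are nested by construction. Default p = 10.

**Coupled dynamics.** Every node carries a 3-variable oscillator —
Lorenz ẋ = α(y−x), ẏ = γx − y − xz, ż = xy − βz (defaults α=10, γ=60,
β=8/3) or Rossler ẋ = −y−z, ẏ = x+ay, ż = b+z(x−c) (defaults
a=b=0.1, c=4) — coupled diffusively:

    ds_i/dt = F(s_i) + ε Σ_j C_ij Γ s_j,

with Γ = I by default and C zero-row-sum. Kernel matrices couple as
C = A (positive off-diagonals, negative diagonal); filtered scales as
C = −L_k, re-signing the graph-Laplacian convention into positive unit
conductances. ε defaults to 13.6 for the perturbative protein protocol
and 1.0 for filtered-scale demonstration/classification runs.

The coupling term is evaluated in deviation form,
ε·[Σ_j W_ij Γ(s_j − s_0) − (Σ_j W_ij) Γ(s_i − s_0)] with W the
off-diagonal part and s_0 node 0's state. For zero-row-sum C this is
algebraically identical to the direct sum, but it makes the
synchronization manifold *exactly* invariant in floating point: once
all rows agree, the coupling is exactly zero and every node performs
identical arithmetic thereafter. Without this, the ~1e−16 row-sum
residue of the direct product is amplified by the transverse chaotic
exponent and identical initial rows drift measurably apart within a
few thousand steps.

Integrators are explicit forward Euler, midpoint RK2, and classical
RK4 (default), with a divergence guard (error at the offending step
once any |state| exceeds 1e6). Convergence-order verification measures
Richardson slopes over h ∈ {1e−2, 5e−3, 2.5e−3} at a horizon of 0.25
time units against an RK4 reference at h = 1e−5: beyond ~0.5 time
units the global error of a chaotic trajectory is dominated by
exponential error amplification and the fitted slope no longer
reflects the scheme's order (we measured apparent RK4 slopes near 4.9
at a 1-unit horizon with γ=60).

**Trajectory protocols and features.** Two protocols produce per-node
trajectories at every scale:

* *perturbative* (proteins): one run per node, the probed node starting
  at (1,1,1) and all others at the origin equilibrium; only the probed
  node's trajectory is kept. How quickly the perturbation is damped or
  amplified encodes the node's local connectivity. All N runs integrate
  simultaneously as one (N × runs × 3) batch, making the coupling term
  a single matrix product per stage.
* *shared* (signals/expression/images): one run per scale from random
  initial states uniform in [−1,1]³ (seeded); every node's trajectory
  is kept. Nodes that share many edges co-synchronize and end up with
  similar statistics.

Per state variable, the post-transient window (default: first 10% of
frames discarded) yields mean, standard deviation, min, max, median,
skewness, excess kurtosis, and RMS (population moment conventions;
skew/kurtosis defined as 0 for constant series). The feature matrix is
N × (p·3·8) with full provenance recorded; scales whose integration
diverges are dropped and listed, never imputed. Default trajectory
lengths are 600 steps at h = 10⁻³ for perturbative runs (≈12 e-folding
times of the Lorenz origin instability at γ = 60, long enough for an
undamped node to reach the attractor) and 2000 steps for shared runs;
demonstration runs use 10⁵ steps.

**Prediction heads.** Protein B-factors: per-protein OLS with
intercept on the features, optionally reduced to the top-30 columns by
variance (deterministic and leakage-free when ranked on training data);
a rank-deficient design falls back to ridge with
λ = 1e−8·trace(XᵀX)/F, recorded on the result; the score is the
Pearson correlation between fitted and experimental values.
Classification: stratified k-fold × multiple seeds around any
scikit-learn-style estimator (random forest, KNN, GBDT, SVM adapters
provided), scored by balanced accuracy (mean per-class recall), with
accuracy/sensitivity/specificity reported for ≤3-class tasks.
R-S scores: for sample j of class k, similarity = mean over same-class
samples of (1 − d/d_max) and residue = (mean distance to out-of-class
samples)/r_max, with d_max the dataset-wide maximal pairwise distance
and r_max the maximal out-of-class mean, so both land in [0,1].

**Simplicial persistent Laplacians.** `tepc.simplicial` implements the
full construction on Vietoris–Rips filtrations: a simplex is born at
half the maximal pairwise distance of its vertex set (growing-balls
radius convention; a diameter-convention switch exists), dimensions up
to 3. Boundary matrices use the alternating-sign convention over
sorted vertex tuples, ∂_0 maps to the zero space. The p-persistent
q-boundary operator is represented by restricting ∂_q of the later
complex to chains whose boundary lies in the earlier one, via an
orthonormal null-space basis of the "outside" rows (an exact
rational-arithmetic route exists for small validation instances);
L_q^{t,p} = B_{q+1}^{t,p}(B_{q+1}^{t,p})ᵀ + (B_q^t)ᵀB_q^t. Persistent
Betti numbers are counted as eigenvalues below 1e−8·(1 + λ_max)
(scale-invariant zero detection); rank computations use an absolute
1e−8 tolerance because genuine singular values of these
integer-derived operators are O(1) while numerically-zero matrices
carry only ~1e−16 noise. The applications above use the graph-level
Laplacian filtration; simplicial non-harmonic spectra are exposed for
analysis but are not part of the default prediction features.

## Synchronization-regime classification

The point-cloud demos classify each scale as `full` if the
time-averaged sync error e(t) (mean pairwise state distance) over the
last 20% of the run falls below 1e−2 × an attractor-scale estimate
(RMS oscillation amplitude of the post-transient flow); `partial` if a
declared node subset passes while the global error does not;
`unsynchronized` otherwise. The thresholds make a visually obvious
distinction assertable; they are not tuned quantities (synchronized
errors sit many orders below, chaotic errors at the attractor scale).

## Synthetic data

The generators define the package's study conditions and are seeded
and fully parameterized:

* `polygon_cloud` — n points on a circle (regular hexadecagon default).
* `chain_cloud` — 120-node chains: the folded portion is a compact
  serpentine (boustrophedon lattice fold) with unit spacing — a
  genuinely 3-D globule, which is what gives the folded cluster a
  Laplacian spectral gap large enough to synchronize at ε ≈ 1; the
  unfolded portion extends with spacing 3 (sparse contacts); jitter
  sd 0.05; default split 80 folded / 40 unfolded.
* `synthetic_signals` — block-correlated Gaussians via shared latent
  factors (global factor for across-class correlation, one per class
  for the within-class excess); requires 0 ≤ across_r ≤ within_r < 1
  for a positive-semidefinite block structure.
* `synthetic_expression` — gamma–Poisson (negative-binomial-like)
  counts, log-normal baseline means, disjoint marker blocks
  up-regulated per type (default 4 types × 125 cells, 400 genes, 10%
  markers, 4-fold effect), library sizes uniform in [0.5, 2].
* `synthetic_protein` — helical-segment Cα traces (3.8 Å spacing,
  compact self-attracting reorientation, termini dangling outward);
  ground-truth flexibility is the pseudo-inverse diagonal of the
  cutoff-kernel (7.3 Å) contact Laplacian — the elastic-network
  construction — and B-factors are a positive affine map of it plus
  Gaussian noise (default 5% of signal sd).

What these emulate — and what they do not: the generators reproduce
geometric compactness vs. extension, block correlation, marker-driven
cluster structure, and an elastic-network flexibility signal. They do
not model scRNA-seq dropout, batch effects, EEG nonstationarity, or
real protein side-chain packing; tests passing on them demonstrate
that the pipeline recovers structure it is designed to see, not
performance on any particular public benchmark.

## Numerical choices and degenerate inputs

* Zero-row-sum validation of couplings at 1e−9 relative; connectivity
  row sums are exact to ≤1e−12 relative by construction.
* A filtration whose off-diagonal weights are all equal is degenerate:
  every scale is empty; a warning is raised and the empty family
  returned.
* Power kernel at zero off-diagonal distance raises division-by-zero;
  correlation coupling with a zero-variance channel names the channel.
* Empty chain groups in the simplicial code return empty matrices and
  β = 0 rather than erroring.
* Master seeds fan out to per-stage seeds through `SeedSequence([master,
  counter])`, all below 2³¹; outputs carry the serialized config, so
  identical config + seed reproduce every output byte for byte (the
  family archive writes fixed zip timestamps for this reason).

## Design choices and limitations

* The per-scale coupling for dynamics is the *binarized* −L_k, not the
  weighted A, following the multiscale-network construction; A itself
  can be passed as a coupling directly.
* The p = 1 family is, by the strict-≤ threshold definition, a single
  empty scale; a "single-scale ablation" therefore has no coupling
  signal at all, and its regression collapses to an undefined
  correlation (surfaced as an error, scored as zero skill in the
  acceptance computation).
* Feature-window lengths (600/2000 steps) and the statistic set are
  package choices; both are configurable, and the statistic list is
  pluggable by name.
* Perturbative probes start from the origin equilibrium rather than a
  pre-synchronized state; with strong coupling and γ = 60, node-wise
  damping dominates and the choice mostly rescales features.
* A second widely printed "Rossler" parameter triple (a=35, b=3, c=28)
  actually parameterizes a Chen-type system; it is not exposed as a
  Rossler preset.
* Dimension > 3 simplices are refused by default (combinatorial
  blow-up); an override flag exists.
* The image-modality reducer defaults to UMAP (3 components) with a
  PCA fallback; UMAP is imported lazily and only when requested.
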