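# tepc — topology-enabled predictions from chaos

Chaotic systems are the textbook example of unpredictability, yet a
*network* of chaotic oscillators coupled through data-derived
connectivity behaves very predictably in one specific sense: how far
and how fast each node synchronizes with the rest reflects that node's
embedded environment. `tepc` turns this observation into a feature
engineering pipeline for quantitative prediction on molecular,
cellular, signal, and image data.

The pipeline:

1. **Connectivity.** Data points (Cα atoms, cells, signal channels,
   image vectors) become nodes. Pairwise couplings come from a radial
   kernel of the Euclidean distance — cutoff, generalized exponential
   `A_ij = exp(−d_ij^κ/(κσ^κ))`, or power law `(d_ij/σ)^(−ν)` — or from
   absolute Pearson correlations for signals. Diagonals are set to minus
   the off-diagonal row sums, so `A` has zero row sums.
2. **Laplacian filtration.** The weighted Laplacian's off-diagonals are
   thresholded at `p` evenly spaced levels between the smallest and
   largest weight, producing a nested family of binarized graph
   Laplacians `L_1 ⊇ … ⊇ L_p` — a multiscale description of the
   network. (Full simplicial persistent Laplacians over Vietoris–Rips
   filtrations, with persistent Betti numbers `β_q^{t,p}` and
   non-harmonic spectra, are available in `tepc.simplicial`.)
3. **Chaotic dynamics.** Each node carries a Lorenz (or Rossler)
   oscillator; at every scale the network evolves under diffusive
   coupling `ds_i/dt = F(s_i) + ε Σ_j C_ij Γ s_j` with `C = −L_k`
   (RK4, Euler, or midpoint RK2 integrators). Depending on scale, the
   system is chaotic, partially synchronized, or fully synchronized.
4. **Features and prediction.** Per-node statistics (mean, std, min,
   max, median, skewness, kurtosis, RMS of each state variable) over
   post-transient windows, concatenated across scales, feed ordinary
   least squares (protein B-factors, scored by Pearson correlation) or
   any scikit-learn classifier under stratified cross-validation
   (balanced accuracy), plus residue–similarity (R-S) score
   visualizations for multiclass problems.

Synthetic generators (`tepc.synthetic`) reproduce every input modality
at desk scale — regular polygons, folded/partially-folded/unfolded
chains, block-correlated signal bundles, clustered expression counts,
and elastic-chain pseudo-proteins with known flexibility — so the whole
platform runs and is tested without any external download.

## Worked example

```bash
python examples/03_bfactor_recovery.py
```

```
 residue_id  experimental  predicted
          1         17.40      16.58
          2         11.09      11.25
          3          8.87       8.47
          4          8.54       8.43
          5          8.02       8.11
          6          7.81       6.92
          7          7.98       7.48
          8          7.50       7.65
          9          7.58       7.17
         10          7.66       7.60

Pearson correlation (predicted vs experimental): 0.989
```

A 100-residue synthetic pseudo-protein's B-factors (an affine function
of its elastic-network flexibility plus 5% noise) are recovered with
PCC ≈ 0.99 from perturbative Lorenz trajectories (κ=1, σ=3, α=10,
γ=60, β=8/3, ε=13.6, h=10⁻³) across ten filtration scales. The other
examples demonstrate the chaos→partial→full synchronization transition
on point clouds, persistent-Laplacian spectral curves, expression
classification, and correlation-coupled signal networks.

A thin CLI mirrors the library:

```bash
tepc synth protein --seed 1 --n 100 --out data/
tepc bfactor --synthetic 100 --seed 1 --out run/
tepc connect --input cloud.txt --kernel exponential --kappa 1 --sigma 3 \
     --scales 10 --out family.npz
tepc demo --input cloud.txt --seed 7 --epsilon 1.1 --out demo/
```

Every pipeline derives all stage seeds from one master seed and writes
its configuration next to its outputs; re-runs are byte-identical.

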