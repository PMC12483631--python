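"""Cell-type classification from a shared chaotic run.

A clustered synthetic expression matrix (4 types × 50 cells here, for
speed) is log-transformed, embedded via Euclidean distances and the
exponential kernel (κ=1, σ=3), filtered into ten binarized Laplacians,
and evolved once per scale from seeded random initial states — every
cell is one oscillator.  Per-cell trajectory statistics feed a random
forest under stratified cross-validation.
"""

from tepc.pipelines import PipelineConfig, run_classification
from tepc.synthetic import synthetic_expression

data = synthetic_expression(
    cells_per_type=50, types=4, genes=200, marker_fraction=0.1,
    effect_size=4.0, seed=0,
)
cfg = PipelineConfig(master_seed=0, cv_seeds=3)
report, baseline = run_classification(data, cfg, baseline=True)

print(f"chaotic-feature balanced accuracy: {report.mean_ba:.3f} ± {report.std_ba:.3f}")
print(f"matched-dimension raw-feature baseline: {baseline.mean_ba:.3f}")
print("confusion matrix (rows true, cols predicted):")
print(report.confusion)
print(
    "\nBalanced accuracy is the mean per-class recall; 0.25 would be "
    "chance for four balanced classes."
)
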