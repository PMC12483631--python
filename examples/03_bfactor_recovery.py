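"""Protein flexibility (B-factor) prediction from perturbative chaos.

A synthetic elastic-chain pseudo-protein provides Cα coordinates and
B-factors derived from its elastic-network flexibility profile (plus 5%
noise).  Each residue is probed by a perturbative run — that residue at
unit state, everything else at rest — across ten filtration scales of
the exponential-kernel contact network (κ=1, σ=3; Lorenz α=10, γ=60,
β=8/3, ε=13.6); trajectory statistics feed a per-protein linear
regression.
"""

from tepc.pipelines import PipelineConfig, run_bfactor
from tepc.synthetic import synthetic_protein

chain = synthetic_protein(n_residues=100, noise_sd=0.05, seed=0)
result, table = run_bfactor(chain, PipelineConfig())

print(table.head(10).to_string(index=False, float_format="%.2f"))
print(f"\nPearson correlation (predicted vs experimental): {result.pcc:.3f}")
print(
    "A PCC near 1 means the multiscale chaotic features recover the "
    "flexibility profile that generated the B-factors."
)
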