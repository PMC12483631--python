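"""Chaos → periodicity across filtration scales on a regular polygon.

Sixteen Lorenz oscillators sit on a regular hexadecagon.  At the
densest filtration scale the binarized Laplacian couples everything and
the network synchronizes fully; at the final (always empty) scale each
oscillator wanders chaotically on its own.  The sync error e(t) is the
mean pairwise distance between node states.
"""

import numpy as np

from tepc.pipelines import PipelineConfig, run_pointcloud_demo
from tepc.synthetic import polygon_cloud

cfg = PipelineConfig(master_seed=7, epsilon=1.1, demo_steps=20_000, record_every=20)
report = run_pointcloud_demo(polygon_cloud(16, 1.0), cfg, scales=[1, 10])

print(f"attractor scale estimate: {report.attractor_scale:.2f}")
for info in report.regimes:
    print(
        f"scale {info['scale']:2d}: regime={info['regime']:>14s}  "
        f"tail sync error = {info['tail_error']:.3g}"
    )
print(
    "\nA 'full' regime means the tail-averaged sync error fell below "
    f"{report.thresholds['full']:.3g} (1% of the attractor scale); the "
    "empty scale leaves independent chaotic orbits with errors on the "
    "scale of the attractor itself."
)
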