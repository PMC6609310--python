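"""Dual regression on a known construction.

Builds a centrality series exactly as templates x time-courses, runs the
two-stage dual regression, and shows that both factors are recovered.
"""

import numpy as np

from decm import TemplateSet, dual_regression
from decm.sliding import CentralitySeries

rng = np.random.default_rng(0)
n_voxels, n_networks, n_windows = 300, 3, 40

q, _ = np.linalg.qr(rng.standard_normal((n_voxels, n_networks)))
templates = q - q.mean(axis=0)                      # spatial patterns
courses = rng.standard_normal((n_networks, n_windows))  # known time courses
series = CentralitySeries(
    values=templates @ courses + 0.02 * rng.standard_normal((n_voxels, n_windows)),
    window_length=10,
    window_starts=np.arange(n_windows),
)

recovered_courses, recovered_maps = dual_regression(series, TemplateSet(maps=templates))
for k in range(n_networks):
    rc = np.corrcoef(recovered_courses.values[k], courses[k])[0, 1]
    rm = np.corrcoef(recovered_maps.values[:, k], templates[:, k])[0, 1]
    print(f"network {k}: course recovery r = {rc:.4f}, map recovery r = {rm:.4f}")
print("-> stage 1 recovers each network's time course, stage 2 its spatial map;")
print("   correlations near 1 mean the linear model is solved essentially exactly.")
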