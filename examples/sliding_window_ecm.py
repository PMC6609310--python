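"""Sliding-window eigenvector centrality on one synthetic subject.

Generates a single synthetic resting-state scan, computes the dynamic EC
series, and compares a window map with the static (whole-scan) map.
"""

import numpy as np

from decm import SynthConfig, extract_timeseries, generate_subject, generate_templates, sliding_window_ecm

cfg = SynthConfig(t_len=120, seed=42)
templates, mask = generate_templates(cfg)
vol, truth = generate_subject(cfg, group="A", subject_seed=1)

ts = extract_timeseries(vol, mask)
dynamic = sliding_window_ecm(ts, n_maps=60)       # 60 maps from 61-volume windows
static = sliding_window_ecm(ts, n_maps=1)         # M=1 reduces to static ECM

print(f"voxels in mask:        {ts.n_voxels}")
print(f"window length:         {dynamic.window_length} volumes "
      f"(T={ts.n_timepoints}, M={dynamic.n_maps})")
print(f"power-iteration steps: median {int(np.median(dynamic.iterations))}, "
      f"all converged: {bool(dynamic.converged.all())}")
print(f"map intensity mean:    {dynamic.values[:, 0].mean():.1f} (scaled target 4500)")

corr = np.corrcoef(dynamic.values.mean(axis=1), static.values[:, 0])[0, 1]
print(f"corr(time-mean dynamic map, static map) = {corr:.4f}")
print("-> centrality patterns are stable across windows; the dynamics are "
      "fluctuations around the static map.")
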