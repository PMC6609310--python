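"""Group inference on a synthetic cohort with a planted effect.

Generates a two-group cohort in which group B has twice the within-network
coupling variability of group A in network 0, runs dECM + dual regression,
and tests each network with TFCE + max-statistic permutation FWE.
"""

from decm import SynthConfig, generate_cohort
from decm.inference import cluster_report
from decm.study import run_cohort_dualreg, run_network_inference

cfg = SynthConfig(n_per_group=10, t_len=120, seed=3)
cohort = generate_cohort(cfg)
results = run_cohort_dualreg(cohort, n_maps=60)

print(f"cohort: {len(cohort.subjects)} subjects, window length "
      f"{results[0].window_length}, {cohort.brain_mask.count} voxels in mask")
for k, name in enumerate(cohort.templates.names):
    res, net_mask = run_network_inference(
        cohort=cohort, results=results, network=k,
        n_perm=500, seed=10 + k, direction=-1,   # test B (variable) > A
    )
    table = cluster_report(res.pcorr, res.tmap, net_mask, alpha=0.05, min_size=10)
    tag = "effect planted" if k == cfg.effect_network else "null"
    print(f"{name} ({tag}): min FWE p = {res.pcorr.min():.4f}, "
          f"clusters >10 voxels: {len(table)}")
print("-> only the planted network should reach FWE p < 0.05; corrected "
      "p-values come from the permutation distribution of the maximum "
      "TFCE statistic inside each network's mask.")
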