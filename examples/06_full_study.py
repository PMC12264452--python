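"""Run the full study pipeline on a desk-scale synthetic dataset.

Simulates a 5 Hz and a sham group (10 subjects each, pre/post), runs the
behavior, ERP, time-frequency, network and statistics stages, and prints
the findings the report flags.  Runtime is a few minutes.
"""

import numpy as np

import cerebwm as c

sim = c.SimConfig(n_channels=32, n_trials=30, n_rest_segments=12,
                  n_subjects_per_group=10, seed=1)
cfg = c.StudyConfig(sim=sim, groups=("rTMS5", "sham"), n_permutations=500,
                    tfr_freqs=np.arange(3.0, 31.0, 0.5),
                    power_bands=("theta", "alpha", "beta1", "beta2"),
                    network_bands=("theta",), seed=1)
report = c.run_study(cfg)

print("== group mean reaction times ==")
print(report.behavioral.groupby(["group", "session"]).mean_rt.mean()
      .unstack().round(3))
print("\n== significant ERP clusters ==")
for key, res in report.erp_cluster_tests.items():
    for cl in res.get("significant", []):
        print(f"  {key}: mass={cl['mass']:.1f} p={cl['pvalue']:.4f}")
print("\n== significant band-power clusters ==")
for key, res in report.power_cluster_tests.items():
    for cl in res.get("significant", []):
        print(f"  {key}: mass={cl['mass']:.1f} p={cl['pvalue']:.4f}")
print("\n== theta-network pre/post tests (FDR-flagged) ==")
nt = report.network_tests
print(nt[nt.fdr_reject][["group", "band", "metric", "pvalue", "direction"]]
      .to_string(index=False))
print("\nExpected pattern: the 5 Hz group shows a positive P150 cluster, "
      "positive theta/alpha power clusters and a theta PLV increase; the "
      "sham group shows none beyond the nominal false-positive rate.")
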