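"""Full pipeline run: cohort -> phantoms -> acquisitions -> T1 maps -> ΔT1 ->
ROI metrics -> group statistics -> report bundle.

Equivalent to `delta-t1 run-all --out out/demo --seed 1 --subjects 3`.
"""

from deltat1 import RunConfig, run_end_to_end

config = RunConfig(
    out_dir="out/demo",
    seed=1,
    n_subjects=3,
    shape=(48, 48, 48),
    lesion_count=3,
    verbosity=0,
)
result = run_end_to_end(config)
print(result["report"])
print(f"outputs written to {result['out_dir']}/ "
      "(per-subject NIfTIs, roi_metrics.csv, covariates.csv, group_stats.csv,"
      " report.txt, provenance.json)")
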