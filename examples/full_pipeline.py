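"""End-to-end run: synthetic cohort -> full report bundle on disk.

Writes assumptions.json, causality_table.csv (6 cross-sectional + 8
longitudinal comparisons with bootstrap CIs), temporality.csv, the four
group-change tables, obesity risk ratios and a reproducibility manifest.
"""
from paircause import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(
    output_dir="paircause_demo_run",
    generator=CohortConfig(n_subjects=800, seed=1),
    statistics=("kernel", "skew"),
    bootstrap_B=200,          # raise to 2000 for production inference
    hoeffding_permutations=499,
    seed=1,
)
manifest = run_pipeline(cfg)
print("completed stages:", manifest["completed_stages"])
print("outputs:", manifest["outputs"])
print("config hash:", manifest["config_hash"])
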