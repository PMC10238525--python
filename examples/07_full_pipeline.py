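"""End-to-end run: simulate -> harmonize -> clump -> score -> combine -> evaluate.

Drives the whole pipeline on a downsized demo configuration and prints the
overall evaluation rows (PVE per PRS with bootstrap CIs).  The same run is
available from the shell as `multiprs run --config demo_config.yaml --out dir/`.
"""

import tempfile
from pathlib import Path

import pandas as pd

from multiprs import pipeline

cfg = pipeline.load_config(Path(__file__).parent / "demo_config.yaml")
with tempfile.TemporaryDirectory() as td:
    report = pipeline.run_pipeline(cfg, td)
    ev = pd.read_csv(Path(td) / "evaluation.tsv", sep="\t")

print("stage timings (s):", {k: v.get("seconds") for k, v in report["stages"].items()})
print(f"\nunrelated subset: {report['stages']['prep']['n_unrelated']} individuals; "
      f"hypertension AUC of the combined score: {report['stages']['evaluate']['htn_auc']}")

overall = ev[(ev.stratum_var == "all") & (ev.trait == "sbp_adj")]
print("\nSBP evaluation, all individuals (beta in mmHg per reference SD):")
print(
    overall[["prs_label", "n", "beta", "se", "pval", "pve", "ci_lo", "ci_hi"]]
    .round(3)
    .to_string(index=False)
)
print("\nMulti-PRS sums typically explain more variance than any single-GWAS "
      "component; every output file carries a SHA-256 hash in run_report.json, so "
      "a rerun with the same config and seed reproduces the run exactly.")
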