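"""Run the full analysis pipeline on a half-scale synthetic cohort.

Simulates the three analysis groups, derives spirometry, renders and
classifies paired CT volumes, fits the normative ULN models, and prints
the CT comparison table and the diagnostic accuracy of both FEV1/FVC
thresholds.
"""

from spiroprm import RunConfig, run_pipeline

config = RunConfig(
    outdir="scratch/example_run",
    seed=42,
    size_factor=0.5,          # half the published group sizes, for speed
    volume_shape=(24, 24, 24),
    log_level="WARNING",
)
report = run_pipeline(config)

t3 = report.tables["table3"]
cols = [c for c in t3.columns if c.endswith(("_mean", "_pct")) or c == "outcome"]
print(t3[cols].to_string(index=False))
print()
for rule, acc in report.accuracy.items():
    print(f"{rule:>10s}: sensitivity {acc['sensitivity']:.2f}, "
          f"specificity {acc['specificity']:.2f}")
print("\n-> discordant subjects carry the largest CT burden; the fixed 0.70")
print("   rule is the more sensitive and less specific of the two thresholds")
print(f"tables and manifest written to {report.outdir}")
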