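"""Run the full simulate→analyze→report pipeline and inspect the recovery
table.

Equivalent to `mechanoephys run-all --simulate --seed 0 --out out/`: the
simulated bundle (force curves, spikes, footprints, calcium, TTL events)
is written next to the report, clocks are aligned, every analysis stage
runs, and estimates are compared against the generator's manifest.
"""

from mechanoephys.pipeline import AnalysisConfig, run_pipeline

report = run_pipeline(AnalysisConfig(seed=0), "scratch/example_run")

print("statistics:")
print(report.statistics.to_string(index=False))
print("\nparameter recovery (estimate vs generator ground truth):")
print(report.recovery.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
print(f"\ntables written to {report.out_dir}; rerunning with the same seed "
      "reproduces the directory byte-for-byte.")
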