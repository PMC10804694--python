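"""A complete miniature run: simulate -> QC -> fit -> metrics -> statistics.

Twenty synthetic subjects on a 16^3 grid, a planted ASD deficit in tissue FA
and excess free water in the simulated tract, end-to-end through the
pipeline, finishing with the published-style report table (group mean +/- SD
and raw/FDR p per effect with significance stars).
"""

from fwtract.pipeline import RunConfig, make_report, run_pipeline

cfg = RunConfig(out_dir="scratch/example_run", seed=11, n_per_cell=5,
                grid_shape=(16, 16, 16), n_directions=64, tract_extent=10)
manifest = run_pipeline(cfg)

qc = manifest["stages"]["qc"]
print(f"subjects: {qc['n_input']} in, {qc['n_retained']} retained, "
      f"{qc['n_excluded']} excluded for motion\n")

report = make_report(cfg.out_dir)
print(report.to_string(index=False))
print("\nEach row is one whole-tract outcome; stars mark FDR-corrected")
print("significance (* < 0.05, ** < 0.01, *** < 0.001). Outputs, per-stage")
print(f"manifests and slice profiles are under {cfg.out_dir}/.")
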