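"""Run the complete pipeline (simulate -> preprocess -> decode -> stats ->
figures) into an output directory with a reproducibility manifest.

The same run is available from the shell as:
    erpdecode run-all --out out_dir --seed 5
"""

from erpdecode.pipeline import load_config, run_pipeline

config = load_config(overrides={
    "synth": {"n_subjects_per_group": 3, "trials_per_run": 40},
    "decoding": {"n_iterations": 10, "parameter_sets": ["set1"]},
    "inference": {"n_perm": 1000},
})
manifest = run_pipeline(config, "scratch/pipeline_demo", seed=5)

print("stages completed:", [s["stage"] for s in manifest["stages"]])
print("files written:", len(manifest["files"]))
print("content hash:", manifest["content_hash"][:16], "...")
print("-> re-running with the same seed reproduces this hash exactly;")
print("   figures (accuracy curves, confusion heatmaps, bin means) and")
print("   their CSV twins are in scratch/pipeline_demo/.")
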