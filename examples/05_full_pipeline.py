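"""One reproducible end-to-end run with a checksum manifest.

Simulate -> rarefy -> filter -> replicate-average -> all-pairs LSA ->
networks -> comparison -> diversity/ordination/PERMANOVA -> planted-edge
recovery, all written under one output directory.
"""

import pandas as pd

from elsanet import LsaConfig, RunConfig, run_pipeline, treatment_gradient_preset

config = RunConfig(
    out_dir="scratch/example_run",
    sim=treatment_gradient_preset(seed=11),
    lsa=LsaConfig(n_perm=1000, seed=11),
    alpha=0.05,
    seed=11,
)
manifest = run_pipeline(config)

print(f"config hash: {manifest['config_hash'][:16]}...")
print(f"{len(manifest['outputs'])} output files")
recovery = pd.read_csv("scratch/example_run/recovery.tsv", sep="\t", index_col=0)
print(recovery.to_string())
comparison = pd.read_csv("scratch/example_run/network_comparison.tsv", sep="\t", index_col=0)
print(comparison.round(3).to_string())
# Re-running with the same config and seed reproduces every checksum in the
# manifest; recovery reports how many planted associations the LSA network
# recovered at the edge-calling threshold (recall) and how clean the calls
# were (precision, sign accuracy).
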