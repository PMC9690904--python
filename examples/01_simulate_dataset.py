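"""Generate a synthetic EPIC-like methylation study with a planted episignature.

Builds a probe manifest and a full dataset (beta values, detection p-values,
sample sheet, ground truth) for 20 discovery cases carrying a 200-probe
hypomethylation signature, 2 signature-free outlier cases, 9 validation
cases, a VUS carrier, a 100-control pool and 3 "other disorder" cohorts.
"""

import episig as es

design = es.SimDesign(seed=1)
manifest = es.generate_manifest(design.n_probes, seed=design.seed)
dataset = es.generate_dataset(design, manifest)

print(f"probes: {len(dataset.beta)}, samples: {dataset.beta.shape[1]}")
print(dataset.samples["role"].value_counts().to_string())
sig = dataset.truth.signature_probe_ids
print(f"\nplanted signature probes: {len(sig)}")
print(f"planted delta-beta range: [{dataset.truth.delta.min():.3f}, {dataset.truth.delta.max():.3f}]")
# negative deltas: cases are hypomethylated relative to controls on these probes
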