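"""Validate the episignature, refine it, and classify a VUS carrier.

The nine validation cases are scored against the discovery signature, then
merged into training for a refined signature; the VUS carrier (who carries
the planted signature) is classified with the refined SVM model.
"""

import episig as es

design = es.SimDesign(seed=1)
dataset = es.generate_dataset(design, es.generate_manifest(design.n_probes, seed=1))
config = es.PipelineConfig(seed=1)
disc = es.run_discovery(config, dataset)
val = es.run_validation_and_refine(config, dataset, disc)

print("validation-case MVP scores against the discovery model:")
print(val.validation_scores.round(3).to_string())
print(f"\nall co-cluster with training cases: {(val.validation_coclustering == 'case').all()}")
print(f"discovery signature: {len(disc.probe_set.probes)} probes; "
      f"refined: {len(val.refined_probe_set.probes)} probes")
call, score = val.vus_call
print(f"VUS call: {call} (MVP = {score:.3f})")
# MVP near 1 = the sample's methylation matches the episignature;
# a 'positive' call supports reclassifying the variant as pathogenic.
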