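"""Call differentially methylated regions from the per-probe results.

Regions need >= 5 significant CpGs within 1 kb of each other, a mean
beta-difference of at least 5% and a Fisher combined p below 0.01.
"""

import episig as es
from episig.dmr import call_dmrs, dmrs_to_frame

design = es.SimDesign(seed=1)
dataset = es.generate_dataset(design, es.generate_manifest(design.n_probes, seed=1))
config = es.PipelineConfig(seed=1)
disc = es.run_discovery(config, dataset)

calls = call_dmrs(disc.dmp, dataset.manifest)
table = dmrs_to_frame(calls)
print(table.to_string(index=False))
print(f"\n{len(calls)} DMRs, "
      f"{sum(c.direction == 'hypo' for c in calls)} hypomethylated")
# an all-hypo planted signature should yield exclusively hypo regions
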