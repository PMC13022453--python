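"""Annotate chromosome extremities and build the Y' variant catalog.

Telomere tracts are scored by TG(1-3) telomericity, Y'/X elements located
by local alignment against element libraries.  Y' copies are condensed
(homopolymer runs > 4 collapsed to 4), compared with
sim = %identity * alignment_length / alignment_span, labeled as the same
variant above 99.9 % similarity, and clustered with average linkage; the
cluster count comes from the elbow of the silhouette-vs-k curve.
"""

from subtel import build_reference_genome, build_extremity_map
from subtel.catalog import (cluster_variants, label_instances,
                            similarity_matrix, variant_length_stats)
from subtel.config import RunConfig
from subtel.simulate import SimConfig

genome, ledger = build_reference_genome(SimConfig(), seed=1)
config = RunConfig()
maps = build_extremity_map(genome, ledger.library,
                           [("X_ancestor", ledger.x_ancestor)], config)

instances = [i for m in maps for i in m.yprime_instances]
print(f"Y' instances detected:    {len(instances)}")
print(f"extremities with Y':      {sum(1 for m in maps if m.yprime_instances)}")
print(f"X elements found:         {sum(m.x_interval is not None for m in maps)} / 32")

variants, matrix = label_instances(instances)
print(f"unique sequence variants: {len(variants)}")
clusters = cluster_variants(similarity_matrix(
    {v.label: v.representative for v in variants}))
print(f"clusters (silhouette elbow): {clusters.chosen_k}")
for s, _ in [variant_length_stats(variants)]:
    for fam in s:
        print(f"  {fam.family:5s} family: {fam.n} variants, "
              f"{fam.min}-{fam.max} bp (mean {fam.mean:.0f})")
# 34 instances collapse to 20 variants in 11 clusters: the two size
# families plus finer subfamily structure, as in a control strain.
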