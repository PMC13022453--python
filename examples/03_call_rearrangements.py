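"""Plant rearrangements in a survivor genome and call them back.

A survivor is compared to the control per extremity: Y' label strings are
aligned by edit distance (unmatched control labels = losses, unmatched
survivor labels = gains, a gained label equal to its neighbour = tandem
amplification, labels absent from the catalog = new variants, tested as
mosaics of known elements).  Terminal duplications and circularization are
called at the sequence level through their homology junctions.
"""

from subtel import build_reference_genome, build_extremity_map, plant_rearrangements
from subtel.catalog import label_instances
from subtel.config import RunConfig
from subtel.pipeline import analyze_survivor
from subtel.simulate import CassetteSpec, SimConfig

# place the duplication cassette between two Y'-free arms so the copied
# segment changes only core/X sequence, not Y' content
probe, probe_led = build_reference_genome(SimConfig(), seed=1)
x_free = [n for n, e in probe_led.extremities.items() if not e.yprimes]
cassettes = [CassetteSpec("bir1", x_free[0], 4000, x_free[1], 6000, 1000, "arm")]
genome, ledger = build_reference_genome(SimConfig(cassettes=cassettes), seed=1)
config = RunConfig()
xlib = [("X_ancestor", ledger.x_ancestor)]
cmaps = build_extremity_map(genome, ledger.library, xlib, config)
variants, _ = label_instances([i for m in cmaps for i in m.yprime_instances])

y_ends = [n for n, e in ledger.extremities.items() if len(e.yprimes) >= 2]
ids = ledger.library.ids
events = [
    {"kind": "loss", "extremity": y_ends[0], "index": 0},
    {"kind": "tandem_amplification", "extremity": y_ends[1], "index": 0},
    {"kind": "new_variant", "extremity": y_ends[2], "donors": [ids[0], ids[10]]},
    {"kind": "terminal_duplication", "extremity": x_free[0], "cassette_id": "bir1"},
]
survivor, _ = plant_rearrangements(genome, ledger, events, seed=7,
                                   survivor_name="survivor")

analysis = analyze_survivor("survivor", survivor, genome, cmaps, variants,
                            ledger.library, xlib, config)
for e in analysis.events:
    payload = {k: v for k, v in e.payload.items() if k != "segments"}
    print(f"{e.kind:22s} {e.extremity:10s} {payload}")
for label, dec in analysis.mosaics.items():
    print(f"mosaic {label}: coverage {dec.coverage:.0%}, donors {dec.donors}")
# Every planted event reappears with its extremity, labels, donor arm and
# exact junction homology; the new Y' is fully explained as a mosaic.
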