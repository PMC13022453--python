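"""Run configuration: the thresholds that drive every detector.

Defaults follow the analysis conventions for nanopore-assembled yeast
genomes: Y' elements are called from local alignments longer than 200 bp,
two Y' copies share a label above 99.9 % similarity of their
homopolymer-condensed sequences, mosaic decomposition requires exact matches
of more than 50 bp, tandem-repeat scanning starts at 30 bp units but circle
candidacy requires >= 50 bp units in arrays of >= 3 copies, and circle
merging/matching uses a 0.98 normalized alignment score.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    yprime_min_aln_len: int = 200       # bp; keep Y' alignments strictly longer
    label_sim_threshold: float = 99.9   # % similarity for same-variant labels
    condensation_max_run: int = 4       # homopolymers > 4 collapsed to 4
    mosaic_min_exact: int = 51          # bp; "perfect alignments of size > 50"
    tandem_min_unit: int = 30           # bp; tandem scan floor
    tandem_use_min_unit: int = 50       # bp; circle candidacy floor
    tandem_min_copies_circle: int = 3   # arrays of >= 3 units are circle candidates
    circle_merge_score: float = 0.98    # normalized score to merge similar units
    circle_match_score: float = 0.98    # normalized score to call a unit match
    upstream_window: int = 15000        # bp compared upstream of the X element
    extremity_window: int = 150000      # bp of each arm analyzed in canonical frame
    min_tract: int = 40                 # bp; minimum terminal telomere tract
    telomericity_threshold: float = 0.8
    telomericity_window: int = 20       # bp sliding window for tract detection
    tract_bridge: int = 10              # bp of non-telomeric gap bridged in a tract
    x_min_cov: float = 0.6              # X called if best alignment >= 60% of element
    anchor_length: int = 1000           # bp subtelomeric read anchor
    anchor_min_match: int = 800         # bp of anchor required on a read
    anchor_min_identity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "seed":
                continue
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"config field {f.name} must be strictly positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
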