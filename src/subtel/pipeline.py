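"""End-to-end orchestration: simulate -> annotate -> catalog -> compare ->
t-circles -> report, with a reproducible manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .annotate import (ExtremityMap, LengthDistribution, build_extremity_map,
                       measure_assembly_telomere_lengths)
from .catalog import (ClusterAssignment, YPrimeVariant, cluster_variants,
                      label_instances, label_survivor_instances,
                      variant_length_stats)
from .config import RunConfig
from .io import Genome, read_fasta, write_annotations, write_fasta
from .rearrange import (AlterationEvent, CloneSummary, detect_circularization,
                        detect_terminal_duplication, diff_genomes,
                        explain_mosaic, summarize_clone)
from .simulate import (CassetteSpec, SimConfig, TruthLedger,
                       build_reference_genome, plant_rearrangements)
from .tcircles import (collect_tracts, consolidate_circles,
                       find_perfect_tandem_arrays, specificity_filter_and_origin,
                       tandem_fraction)

log = logging.getLogger("subtel")


@dataclass
class PipelineManifest:
    control: str
    survivors: list[str]
    config: dict[str, Any]
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def export_yprime_library(ledger: TruthLedger, path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in ledger.library.variants:
            fh.write(f">{v.variant_id} family={v.family}\n{v.sequence}\n")


def export_x_library(ledger: TruthLedger, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">X_ancestor\n{ledger.x_ancestor}\n")


def load_element_library(path: str | Path) -> list[tuple[str, str]]:
    g = read_fasta(path)
    return list(g.chromosomes.items())


@dataclass
class CloneAnalysis:
    name: str
    maps: list[ExtremityMap]
    events: list[AlterationEvent]
    skipped: list[str]
    summary: CloneSummary
    mosaics: dict[str, Any]


def analyze_control(
    genome: Genome,
    yprime_library: list[tuple[str, str]],
    x_library: list[tuple[str, str]],
    config: RunConfig,
):
    """Annotate the control and build its Y' variant catalog."""
    from .simulate import YPrimeLibrary, YPrimeLibraryVariant

    lib = YPrimeLibrary([YPrimeLibraryVariant(n, "unknown", s)
                         for n, s in yprime_library])
    maps = build_extremity_map(genome, lib, x_library, config)
    instances = [i for m in maps for i in m.yprime_instances]
    variants: list[YPrimeVariant] = []
    matrix = None
    clusters: ClusterAssignment | None = None
    if len(instances) >= 2:
        variants, matrix = label_instances(
            instances, config.label_sim_threshold, config.condensation_max_run)
        if len(variants) >= 3:
            reps = {v.label: v.representative for v in variants}
            from .catalog import similarity_matrix
            vmatrix = similarity_matrix(reps)
            clusters = cluster_variants(vmatrix)
    return maps, variants, matrix, clusters


def analyze_survivor(
    name: str,
    survivor: Genome,
    control: Genome,
    control_maps: list[ExtremityMap],
    catalog: list[YPrimeVariant],
    yprime_library,
    x_library,
    config: RunConfig,
) -> CloneAnalysis:
    """Annotate one survivor and call every event class against the control."""
    maps = build_extremity_map(survivor, yprime_library, x_library, config)
    for m in maps:
        label_survivor_instances(m.yprime_instances, catalog,
                                 config.label_sim_threshold,
                                 config.condensation_max_run)
    events, skipped = diff_genomes(control_maps, maps)
    dup_events, dup_skipped = detect_terminal_duplication(
        control, survivor, control_maps, maps, config)
    circ_events, circ_anomalies = detect_circularization(survivor, control, config)
    events = events + dup_events + circ_events
    skipped = skipped + dup_skipped
    # mosaic explanation of novel labels
    catalog_seqs = {v.label: v.representative for v in catalog}
    mosaics: dict[str, Any] = {}
    seen_new = set()
    for m in maps:
        for inst in m.yprime_instances:
            if inst.label and inst.label.startswith("new") and inst.label not in seen_new:
                seen_new.add(inst.label)
                from .catalog import condense_homopolymers
                dec = explain_mosaic(
                    condense_homopolymers(inst.sequence, config.condensation_max_run),
                    catalog_seqs, config.mosaic_min_exact)
                mosaics[inst.label] = dec
    summary = summarize_clone(name, events, control_maps, skipped)
    return CloneAnalysis(name=name, maps=maps, events=events, skipped=skipped,
                         summary=summary, mosaics=mosaics)


def tcircle_analysis(
    genomes: dict[str, Genome],
    control_name: str,
    config: RunConfig,
):
    """Tandem arrays, circle consolidation, specificity/origin, fractions."""
    tracts_by_clone = {name: collect_tracts(g, config) for name, g in genomes.items()}
    arrays_by_clone = {}
    circles_by_clone = {}
    fractions = {}
    for name, tracts in tracts_by_clone.items():
        arrays_by_tract = {}
        all_arrays = []
        for ext_name, tract in tracts:
            arrs = find_perfect_tandem_arrays(
                tract, config.tandem_min_unit, 2, extremity=ext_name)
            arrays_by_tract[ext_name] = arrs
            all_arrays.extend(arrs)
        arrays_by_clone[name] = arrays_by_tract
        if name == control_name:
            circles_by_clone[name] = []
            continue
        circles = consolidate_circles(
            all_arrays, clone=name, min_unit_use=config.tandem_use_min_unit,
            min_copies=config.tandem_min_copies_circle,
            merge_score=config.circle_merge_score)
        circles = [specificity_filter_and_origin(
            c, tracts_by_clone, control_name, config.circle_match_score)
            for c in circles]
        circles_by_clone[name] = [c for c in circles if not c.discarded]
    for name in genomes:
        flat = [a for arrs in arrays_by_clone[name].values() for a in arrs]
        fractions[name] = tandem_fraction(
            name, tracts_by_clone[name], arrays_by_clone[name],
            circles_by_clone.get(name, []), config.tandem_use_min_unit,
            config.circle_match_score)
    return tracts_by_clone, arrays_by_clone, circles_by_clone, fractions


# ---------------------------------------------------------------------------
# Reporting


def events_table(analyses: list[CloneAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for e in a.events:
            rows.append({"clone": a.name, "extremity": e.extremity,
                         "kind": e.kind,
                         **{f"payload_{k}": v for k, v in e.payload.items()
                            if not isinstance(v, (list, dict))}})
    return pd.DataFrame(rows, columns=None if rows else
                        ["clone", "extremity", "kind"])


def run_pipeline(
    control_path: str | Path,
    survivor_paths: list[str | Path],
    yprime_library_path: str | Path,
    x_library_path: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
    seed: int = 0,
) -> PipelineManifest:
    """Full analysis of one control and >= 1 survivor assemblies.

    Writes BED annotations, the instance/variant tables, the similarity
    matrix, the event table, clone summaries, circle and tandem-fraction
    tables, and a manifest; reruns with identical inputs are byte-stable.
    """
    config = config or RunConfig()
    config.seed = seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in [control_path, *survivor_paths, yprime_library_path, x_library_path]:
        if not Path(p).exists():
            raise FileNotFoundError(p)
    manifest = PipelineManifest(
        control=str(control_path), survivors=[str(p) for p in survivor_paths],
        config=asdict(config), version=__version__, seed=seed)

    t0 = time.monotonic()
    control = read_fasta(control_path, name="control")
    ylib_records = load_element_library(yprime_library_path)
    xlib = load_element_library(x_library_path)
    from .simulate import YPrimeLibrary, YPrimeLibraryVariant
    ylib = YPrimeLibrary([YPrimeLibraryVariant(n, "unknown", s) for n, s in ylib_records])

    control_maps, variants, matrix, clusters = analyze_control(
        control, ylib_records, xlib, config)
    manifest.wall_clock["annotate_control"] = time.monotonic() - t0
    write_annotations(control_maps, control, outdir / "control.annotations.bed",
                      outdir / "control.annotations.tsv")

    if matrix is not None:
        pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids) \
            .to_csv(outdir / "similarity_matrix.tsv", sep="\t")
    var_rows = [{"label": v.label, "n_members": len(v.members),
                 "length": v.representative_length, "family": v.family,
                 "fragile": v.fragile,
                 "cluster": clusters.assignment.get(v.label) if clusters else None}
                for v in variants]
    pd.DataFrame(var_rows).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    stats, flagged = variant_length_stats(variants)
    with open(outdir / "catalog_summary.json", "w") as fh:
        json.dump({
            "n_instances": sum(len(m.yprime_instances) for m in control_maps),
            "n_extremities_with_yprime": sum(
                1 for m in control_maps if m.yprime_instances),
            "n_variants": len(variants),
            "chosen_k": clusters.chosen_k if clusters else None,
            "family_stats": [asdict(s) for s in stats],
            "intermediate_variants": flagged,
        }, fh, indent=1)

    analyses = []
    genomes = {"control": control}
    for path in survivor_paths:
        name = Path(path).stem
        t1 = time.monotonic()
        surv = read_fasta(path, name=name)
        genomes[name] = surv
        a = analyze_survivor(name, surv, control, control_maps, variants,
                             ylib, xlib, config)
        manifest.wall_clock[f"compare_{name}"] = time.monotonic() - t1
        write_annotations(a.maps, surv, outdir / f"{name}.annotations.bed",
                          outdir / f"{name}.annotations.tsv")
        analyses.append(a)

    events_table(analyses).to_csv(outdir / "events.tsv", sep="\t", index=False)
    with open(outdir / "clone_summaries.json", "w") as fh:
        json.dump({a.name: asdict(a.summary) for a in analyses}, fh, indent=1)

    t2 = time.monotonic()
    tracts, arrays, circles, fractions = tcircle_analysis(genomes, "control", config)
    manifest.wall_clock["tcircles"] = time.monotonic() - t2
    circ_rows = []
    for clone, cs in circles.items():
        for c in cs:
            for r in c.matches:
                circ_rows.append({"clone": clone, "circle": c.circle_id,
                                  "unit_length": c.unit_length, "origin": c.origin,
                                  "match_genome": r.genome,
                                  "match_extremity": r.extremity,
                                  "start": r.start, "phase": r.phase,
                                  "copies": r.copies})
    pd.DataFrame(circ_rows, columns=None if circ_rows else
                 ["clone", "circle", "unit_length", "origin", "match_genome",
                  "match_extremity", "start", "phase", "copies"]) \
        .to_csv(outdir / "circles.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(f) for f in fractions.values()]) \
        .to_csv(outdir / "tandem_fractions.tsv", sep="\t", index=False)
    arr_rows = [{"clone": clone, "extremity": a.extremity, "start": a.start,
                 "unit_length": a.unit_length, "copies": a.copies}
                for clone, by_tract in arrays.items()
                for arrs in by_tract.values() for a in arrs]
    pd.DataFrame(arr_rows, columns=None if arr_rows else
                 ["clone", "extremity", "start", "unit_length", "copies"]) \
        .to_csv(outdir / "tandem_arrays.tsv", sep="\t", index=False)

    length_rows = []
    for name, g in genomes.items():
        dist = measure_assembly_telomere_lengths(g, config)
        df = dist.summary()
        df.insert(0, "clone", name)
        length_rows.append(df)
    pd.concat(length_rows).to_csv(outdir / "telomere_lengths.tsv", sep="\t",
                                  index=False)

    manifest.outputs = {p.name: str(p) for p in sorted(outdir.iterdir())}
    manifest.save(outdir / "manifest.json")
    log.info("pipeline finished: %s clones, outputs in %s", len(analyses), outdir)
    return manifest


def calibrated_survivor_plan(
    ledger: TruthLedger,
    rng,
    mean_losses: float = 8.3,
    sd_losses: float = 3.7,
    mean_gains: float = 18.0,
    sd_gains: float = 8.9,
    n_mosaics: int = 2,
    n_mutated_novels: int = 0,
) -> list[dict[str, Any]]:
    """Random Y'-associated event plan at survivor-like event rates.

    Losses and gains per clone are drawn around the rates observed in
    uncapping survivors (~8 losses, ~18 gains per clone, concentrated on
    ~7 extremities); gains are realized as a mix of direct acquisitions and
    tandem amplifications.  Amplified ends are kept at <= 5 elements so
    they remain resolvable; mosaic donors are taken from different size
    families so the hybrid is unambiguously novel.
    """
    import numpy as np

    counts = {n: len(e.yprimes) for n, e in ledger.extremities.items()}
    ids = ledger.library.ids
    shorts = [v.variant_id for v in ledger.library.variants if v.family == "short"]
    longs = [v.variant_id for v in ledger.library.variants if v.family == "long"]
    events: list[dict[str, Any]] = []

    # events concentrate on a limited "active" set of extremities
    n_active = int(np.clip(rng.normal(7.4, 3.1), 3, 11))
    y_ends = [n for n, c in counts.items() if c > 0]
    x_ends = [n for n, c in counts.items() if c == 0]
    rng.shuffle(y_ends)
    rng.shuffle(x_ends)
    active = y_ends[: max(2, n_active - 1)] + x_ends[:1]

    n_loss = int(np.clip(rng.normal(mean_losses, sd_losses), 1, 14))
    budget = {n: counts[n] for n in active}
    for _ in range(n_loss):
        avail = [n for n in active if budget[n] > 0]
        if not avail:
            break
        ext = avail[rng.integers(0, len(avail))]
        events.append({"kind": "loss", "extremity": ext,
                       "index": int(rng.integers(0, budget[ext]))})
        budget[ext] -= 1

    n_gain = int(np.clip(rng.normal(mean_gains, sd_gains), 2, 30))
    gained = 0
    # events apply sequentially: gains/tandems index the post-loss structure
    occupancy = dict(budget)
    guard = 0
    while gained < n_gain and guard < 400:
        guard += 1
        ext = active[rng.integers(0, len(active))]
        if occupancy[ext] >= 1 and occupancy[ext] <= 3 and rng.random() < 0.6:
            copies = int(min(rng.integers(1, 4), 5 - occupancy[ext],
                             n_gain - gained))
            if copies < 1:
                continue
            events.append({"kind": "tandem_amplification", "extremity": ext,
                           "index": int(rng.integers(0, occupancy[ext])),
                           "copies": copies})
            occupancy[ext] += copies
            gained += copies
        elif occupancy[ext] <= 4:
            events.append({"kind": "gain", "extremity": ext,
                           "variant_id": ids[rng.integers(0, len(ids))],
                           "index": int(rng.integers(0, occupancy[ext] + 1))})
            occupancy[ext] += 1
            gained += 1

    candidates = [n for n in active if occupancy[n] <= 4]
    for _ in range(n_mosaics):
        if not candidates:
            break
        ext = candidates[rng.integers(0, len(candidates))]
        donors = [shorts[rng.integers(0, len(shorts))],
                  longs[rng.integers(0, len(longs))]]
        events.append({"kind": "new_variant", "extremity": ext,
                       "donors": donors})
        occupancy[ext] += 1
        candidates = [n for n in active if occupancy[n] <= 4]
    for _ in range(n_mutated_novels):
        if not candidates:
            break
        ext = candidates[rng.integers(0, len(candidates))]
        events.append({"kind": "new_variant", "extremity": ext,
                       "mode": "mutated",
                       "base_variant": ids[rng.integers(0, len(ids))],
                       "divergence": 0.08})
        occupancy[ext] += 1
        candidates = [n for n in active if occupancy[n] <= 4]
    return events


# ---------------------------------------------------------------------------
# Demo dataset


def default_yas_events(ledger: TruthLedger) -> list[dict[str, Any]]:
    """A Y'-associated survivor event plan on the default control."""
    with_y = [e.name for e in ledger.extremities.values() if len(e.yprimes) >= 2]
    x_only = [e.name for e in ledger.extremities.values() if not e.yprimes]
    ids = ledger.library.ids
    events: list[dict[str, Any]] = []
    plan = iter(with_y)
    for kind in ("loss", "tandem_amplification", "new_variant", "loss"):
        ext = next(plan, None)
        if ext is None:
            break
        if kind == "loss":
            events.append({"kind": "loss", "extremity": ext, "index": 0})
        elif kind == "tandem_amplification":
            events.append({"kind": "tandem_amplification", "extremity": ext,
                           "index": 0, "copies": 2})
        else:
            events.append({"kind": "new_variant", "extremity": ext,
                           "donors": [ids[1], ids[2]]})
    if x_only:
        events.append({"kind": "gain", "extremity": x_only[0], "variant_id": ids[0]})
    return events


def default_tiil_events(ledger: TruthLedger, seed: int) -> list[dict[str, Any]]:
    """A type-II-like survivor plan: heterogeneous telomere elongation with
    rolling-circle amplification, plus a few short ends."""
    import numpy as np

    rng = np.random.default_rng(seed)
    ext_names = list(ledger.extremities)
    origin_ext = ext_names[4]
    tract = ledger.extremities[origin_ext].tract
    unit_len = 139
    targets = [e for e in ext_names[6:12]]
    events: list[dict[str, Any]] = [{
        "kind": "circle_amplification",
        "origin": {"extremity": origin_ext, "offset": 60, "length": unit_len},
        "targets": [
            {"extremity": t, "copies": int(c), "phase": int(p)}
            for t, c, p in zip(
                targets[:3],
                rng.integers(4, 10, size=3),
                rng.integers(0, unit_len, size=3))
        ],
    }]
    for t in targets[3:]:
        events.append({"kind": "telomere_elongation", "extremity": t,
                       "length": int(rng.integers(4000, 10001))})
    return events


def make_demo(outdir: str | Path, seed: int = 0,
              config: SimConfig | None = None) -> dict[str, Path]:
    """Write a control, a YAS-like survivor, a T-II-L-like survivor and the
    truth ledger of each."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimConfig()
    control, ledger = build_reference_genome(config, seed=seed)
    yas, yas_ledger = plant_rearrangements(
        control, ledger, default_yas_events(ledger), seed=seed + 1,
        survivor_name="survivor_yas")
    tiil, tiil_ledger = plant_rearrangements(
        control, ledger, default_tiil_events(ledger, seed), seed=seed + 2,
        survivor_name="survivor_tiil")
    paths = {}
    for g, led, stem in ((control, ledger, "control"),
                         (yas, yas_ledger, "survivor_yas"),
                         (tiil, tiil_ledger, "survivor_tiil")):
        p = outdir / f"{stem}.fasta"
        write_fasta(g, p)
        paths[stem] = p
    ledger.to_json(outdir / "truth.json")
    yas_ledger.to_json(outdir / "truth_yas.json")
    tiil_ledger.to_json(outdir / "truth_tiil.json")
    export_yprime_library(ledger, outdir / "yprime_library.fasta")
    export_x_library(ledger, outdir / "x_library.fasta")
    paths["truth"] = outdir / "truth.json"
    paths["yprime_library"] = outdir / "yprime_library.fasta"
    paths["x_library"] = outdir / "x_library.fasta"
    return paths
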