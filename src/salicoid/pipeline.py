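"""End-to-end orchestration: simulate -> classify -> synteny -> ki -> date.

A single JSON-style config drives the run; every stochastic stage derives
its randomness from the top-level seed, so a run is byte-reproducible.
Artifacts are written per stage together with a manifest (inputs,
parameters, seed, SHA-256 checksums); the consolidated report aggregates
the orthology-call table, the rearrangement event list and rate, the Ki
summaries with rank-sum tests, and the dating scenarios.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import distances as dist
from . import homology as hom
from . import synteny as syn
from .dating import Calibration, DEFAULT_CALIBRATIONS, scenario_report
from .genome import SimulatedGenome, TruthLog
from .maps import LinkageMap
from .params import EvolutionParams
from .seqio import (genome_refseqs, write_anchor_tsv, write_genome_fasta,
                    write_genotype_tsv, write_json, write_marker_fasta)
from .simulate import (build_linkage_map, sample_markers, simulate_cp_genotypes,
                       simulate_pair)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "salicoid_run",
    "stages": {"simulate": True, "classify": True, "synteny": True,
               "distances": True, "dating": True},
    "simulate": {"map_noise_sd": 0.0,
                 "genotypes": {"enabled": False, "n_offspring": 200}},
    "homology": {"min_score": 40.0, "k": 11},
    "synteny": {"min_markers": 3, "min_inv_markers": 3},
    "distances": {"model": "tn93", "keep_saturated": True},
    "dating": {},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def resolve_config(config: Optional[Mapping] = None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


# ---------------------------------------------------------------------------
# classification over a marker panel
# ---------------------------------------------------------------------------

def classify_markers(markers: Sequence[hom.MarkerRecord],
                     reference: Sequence[hom.RefSeq],
                     min_score: float = 40.0, k: int = 11,
                     min_markers: int = 3) -> Dict[str, object]:
    """Search, paralog-2 discovery and two-pass orthology classification.

    Pass 1 classifies with an empty partner table (categories a/d only);
    the expected-ortholog calls seed a correspondence table from which
    syntenic partnerships are derived; pass 2 reclassifies with those
    partners so paralog-2 calls can be synteny-checked.
    """
    index = hom.ReferenceIndex(reference, k=k)
    ref_by_anchor = {(r.chrom, r.start, r.end): r for r in reference}

    hits_per_marker: Dict[str, List[hom.HomologyHit]] = {}
    paralog2: Dict[str, Optional[hom.Anchor]] = {}
    for marker in markers:
        hits_per_marker[marker.name] = hom.search_hits(
            marker.fragment, index, min_score=min_score, k=k)
        anchor = marker.expected_anchor
        key = (anchor.chrom, anchor.start, anchor.end)
        ref_gene = ref_by_anchor.get(key)
        if ref_gene is None:
            for r in reference:
                if r.anchor.overlaps(anchor):
                    ref_gene = r
                    break
        paralog2[marker.name] = (hom.find_paralog2(ref_gene, index,
                                                   min_score=min_score, k=k)
                                 if ref_gene is not None else None)

    def run_pass(partners: Mapping[str, Set[str]]) -> List[hom.OrthologyCall]:
        return [hom.classify_orthology(m, hits_per_marker[m.name], partners,
                                       paralog2=paralog2[m.name])
                for m in markers]

    first = run_pass({})
    corr_rows = []
    marker_by_name = {m.name: m for m in markers}
    for call in first:
        if call.category != hom.ORTHOLOG_EXPECTED:
            continue
        m = marker_by_name[call.marker]
        if m.linkage_group is None or m.cm is None:
            continue
        corr_rows.append((call.marker, m.linkage_group, m.cm,
                          call.paralog1.chrom, call.paralog1.midpoint))
    partners_map: Dict[str, Set[str]] = {}
    partner_table = None
    if corr_rows:
        corr = syn.make_correspondence(corr_rows)
        partner_table = syn.assign_syntenic_groups(corr, min_markers=min_markers)
        partners_map = partner_table.as_mapping()
    calls = run_pass(partners_map)

    final_rows = []
    for call in calls:
        m = marker_by_name[call.marker]
        if m.linkage_group is None or m.cm is None:
            continue
        if call.category == hom.ORTHOLOG_EXPECTED:
            locus = call.paralog1
        elif call.category == hom.ORTHOLOG_OF_PARALOG2:
            locus = call.paralog2
        else:
            continue
        if locus.midpoint is None:
            continue
        final_rows.append((call.marker, m.linkage_group, m.cm,
                           locus.chrom, locus.midpoint))
    corr = syn.make_correspondence(final_rows) if final_rows else \
        pd.DataFrame(columns=syn.CORR_COLUMNS)
    return {"calls": calls, "correspondence": corr,
            "partner_table": partner_table, "paralog2": paralog2}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _category_counts(calls: Sequence[hom.OrthologyCall]) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    return counts


def run(config: Optional[Mapping] = None) -> dict:
    """Execute the configured stages in dependency order; returns the report."""
    cfg = resolve_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    report: dict = {"seed": cfg["seed"], "stages_run": []}
    written: List[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    sim_cfg = dict(cfg["simulate"])
    noise_sd = sim_cfg.pop("map_noise_sd", 0.0)
    geno_cfg = sim_cfg.pop("genotypes", {"enabled": False})
    params = EvolutionParams.from_dict({**sim_cfg, "seed": cfg["seed"]})

    focal = reference = truth = None
    markers = lmap = None
    current = "simulate"
    try:
        if stages.get("simulate"):
            focal, reference, truth = simulate_pair(params)
            markers = sample_markers(focal, params)
            lmap = build_linkage_map(focal, markers, params, noise_sd=noise_sd)
            emit("focal_genome.fasta", lambda p: write_genome_fasta(focal, p))
            emit("reference_genome.fasta",
                 lambda p: write_genome_fasta(reference, p))
            emit("markers.fasta", lambda p: write_marker_fasta(markers, p))
            emit("anchors.tsv", lambda p: write_anchor_tsv(markers, p))
            emit("map.tsv", lambda p: lmap.to_tsv(p))
            emit("truth.json", lambda p: truth.to_json(p))
            report["stages_run"].append("simulate")
            report["simulate"] = {
                "n_markers": int(len(markers)),
                "n_chromosomes_focal": len(focal.chromosomes),
                "n_chromosomes_reference": len(reference.chromosomes),
                "n_true_events": len(truth.events),
            }
            if geno_cfg.get("enabled"):
                genotypes, marker_info = simulate_cp_genotypes(
                    lmap, int(geno_cfg.get("n_offspring", 200)),
                    seed=cfg["seed"])
                emit("genotypes.tsv",
                     lambda p: write_genotype_tsv(genotypes, marker_info, p))
                report["simulate"]["n_offspring"] = int(len(genotypes))

        classification = None
        current = "classify"
        if stages.get("classify"):
            if markers is None:
                raise RuntimeError("classify requires the simulate stage")
            positions = lmap.positions()
            ref_index_by_key = reference.gene_index()
            records = []
            for row in markers.itertuples():
                key = (row.ancestral_id, row.wgd_copy)
                chrom, gene = ref_index_by_key[key]
                lg, cm = positions.get(row.marker, (None, None))
                records.append(hom.MarkerRecord(
                    name=row.marker, fragment=row.fragment,
                    expected_anchor=hom.Anchor(chrom, gene.start, gene.end),
                    linkage_group=lg, cm=cm))
            classification = classify_markers(
                records, genome_refseqs(reference),
                min_score=cfg["homology"]["min_score"],
                k=cfg["homology"]["k"],
                min_markers=cfg["synteny"]["min_markers"])
            calls = classification["calls"]
            emit("orthology_calls.tsv",
                 lambda p: hom.calls_to_frame(calls).to_csv(
                     p, sep="\t", index=False))
            report["stages_run"].append("classify")
            report["classification"] = _category_counts(calls)

        current = "synteny"
        events = []
        if stages.get("synteny"):
            if classification is None:
                raise RuntimeError("synteny requires the classify stage")
            corr = classification["correspondence"]
            partner_table = syn.assign_syntenic_groups(
                corr, min_markers=cfg["synteny"]["min_markers"])
            events = (syn.detect_fission_fusion(partner_table)
                      + syn.detect_inversions(
                          corr, cfg["synteny"]["min_inv_markers"])
                      + syn.detect_single_marker_translocations(
                          corr, partner_table))
            assigned_total = sum(
                max(g.end for g in c.genes) for c in reference.chromosomes
                if c.genes)
            covered, percent = syn.map_coverage(corr, assigned_total)
            rate = syn.rearrangement_rate(len(events), params.t_spec)
            emit("events.json", lambda p: write_json(
                [e.to_dict() for e in events], p))
            report["stages_run"].append("synteny")
            report["synteny"] = {
                "n_events": len(events),
                "events_by_type": _category_counts_events(events),
                "rearrangement_rate_per_my_per_genome": rate,
                "coverage_bp": covered,
                "coverage_percent": percent,
            }

        current = "distances"
        summaries = {}
        if stages.get("distances"):
            if markers is None:
                raise RuntimeError("distances requires the simulate stage")
            ref_index_by_key = reference.gene_index()
            estimates: List[dist.KiEstimate] = []
            for row in markers.itertuples():
                key1 = (row.amplified_ancestral_id, 1)
                key2 = (row.amplified_ancestral_id, 2)
                if key1 not in ref_index_by_key or key2 not in ref_index_by_key:
                    continue
                p1 = ref_index_by_key[key1][1].sequence
                p2 = ref_index_by_key[key2][1].sequence
                if row.amplified_wgd_copy == 2:
                    p1, p2 = p2, p1  # focal fragment's true ortholog is copy 2
                triplet = dist.align_triplet(row.fragment, p1, p2)
                estimates.extend(dist.triplet_ki(
                    triplet, model=cfg["distances"]["model"], name=row.marker))
            by_class: Dict[str, List[dist.KiEstimate]] = {}
            for e in estimates:
                by_class.setdefault(e.ki_class, []).append(e)
            keep = cfg["distances"]["keep_saturated"]
            summaries = {cls: dist.summarize_ki(v, keep_saturated=keep)
                         for cls, v in by_class.items()}
            tests = {}
            pairs = [("ortholog", "cross_lineage_paralog"),
                     ("ortholog", "within_lineage_paralog"),
                     ("cross_lineage_paralog", "within_lineage_paralog")]
            for a, b in pairs:
                if a in by_class and b in by_class:
                    res = dist.rank_sum_test(
                        [e.distance for e in by_class[a]],
                        [e.distance for e in by_class[b]])
                    tests[f"{a}_vs_{b}"] = {"W": res.W, "U": res.U,
                                            "p": res.p, "method": res.method}
            emit("ki_estimates.tsv", lambda p: pd.DataFrame(
                [vars(e) for e in estimates]).to_csv(p, sep="\t", index=False))
            emit("ki_summaries.json", lambda p: write_json(
                {cls: s.to_dict() for cls, s in summaries.items()}, p))
            emit("ki_tests.json", lambda p: write_json(tests, p))
            report["stages_run"].append("distances")
            report["distances"] = {
                "n_pairs_per_class": {c: s.n for c, s in summaries.items()},
                "summaries": {c: s.to_dict() for c, s in summaries.items()},
                "tests": tests,
            }

        current = "dating"
        if stages.get("dating"):
            if not summaries:
                raise RuntimeError("dating requires the distances stage")
            cal_cfg = cfg["dating"].get("calibrations")
            calibrations = (tuple(Calibration(**c) for c in cal_cfg)
                            if cal_cfg else DEFAULT_CALIBRATIONS)
            scenarios = scenario_report(
                summaries["ortholog"].to_dict(),
                summaries["within_lineage_paralog"].to_dict(),
                calibrations)
            emit("dating.json", lambda p: write_json(scenarios, p))
            report["stages_run"].append("dating")
            report["dating"] = scenarios
    except Exception as exc:  # partial outputs stay on disk
        raise StageError(current, exc) from exc

    resolved_path = outdir / "config.json"
    write_json(cfg, resolved_path)
    written.append(resolved_path)
    manifest = {
        "seed": cfg["seed"],
        "parameters": params.to_dict(),
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in written},
    }
    write_json(manifest, outdir / "manifest.json")
    write_json(report, outdir / "report.json")
    return report


def _category_counts_events(events) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for e in events:
        counts[e.type] = counts.get(e.type, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: Mapping[str, str]) -> List[dict]:
    """Schema and sanity diagnostics for TSV/FASTA/JSON inputs.

    ``paths`` maps kind ('anchors', 'map', 'fasta', 'json') to a file path.
    Returns a list of diagnostics ({level, file, message}); never raises for
    content problems.
    """
    diags: List[dict] = []

    def add(level, file, message):
        diags.append({"level": level, "file": str(file), "message": message})

    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            add("error", path, "file does not exist")
            continue
        try:
            if kind == "anchors":
                df = pd.read_csv(path, sep="\t")
                for col in ("marker", "chrom", "start", "end"):
                    if col not in df.columns:
                        add("error", path, f"missing column {col!r}")
                if {"marker", "start", "end"} <= set(df.columns):
                    bad = df[df["start"] > df["end"]]
                    for row in bad.itertuples():
                        add("error", path,
                            f"start > end for marker {row.marker!r}")
                    dup = df.loc[df["marker"].duplicated(), "marker"]
                    for m in dup:
                        add("warning", path, f"duplicate marker name {m!r}")
                    if (df[["start", "end"]] < 1).any().any():
                        add("error", path,
                            "coordinates must be 1-based (>= 1)")
            elif kind == "map":
                df = pd.read_csv(path, sep="\t")
                for col in ("linkage_group", "marker", "cM"):
                    if col not in df.columns:
                        add("error", path, f"missing column {col!r}")
                if "marker" in df.columns:
                    for m in df.loc[df["marker"].duplicated(), "marker"]:
                        add("warning", path, f"duplicate marker name {m!r}")
                if {"linkage_group", "cM"} <= set(df.columns):
                    for g, sub in df.groupby("linkage_group"):
                        if (np.diff(sub["cM"].to_numpy()) < -1e-9).any():
                            add("warning", path,
                                f"cM not sorted within group {g}")
            elif kind == "fasta":
                from .seqio import read_located_fasta
                read_located_fasta(path)
            elif kind == "json":
                json.loads(path.read_text())
            else:
                add("warning", path, f"unknown input kind {kind!r}")
        except Exception as exc:
            add("error", path, f"unreadable: {exc}")
    return diags
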