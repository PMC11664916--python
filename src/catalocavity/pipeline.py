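"""End-to-end discovery funnel orchestration.

Runs the stages in order: template structures -> truncated-ligand cavity
clouds; target structures -> cavity clouds; template x target matching and
threshold filtering (a candidate passing ANY template enters the pool —
several related templates are used precisely to widen the net); the
sequence funnel (BLAST-hit filter -> greedy clustering -> conserved-
arginine filter) whose survivors join the pool; docking evaluation of the
pooled candidates and a per-provenance-group top-k shortlist.  Nothing is
silently dropped by triage: the match report keeps the flavin-side and
electrostatic flags for reviewer inspection.

Outputs are deterministic for a fixed config and seed (reports carry no
timestamps), so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import __version__
from .cavity import PointCloud, procreate_cavity, write_cloud_json
from .docking_eval import build_matrix, read_docking_table, top_k
from .matching import MatchResult, align_clouds, filter_matches, match_report_frame
from .seqpipe import (
    conserved_residue_filter,
    filter_hits,
    greedy_cluster,
    read_blast_table,
    read_fasta,
)
from .structure_io import infer_ligand_spec, locate_flavin, read_structure, truncate_ligand

__all__ = ["RunConfig", "RunReport", "run_all", "load_config", "StageError"]

log = logging.getLogger("catalocavity")


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


@dataclass
class RunConfig:
    """Inputs and thresholds for a full funnel run (defaults = funnel values)."""

    templates: list[dict] = field(default_factory=list)   # {path, ligand}
    targets: list[dict] = field(default_factory=list)     # {path, ligand}
    blast_table: Optional[str] = None
    fasta: Optional[str] = None
    reference_id: Optional[str] = None
    docking_table: Optional[str] = None
    out_dir: str = "catalocavity_out"
    seed: int = 0
    # structure side
    keep_carbons: int = 8
    flavin_residue: str = "FAD"
    grid_spacing: float = 0.8
    probe_radius: float = 1.4
    max_ligand_distance: float = 5.0
    # matching
    score_max: float = 0.05
    ov12_min: float = 70.0
    ov21_min: float = 10.0
    strict_ov21: float = 30.0
    large_pool_size: int = 100
    epsilon: float = 1.0
    # sequence funnel
    min_identity: float = 30.0
    min_cov: float = 80.0
    cluster_cutoff: float = 70.0
    ref_pos: int = 451
    conserved_residue: str = "R"
    # docking
    top_k: int = 5

    def __post_init__(self) -> None:
        if not (self.templates or self.blast_table or self.docking_table):
            raise ValueError("config needs at least one input source")
        if not 0 < self.score_max <= 1:
            raise ValueError("score_max must be in (0, 1]")
        for name in ("ov12_min", "ov21_min", "strict_ov21",
                     "min_identity", "min_cov", "cluster_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 101:
                raise ValueError(f"{name}={v} outside [0, 101]")


@dataclass
class RunReport:
    """Per-stage counts plus the final shortlist with provenance."""

    config: dict
    version: str
    stage_counts: dict = field(default_factory=dict)
    matches: list = field(default_factory=list)
    structure_candidates: list = field(default_factory=list)
    sequence_candidates: list = field(default_factory=list)
    shortlist: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"catalocavity {self.version} run report", ""]
        for stage, counts in self.stage_counts.items():
            lines.append(f"[{stage}] " + ", ".join(
                f"{k}={v}" for k, v in counts.items()))
        lines.append("")
        lines.append("shortlist: " + (", ".join(
            f"{c['candidate_id']} ({c['group']}, sum={c['score_sum']:.3f})"
            for c in self.shortlist) or "(empty)"))
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _structure_to_cloud(entry: dict, config: RunConfig, *,
                        truncate: bool) -> PointCloud:
    s = read_structure(entry["path"])
    spec = infer_ligand_spec(s, entry["ligand"])
    if truncate and len(spec.chain_carbons) > config.keep_carbons:
        s = truncate_ligand(s, spec, config.keep_carbons)
        spec = dataclasses.replace(
            spec, chain_carbons=spec.chain_carbons[:config.keep_carbons])
    frame = locate_flavin(s, config.flavin_residue, ligand_spec=spec)
    return procreate_cavity(
        s, spec, frame, grid_spacing=config.grid_spacing,
        probe_radius=config.probe_radius,
        max_ligand_distance=config.max_ligand_distance)


def run_all(config: RunConfig) -> RunReport:
    """Execute the full funnel and write the run report.

    Raises StageError on any stage failure; an empty shortlist is a
    successful run with a warning.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)

    # --- stage 1: cavities -------------------------------------------------
    templates: list[PointCloud] = []
    targets: list[PointCloud] = []
    try:
        for entry in config.templates:
            cloud = _structure_to_cloud(entry, config, truncate=True)
            templates.append(cloud)
            write_cloud_json(cloud, os.path.join(
                config.out_dir, f"template_{cloud.source_id}.json"))
        for entry in config.targets:
            targets.append(_structure_to_cloud(entry, config, truncate=False))
    except Exception as exc:
        raise StageError(f"[cavity] {exc}") from exc
    report.stage_counts["cavity"] = {
        "templates": len(templates), "targets": len(targets),
        "template_points": sum(len(c) for c in templates),
        "target_points": sum(len(c) for c in targets)}
    log.info("cavity: %d templates, %d targets", len(templates), len(targets))

    # --- stage 2: matching -------------------------------------------------
    results: list[MatchResult] = []
    structure_candidates: list[str] = []
    try:
        large_pool = len(targets) > config.large_pool_size
        for template in templates:
            for target in targets:
                results.append(align_clouds(template, target,
                                            epsilon=config.epsilon))
        kept = filter_matches(results, score_max=config.score_max,
                              ov12_min=config.ov12_min,
                              ov21_min=config.ov21_min,
                              strict_ov21=config.strict_ov21,
                              large_pool=large_pool)
        kept_ids = {(r.template_id, r.target_id) for r in kept}
        # union over templates: any-pass admits the target
        structure_candidates = list(dict.fromkeys(r.target_id for r in kept))
        frame = match_report_frame(results, kept_ids)
        frame.to_csv(os.path.join(config.out_dir, "matches.tsv"),
                     sep="\t", index=False)
        report.matches = frame.to_dict(orient="records")
    except Exception as exc:
        raise StageError(f"[matching] {exc}") from exc
    report.stage_counts["matching"] = {
        "pairs": len(results), "kept_pairs": sum(1 for r in report.matches
                                                 if r["kept"]),
        "candidates": len(structure_candidates)}
    report.structure_candidates = structure_candidates
    log.info("matching: %d pairs -> %d structure candidates",
             len(results), len(structure_candidates))

    # --- stage 3: sequence funnel -----------------------------------------
    sequence_candidates: list[str] = []
    try:
        if config.blast_table and config.fasta:
            hits = read_blast_table(config.blast_table)
            passing = filter_hits(hits, config.min_identity, config.min_cov)
            pass_ids = {h.subject_id for h in passing}
            seqs = read_fasta(config.fasta)
            if config.reference_id is None:
                raise ValueError("reference_id required with a FASTA input")
            reference = next((r for r in seqs if r.id == config.reference_id),
                             None)
            if reference is None:
                raise ValueError(f"reference {config.reference_id!r} not in FASTA")
            pool_seqs = [r for r in seqs if r.id in pass_ids]
            n_clusters = 0
            if pool_seqs:
                clusters = greedy_cluster(pool_seqs, config.cluster_cutoff)
                n_clusters = len(clusters.clusters)
                reps = [r for r in pool_seqs
                        if r.id in set(clusters.representative_ids)]
                kept_reps, reports = conserved_residue_filter(
                    reps, reference, config.ref_pos, config.conserved_residue)
                sequence_candidates = [r.id for r in kept_reps]
                import pandas as pd
                pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
                    os.path.join(config.out_dir, "conservation.tsv"),
                    sep="\t", index=False)
            report.stage_counts["sequence"] = {
                "hits": len(hits), "hits_pass": len(passing),
                "sequences": len(pool_seqs), "clusters": n_clusters,
                "arg_kept": len(sequence_candidates)}
            log.info("sequence funnel: %d hits -> %d pass -> %d clusters "
                     "-> %d with conserved arginine", len(hits), len(passing),
                     n_clusters, len(sequence_candidates))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[seqpipe] {exc}") from exc
    report.sequence_candidates = sequence_candidates

    # --- stage 4: docking evaluation and shortlist -------------------------
    try:
        pool = ([(c, "structure") for c in structure_candidates]
                + [(c, "sequence") for c in sequence_candidates])
        if config.docking_table and pool:
            clusters_in = read_docking_table(config.docking_table)
            pool_ids = [c for c, _ in pool]
            groups = dict(pool)
            relevant = [c for c in clusters_in if c.candidate_id in groups]
            matrix = build_matrix(relevant, candidates=pool_ids)
            matrix.to_frame().to_csv(
                os.path.join(config.out_dir, "score_matrix.tsv"), sep="\t")
            import warnings as _warnings
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                shortlist_ids = top_k(matrix, config.top_k, groups)
                report.warnings.extend(str(w.message) for w in caught)
            sums = matrix.sums
            report.shortlist = [
                {"candidate_id": c, "group": groups[c],
                 "score_sum": sums.get(c, 0.0)} for c in shortlist_ids]
            report.stage_counts["docking"] = {
                "clusters": len(clusters_in), "pool": len(pool_ids),
                "shortlist": len(report.shortlist)}
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[docking] {exc}") from exc

    if not report.shortlist:
        report.warnings.append("empty shortlist: no candidate passed the funnel")
        log.warning("empty shortlist")

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        fh.write(report.to_json())
    with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
        fh.write(report.to_text())
    return report
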