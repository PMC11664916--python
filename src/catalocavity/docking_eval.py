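"""Docking-result evaluation and candidate ranking.

Docking engines report, per candidate enzyme and ligand, a set of pose
clusters with a binding energy E (kcal/mol) and the distance d (Angstrom)
between the substrate's carboxyl carbon and the flavin N5.  For each
candidate-ligand pair the cluster with minimal distance is selected (tie:
lower energy, then lower cluster id) and scored with the combined score
|E/d|, which favours both tight binding and a catalytically close carboxyl
group.  Scores are arranged in a candidate x ligand matrix; candidates are
ranked by their row sums, optionally per provenance group (e.g. top-5 among
sequence-derived and top-5 among structure-derived candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DockingCluster",
    "ScoreMatrix",
    "select_cluster",
    "combined_score",
    "build_matrix",
    "top_k",
    "pareto_clusters",
    "read_docking_table",
    "DOCKING_COLUMNS",
]

DOCKING_COLUMNS = ["candidate_id", "ligand_id", "cluster_id",
                   "energy_kcal_mol", "distance_A"]


@dataclass(frozen=True)
class DockingCluster:
    candidate_id: str
    ligand_id: str
    cluster_id: int
    energy: float    # kcal/mol, typically negative
    distance: float  # Angstrom, carboxyl C to flavin N5

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")


@dataclass(frozen=True)
class ScoreMatrix:
    """Candidate x ligand combined-score grid with per-candidate sums.

    Missing candidate-ligand pairs score 0 (so sums stay comparable across
    candidates with unequal docking coverage) and are listed in ``missing``.
    """

    candidates: tuple[str, ...]
    ligands: tuple[str, ...]
    scores: np.ndarray  # (n_candidates, n_ligands), >= 0
    missing: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        sc = np.asarray(self.scores, float)
        object.__setattr__(self, "scores", sc)
        if sc.shape != (len(self.candidates), len(self.ligands)):
            raise ValueError("score grid shape mismatch")
        if (sc < 0).any():
            raise ValueError("combined scores must be >= 0")

    @property
    def sums(self) -> dict[str, float]:
        return {c: float(self.scores[i].sum())
                for i, c in enumerate(self.candidates)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.candidates),
                            columns=list(self.ligands))


def select_cluster(clusters: Sequence[DockingCluster]) -> DockingCluster:
    """Representative cluster for one candidate-ligand pair.

    Minimal carboxyl-to-N5 distance wins; ties resolved by lower (more
    negative) energy, then by lower cluster id.  Order-invariant.
    """
    if not clusters:
        raise ValueError("no clusters to select from")
    return min(clusters, key=lambda c: (c.distance, c.energy, c.cluster_id))


def combined_score(energy: float, distance: float) -> float:
    """|E/d|: absolute ratio of binding energy to carboxyl-N5 distance."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return abs(energy / distance)


def build_matrix(all_clusters: Sequence[DockingCluster],
                 candidates: Optional[Sequence[str]] = None,
                 ligands: Optional[Sequence[str]] = None) -> ScoreMatrix:
    """Group clusters by (candidate, ligand), select, score, and sum.

    Exact duplicate rows are dropped before selection.  Candidate and
    ligand orderings default to first appearance; passing them explicitly
    allows rows/columns with no clusters at all (scored 0).
    """
    unique = list(dict.fromkeys(all_clusters))  # dedup, preserve order
    if candidates is None:
        candidates = list(dict.fromkeys(c.candidate_id for c in unique))
    if ligands is None:
        ligands = list(dict.fromkeys(c.ligand_id for c in unique))
    groups: dict[tuple[str, str], list[DockingCluster]] = {}
    for c in unique:
        groups.setdefault((c.candidate_id, c.ligand_id), []).append(c)
    scores = np.zeros((len(candidates), len(ligands)))
    missing = []
    for i, cand in enumerate(candidates):
        for j, lig in enumerate(ligands):
            grp = groups.get((cand, lig))
            if grp is None:
                missing.append((cand, lig))
                continue
            best = select_cluster(grp)
            scores[i, j] = combined_score(best.energy, best.distance)
    return ScoreMatrix(tuple(candidates), tuple(ligands), scores,
                       tuple(missing))


def top_k(matrix: ScoreMatrix, k: int = 5,
          group_labels: Optional[Mapping[str, str]] = None) -> list[str]:
    """The k candidates with the largest score sums, per group.

    With ``group_labels`` (candidate id -> group name) the selection runs
    within each group and the groups are concatenated in sorted group-name
    order — mirroring a per-source shortlist (e.g. 5 + 5 finalists from two
    search arms).  Ties are broken by candidate id ascending.  If a group
    holds fewer than k candidates, all of them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sums = matrix.sums
    if group_labels is None:
        groups: dict[str, list[str]] = {"": list(matrix.candidates)}
    else:
        groups = {}
        for cand in matrix.candidates:
            groups.setdefault(group_labels.get(cand, ""), []).append(cand)
    out: list[str] = []
    for name in sorted(groups):
        members = groups[name]
        if len(members) < k:
            warnings.warn(f"group {name!r} has only {len(members)} candidates "
                          f"(k={k}); returning all", stacklevel=2)
        ranked = sorted(members, key=lambda c: (-sums[c], c))
        out.extend(ranked[:k])
    return out


def pareto_clusters(clusters: Sequence[DockingCluster]) -> list[DockingCluster]:
    """Clusters non-dominated in (distance, energy), both minimized.

    Reviewer-facing alternative view to the minimal-distance rule: a
    cluster is kept iff no other cluster is at least as close AND at least
    as tightly bound, with one strict.  Sorted by distance ascending.
    """
    keep = []
    for c in clusters:
        dominated = any(
            (o.distance <= c.distance and o.energy <= c.energy)
            and (o.distance < c.distance or o.energy < c.energy)
            for o in clusters)
        if not dominated:
            keep.append(c)
    return sorted(keep, key=lambda c: (c.distance, c.energy, c.cluster_id))


def read_docking_table(path) -> list[DockingCluster]:
    """Read a TSV of docking clusters (header = DOCKING_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(DOCKING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"docking table missing columns: {sorted(missing)}")
    return [DockingCluster(str(r.candidate_id), str(r.ligand_id),
                           int(r.cluster_id), float(r.energy_kcal_mol),
                           float(r.distance_A))
            for r in df.itertuples(index=False)]
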