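"""Rigid cavity point-cloud matching, scoring, filtering and triage.

A template cloud is aligned onto a target cloud by superposing their flavin
frames (N5 on N5, ring normal on ring normal, in-plane axis on in-plane
axis) followed by ICP refinement.  Matches are scored with a [0, 1]
composite dissimilarity (lower is better) built from the bidirectional
overlap percentages and the property distances of matched point pairs, and
filtered with the discovery-funnel thresholds: total score < 0.05 and
overlaps above 70 % (template -> target) and above 10 % (target ->
template; 30 % for larger candidate pools).  Two automated triage checks
replace the manual inspection of matching scenes: whether both flavins sit
on the same side of the matched cloud, and whether the potential next to N5
stabilizes negative charge.

The score formula itself is this package's own construction (the thresholds
it serves come from the discovery funnel; the platform that produced them
does not publish its formula); it is calibrated so a self-match scores
exactly 0 and fully disjoint clouds score 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .cavity import PointCloud, negative_charge_stabilization
from .structure_io import FlavinFrame, flavin_frame_axes

__all__ = [
    "MatchResult",
    "align_clouds",
    "overlap_fraction",
    "total_score",
    "flavin_same_side",
    "filter_matches",
    "match_report_frame",
]

DEFAULT_EPSILON = 1.0          # Angstrom pairing tolerance
ELECTRO_DEADBAND_FRACTION = 0.10
HBOND_COMPAT_TOL = 0.5
W_GEO, W_PROP = 0.7, 0.3
ICP_MAX_ITER = 50
ICP_TOL = 1e-6
LARGE_POOL_SIZE = 100          # targets; ">30 %" reverse-overlap rule applies above


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one template cloud against one target cloud.

    ``rotation``/``translation`` map template coordinates into the target
    frame.  ``total_score`` is the composite dissimilarity (lower = better);
    overlaps are percentages.  ``electro_ok`` is tri-state: True/False, or
    None when no target point lies near N5 (inconclusive).
    """

    rotation: np.ndarray
    translation: np.ndarray
    total_score: float
    overlap_1to2: float
    overlap_2to1: float
    flavin_same_side: bool
    electro_ok: Optional[bool]
    template_id: str = ""
    target_id: str = ""
    kept: Optional[bool] = None

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation matrix is not orthonormal")
        for ov in (self.overlap_1to2, self.overlap_2to1):
            if not 0.0 <= ov <= 100.0:
                raise ValueError("overlap percentages must lie in [0, 100]")
        if self.total_score < 0:
            raise ValueError("total_score must be >= 0")


def _electro_deadband(cloud: PointCloud) -> float:
    e = np.abs(cloud.electrostatic)
    return ELECTRO_DEADBAND_FRACTION * (e.max() if len(e) else 0.0)


def _compat_matrix(a_props: np.ndarray, b_props: np.ndarray,
                   deadband: float) -> np.ndarray:
    """Pairwise property compatibility between a-points (rows) and b-points.

    Electrostatic sign must agree unless either value sits inside the
    dead-band (then it is a wildcard); donor and acceptor scores must agree
    within HBOND_COMPAT_TOL.
    """
    ea, eb = a_props[:, 0][:, None], b_props[:, 0][None, :]
    sign_ok = (np.abs(ea) <= deadband) | (np.abs(eb) <= deadband) | (ea * eb > 0)
    don_ok = np.abs(a_props[:, 1][:, None] - b_props[:, 1][None, :]) <= HBOND_COMPAT_TOL
    acc_ok = np.abs(a_props[:, 2][:, None] - b_props[:, 2][None, :]) <= HBOND_COMPAT_TOL
    return sign_ok & don_ok & acc_ok


def _matched_mask(a: PointCloud, b: PointCloud, transform, epsilon: float,
                  properties: bool) -> np.ndarray:
    """Boolean mask over a-points: has a compatible b-point within epsilon."""
    R, t = transform
    moved = a.coords @ np.asarray(R, float).T + np.asarray(t, float)
    tree = cKDTree(b.coords)
    neighbor_lists = tree.query_ball_point(moved, epsilon)
    mask = np.zeros(len(a), bool)
    if properties:
        deadband = _electro_deadband(a)
    for i, idx in enumerate(neighbor_lists):
        if not idx:
            continue
        if not properties:
            mask[i] = True
            continue
        compat = _compat_matrix(a.properties[i:i + 1], b.properties[idx], deadband)
        mask[i] = bool(compat.any())
    return mask


def overlap_fraction(a: PointCloud, b: PointCloud, transform,
                     epsilon: float = DEFAULT_EPSILON,
                     properties: bool = True) -> float:
    """Percentage of a-points with a property-compatible b-point within epsilon.

    ``transform`` is a (rotation, translation) pair mapping a's coordinates
    into b's frame.  ``properties=False`` gives the geometry-only overlap.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("clouds must be non-empty")
    mask = _matched_mask(a, b, transform, epsilon, properties)
    return 100.0 * int(mask.sum()) / len(a)


def _property_distance_term(a: PointCloud, b: PointCloud, transform,
                            epsilon: float) -> float:
    """Mean normalized property distance over matched pairs, both directions.

    Each matched a-point contributes the distance to its nearest compatible
    b-point: |delta e| / (2 e_max) for the potential (e_max over both
    clouds) and |delta| for the [0, 1]-bounded donor/acceptor/
    hydrophobicity/buriedness scores, averaged over the five properties and
    capped at 1.  No matched pairs at all -> 1 (maximal mismatch).
    """
    emax = max(np.abs(a.electrostatic).max(initial=0.0),
               np.abs(b.electrostatic).max(initial=0.0), 1e-12)
    R, t = transform
    R = np.asarray(R, float)
    t = np.asarray(t, float)
    Rinv, tinv = R.T, -R.T @ t
    dists: list[float] = []

    def collect(src: PointCloud, dst: PointCloud, tr) -> None:
        Rm, tm = tr
        moved = src.coords @ np.asarray(Rm, float).T + np.asarray(tm, float)
        tree = cKDTree(dst.coords)
        neighbor_lists = tree.query_ball_point(moved, epsilon)
        deadband = _electro_deadband(src)
        for i, idx in enumerate(neighbor_lists):
            if not idx:
                continue
            compat = _compat_matrix(src.properties[i:i + 1],
                                    dst.properties[idx], deadband)[0]
            if not compat.any():
                continue
            cand = np.asarray(idx)[compat]
            d = np.linalg.norm(dst.coords[cand] - moved[i], axis=1)
            j = cand[np.argmin(d)]
            delta = np.abs(src.properties[i] - dst.properties[j])
            delta[0] = delta[0] / (2.0 * emax)
            dists.append(min(float(delta.mean()), 1.0))

    collect(a, b, (R, t))
    collect(b, a, (Rinv, tinv))
    if not dists:
        return 1.0
    return float(np.mean(dists))


def total_score(a: PointCloud, b: PointCloud, transform,
                epsilon: float = DEFAULT_EPSILON,
                properties: bool = True) -> float:
    """Composite [0, 1] dissimilarity of two clouds under a rigid transform.

    score = W_GEO * (1 - H/100) + W_PROP * property_term, where H is the
    harmonic mean of the two directional overlap percentages.  Identical
    clouds score 0; disjoint clouds score 1.
    """
    ov_ab = overlap_fraction(a, b, transform, epsilon, properties)
    R, t = transform
    R = np.asarray(R, float)
    t = np.asarray(t, float)
    inv = (R.T, -R.T @ t)
    ov_ba = overlap_fraction(b, a, inv, epsilon, properties)
    sym = 0.0 if (ov_ab <= 0 or ov_ba <= 0) else 2.0 * ov_ab * ov_ba / (ov_ab + ov_ba)
    prop_term = _property_distance_term(a, b, (R, t), epsilon) if properties else (
        1.0 if sym == 0.0 else 0.0)
    return W_GEO * (1.0 - sym / 100.0) + W_PROP * prop_term


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _frame_transform(src: FlavinFrame, dst: FlavinFrame) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform superposing src's flavin frame onto dst's (n5 -> n5)."""
    A = flavin_frame_axes(src)   # rows = axes
    B = flavin_frame_axes(dst)
    R = B.T @ A
    t = dst.n5 - R @ src.n5
    return R, t


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping points P onto Q (proper rotation)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cq - R @ cp


def align_clouds(template: PointCloud, target: PointCloud,
                 epsilon: float = DEFAULT_EPSILON,
                 properties: bool = True,
                 electro_radius: float = 4.0) -> MatchResult:
    """Align a template cloud onto a target cloud and score the match.

    Initialization superposes the flavin frames; ICP then alternates
    nearest-neighbour pairing (pairs within 2 * epsilon, ties broken by the
    lowest target index) with least-squares rigid updates, for at most
    ICP_MAX_ITER iterations or until the score improves by less than
    ICP_TOL.  The transform with the lowest total score seen along the
    trajectory is returned.
    """
    if len(template) == 0 or len(target) == 0:
        raise ValueError("clouds must be non-empty")
    R, t = _frame_transform(template.frame, target.frame)
    tree = cKDTree(target.coords)

    def pairs(Rc, tc):
        moved = template.coords @ Rc.T + tc
        dist, idx = tree.query(moved, k=1, distance_upper_bound=2.0 * epsilon)
        ok = np.isfinite(dist)
        return ok, idx

    ok, idx = pairs(R, t)
    if not ok.any():
        # frames superposed but supports disjoint: report the worst case
        return MatchResult(R, t, 1.0, 0.0, 0.0,
                           flavin_same_side(template, target, (R, t)),
                           None, template.source_id, target.source_id)

    best_score = total_score(template, target, (R, t), epsilon, properties)
    best = (R, t)
    prev_score = best_score
    for _ in range(ICP_MAX_ITER):
        ok, idx = pairs(R, t)
        if not ok.any():
            break
        R, t = _kabsch(template.coords[ok], target.coords[idx[ok]])
        score = total_score(template, target, (R, t), epsilon, properties)
        if score < best_score:
            best_score, best = score, (R, t)
        if abs(prev_score - score) < ICP_TOL:
            break
        prev_score = score

    R, t = best
    ov12 = overlap_fraction(template, target, (R, t), epsilon, properties)
    ov21 = overlap_fraction(target, template, (R.T, -R.T @ t), epsilon, properties)
    return MatchResult(
        rotation=R, translation=t, total_score=best_score,
        overlap_1to2=ov12, overlap_2to1=ov21,
        flavin_same_side=flavin_same_side(template, target, (R, t)),
        electro_ok=negative_charge_stabilization(target, electro_radius),
        template_id=template.source_id, target_id=target.source_id)


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------

def flavin_same_side(template: PointCloud, target: PointCloud,
                     transform) -> bool:
    """Do the two flavins sit on the same side of the matched cloud?

    The template cloud and frame are mapped into the target's space.  The
    check passes iff (a) the ring normals subtend less than 90 degrees and
    (b) the two N5 atoms fall on the same side of the plane through the
    mapped template cloud's centroid, normal to the mapped ring normal.
    Catches matching scenes where the clouds superpose well but the
    cofactors face opposite directions.
    """
    R, t = transform
    R = np.asarray(R, float)
    t = np.asarray(t, float)
    tf = template.frame.transformed(R, t)
    cos = float(np.dot(tf.ring_normal, target.frame.ring_normal))
    if cos <= 0.0:
        return False
    centroid = (template.coords @ R.T + t).mean(axis=0)
    s_template = float(np.dot(tf.n5 - centroid, tf.ring_normal))
    s_target = float(np.dot(target.frame.n5 - centroid, tf.ring_normal))
    return s_template * s_target > 0.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_matches(results: Sequence[MatchResult], score_max: float = 0.05,
                   ov12_min: float = 70.0, ov21_min: float = 10.0,
                   strict_ov21: float = 30.0,
                   large_pool: bool = False) -> list[MatchResult]:
    """Apply the funnel thresholds; annotate (never drop on) triage flags.

    Keeps results with total_score < score_max, overlap_1to2 > ov12_min and
    overlap_2to1 above the reverse threshold (the stricter one for large
    candidate pools).  All inequalities are strict, so boundary values fail.
    Input order is preserved; the triage flags (flavin side, electrostatic
    stabilization) stay attached for reviewer inspection but do not remove
    anything.
    """
    rev_min = strict_ov21 if large_pool else ov21_min
    kept = []
    for r in results:
        ok = (r.total_score < score_max and r.overlap_1to2 > ov12_min
              and r.overlap_2to1 > rev_min)
        if ok:
            kept.append(replace(r, kept=True))
    return kept


def match_report_frame(results: Sequence[MatchResult],
                       kept_ids: Optional[set] = None):
    """Tabular (pandas) report of match results for TSV export."""
    import pandas as pd
    rows = []
    for r in results:
        rows.append({
            "template_id": r.template_id,
            "target_id": r.target_id,
            "total_score": r.total_score,
            "overlap_1to2": r.overlap_1to2,
            "overlap_2to1": r.overlap_2to1,
            "flavin_same_side": r.flavin_same_side,
            "electro_ok": "inconclusive" if r.electro_ok is None else bool(r.electro_ok),
            "kept": (r.template_id, r.target_id) in kept_ids
                    if kept_ids is not None else bool(r.kept),
        })
    return pd.DataFrame(rows)
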