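"""Deterministic synthetic inputs with planted ground truth.

Every input the discovery funnel consumes can be emulated here so the whole
pipeline runs and is testable without structure databases, BLAST servers or
a docking engine:

* ``make_toy_enzyme`` — a buried-tunnel pseudo-protein (cylindrical carbon
  shell), a linear fatty-acid ligand threaded inside, a planar six-atom
  flavin mimic (atoms N5/N10/C4A/C5A/C9A/C10) at the tunnel head, and
  optionally a charged side-chain mimic (arginine-like +1 or aspartate-like
  -1) next to N5;
* ``make_cloud_pair`` — two point clouds related by a known rigid transform
  with an exactly constructed directional overlap;
* ``make_blast_table`` — an outfmt-6-style table with a planted number of
  rows passing the identity/coverage filter;
* ``make_sequence_families`` — sequence families built by point-mutating
  unrelated seeds around a shared conserved scaffold, with R or K planted
  at the mapped reference position;
* ``make_docking_table`` — docking cluster tables with a fully enumerated
  expected score matrix, sums and per-group top-k.

All geometry/expectation values in a manifest are computed by plain
brute-force loops, independent of the production code paths they are later
checked against.  Same seed, same bytes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .cavity import (
    DEFAULT_BURIEDNESS_MIN,
    OVERLAP_FACTOR,
    VDW_RADII,
    BURIEDNESS_RAY_LENGTH,
    PointCloud,
    icosahedral_directions,
    vdw_radius,
)
from .structure_io import (
    Atom,
    FlavinFrame,
    LigandSpec,
    Structure,
    flavin_frame_axes,
    ligand_heavy_atoms,
)

__all__ = [
    "FixtureManifest",
    "make_toy_enzyme",
    "make_cloud_pair",
    "make_blast_table",
    "make_sequence_families",
    "make_docking_table",
    "brute_force_cavity_points",
    "random_rotation",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureManifest:
    """Planted ground truth accompanying a generated fixture."""

    seed: int
    description: str
    planted: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True,
                          default=_jsonable)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


# ---------------------------------------------------------------------------
# brute-force cavity oracle
# ---------------------------------------------------------------------------

def brute_force_cavity_points(s: Structure, spec: LigandSpec, frame: FlavinFrame,
                              grid_spacing: float = 0.8, probe_radius: float = 1.4,
                              max_ligand_distance: float = 5.0,
                              buriedness_min: float = DEFAULT_BURIEDNESS_MIN,
                              ) -> np.ndarray:
    """All-pairs enumeration of the cavity grid rules (no spatial index).

    Same grid definition and filter rules as the production implementation,
    evaluated with explicit loops over every (point, atom) pair; used as
    the independent oracle for cavity procreation.
    """
    lig = ligand_heavy_atoms(s, spec)
    lig_xyz = np.stack([a.coords for a in lig])
    prot = s.protein_heavy_atoms()
    prot_xyz = s.coords_of(prot)
    prot_r = np.array([vdw_radius(a.element) for a in prot])
    dirs = icosahedral_directions()

    axes = flavin_frame_axes(frame)
    origin = frame.ring_centroid
    local = (lig_xyz - origin) @ axes.T
    lo = np.floor((local.min(axis=0) - max_ligand_distance) / grid_spacing).astype(int)
    hi = np.ceil((local.max(axis=0) + max_ligand_distance) / grid_spacing).astype(int)
    ranges = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
    pts = (np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)
           * grid_spacing) @ axes + origin

    # (b) all-pairs point-to-ligand distances
    d_lig = np.linalg.norm(pts[:, None, :] - lig_xyz[None, :, :], axis=-1)
    pts = pts[d_lig.min(axis=1) <= max_ligand_distance]

    # (a) all-pairs point-to-protein clearance
    if len(prot_xyz) and len(pts):
        d_prot = np.linalg.norm(pts[:, None, :] - prot_xyz[None, :, :], axis=-1)
        clearance = prot_r + OVERLAP_FACTOR * probe_radius
        pts = pts[np.all(d_prot >= clearance[None, :], axis=1)]

    # (c) ray-based buriedness, one full point x atom sweep per direction;
    # ray set expressed in the flavin frame, matching the cavity contract
    if buriedness_min > 0 and len(prot_xyz) and len(pts):
        hits = np.zeros(len(pts))
        rel = prot_xyz[None, :, :] - pts[:, None, :]        # (n, m, 3)
        rel_sq = (rel ** 2).sum(axis=-1)                    # (n, m)
        for d in dirs @ axes:
            t = rel @ d                                     # (n, m)
            perp2 = rel_sq - t ** 2
            occluded = (t > 0) & (t <= BURIEDNESS_RAY_LENGTH) & \
                       (perp2 <= (prot_r ** 2)[None, :])
            hits += occluded.any(axis=1)
        pts = pts[hits / len(dirs) >= buriedness_min]
    return np.asarray(pts).reshape(-1, 3)


# ---------------------------------------------------------------------------
# toy enzyme
# ---------------------------------------------------------------------------

def make_toy_enzyme(seed: int = 0, n_shell_atoms: int = 300,
                    tunnel_length: float = 14.0, arg_near_n5: bool = True,
                    flavin_pose: Optional[tuple[np.ndarray, np.ndarray]] = None,
                    ligand_carbons: int = 8,
                    charged_residue: Optional[str] = None,
                    tunnel_radius: float = 6.0,
                    compute_cavity_oracle: bool = True,
                    ) -> tuple[Structure, LigandSpec, FixtureManifest]:
    """Emit a tunnel-cavity pseudo-enzyme with bound fatty acid and flavin.

    Canonical build: tunnel axis along +x; a cylindrical shell of apolar
    carbon pseudo-residues (one CA atom each) of radius ``tunnel_radius``
    with a capped head end, a linear C``ligand_carbons`` fatty acid on the
    axis, the six-atom isoalloxazine mimic in the x = -1 plane at the
    tunnel head (N5 closest to the carboxyl carbon), and optionally a
    charged side-chain mimic near N5 (ARG by default when ``arg_near_n5``;
    pass ``charged_residue='ASP'`` for the destabilizing variant).  The
    whole scene is then moved by ``flavin_pose`` (rotation, translation).

    The manifest records exact atom counts and the brute-force cavity point
    count at default cavity parameters.
    """
    if tunnel_length < 6.0:
        raise ValueError("tunnel_length must be >= 6 Angstrom")
    min_clear = VDW_RADII["C"] + OVERLAP_FACTOR * 1.4
    if tunnel_radius - min_clear < 1.0:
        raise ValueError("tunnel narrower than the ligand: no interior space")
    if charged_residue is None and arg_near_n5:
        charged_residue = "ARG"
    rng = np.random.default_rng(seed)

    atoms: list[Atom] = []
    serial = 0
    resnum = 0

    def add(name, element, resname, chain, num, xyz, het):
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial, name, element, resname, chain, num,
                          np.asarray(xyz, float), het))

    # --- shell: rings of carbon pseudo-residues along the tunnel ---------
    x0, x1 = -3.0, tunnel_length
    n_cap = 21
    n_ring_atoms = max(n_shell_atoms - n_cap, 30)
    ring_spacing = 1.2
    n_rings = max(int(round((x1 - x0) / ring_spacing)) + 1, 2)
    per_ring = max(n_ring_atoms // n_rings, 6)
    for ri in range(n_rings):
        x = x0 + ri * ring_spacing
        offset = (ri % 2) * math.pi / per_ring
        for ai in range(per_ring):
            ang = offset + 2 * math.pi * ai / per_ring
            resnum += 1
            jitter = rng.normal(scale=0.08, size=3)  # seed-dependent wall texture
            add("CA", "C", "UNK", "A", resnum,
                (x + jitter[0], tunnel_radius * math.cos(ang) + jitter[1],
                 tunnel_radius * math.sin(ang) + jitter[2]),
                het=False)
    # head cap: disc of atoms closing the x = x0 end (jittered like the
    # shell so no atom sits on an exact grid/ray coincidence)
    for rr, nn in ((0.0, 1), (2.0, 6), (4.0, 14)):
        for ai in range(nn):
            ang = 2 * math.pi * ai / nn
            resnum += 1
            jitter = rng.normal(scale=0.08, size=3)
            add("CA", "C", "UNK", "A", resnum,
                (x0 + jitter[0], rr * math.cos(ang) + jitter[1],
                 rr * math.sin(ang) + jitter[2]), het=False)

    n_protein_shell = len(atoms)

    # --- charged side-chain mimic near N5 (N5 sits at (-1, 1.4, 0)); the
    # group gets one small rigid offset so no atom lands on an exact
    # grid/ray coincidence
    group_jitter = rng.normal(scale=0.05, size=3)
    if charged_residue == "ARG":
        resnum += 1
        for name, xyz in (("CZ", (-1.0, 4.0, 2.0)), ("NE", (-1.0, 3.6, 1.8)),
                          ("NH1", (-0.2, 4.2, 2.2)), ("NH2", (-1.8, 4.2, 2.2))):
            add(name, name[0], "ARG", "A", resnum,
                np.asarray(xyz) + group_jitter, het=False)
    elif charged_residue == "ASP":
        resnum += 1
        for name, xyz in (("CG", (-1.0, 4.0, 2.0)), ("OD1", (-0.4, 3.8, 2.0)),
                          ("OD2", (-1.6, 3.8, 2.0))):
            add(name, name[0], "ASP", "A", resnum,
                np.asarray(xyz) + group_jitter, het=False)
    elif charged_residue is not None:
        raise ValueError(f"unsupported charged_residue {charged_residue!r}")

    n_protein = len(atoms)

    # --- flavin mimic: hexagon in the x = -1 plane -----------------------
    ring_names = ("N5", "C4A", "C5A", "N10", "C9A", "C10")
    for idx, name in enumerate(ring_names):
        ang = 2 * math.pi * idx / 6.0  # N5 at angle 0 -> (-1, 1.4, 0)
        add(name, name[0], "FAD", "F", 900,
            (-1.0, 1.4 * math.cos(ang), 1.4 * math.sin(ang)), het=True)

    # --- fatty acid ligand on the axis ------------------------------------
    chain_names = tuple(f"C{i + 1}" for i in range(ligand_carbons))
    for i, name in enumerate(chain_names):
        add(name, "C", "FAT", "L", 500, (1.5 + 1.25 * i, 0.0, 0.0), het=True)
    add("O1", "O", "FAT", "L", 500, (0.9, 1.0, 0.0), het=True)
    add("O2", "O", "FAT", "L", 500, (0.9, -1.0, 0.0), het=True)

    spec = LigandSpec("FAT", "L", 500, carboxyl_carbon="C1",
                      chain_carbons=chain_names,
                      carboxylate_oxygens=("O1", "O2"))
    structure = Structure(atoms, id=f"toy{seed}")

    if flavin_pose is not None:
        R, t = flavin_pose
        structure = structure.transformed(np.asarray(R, float),
                                          np.asarray(t, float))

    manifest = FixtureManifest(
        seed=seed,
        description="tunnel-cavity toy enzyme with flavin mimic and fatty acid",
        planted={
            "n_atoms": len(structure),
            "n_protein_atoms": n_protein,
            "n_shell_atoms": n_protein_shell,
            "n_ligand_heavy_atoms": ligand_carbons + 2,
            "n_flavin_atoms": 6,
            "charged_residue": charged_residue,
            "expected_stabilization": {"ARG": True, "ASP": False,
                                       None: None}[charged_residue],
            "ligand_carbons": ligand_carbons,
        })
    if compute_cavity_oracle:
        from .structure_io import locate_flavin
        frame = locate_flavin(structure, "FAD", ligand_spec=spec)
        pts = brute_force_cavity_points(structure, spec, frame)
        manifest.planted["cavity_point_count"] = int(len(pts))
    return structure, spec, manifest


# ---------------------------------------------------------------------------
# cloud pairs with known transform and exact overlap
# ---------------------------------------------------------------------------

def _min_separation_points(rng: np.random.Generator, n: int, box: float,
                           min_dist: float,
                           avoid: Optional[np.ndarray] = None,
                           avoid_dist: float = 0.0) -> np.ndarray:
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("point sampling failed; box too small")
        p = rng.uniform(-box / 2, box / 2, size=3)
        if pts and min(np.linalg.norm(p - q) for q in pts) < min_dist:
            continue
        if avoid is not None and len(avoid) and \
                np.linalg.norm(avoid - p, axis=1).min() < avoid_dist:
            continue
        pts.append(p)
    return np.array(pts)


def _random_frame(rng: np.random.Generator, near: np.ndarray) -> FlavinFrame:
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)
    u = rng.normal(size=3)
    u -= np.dot(u, normal) * normal
    u /= np.linalg.norm(u)
    centroid = near + rng.normal(scale=0.5, size=3)
    n5 = centroid + 1.5 * u + 0.5 * normal
    return FlavinFrame(n5, centroid, normal)


def make_cloud_pair(seed: int = 0, n_points: int = 200,
                    overlap_target: float = 100.0,
                    transform: Optional[tuple[np.ndarray, np.ndarray]] = None,
                    epsilon: float = 1.0, grid_spacing: float = 0.8,
                    ) -> tuple[PointCloud, PointCloud, FixtureManifest]:
    """Two clouds related by a known rigid transform.

    Cloud B consists of the transform applied to a subset of A (fraction
    set by ``overlap_target``) plus decoy points kept at least 2 * epsilon
    away from every mapped A point, so both directional overlaps are exact
    by construction and recorded in the manifest.
    """
    if not 0.0 <= overlap_target <= 100.0:
        raise ValueError("overlap_target must be in [0, 100]")
    rng = np.random.default_rng(seed)
    if transform is None:
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
    else:
        R = np.asarray(transform[0], float)
        t = np.asarray(transform[1], float)

    box = max(10.0, 2.8 * n_points ** (1.0 / 3.0) * (2 * epsilon))
    a_pts = _min_separation_points(rng, n_points, box, 2 * epsilon + 0.1)
    props = np.column_stack([
        np.where(rng.random(n_points) < 0.5, -1.0, 1.0)
        * rng.uniform(0.3, 1.0, n_points),            # electro, clear of dead-band
        rng.uniform(0, 1, n_points),                   # donor
        rng.uniform(0, 1, n_points),                   # acceptor
        rng.uniform(0, 1, n_points),                   # hydrophobicity
        rng.uniform(0, 1, n_points),                   # buriedness
    ])
    frame_a = _random_frame(rng, a_pts.mean(axis=0))

    m = int(round(n_points * overlap_target / 100.0))
    subset = rng.permutation(n_points)[:m]
    mapped_all = a_pts @ R.T + t
    b_pts = [mapped_all[i] for i in subset]
    b_props = [props[i] for i in subset]
    n_decoys = n_points - m
    if n_decoys:
        decoys = _min_separation_points(
            rng, n_decoys, box, 2 * epsilon + 0.1,
            avoid=mapped_all, avoid_dist=2 * epsilon + 0.1)
        for d in decoys:
            b_pts.append(d)
            b_props.append(np.array([
                -1.0 if rng.random() < 0.5 else 1.0,
                rng.uniform(0, 1), rng.uniform(0, 1),
                rng.uniform(0, 1), rng.uniform(0, 1)]))
    frame_b = frame_a.transformed(R, t)
    cloud_a = PointCloud(a_pts, props, frame_a, grid_spacing, f"pairA{seed}")
    cloud_b = PointCloud(np.array(b_pts), np.array(b_props), frame_b,
                         grid_spacing, f"pairB{seed}")
    manifest = FixtureManifest(
        seed=seed,
        description="cloud pair related by a known rigid transform",
        planted={
            "rotation": R, "translation": t,
            "n_points_a": n_points, "n_points_b": len(cloud_b),
            "n_mapped": m,
            "overlap_a_to_b": 100.0 * m / n_points,
            "overlap_b_to_a": 100.0 * m / len(cloud_b),
            "epsilon": epsilon,
        })
    return cloud_a, cloud_b, manifest


# ---------------------------------------------------------------------------
# BLAST table
# ---------------------------------------------------------------------------

def make_blast_table(seed: int = 0, n_hits: int = 50, n_pass: int = 23,
                     min_identity: float = 30.0, min_cov: float = 80.0,
                     qlen: int = 600, path=None,
                     ) -> tuple[list[list], FixtureManifest]:
    """Headerless 16-column BLAST-style table with planted pass labels.

    Exactly ``n_pass`` rows satisfy identity >= min_identity and both
    coverages >= min_cov; every failing row misses at least one threshold
    by a clear margin (no boundary-value rows).
    """
    if n_pass > n_hits:
        raise ValueError("n_pass cannot exceed n_hits")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n_hits):
        is_pass = i < n_pass
        sid = f"hit{i:04d}"
        slen = int(rng.integers(450, 800))
        if is_pass:
            pid = float(np.round(rng.uniform(min_identity + 2, 95), 1))
            qspan = int(rng.integers(int(qlen * (min_cov + 2) / 100), qlen + 1))
            sspan = int(rng.integers(int(slen * (min_cov + 2) / 100), slen + 1))
        else:
            mode = rng.integers(0, 3)
            pid = float(np.round(
                rng.uniform(5, min_identity - 2) if mode == 0
                else rng.uniform(min_identity + 2, 95), 1))
            qspan = int(rng.integers(int(qlen * 0.4), int(qlen * (min_cov - 3) / 100))
                        if mode == 1 else
                        rng.integers(int(qlen * (min_cov + 2) / 100), qlen + 1))
            sspan = int(rng.integers(int(slen * 0.4), int(slen * (min_cov - 3) / 100))
                        if mode == 2 else
                        rng.integers(int(slen * (min_cov + 2) / 100), slen + 1))
        length = max(qspan, sspan)
        mismatch = int(round(length * (100 - pid) / 100))
        evalue = float(f"{rng.uniform(1e-180, 1e-5):.3e}")
        bitscore = float(np.round(rng.uniform(50, 900), 1))
        rows.append(["query", sid, pid, length, mismatch, 0,
                     1, qspan, 1, sspan, evalue, bitscore,
                     qlen, slen,
                     float(np.round(100.0 * qspan / qlen, 3)),
                     float(np.round(100.0 * sspan / slen, 3))])
        labels.append((sid, bool(is_pass)))
    order = rng.permutation(n_hits)
    rows = [rows[i] for i in order]
    labels = dict(labels)
    if path is not None:
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
    manifest = FixtureManifest(
        seed=seed, description="BLAST tabular hits with planted pass labels",
        planted={"n_hits": n_hits, "n_pass": n_pass,
                 "pass_ids": sorted(s for s, ok in labels.items() if ok),
                 "min_identity": min_identity, "min_cov": min_cov})
    return rows, manifest


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

def make_sequence_families(seed: int = 0, n_families: int = 5,
                           members_per_family: int = 10, length: int = 500,
                           within_id: float = 90.0, between_id: float = 40.0,
                           arg_conserved_fraction: float = 1.0,
                           ref_pos: int = 451,
                           triad_positions: tuple[int, int] = (432, 466),
                           ) -> tuple[list, "object", FixtureManifest]:
    """Sequence families with planted cluster and conservation structure.

    All sequences share a conserved scaffold (every 7th position plus a
    block around the triad) copied from a generated reference, which keeps
    between-family identity around 25-35 % (< ``between_id``) while making
    the global alignment of any pair gapless, so reference position
    ``ref_pos`` maps to the same column in every sequence.  Family members
    are point mutants of their seed at non-scaffold positions (<= 5 % of
    positions each), giving pairwise within-family identity >= 90 %.  An
    ``arg_conserved_fraction`` of families keeps R at the mapped position;
    the rest carry K there.

    Returns (records, reference_record, manifest); records are
    seqpipe.SequenceRecord.  Member ids are ``fam<f>_m<j>`` with zero-padded
    j so the family seed (j = 0) is also the deterministic greedy-cluster
    representative.
    """
    from .seqpipe import SequenceRecord

    if length < max(ref_pos, *triad_positions):
        raise ValueError("length must cover the conserved positions")
    max_mut = int(length * (100.0 - within_id) / 100.0 / 2)
    if max_mut < 1:
        raise ValueError(f"within_id={within_id} infeasible at length {length}")
    rng = np.random.default_rng(seed)
    ref = list(rng.choice(list(AA20), size=length))
    ref[ref_pos - 1] = "R"
    ref[triad_positions[0] - 1] = "C"
    ref[triad_positions[1] - 1] = "Y"

    block_lo = min(ref_pos, *triad_positions) - 8
    block_hi = max(ref_pos, *triad_positions) + 8
    scaffold = set(range(0, length, 7)) | set(range(block_lo - 1, block_hi))
    free = sorted(set(range(length)) - scaffold)

    n_arg = int(round(n_families * arg_conserved_fraction))
    records = []
    assignment: dict[str, int] = {}
    family_arg: dict[str, bool] = {}
    for f in range(n_families):
        seq = list(rng.choice(list(AA20), size=length))
        for p in scaffold:
            seq[p] = ref[p]
        has_arg = f < n_arg
        if not has_arg:
            seq[ref_pos - 1] = "K"
        rep_id = f"fam{f}_m{0:02d}"
        family_arg[rep_id] = has_arg
        for j in range(members_per_family):
            member = list(seq)
            if j > 0:
                k = int(rng.integers(3, max_mut + 1))
                pos = rng.choice(free, size=k, replace=False)
                for p in pos:
                    choices = [a for a in AA20 if a != member[p]]
                    member[p] = choices[int(rng.integers(0, len(choices)))]
            sid = f"fam{f}_m{j:02d}"
            records.append(SequenceRecord(sid, "".join(member)))
            assignment[sid] = f
    reference = SequenceRecord("reference", "".join(ref))
    manifest = FixtureManifest(
        seed=seed, description="planted sequence families with conserved scaffold",
        planted={
            "n_families": n_families,
            "members_per_family": members_per_family,
            "assignment": assignment,
            "representatives": sorted(family_arg),
            "arg_conserved": family_arg,
            "expected_kept_representatives":
                sorted(r for r, ok in family_arg.items() if ok),
            "ref_pos": ref_pos,
            "triad_positions": list(triad_positions),
        })
    return records, reference, manifest


# ---------------------------------------------------------------------------
# docking table
# ---------------------------------------------------------------------------

def make_docking_table(seed: int = 0, n_candidates: int = 14,
                       n_ligands: int = 25, top_k: int = 5,
                       missing_fraction: float = 0.04, path=None,
                       candidates: Optional[list[str]] = None,
                       groups: Optional[dict[str, str]] = None,
                       ) -> tuple[list[dict], FixtureManifest]:
    """Docking cluster table with fully enumerated expected results.

    Candidates split into two provenance groups ("blast", "pdb");
    per candidate-ligand pair 1-4 clusters with random energies
    (kcal/mol, negative) and carboxyl-to-N5 distances (Angstrom); a small
    fraction of pairs is left undocked.  The manifest's expected matrix,
    sums and per-group top-k are computed here with plain loops
    (minimal-distance cluster, tie -> lower energy -> lower cluster id;
    score |E/d|; missing pair -> 0).
    """
    rng = np.random.default_rng(seed)
    if candidates is None:
        half = n_candidates // 2
        candidates = [f"blast{i:02d}" for i in range(half)] + \
                     [f"pdb{i:02d}" for i in range(n_candidates - half)]
        groups = {c: ("blast" if c.startswith("blast") else "pdb")
                  for c in candidates}
    elif groups is None:
        groups = {c: "" for c in candidates}
    cands = list(candidates)
    ligands = [f"lig{j:02d}" for j in range(n_ligands)]
    rows: list[dict] = []
    expected_scores: dict[str, dict[str, float]] = {c: {} for c in cands}
    missing: list[tuple[str, str]] = []
    for c in cands:
        for lig in ligands:
            if rng.random() < missing_fraction:
                expected_scores[c][lig] = 0.0
                missing.append((c, lig))
                continue
            n_cl = int(rng.integers(1, 5))
            best = None
            for cl in range(n_cl):
                e = float(np.round(rng.uniform(-12.0, -1.0), 3))
                d = float(np.round(rng.uniform(2.5, 9.0), 3))
                rows.append({"candidate_id": c, "ligand_id": lig,
                             "cluster_id": cl, "energy_kcal_mol": e,
                             "distance_A": d})
                key = (d, e, cl)
                if best is None or key < best:
                    best = key
            expected_scores[c][lig] = abs(best[1] / best[0])
    expected_sums = {
        c: float(np.array([expected_scores[c][lig] for lig in ligands]).sum())
        for c in cands}

    def group_top(gname: str) -> list[str]:
        members = [c for c in cands if groups[c] == gname]
        return sorted(members, key=lambda c: (-expected_sums[c], c))[:top_k]

    expected_top = [c for g in sorted(set(groups.values()))
                    for c in group_top(g)]
    if path is not None:
        with open(path, "w") as fh:
            fh.write("candidate_id\tligand_id\tcluster_id\t"
                     "energy_kcal_mol\tdistance_A\n")
            for r in rows:
                fh.write(f"{r['candidate_id']}\t{r['ligand_id']}\t"
                         f"{r['cluster_id']}\t{r['energy_kcal_mol']}\t"
                         f"{r['distance_A']}\n")
    manifest = FixtureManifest(
        seed=seed, description="docking clusters with enumerated expectations",
        planted={
            "candidates": cands, "ligands": ligands, "groups": groups,
            "expected_scores": expected_scores,
            "expected_sums": expected_sums,
            "expected_top_k": expected_top,
            "k": top_k,
            "missing_pairs": missing,
        })
    return rows, manifest


# ---------------------------------------------------------------------------
# composed end-to-end bundle
# ---------------------------------------------------------------------------

def make_funnel_bundle(seed: int, out_dir) -> FixtureManifest:
    """Compose every generator into one end-to-end fixture directory.

    Writes template/target PDBs, a BLAST table, a FASTA file, a docking
    table and a run-config YAML under ``out_dir``.  The scene is built so
    each stage's outcome is predictable:

    * one template (18-carbon ligand, truncated to C8 by the pipeline) and
      four targets — two rigid-motion copies of the template scene (which
      must pass the match filter) and two geometrically different decoys
      (wider and narrower tunnels, which must not);
    * a BLAST table over six 4-member sequence families where exactly the
      members of families 0-3 pass the 30/80/80 filter, and of those
      clusters only families 0-2 keep the reference arginine;
    * a docking table over the five expected pool candidates plus two
      out-of-pool distractors, with enumerated expected sums and the
      per-group top-2 shortlist.
    """
    import os

    import yaml

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    from .structure_io import write_structure

    # --- structures --------------------------------------------------------
    template, _, _ = make_toy_enzyme(seed=seed, ligand_carbons=18,
                                     compute_cavity_oracle=False)
    write_structure(template, os.path.join(out_dir, "template.pdb"))
    target_entries = []
    expected_structure = []
    for i in range(2):  # rigid copies: must match
        R = random_rotation(rng)
        t = rng.uniform(-15, 15, size=3)
        good, _, _ = make_toy_enzyme(seed=seed, ligand_carbons=8,
                                     flavin_pose=(R, t),
                                     compute_cavity_oracle=False)
        name = f"target_good{i}"
        write_structure(good, os.path.join(out_dir, f"{name}.pdb"))
        target_entries.append({"path": os.path.join(out_dir, f"{name}.pdb"),
                               "ligand": "FAT:L:500"})
        expected_structure.append(name)
    for i, radius in enumerate((8.5, 4.2)):  # decoys: must fail
        decoy, _, _ = make_toy_enzyme(seed=seed + 1000 + i, ligand_carbons=8,
                                      tunnel_radius=radius,
                                      compute_cavity_oracle=False)
        name = f"target_decoy{i}"
        write_structure(decoy, os.path.join(out_dir, f"{name}.pdb"))
        target_entries.append({"path": os.path.join(out_dir, f"{name}.pdb"),
                               "ligand": "FAT:L:500"})

    # --- sequences ---------------------------------------------------------
    records, reference, fam_manifest = make_sequence_families(
        seed=seed, n_families=6, members_per_family=4,
        arg_conserved_fraction=0.5)  # families 0-2 keep R
    from .seqpipe import write_fasta
    fasta_path = os.path.join(out_dir, "sequences.fasta")
    write_fasta(list(records) + [reference], fasta_path)

    pass_families = {0, 1, 2, 3}
    blast_path = os.path.join(out_dir, "blast.tsv")
    qlen = 600
    with open(blast_path, "w") as fh:
        for r in records:
            fam = int(r.id.split("_")[0][3:])
            ok = fam in pass_families
            slen = len(r)
            if ok:
                pid = float(np.round(rng.uniform(35, 90), 1))
                qspan = int(rng.integers(int(qlen * 0.85), qlen + 1))
                sspan = int(rng.integers(int(slen * 0.85), slen + 1))
            else:
                pid = float(np.round(rng.uniform(10, 25), 1))
                qspan = int(rng.integers(int(qlen * 0.45), int(qlen * 0.7)))
                sspan = int(rng.integers(int(slen * 0.45), int(slen * 0.7)))
            fh.write("\t".join(str(x) for x in [
                "reference", r.id, pid, max(qspan, sspan),
                int(max(qspan, sspan) * (100 - pid) / 100), 0,
                1, qspan, 1, sspan, 1e-20, 200.0, qlen, slen,
                float(np.round(100.0 * qspan / qlen, 3)),
                float(np.round(100.0 * sspan / slen, 3))]) + "\n")
    # greedy clustering of the passing members recovers families 0-3 with
    # the zero-padded m00 member as representative; the arginine filter
    # then keeps families 0-2.
    expected_sequence = [f"fam{f}_m00" for f in range(3)]

    # --- docking -----------------------------------------------------------
    pool = expected_structure + expected_sequence
    groups = {c: ("structure" if c in expected_structure else "sequence")
              for c in pool}
    all_cands = pool + ["distractor0", "distractor1"]
    all_groups = dict(groups, distractor0="structure", distractor1="sequence")
    dock_path = os.path.join(out_dir, "docking.tsv")
    _, dock_manifest = make_docking_table(
        seed=seed, n_ligands=10, top_k=2, missing_fraction=0.0,
        path=dock_path, candidates=all_cands, groups=all_groups)
    sums = dock_manifest.planted["expected_sums"]

    def group_top(gname, k=2):
        members = [c for c in pool if groups[c] == gname]
        return sorted(members, key=lambda c: (-sums[c], c))[:k]

    expected_shortlist = group_top("sequence") + group_top("structure")

    config = {
        "templates": [{"path": os.path.join(out_dir, "template.pdb"),
                       "ligand": "FAT:L:500"}],
        "targets": target_entries,
        "blast_table": blast_path,
        "fasta": fasta_path,
        "reference_id": "reference",
        "docking_table": dock_path,
        "out_dir": os.path.join(out_dir, "run"),
        "seed": seed,
        "top_k": 2,
    }
    config_path = os.path.join(out_dir, "run.yml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    manifest = FixtureManifest(
        seed=seed, description="composed end-to-end funnel bundle",
        planted={
            "config_path": config_path,
            "expected_structure_candidates": expected_structure,
            "expected_sequence_candidates": expected_sequence,
            "expected_shortlist": expected_shortlist,
            "expected_sums": {c: sums[c] for c in pool},
            "groups": groups,
        })
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest
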