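"""Cavity point-cloud procreation and physico-chemical annotation.

The active-site "catalophore" is represented as a point cloud: virtual
points filling the empty space around the protein-bound (truncated) ligand,
each annotated with a small physico-chemical property vector.  The point
placement and property definitions here are this package's own
reconstruction of that idea (the platforms that inspired it are
proprietary); they are deterministic and documented in docs/methods.md:

* points live on a regular grid expressed in the flavin-frame coordinate
  system, so the cloud is equivariant under rigid motions of the structure;
* a grid point survives iff it clears every protein heavy atom by that
  atom's van der Waals radius plus half the probe radius, lies within
  ``max_ligand_distance`` of a retained ligand heavy atom, and is buried
  (fraction of occluded rays >= ``buriedness_min``);
* properties: Coulomb potential with distance-dependent dielectric
  eps(r) = 4r over residue-template integer charges, hydrogen-bond
  donor/acceptor ramps, apolar-carbon fraction, and ray-based buriedness.

Units: Angstrom for all distances; the electrostatic potential is in
consistent arbitrary units (e * A^-1 / (4 eps0) scale) -- only its sign and
relative magnitude are used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    FlavinFrame,
    LigandSpec,
    Structure,
    flavin_frame_axes,
    ligand_heavy_atoms,
)

__all__ = [
    "PointProperties",
    "PointCloud",
    "EmptyCavityError",
    "VDW_RADII",
    "procreate_cavity",
    "annotate_properties",
    "negative_charge_stabilization",
    "partial_charges",
    "icosahedral_directions",
    "cloud_to_json_dict",
    "cloud_from_json_dict",
    "write_cloud_json",
    "read_cloud_json",
    "write_cloud_pdb",
]

# Bondi-style van der Waals radii (Angstrom); fixed in code for
# bit-reproducibility.  Unknown elements fall back to carbon.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20,
}
DEFAULT_VDW = 1.70

# grid-point clearance = vdW + OVERLAP_FACTOR * probe_radius
OVERLAP_FACTOR = 0.5

# hydrogen-bond distance ramp: score 1 at <=RAMP_LO, 0 at >=RAMP_HI
HBOND_RAMP_LO = 2.5
HBOND_RAMP_HI = 4.0
HYDROPHOBIC_RADIUS = 4.5
BURIEDNESS_RAY_LENGTH = 8.0
ELECTRO_CUTOFF = 12.0
DEFAULT_BURIEDNESS_MIN = 0.4

# Side-chain hydrogen-bond donor / acceptor atoms by (residue, atom name);
# the backbone amide N donates and the carbonyl O accepts for all residues.
_SIDECHAIN_DONORS = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"),
}
# Polar carbons excluded from the hydrophobicity count (carboxylate, amide
# and guanidinium carbons plus the backbone carbonyl carbon).
_POLAR_CARBONS = {
    ("ARG", "CZ"), ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"),
}


class EmptyCavityError(ValueError):
    """No grid point survived the cavity filters."""


@dataclass(frozen=True)
class PointProperties:
    """Per-point physico-chemical annotation."""

    electrostatic: float = 0.0
    hbond_donor: float = 0.0
    hbond_acceptor: float = 0.0
    hydrophobicity: float = 0.0
    buriedness: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.electrostatic):
            raise ValueError("electrostatic potential must be finite")
        for name in ("hbond_donor", "hbond_acceptor", "hydrophobicity", "buriedness"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.electrostatic, self.hbond_donor,
                         self.hbond_acceptor, self.hydrophobicity,
                         self.buriedness])


@dataclass
class PointCloud:
    """Annotated cavity point cloud with its flavin anchor frame."""

    coords: np.ndarray          # (n, 3) Angstrom
    properties: np.ndarray      # (n, 5): electro, donor, acceptor, hydroph, buried
    frame: FlavinFrame
    grid_spacing: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        self.properties = np.asarray(self.properties, float).reshape(-1, 5)
        if len(self.properties) != len(self.coords):
            raise ValueError("coords/properties length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def electrostatic(self) -> np.ndarray:
        return self.properties[:, 0]

    def point_properties(self, i: int) -> PointProperties:
        e, d, a, h, b = self.properties[i]
        return PointProperties(e, d, a, h, b)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return PointCloud(self.coords @ R.T + t, self.properties.copy(),
                          self.frame.transformed(R, t), self.grid_spacing,
                          self.source_id)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def icosahedral_directions() -> np.ndarray:
    """42 unit directions: icosahedron vertices plus edge midpoints.

    A fixed, seed-free direction set keeps the buriedness estimate
    deterministic and orientation-stable enough at 42 samples.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts.append((0.0, a, b))
            verts.append((a, b, 0.0))
            verts.append((b, 0.0, a))
    v = np.array(verts)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # edge midpoints: the 30 closest vertex pairs
    d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
    iu = np.triu_indices(len(v), 1)
    pair_d2 = d2[iu]
    edge_cut = np.partition(pair_d2, 29)[29] + 1e-9
    mids = []
    for i, j in zip(*iu):
        if d2[i, j] <= edge_cut:
            m = v[i] + v[j]
            mids.append(m / np.linalg.norm(m))
    dirs = np.vstack([v, np.array(mids)])
    assert dirs.shape == (42, 3)
    return dirs


_ICOSA_DIRS = icosahedral_directions()


def partial_charges(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Residue-template integer charges: (positions (m,3), charges (m,)).

    Arg +1 at the guanidinium nitrogen centroid, Lys +1 at NZ, Asp/Glu -1 at
    the carboxylate oxygen midpoint.  His neutral; termini ignored.
    """
    groups = {
        "ARG": (("NE", "NH1", "NH2"), +1.0),
        "LYS": (("NZ",), +1.0),
        "ASP": (("OD1", "OD2"), -1.0),
        "GLU": (("OE1", "OE2"), -1.0),
    }
    by_res: dict[tuple[str, str, int], dict[str, Atom]] = {}
    for a in s.atoms:
        if a.is_hetero or a.residue_name not in groups:
            continue
        by_res.setdefault((a.chain, a.residue_name, a.residue_number), {})[a.name] = a
    pos, q = [], []
    for (_, resname, _), atoms in sorted(by_res.items()):
        names, charge = groups[resname]
        found = [atoms[n].coords for n in names if n in atoms]
        if found:
            pos.append(np.mean(found, axis=0))
            q.append(charge)
    if not pos:
        return np.empty((0, 3)), np.empty(0)
    return np.stack(pos), np.array(q)


def buriedness_of_points(points: np.ndarray, protein_xyz: np.ndarray,
                         protein_vdw: np.ndarray,
                         ray_length: float = BURIEDNESS_RAY_LENGTH,
                         directions: Optional[np.ndarray] = None) -> np.ndarray:
    """Fraction of the 42 icosahedral rays occluded by a protein atom.

    A ray from p in direction d is occluded if some atom centre projects
    onto the ray at 0 < t <= ray_length with perpendicular distance <= its
    vdW radius.  Pass ``directions`` expressed in a structure-intrinsic
    frame (e.g. the flavin frame) to keep the estimate equivariant under
    rigid motions; the default is the world-axis icosahedral set.
    """
    n = len(points)
    if n == 0:
        return np.empty(0)
    if len(protein_xyz) == 0:
        return np.zeros(n)
    out = np.empty(n)
    dirs = _ICOSA_DIRS if directions is None else np.asarray(directions, float)
    for i, p in enumerate(points):
        rel = protein_xyz - p                        # (m, 3)
        t = rel @ dirs.T                             # (m, 42) projections
        perp2 = (rel ** 2).sum(axis=1)[:, None] - t ** 2
        hit = (t > 0) & (t <= ray_length) & (perp2 <= (protein_vdw ** 2)[:, None])
        out[i] = hit.any(axis=0).mean()
    return out


# ---------------------------------------------------------------------------
# cavity procreation
# ---------------------------------------------------------------------------

def procreate_cavity(s: Structure, spec: LigandSpec, frame: FlavinFrame,
                     grid_spacing: float = 0.8, probe_radius: float = 1.4,
                     max_ligand_distance: float = 5.0,
                     buriedness_min: float = DEFAULT_BURIEDNESS_MIN,
                     annotate: bool = True) -> PointCloud:
    """Build the cavity point cloud around the bound (truncated) ligand.

    The grid is laid out along the flavin-frame axes over the ligand's
    bounding box padded by ``max_ligand_distance``; ligand atoms are treated
    as empty space.  Set ``buriedness_min`` to 0 to disable the solvent
    filter.  With ``annotate`` the surviving points are annotated in place.
    """
    if not 0.3 <= grid_spacing <= 2.0:
        raise ValueError("grid_spacing must be within [0.3, 2.0] Angstrom")
    if frame is None:
        raise ValueError("a flavin frame is required to anchor the grid")
    lig_atoms = ligand_heavy_atoms(s, spec)
    lig_xyz = np.stack([a.coords for a in lig_atoms])
    prot = s.protein_heavy_atoms()
    prot_xyz = s.coords_of(prot)
    prot_vdw = np.array([vdw_radius(a.element) for a in prot])

    axes = flavin_frame_axes(frame)           # rows e1, e2, e3
    origin = frame.ring_centroid
    lig_local = (lig_xyz - origin) @ axes.T
    lo = np.floor((lig_local.min(axis=0) - max_ligand_distance) / grid_spacing)
    hi = np.ceil((lig_local.max(axis=0) + max_ligand_distance) / grid_spacing)
    ii = [np.arange(int(l), int(h) + 1) for l, h in zip(lo, hi)]
    gi, gj, gk = np.meshgrid(*ii, indexing="ij")
    local = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3) * grid_spacing
    pts = local @ axes + origin

    # (b) near the retained ligand
    lig_tree = cKDTree(lig_xyz)
    near_lig = lig_tree.query(pts, k=1)[0] <= max_ligand_distance
    pts = pts[near_lig]

    # (a) clearance from every protein heavy atom
    if len(prot_xyz) and len(pts):
        clearance = prot_vdw + OVERLAP_FACTOR * probe_radius
        tree = cKDTree(prot_xyz)
        max_clear = clearance.max()
        ok = np.ones(len(pts), bool)
        neighbors = tree.query_ball_point(pts, max_clear)
        for i, idx in enumerate(neighbors):
            if idx:
                d = np.linalg.norm(prot_xyz[idx] - pts[i], axis=1)
                ok[i] = np.all(d >= clearance[idx])
        pts = pts[ok]

    # (c) buriedness; ray directions anchored to the flavin frame so the
    # filter is equivariant under rigid motions of the structure
    buried = buriedness_of_points(pts, prot_xyz, prot_vdw,
                                  directions=_ICOSA_DIRS @ axes)
    keep = buried >= buriedness_min
    pts, buried = pts[keep], buried[keep]

    if len(pts) == 0:
        raise EmptyCavityError(
            f"no cavity points survived for {s.id!r} "
            f"(spacing {grid_spacing}, probe {probe_radius})")

    props = np.zeros((len(pts), 5))
    props[:, 4] = buried
    cloud = PointCloud(pts, props, frame, grid_spacing, source_id=s.id)
    if annotate:
        cloud = annotate_properties(cloud, s, precomputed_buriedness=True)
    return cloud


def annotate_properties(cloud: PointCloud, s: Structure, *,
                        precomputed_buriedness: bool = False) -> PointCloud:
    """Annotate each point with the five-property vector (in place)."""
    pts = cloud.coords
    n = len(pts)
    prot = s.protein_heavy_atoms()
    prot_xyz = s.coords_of(prot)
    prot_vdw = np.array([vdw_radius(a.element) for a in prot])

    electro = np.zeros(n)
    qpos, qval = partial_charges(s)
    if len(qpos):
        diff = pts[:, None, :] - qpos[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        r = np.maximum(r, 1e-6)
        contrib = np.where(r <= ELECTRO_CUTOFF, qval[None, :] / (4.0 * r * r), 0.0)
        electro = contrib.sum(axis=1)  # eps(r) = 4r  =>  q / (4 r^2)

    donors, acceptors = [], []
    for a in prot:
        if a.name == "N":
            donors.append(a.coords)
        if a.name == "O":
            acceptors.append(a.coords)
        key = (a.residue_name, a.name)
        if key in _SIDECHAIN_DONORS:
            donors.append(a.coords)
        if key in _SIDECHAIN_ACCEPTORS:
            acceptors.append(a.coords)

    def ramp_max(sites: list[np.ndarray]) -> np.ndarray:
        if not sites:
            return np.zeros(n)
        d = np.linalg.norm(pts[:, None, :] - np.stack(sites)[None, :, :], axis=-1)
        score = np.clip((HBOND_RAMP_HI - d) / (HBOND_RAMP_HI - HBOND_RAMP_LO), 0.0, 1.0)
        return score.max(axis=1)

    donor = ramp_max(donors)
    acceptor = ramp_max(acceptors)

    hydro = np.zeros(n)
    if len(prot_xyz):
        apolar = np.array([
            a.element.upper() == "C" and a.name != "C"
            and (a.residue_name, a.name) not in _POLAR_CARBONS
            for a in prot])
        tree = cKDTree(prot_xyz)
        for i, idx in enumerate(tree.query_ball_point(pts, HYDROPHOBIC_RADIUS)):
            if idx:
                hydro[i] = apolar[idx].mean()

    if precomputed_buriedness:
        buried = cloud.properties[:, 4]
    else:
        axes = flavin_frame_axes(cloud.frame)
        buried = buriedness_of_points(pts, prot_xyz, prot_vdw,
                                      directions=_ICOSA_DIRS @ axes)

    cloud.properties = np.column_stack([electro, donor, acceptor, hydro, buried])
    return cloud


def negative_charge_stabilization(cloud: PointCloud, radius: float = 4.0) -> Optional[bool]:
    """Is the cavity next to the flavin N5 stabilizing toward negative charge?

    True iff the mean electrostatic potential over the points within
    ``radius`` of N5 is strictly positive (a positive potential stabilizes
    an anionic substrate/intermediate).  Returns None (inconclusive) when no
    point lies within ``radius`` -- deliberately distinct from False.
    """
    d = np.linalg.norm(cloud.coords - cloud.frame.n5, axis=1)
    near = d <= radius
    if not near.any():
        return None
    return bool(cloud.electrostatic[near].mean() > 0.0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_PROP_NAMES = ("electrostatic", "hbond_donor", "hbond_acceptor",
               "hydrophobicity", "buriedness")


def cloud_to_json_dict(cloud: PointCloud) -> dict:
    return {
        "source_id": cloud.source_id,
        "grid_spacing": cloud.grid_spacing,
        "frame": {
            "n5": cloud.frame.n5.tolist(),
            "ring_centroid": cloud.frame.ring_centroid.tolist(),
            "ring_normal": cloud.frame.ring_normal.tolist(),
        },
        "points": [
            {"coords": c.tolist(),
             **{k: float(v) for k, v in zip(_PROP_NAMES, p)}}
            for c, p in zip(cloud.coords, cloud.properties)
        ],
    }


def cloud_from_json_dict(d: dict) -> PointCloud:
    frame = FlavinFrame(np.array(d["frame"]["n5"]),
                        np.array(d["frame"]["ring_centroid"]),
                        np.array(d["frame"]["ring_normal"]))
    pts = np.array([p["coords"] for p in d["points"]], float).reshape(-1, 3)
    props = np.array([[p[k] for k in _PROP_NAMES] for p in d["points"]],
                     float).reshape(-1, 5)
    return PointCloud(pts, props, frame, float(d["grid_spacing"]),
                      d.get("source_id", ""))


def write_cloud_json(cloud: PointCloud, path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump(cloud_to_json_dict(cloud), fh, indent=1)


def read_cloud_json(path) -> PointCloud:
    import json
    with open(path) as fh:
        return cloud_from_json_dict(json.load(fh))


def write_cloud_pdb(cloud: PointCloud, path) -> None:
    """Pseudo-atom PDB export for visual inspection (B-factor = potential)."""
    with open(path, "w") as fh:
        for i, (c, p) in enumerate(zip(cloud.coords, cloud.properties), start=1):
            fh.write(
                f"HETATM{i % 100000:5d}  PT  CAV P{i % 10000:4d}    "
                f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{p[0]:6.2f}"
                f"          PT\n")
        fh.write("END\n")
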