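"""Shared fixtures: small hand-built structures and seeded generators."""

import numpy as np
import pytest

from catalocavity.structure_io import Atom, LigandSpec, Structure


def make_atom(serial, name, element, resname, chain, resnum, xyz, het=False):
    return Atom(serial, name, element, resname, chain, resnum,
                np.asarray(xyz, float), het)


def planar_fad(center=(0.0, 0.0, 0.0), radius=1.4, start_serial=1000):
    """Six-atom isoalloxazine mimic in the z=0 plane around ``center``."""
    names = ("N5", "C4A", "C5A", "N10", "C9A", "C10")
    atoms = []
    for i, name in enumerate(names):
        ang = 2 * np.pi * i / 6
        xyz = np.asarray(center, float) + radius * np.array(
            [np.cos(ang), np.sin(ang), 0.0])
        atoms.append(make_atom(start_serial + i, name, name[0], "FAD", "F",
                               900, xyz, het=True))
    return atoms


def fatty_acid(n_carbons, start=(3.0, 0.0, 0.0), step=1.25, start_serial=2000):
    """Linear fatty-acid mimic along +x with carboxylate oxygens on C1."""
    atoms = []
    origin = np.asarray(start, float)
    for i in range(n_carbons):
        atoms.append(make_atom(start_serial + i, f"C{i + 1}", "C", "FAT", "L",
                               500, origin + [step * i, 0, 0], het=True))
    atoms.append(make_atom(start_serial + n_carbons, "O1", "O", "FAT", "L",
                           500, origin + [-0.6, 1.0, 0.0], het=True))
    atoms.append(make_atom(start_serial + n_carbons + 1, "O2", "O", "FAT", "L",
                           500, origin + [-0.6, -1.0, 0.0], het=True))
    spec = LigandSpec("FAT", "L", 500, carboxyl_carbon="C1",
                      chain_carbons=tuple(f"C{i + 1}" for i in range(n_carbons)))
    return atoms, spec


@pytest.fixture
def fad_structure():
    """Lone planar flavin, ring in the z=0 plane centred at the origin."""
    return Structure(planar_fad(), id="fad_only")


@pytest.fixture
def fad_with_ligand():
    """Flavin plus an 8-carbon fatty acid approaching along +x."""
    lig, spec = fatty_acid(8)
    return Structure(planar_fad() + lig, id="fad_lig"), spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240631)
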