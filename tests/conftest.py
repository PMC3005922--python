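"""Shared fixtures: tiny hand-built structure files and synthetic datasets."""
from __future__ import annotations

import textwrap

import numpy as np
import pytest

from tscc.synthdata import SynthSpec, make_pose_set, make_receptor


def _pdb_line(serial, name, alt, res, chain, resseq, x, y, z, elem):
    return (
        f"ATOM  {serial:5d}  {name:<3s}{alt:1s}{res:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{20.0:6.2f}          {elem:>2s}"
    )


@pytest.fixture
def fixture_pdb(tmp_path):
    """Three-residue receptor: 22 records, 2 hydrogens, 1 altLoc duplicate.

    After loading: 19 heavy atoms (SER 6, GLY 4, LYS 9).
    """
    rows = [
        # SER 1 with two hydrogens
        _pdb_line(1, "N", " ", "SER", "A", 1, 0.0, 0.0, 0.0, "N"),
        _pdb_line(2, "CA", " ", "SER", "A", 1, 1.5, 0.0, 0.0, "C"),
        _pdb_line(3, "C", " ", "SER", "A", 1, 2.2, 1.3, 0.0, "C"),
        _pdb_line(4, "O", " ", "SER", "A", 1, 3.4, 1.3, 0.2, "O"),
        _pdb_line(5, "CB", " ", "SER", "A", 1, 2.1, -1.2, 0.6, "C"),
        _pdb_line(6, "OG", " ", "SER", "A", 1, 1.6, -2.4, 0.1, "O"),
        _pdb_line(7, "H", " ", "SER", "A", 1, -0.5, 0.8, 0.2, "H"),
        _pdb_line(8, "HG", " ", "SER", "A", 1, 0.7, -2.4, 0.3, "H"),
        # GLY 2 with CA in two alternate locations
        _pdb_line(9, "N", " ", "GLY", "A", 2, 1.6, 2.4, -0.2, "N"),
        _pdb_line(10, "CA", "A", "GLY", "A", 2, 2.3, 3.7, -0.3, "C"),
        _pdb_line(11, "CA", "B", "GLY", "A", 2, 2.4, 3.6, -0.4, "C"),
        _pdb_line(12, "C", " ", "GLY", "A", 2, 1.5, 4.9, 0.1, "C"),
        _pdb_line(13, "O", " ", "GLY", "A", 2, 0.3, 4.8, 0.3, "O"),
        # LYS 3, far away (> 14 A), with a charged NZ
        _pdb_line(14, "N", " ", "LYS", "A", 3, 20.0, 20.0, 20.0, "N"),
        _pdb_line(15, "CA", " ", "LYS", "A", 3, 21.5, 20.0, 20.0, "C"),
        _pdb_line(16, "C", " ", "LYS", "A", 3, 22.2, 21.3, 20.0, "C"),
        _pdb_line(17, "O", " ", "LYS", "A", 3, 23.4, 21.3, 20.2, "O"),
        _pdb_line(18, "CB", " ", "LYS", "A", 3, 22.1, 18.8, 20.6, "C"),
        _pdb_line(19, "CG", " ", "LYS", "A", 3, 21.6, 17.5, 20.1, "C"),
        _pdb_line(20, "CD", " ", "LYS", "A", 3, 22.3, 16.3, 20.7, "C"),
        _pdb_line(21, "CE", " ", "LYS", "A", 3, 21.8, 15.0, 20.2, "C"),
        _pdb_line(22, "NZ", " ", "LYS", "A", 3, 22.5, 13.8, 20.8, "N")[:78] + "1+",
    ]
    path = tmp_path / "receptor.pdb"
    path.write_text("\n".join(rows) + "\nEND\n")
    return path


_MOLBLOCK = """{name}
  tscc  3D

{counts}
{atoms}{bonds}{props}M  END
>  <docked_energy>
{energy}

$$$$
"""


def _molblock(name, atoms, bonds, energy, chg=None):
    atom_rows = "".join(
        f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n"
        for el, x, y, z in atoms
    )
    bond_rows = "".join(f"{i:3d}{j:3d}{o:3d}  0\n" for i, j, o in bonds)
    props = ""
    if chg:
        entries = "".join(f"{idx:4d}{q:4d}" for idx, q in chg)
        props = f"M  CHG{len(chg):3d}{entries}\n"
    counts = f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    return _MOLBLOCK.format(
        name=name, counts=counts, atoms=atom_rows, bonds=bond_rows,
        props=props, energy=energy,
    )


@pytest.fixture
def fixture_sdf(tmp_path):
    """SDF with 3 poses (energies -8.1/-7.2/-9.0); pose 2 has explicit H,
    pose 3 has a +1 nitrogen."""
    blocks = [
        _molblock(
            "poseA",
            [("C", 0.0, 0.0, 0.0), ("C", 1.5, 0.0, 0.0), ("O", 2.2, 1.2, 0.0)],
            [(1, 2, 1), (2, 3, 2)],
            "-8.1",
        ),
        _molblock(
            "poseB",
            [
                ("C", 0.0, 0.0, 0.0),
                ("N", 1.5, 0.0, 0.0),
                ("C", 2.2, 1.2, 0.0),
                ("H", 1.9, -0.9, 0.0),
                ("H", -0.5, 0.9, 0.0),
            ],
            [(1, 2, 1), (2, 3, 1), (2, 4, 1), (1, 5, 1)],
            "-7.2",
        ),
        _molblock(
            "poseC",
            [
                ("C", 0.0, 0.0, 0.0),
                ("N", 1.5, 0.0, 0.0),
                ("C", 2.9, 0.1, 0.0),
                ("C", 3.6, 1.3, 0.4),
            ],
            [(1, 2, 1), (2, 3, 1), (3, 4, 1)],
            "-9.0",
            chg=[(2, 1)],
        ),
    ]
    path = tmp_path / "poses.sdf"
    path.write_text("".join(blocks))
    return path


@pytest.fixture
def fixture_mol2(tmp_path):
    """MOL2 with two molecules, one charged N, energies in # comments."""
    text = textwrap.dedent(
        """\
        # docked_energy = -7.5
        @<TRIPOS>MOLECULE
        ligA
        4 3 0 0 0
        SMALL
        USER_CHARGES
        @<TRIPOS>ATOM
        1 N1 0.0 0.0 0.0 N.4 1 LIG 0.0
        2 C1 1.5 0.0 0.0 C.3 1 LIG 0.0
        3 C2 3.0 0.0 0.0 C.3 1 LIG 0.0
        4 C3 4.5 0.0 0.0 C.3 1 LIG 0.0
        @<TRIPOS>BOND
        1 1 2 1
        2 2 3 1
        3 3 4 1
        # docked_energy = -6.25
        @<TRIPOS>MOLECULE
        ligB
        3 2 0 0 0
        SMALL
        USER_CHARGES
        @<TRIPOS>ATOM
        1 C1 0.0 0.0 0.0 C.3 1 LIG 0.0
        2 C2 1.5 0.0 0.0 C.3 1 LIG 0.0
        3 O1 2.2 1.2 0.0 O.3 1 LIG 0.0
        @<TRIPOS>BOND
        1 1 2 1
        2 2 3 1
        """
    )
    path = tmp_path / "poses.mol2"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def synth_spec():
    return SynthSpec(seed=1)


@pytest.fixture(scope="session")
def synth_dataset(synth_spec):
    """(site, poses, mode_labels, family_labels) for the default scenario."""
    site = make_receptor(synth_spec)
    poses, modes, families = make_pose_set(synth_spec, site)
    return site, poses, modes, families
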