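"""Structure input/output.

Readers for receptor structures (PDB) and docked ligand poses (SDF / MOL2),
plus the binding-site extraction step that precedes interaction profiling.
All readers return heavy-atom-only records: hydrogens are stripped on load
and hydrogen-bond donor/acceptor character is inferred from a fixed
element/valence rule table so that runs are deterministic regardless of
whether the input carried explicit hydrogens.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D
from scipy.spatial.distance import cdist

logger = logging.getLogger("tscc")

# hydrogen-bond character labels
HB_DONOR = "donor"
HB_ACCEPTOR = "acceptor"
HB_BOTH = "both"
HB_NONPOLAR = "nonpolar"
HB_CLASSES = (HB_DONOR, HB_ACCEPTOR, HB_BOTH, HB_NONPOLAR)

#: PDB atom-name stems treated as hydroxyl oxygens (donor+acceptor) when no
#: hydrogen count is available (receptor atoms carry no bond graph);
#: trailing digits are ignored when matching (OG1 of Thr matches OG).
HYDROXYL_NAMES = frozenset({"OG", "OH", "OW"})

_KNOWN_ELEMENTS = frozenset(
    "C N O S P F Cl Br I B Se Si Na K Mg Ca Zn Fe Mn Cu Ni Co Cl".split()
)


class EmptyStructureError(ValueError):
    """Raised when a structure file yields zero heavy atoms."""


class EmptySiteError(ValueError):
    """Raised when binding-site extraction selects no residues."""


class PoseParseError(ValueError):
    """Raised when a pose record cannot be parsed."""


@dataclass(frozen=True, eq=False)
class Atom:
    """One heavy atom: identity, position, formal charge and H-bond class.

    ``residue_tag`` is ``chain:resname:resnum`` and is only set for receptor
    atoms; ``name`` is the PDB/SDF atom name used in profile column labels.
    """

    serial: int
    element: str
    name: str
    coords: np.ndarray
    formal_charge: int = 0
    hb_class: str = HB_NONPOLAR
    residue_tag: str | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coords, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", xyz)
        if self.element.capitalize() in ("H", "D"):
            raise ValueError(f"atom {self.serial}: hydrogens are stripped on load")
        if self.hb_class not in HB_CLASSES:
            raise ValueError(f"atom {self.serial}: bad hb_class {self.hb_class!r}")


@dataclass
class ReceptorSite:
    """An ordered set of receptor heavy atoms; order fixes profile columns."""

    atoms: list[Atom]
    source_id: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("receptor atom serials must be unique")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def atom_labels(self) -> list[str]:
        """``chain:resname:resnum:atomname`` label per atom, in site order."""
        return [f"{a.residue_tag or '?'}:{a.name}" for a in self.atoms]


@dataclass
class LigandPose:
    """A docked ligand pose: heavy atoms, bond graph and docked energy."""

    pose_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    docked_energy: float

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError(f"pose {self.pose_id}: self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise PoseParseError(
                    f"pose {self.pose_id}: bond ({i},{j}) references missing atom"
                )
        if not np.isfinite(self.docked_energy):
            raise ValueError(f"pose {self.pose_id}: docked_energy must be finite")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


def hb_class_for(element: str, name: str = "", n_hydrogens: int | None = None) -> str:
    """Donor/acceptor class from the element/valence rule table.

    When a hydrogen count is known (ligand atoms, via the molecular graph)
    it decides donor capability; otherwise (receptor PDB atoms) the atom
    name decides hydroxyl oxygens and every nitrogen is assumed protonated,
    which is the common case for amino-acid nitrogens at neutral pH.
    """
    el = element.capitalize()
    if el == "N":
        if n_hydrogens is None or n_hydrogens > 0:
            return HB_DONOR
        return HB_ACCEPTOR
    if el == "O":
        if n_hydrogens is not None:
            return HB_BOTH if n_hydrogens > 0 else HB_ACCEPTOR
        stem = re.sub(r"\d+$", "", name.strip().upper())
        return HB_BOTH if stem in HYDROXYL_NAMES else HB_ACCEPTOR
    if el == "S":
        return HB_ACCEPTOR
    if el not in _KNOWN_ELEMENTS:
        logger.warning("unknown element %r: classed nonpolar", element)
    return HB_NONPOLAR


def assign_hb_classes(atoms: Iterable[Atom]) -> list[Atom]:
    """Return atoms with hb_class set by the rule table (idempotent)."""
    return [replace(a, hb_class=hb_class_for(a.element, a.name)) for a in atoms]


# ---------------------------------------------------------------------------
# receptor (PDB)
# ---------------------------------------------------------------------------

def read_receptor(path: str | Path) -> ReceptorSite:
    """Read a PDB receptor: first model, first/blank altLoc, no hydrogens.

    Formal charges come from the PDB charge column (0 when absent); serials
    are preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise OSError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                seen: set[str] = set()
                icode = res.seqid.icode.strip()
                tag = f"{chain.name}:{res.name}:{res.seqid.num}{icode}"
                for at in res:
                    if at.is_hydrogen():
                        continue
                    if at.name in seen:
                        continue  # keep blank/first altLoc only
                    seen.add(at.name)
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            element=at.element.name,
                            name=at.name,
                            coords=(at.pos.x, at.pos.y, at.pos.z),
                            formal_charge=int(at.charge),
                            residue_tag=tag,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"{path}: no heavy atoms found")
    return ReceptorSite(atoms=assign_hb_classes(atoms), source_id=path.stem)


def write_receptor_pdb(site: ReceptorSite, path: str | Path) -> None:
    """Write a receptor site back to PDB (serials, charges preserved)."""
    # gemmi containers copy on add_*, so group atoms first, build last
    grouped: dict[tuple[str, str, str], list[Atom]] = {}
    for a in site.atoms:
        tag = a.residue_tag or "A:UNK:1"
        chain_name, resname, resnum = tag.split(":")
        grouped.setdefault((chain_name, resname, resnum), []).append(a)
    st = gemmi.Structure()
    st.name = site.source_id or "receptor"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for (chain_name, resname, resnum), members in grouped.items():
        res = gemmi.Residue()
        res.name = resname
        res.het_flag = "A"
        m = re.match(r"(-?\d+)([A-Za-z]?)", resnum)
        res.seqid = gemmi.SeqId(int(m.group(1)), m.group(2) or " ")
        for a in members:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.charge = int(a.formal_charge)
            at.serial = a.serial
            res.add_atom(at)
        chains.setdefault(chain_name, gemmi.Chain(chain_name)).add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path), gemmi.PdbWriteOptions(preserve_serial=True))


# ---------------------------------------------------------------------------
# poses (SDF / MOL2)
# ---------------------------------------------------------------------------

def _pose_from_rdkit(
    mol: Chem.Mol, index: int, energy: float, pose_id: str | None = None
) -> LigandPose:
    if mol.GetNumConformers() == 0:
        raise PoseParseError(f"molecule {index}: no coordinates")
    conf = mol.GetConformer()
    name = pose_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
    name = name.strip() or f"pose{index}"
    atoms = []
    for a in mol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(
            Atom(
                serial=a.GetIdx() + 1,
                element=a.GetSymbol(),
                name=f"{a.GetSymbol()}{a.GetIdx() + 1}",
                coords=(p.x, p.y, p.z),
                formal_charge=a.GetFormalCharge(),
                hb_class=hb_class_for(a.GetSymbol(), n_hydrogens=a.GetTotalNumHs()),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    return LigandPose(pose_id=name, atoms=atoms, bonds=bonds, docked_energy=energy)


def _energy_from_props(
    mol: Chem.Mol, index: int, energy_field: str, default_energy: float | None
) -> float:
    if mol.HasProp(energy_field):
        return float(mol.GetProp(energy_field))
    if default_energy is not None:
        return float(default_energy)
    raise PoseParseError(
        f"molecule {index}: missing energy field {energy_field!r} "
        "and no default energy set"
    )


def read_poses(
    path: str | Path,
    energy_field: str = "docked_energy",
    default_energy: float | None = None,
) -> list[LigandPose]:
    """Read docked poses from an SDF or MOL2 file, in file order.

    Hydrogens are stripped; formal charges come from the file. The docked
    energy is read from the SDF property (or MOL2 ``# field = value``
    comment) named by ``energy_field``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return _read_sdf(path, energy_field, default_energy)
    if suffix == ".mol2":
        return _read_mol2(path, energy_field, default_energy)
    raise ValueError(f"unsupported pose file format: {path.suffix!r}")


def _read_sdf(
    path: Path, energy_field: str, default_energy: float | None
) -> list[LigandPose]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    poses = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise PoseParseError(f"{path}: molecule {i} failed to parse")
        energy = _energy_from_props(mol, i, energy_field, default_energy)
        poses.append(_pose_from_rdkit(mol, i, energy))
    if not poses:
        raise EmptyStructureError(f"{path}: no molecules found")
    return poses


_MOL2_ENERGY_RE = r"^#\s*{field}\s*[:=]\s*(-?[\d.]+(?:[eE][+-]?\d+)?)\s*$"


def _read_mol2(
    path: Path, energy_field: str, default_energy: float | None
) -> list[LigandPose]:
    text = path.read_text()
    starts = [m.start() for m in re.finditer(r"@<TRIPOS>MOLECULE", text)]
    if not starts:
        raise EmptyStructureError(f"{path}: no MOL2 molecule records")
    energy_re = re.compile(
        _MOL2_ENERGY_RE.format(field=re.escape(energy_field)), re.MULTILINE
    )
    poses = []
    bounds = starts + [len(text)]
    for i in range(len(starts)):
        block = text[bounds[i] : bounds[i + 1]]
        # the energy comment precedes each molecule's MOLECULE tag
        head_start = 0 if i == 0 else bounds[i - 1]
        matches = list(energy_re.finditer(text[head_start : starts[i]]))
        m = matches[-1] if matches else None
        mol = Chem.MolFromMol2Block(block, removeHs=True, sanitize=True)
        if mol is None:
            raise PoseParseError(f"{path}: MOL2 record {i} failed to parse")
        if m is not None:
            energy = float(m.group(1))
        elif default_energy is not None:
            energy = float(default_energy)
        else:
            raise PoseParseError(
                f"{path}: record {i} missing energy comment "
                f"'# {energy_field} = ...' and no default energy set"
            )
        poses.append(_pose_from_rdkit(mol, i, energy))
    return poses


def pose_to_rdkit(pose: LigandPose) -> Chem.Mol:
    """Build an RDKit molecule (with conformer and charges) from a pose."""
    em = Chem.RWMol()
    for a in pose.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(int(a.formal_charge))
        em.AddAtom(ra)
    order_map = {
        1.0: Chem.BondType.SINGLE,
        1.5: Chem.BondType.AROMATIC,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
    }
    for i, j, order in pose.bonds:
        em.AddBond(int(i), int(j), order_map.get(float(order), Chem.BondType.SINGLE))
    mol = em.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, a in enumerate(pose.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
    mol.AddConformer(conf)
    mol.SetProp("_Name", pose.pose_id)
    return mol


def write_poses_sdf(
    poses: Sequence[LigandPose],
    path: str | Path,
    energy_field: str = "docked_energy",
) -> None:
    """Write poses to an SDF file with the docked energy as a property."""
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = pose_to_rdkit(pose)
            mol.SetProp(energy_field, f"{pose.docked_energy:.17g}")
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# binding site
# ---------------------------------------------------------------------------

def extract_binding_site(
    receptor: ReceptorSite,
    reference_ligand: LigandPose | np.ndarray,
    radius: float = 10.0,
) -> ReceptorSite:
    """Residue-level binding-site extraction.

    Keeps every residue with at least one atom within ``radius`` of at least
    one reference-ligand atom (all atoms of such residues are kept); atom
    ordering is inherited from the input receptor. The reference may be a
    pose or a bare (n, 3) coordinate array.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ref = (
        reference_ligand.coords
        if isinstance(reference_ligand, LigandPose)
        else np.asarray(reference_ligand, dtype=float)
    )
    if ref.size == 0:
        raise ValueError("reference ligand has no atoms")
    dmin = cdist(receptor.coords, ref).min(axis=1)
    hit_tags = {
        a.residue_tag for a, d in zip(receptor.atoms, dmin) if d <= radius
    }
    site_atoms = [a for a in receptor.atoms if a.residue_tag in hit_tags]
    if not site_atoms:
        raise EmptySiteError(
            f"no residues within {radius} A of the reference ligand"
        )
    return ReceptorSite(atoms=site_atoms, source_id=receptor.source_id)
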