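"""Protein-ligand interaction profiles.

Each docked pose is converted into a real-valued vector indexed by the
binding-site atoms: the entry for receptor atom j is the summed pairwise
energy that atom receives from every ligand heavy atom, using a piecewise
linear potential (PLP) whose parameters depend on whether the atom pair can
hydrogen-bond or is purely steric, plus a Coulomb term between formally
charged atoms (332.0 converts e^2/A to kcal/mol).

The PLP well is trapezoidal: a linear contact penalty falling from V5 at
r=0 to zero at V1, a linear descent to the well depth V6 at V2, a flat well
on [V2, V3], a linear return to zero at V4 and zero beyond. Stacking the
profiles of all poses and dropping receptor atoms touched by no pose (the
"involved atoms" columns) yields the matrix clustered in stage one.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import HB_ACCEPTOR, HB_BOTH, HB_DONOR, Atom, LigandPose, ReceptorSite

COULOMB_FACTOR = 332.0  # kcal*A/(mol*e^2)

HBOND = "hbond"
STERIC = "steric"


class DegenerateGeometryError(ValueError):
    """Raised when two atoms coincide (r = 0)."""


@dataclass(frozen=True)
class PLPParams:
    """Piecewise-linear potential parameters for one interaction class.

    v1 < v2 < v3 < v4 are breakpoint distances in Angstrom; v5 >= 0 is the
    contact penalty at r = 0 and v6 <= 0 the well depth, both in kcal/mol.
    """

    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    v6: float

    def __post_init__(self) -> None:
        if not (0 < self.v1 < self.v2 < self.v3 < self.v4):
            raise ValueError(
                f"breakpoints must satisfy 0 < V1 < V2 < V3 < V4, got "
                f"{self.v1}, {self.v2}, {self.v3}, {self.v4}"
            )
        if not (self.v5 >= 0 >= self.v6):
            raise ValueError("require V5 >= 0 >= V6")


#: Default per-class parameters, following the published piecewise linear
#: potential convention for docking scoring (deep narrow well for hydrogen
#: bonds, shallow wide well for steric contacts). Override via config.
DEFAULT_PLP: dict[str, PLPParams] = {
    HBOND: PLPParams(2.3, 2.6, 3.1, 3.6, 20.0, -2.5),
    STERIC: PLPParams(3.3, 3.6, 4.5, 5.5, 20.0, -0.4),
}

DEFAULT_ES_CUTOFF = 12.0  # Angstrom
DEFAULT_EPSILON = 1e-6  # kcal/mol, involved-atom detection


def plp_energy(r, params: PLPParams):
    """Piecewise-linear pair potential at distance(s) ``r`` (kcal/mol).

    Accepts a scalar or array; negative distances are rejected.
    """
    scalar = np.isscalar(r) or np.ndim(r) == 0
    arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(arr < 0):
        raise ValueError("distance must be non-negative")
    v1, v2, v3, v4, v5, v6 = (
        params.v1, params.v2, params.v3, params.v4, params.v5, params.v6,
    )
    out = np.zeros_like(arr)
    m = arr < v1
    out[m] = v5 * (v1 - arr[m]) / v1
    m = (arr >= v1) & (arr < v2)
    out[m] = v6 * (arr[m] - v1) / (v2 - v1)
    m = (arr >= v2) & (arr <= v3)
    out[m] = v6
    m = (arr > v3) & (arr < v4)
    out[m] = v6 * (v4 - arr[m]) / (v4 - v3)
    return float(out[0]) if scalar else out


def electrostatic_energy(
    q_i: float, q_j: float, r: float, cutoff: float = DEFAULT_ES_CUTOFF
) -> float:
    """Coulomb energy 332.0*q_i*q_j/r, zero unless both charged and r <= cutoff."""
    if r == 0:
        raise DegenerateGeometryError("overlapping atoms (r = 0)")
    if q_i == 0 or q_j == 0 or r > cutoff:
        return 0.0
    return COULOMB_FACTOR * q_i * q_j / r


def _donor_capable(hb_class: str) -> bool:
    return hb_class in (HB_DONOR, HB_BOTH)


def _acceptor_capable(hb_class: str) -> bool:
    return hb_class in (HB_ACCEPTOR, HB_BOTH)


def classify_pair(a: Atom, b: Atom) -> str:
    """``hbond`` if one atom can donate and the other accept, else ``steric``."""
    if (_donor_capable(a.hb_class) and _acceptor_capable(b.hb_class)) or (
        _donor_capable(b.hb_class) and _acceptor_capable(a.hb_class)
    ):
        return HBOND
    return STERIC


@dataclass
class InteractionProfile:
    """Per-receptor-atom interaction energies of one pose (kcal/mol)."""

    pose_id: str
    energies: dict[int, float]  # receptor-site atom serial -> E_j

    def values_for(self, serials: Sequence[int]) -> np.ndarray:
        return np.array([self.energies[s] for s in serials], dtype=float)


def atom_profile(
    site: ReceptorSite,
    pose: LigandPose,
    params: Mapping[str, PLPParams] = DEFAULT_PLP,
    es_cutoff: float = DEFAULT_ES_CUTOFF,
    include_electrostatics: bool = True,
) -> InteractionProfile:
    """Interaction energy E_j of every site atom j with one docked pose.

    E_j sums, over all ligand heavy atoms i, the class-dependent PLP term
    plus (optionally) the Coulomb term between formal charges.
    """
    if len(site) == 0 or len(pose) == 0:
        raise ValueError("site and pose must be non-empty")
    r = cdist(site.coords, pose.coords)  # site x ligand
    if np.any(r < 1e-12):
        j, i = np.argwhere(r < 1e-12)[0]
        raise DegenerateGeometryError(
            f"receptor atom serial {site.atoms[j].serial} overlaps ligand atom "
            f"serial {pose.atoms[i].serial} in pose {pose.pose_id}"
        )
    site_donor = np.array([_donor_capable(a.hb_class) for a in site.atoms])
    site_acc = np.array([_acceptor_capable(a.hb_class) for a in site.atoms])
    lig_donor = np.array([_donor_capable(a.hb_class) for a in pose.atoms])
    lig_acc = np.array([_acceptor_capable(a.hb_class) for a in pose.atoms])
    hbond_mask = (site_donor[:, None] & lig_acc[None, :]) | (
        site_acc[:, None] & lig_donor[None, :]
    )
    energy = np.where(
        hbond_mask, plp_energy(r, params[HBOND]), plp_energy(r, params[STERIC])
    )
    if include_electrostatics:
        q_site = np.array([a.formal_charge for a in site.atoms], dtype=float)
        q_lig = np.array([a.formal_charge for a in pose.atoms], dtype=float)
        qq = q_site[:, None] * q_lig[None, :]
        es = np.where((qq != 0) & (r <= es_cutoff), COULOMB_FACTOR * qq / r, 0.0)
        energy = energy + es
    totals = energy.sum(axis=1)
    return InteractionProfile(
        pose_id=pose.pose_id,
        energies={a.serial: float(e) for a, e in zip(site.atoms, totals)},
    )


@dataclass
class ProfileMatrix:
    """Poses x involved-atoms interaction-energy matrix.

    Columns where no pose deposits energy above ``epsilon`` have been
    dropped; ``atom_serials`` (and the optional human-readable
    ``atom_labels``) record the surviving columns in site order.
    """

    pose_ids: list[str]
    atom_serials: list[int]
    values: np.ndarray
    atom_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pose_ids), len(self.atom_serials)):
            raise ValueError("values shape does not match ids")

    @property
    def n_involved_atoms(self) -> int:
        return len(self.atom_serials)

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.atom_labels or [str(s) for s in self.atom_serials]
        return pd.DataFrame(self.values, index=self.pose_ids, columns=cols)


def build_profile_matrix(
    profiles: Sequence[InteractionProfile],
    epsilon: float = DEFAULT_EPSILON,
    site: ReceptorSite | None = None,
) -> ProfileMatrix:
    """Stack pose profiles and drop columns that no pose touches.

    A column (receptor atom) survives if any pose has |E_j| >= epsilon;
    surviving values are copied unmodified. Passing the site attaches
    human-readable column labels.
    """
    if not profiles:
        raise ValueError("no profiles given")
    serials = list(profiles[0].energies.keys())
    key_set = set(serials)
    for p in profiles[1:]:
        if set(p.energies.keys()) != key_set:
            raise ValueError("profiles do not share a receptor site")
    mat = np.vstack([p.values_for(serials) for p in profiles])
    keep = np.abs(mat).max(axis=0) >= epsilon
    if not keep.any():
        raise ValueError("all profile columns are zero: empty matrix")
    labels = None
    if site is not None:
        by_serial = dict(zip([a.serial for a in site.atoms], site.atom_labels()))
        labels = [by_serial[s] for s, k in zip(serials, keep) if k]
    return ProfileMatrix(
        pose_ids=[p.pose_id for p in profiles],
        atom_serials=[s for s, k in zip(serials, keep) if k],
        values=mat[:, keep],
        atom_labels=labels,
    )
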