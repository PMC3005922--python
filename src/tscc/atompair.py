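"""Atom-pair structural descriptors.

A molecule's 2D topology is encoded as a binary vector keyed by
(atom type, atom type, shortest bond-path length): bit (t_a, t_b, k) is on
when the molecule contains at least one pair of atoms of types t_a and t_b
separated by k bonds. With the default 10-type alphabet and 15 topological
distance bins this gives 10*11/2 * 15 = 825 descriptor positions; path
lengths beyond 15 bonds fold into the last bin, and pairs in different
connected components set no bit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .structio import LigandPose

#: default atom-type alphabet: the eight organic/heteroatom elements most
#: informative for drug-like molecules, the remaining halogen, and a
#: catch-all. 10 types -> 55 unordered type pairs.
ATOM_TYPES: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "X")

DEFAULT_N_BINS = 15

UNREACHABLE = -1


def atom_type_of(element: str, alphabet: Sequence[str] = ATOM_TYPES) -> str:
    """Map an element symbol onto the typing alphabet ('X' = anything else)."""
    el = element.capitalize()
    return el if el in alphabet else alphabet[-1]


@dataclass
class MolGraph:
    """Bonded molecular graph: typed nodes, simple undirected edges."""

    node_types: list[str]
    edges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.node_types)
        seen = set()
        clean = []
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references missing node")
            key = (min(i, j), max(i, j))
            if key in seen:
                continue  # collapse multi-edges
            seen.add(key)
            clean.append(key)
        self.edges = clean

    def __len__(self) -> int:
        return len(self.node_types)

    @classmethod
    def from_pose(
        cls, pose: LigandPose, alphabet: Sequence[str] = ATOM_TYPES
    ) -> "MolGraph":
        return cls(
            node_types=[atom_type_of(a.element, alphabet) for a in pose.atoms],
            edges=[(i, j) for i, j, _ in pose.bonds],
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self)))
        g.add_edges_from(self.edges)
        return g


def topo_distances(g: MolGraph) -> np.ndarray:
    """All-pairs shortest bond-path lengths (BFS); -1 marks unreachable."""
    n = len(g)
    d = np.full((n, n), UNREACHABLE, dtype=int)
    nxg = g.to_networkx()
    for src, lengths in nx.all_pairs_shortest_path_length(nxg):
        for dst, length in lengths.items():
            d[src, dst] = length
    return d


def ap_keys(
    alphabet: Sequence[str] = ATOM_TYPES, n_bins: int = DEFAULT_N_BINS
) -> list[tuple[str, str, int]]:
    """Descriptor key order: lexicographic over (unordered type pair, bin)."""
    types = sorted(alphabet)
    keys = []
    for i, ta in enumerate(types):
        for tb in types[i:]:
            for b in range(1, n_bins + 1):
                keys.append((ta, tb, b))
    return keys


def _key_index(
    alphabet: Sequence[str], n_bins: int
) -> dict[tuple[str, str, int], int]:
    return {k: i for i, k in enumerate(ap_keys(alphabet, n_bins))}


@dataclass
class APVector:
    """Binary atom-pair descriptor of one molecule."""

    bits: np.ndarray
    alphabet: tuple[str, ...] = ATOM_TYPES
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        expected = len(self.alphabet) * (len(self.alphabet) + 1) // 2 * self.n_bins
        if self.bits.shape != (expected,):
            raise ValueError(f"descriptor length must be {expected}")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("descriptor must be binary")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def on_keys(self) -> list[tuple[str, str, int]]:
        keys = ap_keys(self.alphabet, self.n_bins)
        return [keys[i] for i in np.flatnonzero(self.bits)]


def atom_pair_descriptor(
    g: MolGraph,
    n_bins: int = DEFAULT_N_BINS,
    alphabet: Sequence[str] = ATOM_TYPES,
) -> APVector:
    """Binary atom-pair descriptor: one bit per realized (type, type, bin).

    The bin of a pair at topological distance d is min(d, n_bins), so all
    long-range pairs land in the last bin rather than being discarded.
    """
    idx = _key_index(alphabet, n_bins)
    bits = np.zeros(len(idx), dtype=np.uint8)
    d = topo_distances(g)
    n = len(g)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] == UNREACHABLE:
                continue
            ta, tb = sorted((g.node_types[i], g.node_types[j]))
            bits[idx[(ta, tb, min(int(d[i, j]), n_bins))]] = 1
    return APVector(bits=bits, alphabet=tuple(alphabet), n_bins=n_bins)


def descriptor_matrix(
    mols: Sequence[MolGraph],
    n_bins: int = DEFAULT_N_BINS,
    alphabet: Sequence[str] = ATOM_TYPES,
) -> tuple[np.ndarray, list[tuple[str, str, int]]]:
    """Stack descriptors and drop columns zero across all molecules.

    Returns the reduced binary matrix (one row per molecule, input order)
    and the retained keys. Dropping all-zero columns changes no pairwise
    Tanimoto distance since those positions contribute to neither
    intersection nor union.
    """
    if not mols:
        raise ValueError("no molecules given")
    full = np.vstack(
        [atom_pair_descriptor(g, n_bins, alphabet).bits for g in mols]
    )
    keep = full.any(axis=0)
    keys = ap_keys(alphabet, n_bins)
    return full[:, keep], [k for k, kept in zip(keys, keep) if kept]
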