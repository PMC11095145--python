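"""SMILES -> molecular graph with fixed-width atom/bond feature vectors.

Heavy atoms only; hydrogens are implicit and surface in the H-count block.
Feature widths are fixed at 30 (atoms) and 11 (bonds).  The concrete
layout is this package's dialect:

atom (30): element one-hot {C,N,O,F,P,S,Cl,Br,I,other} (10) | degree
one-hot 0-5 (6) | total-H-count one-hot 0-4 (5) | hybridization one-hot
{sp,sp2,sp3,other} (4) | formal charge (1) | aromatic flag (1) | in-ring
flag (1) | radical electrons (1) | chirality-specified flag (1)

bond (11): type one-hot {single,double,triple,aromatic} (4) | conjugated
flag (1) | in-ring flag (1) | stereo one-hot {none,Z,E,cis,trans} (5)

Values outside a one-hot range (e.g. degree > 5) leave that block
all-zero, so every one-hot block sums to at most 1.  Edges are stored
once as unordered index pairs; the network layer expands both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .compound_io import CompoundDataset, ValidationError, parse_single_fragment

logger = logging.getLogger(__name__)

ATOM_FEATURE_WIDTH = 30
BOND_FEATURE_WIDTH = 11

ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")  # slot 9 = other

_HYBRIDIZATIONS = {
    Chem.HybridizationType.SP: 0,
    Chem.HybridizationType.SP2: 1,
    Chem.HybridizationType.SP3: 2,
}

_BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

_STEREO = {
    Chem.BondStereo.STEREONONE: 0,
    Chem.BondStereo.STEREOZ: 1,
    Chem.BondStereo.STEREOE: 2,
    Chem.BondStereo.STEREOCIS: 3,
    Chem.BondStereo.STEREOTRANS: 4,
}


@dataclass
class MolecularGraph:
    compound_id: str
    atom_features: np.ndarray  # (n_atoms, 30)
    bond_features: np.ndarray  # (n_bonds, 11)
    edges: np.ndarray          # (n_bonds, 2) unordered heavy-atom index pairs

    def __post_init__(self) -> None:
        if self.atom_features.shape[0] < 1:
            raise ValidationError(f"{self.compound_id!r}: graph must have at least one atom")
        if self.atom_features.shape[1] != ATOM_FEATURE_WIDTH:
            raise ValidationError(f"{self.compound_id!r}: atom feature width must be {ATOM_FEATURE_WIDTH}")
        if self.bond_features.shape[1] != BOND_FEATURE_WIDTH:
            raise ValidationError(f"{self.compound_id!r}: bond feature width must be {BOND_FEATURE_WIDTH}")
        if len(self.edges) and self.edges.max() >= self.n_atoms:
            raise ValidationError(f"{self.compound_id!r}: edge endpoint out of range")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_features.shape[0]


def _one_hot(width: int, index: int | None) -> np.ndarray:
    v = np.zeros(width)
    if index is not None and 0 <= index < width:
        v[index] = 1.0
    return v


def _atom_vector(atom: Chem.Atom) -> np.ndarray:
    symbol = atom.GetSymbol()
    if symbol in ELEMENTS:
        element = ELEMENTS.index(symbol)
    else:
        element = 9
        logger.debug("element %s outside alphabet; using 'other' slot", symbol)
    hyb = _HYBRIDIZATIONS.get(atom.GetHybridization(), 3)
    return np.concatenate(
        [
            _one_hot(10, element),
            _one_hot(6, atom.GetDegree()),
            _one_hot(5, atom.GetTotalNumHs()),
            _one_hot(4, hyb),
            [float(atom.GetFormalCharge())],
            [float(atom.GetIsAromatic())],
            [float(atom.IsInRing())],
            [float(atom.GetNumRadicalElectrons())],
            [float(atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED)],
        ]
    )


def _bond_vector(bond: Chem.Bond) -> np.ndarray:
    return np.concatenate(
        [
            _one_hot(4, _BOND_TYPES.get(bond.GetBondType())),
            [float(bond.GetIsConjugated())],
            [float(bond.IsInRing())],
            _one_hot(5, _STEREO.get(bond.GetStereo(), 0)),
        ]
    )


def featurize_graph(smiles: str, compound_id: str = "") -> MolecularGraph:
    """Featurize one SMILES.  Atom order is the parser's order for that
    SMILES, so a renumbered rewriting yields the permuted graph."""
    mol = parse_single_fragment(smiles)
    if mol is None:
        raise ValidationError(f"cannot parse SMILES {smiles!r}")
    n = mol.GetNumAtoms()
    atom_features = np.vstack([_atom_vector(a) for a in mol.GetAtoms()])
    if mol.GetNumBonds():
        bond_features = np.vstack([_bond_vector(b) for b in mol.GetBonds()])
        edges = np.array(
            [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()], dtype=int
        )
    else:
        bond_features = np.empty((0, BOND_FEATURE_WIDTH))
        edges = np.empty((0, 2), dtype=int)
    return MolecularGraph(compound_id or smiles, atom_features, bond_features, edges)


def batch_featurize(dataset: CompoundDataset) -> list[MolecularGraph]:
    """Featurize every record, in dataset order; one failure aborts with
    the compound named."""
    graphs = []
    for rec in dataset:
        try:
            graphs.append(featurize_graph(rec.smiles, rec.compound_id))
        except ValidationError as exc:
            raise ValidationError(f"compound {rec.compound_id!r}: {exc}") from exc
    return graphs
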