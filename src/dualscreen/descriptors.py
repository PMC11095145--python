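"""The 12-descriptor physicochemical panel for the tabular model path.

The panel: monoisotopic molecular weight, Crippen LogP, Ertl TPSA,
Lipinski H-bond donor and acceptor counts, rotatable bonds, sp3 carbon
fraction, aromatic ring count, Gasteiger max/min partial charge, and
nitrogen/oxygen atom counts.  Partial charges use iterative partial
equalization of orbital electronegativities; molecules for which the
scheme yields non-finite values get 0.0 imputed and the event is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .compound_io import CompoundDataset, ValidationError, num_fragments, parse_single_fragment

logger = logging.getLogger(__name__)

DESCRIPTOR_NAMES = (
    "exact_mol_wt",
    "mol_logp",
    "tpsa",
    "num_h_donors",
    "num_h_acceptors",
    "num_rotatable_bonds",
    "fraction_csp3",
    "num_aromatic_rings",
    "max_partial_charge",
    "min_partial_charge",
    "num_nitrogen",
    "num_oxygen",
)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)


@dataclass(frozen=True)
class DescriptorVector:
    exact_mol_wt: float          # Da, monoisotopic
    mol_logp: float              # unitless octanol-water partition estimate
    tpsa: float                  # A^2 topological polar surface area
    num_h_donors: int
    num_h_acceptors: int
    num_rotatable_bonds: int
    fraction_csp3: float         # in [0, 1]; 0 for carbon-free molecules
    num_aromatic_rings: int
    max_partial_charge: float    # e
    min_partial_charge: float    # e
    num_nitrogen: int
    num_oxygen: int
    charge_imputed: bool = False  # True when Gasteiger charges were non-finite

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES], dtype=float)


def _gasteiger_extrema(mol: Chem.Mol) -> tuple[float, float, bool]:
    max_q = Descriptors.MaxPartialCharge(mol)
    min_q = Descriptors.MinPartialCharge(mol)
    if max_q is None or min_q is None or not (math.isfinite(max_q) and math.isfinite(min_q)):
        return 0.0, 0.0, True
    return float(max_q), float(min_q), False


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the 12-descriptor panel for one single-fragment SMILES."""
    mol = parse_single_fragment(smiles)
    if mol is None:
        raise ValidationError(f"cannot parse SMILES {smiles!r}")
    if num_fragments(mol) > 1:
        raise ValidationError(f"multi-fragment SMILES not allowed: {smiles!r}")
    max_q, min_q, imputed = _gasteiger_extrema(mol)
    if imputed:
        logger.warning("non-finite partial charges for %r; imputed 0.0", smiles)
    return DescriptorVector(
        exact_mol_wt=float(Descriptors.ExactMolWt(mol)),
        mol_logp=float(Crippen.MolLogP(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
        num_h_donors=int(Lipinski.NumHDonors(mol)),
        num_h_acceptors=int(Lipinski.NumHAcceptors(mol)),
        num_rotatable_bonds=int(Lipinski.NumRotatableBonds(mol)),
        fraction_csp3=float(Lipinski.FractionCSP3(mol)),
        num_aromatic_rings=int(rdMolDescriptors.CalcNumAromaticRings(mol)),
        max_partial_charge=max_q,
        min_partial_charge=min_q,
        num_nitrogen=sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "N"),
        num_oxygen=sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "O"),
        charge_imputed=imputed,
    )


def featurize_table(dataset: CompoundDataset) -> pd.DataFrame:
    """Descriptor matrix (n_compounds x 12) indexed by compound_id, rows in
    dataset order.  Raises naming the first compound whose SMILES fails."""
    rows = []
    n_imputed = 0
    for rec in dataset:
        try:
            vec = compute_descriptors(rec.smiles)
        except ValidationError as exc:
            raise ValidationError(f"compound {rec.compound_id!r}: {exc}") from exc
        n_imputed += vec.charge_imputed
        rows.append(vec.to_array())
    if n_imputed:
        logger.info("partial charges imputed for %d/%d compounds", n_imputed, len(dataset))
    mat = np.vstack(rows) if rows else np.empty((0, N_DESCRIPTORS))
    frame = pd.DataFrame(mat, columns=list(DESCRIPTOR_NAMES), index=dataset.compound_ids)
    frame.index.name = "compound_id"
    if not np.isfinite(frame.to_numpy()).all():
        bad = frame.index[~np.isfinite(frame.to_numpy()).all(axis=1)][0]
        raise ValidationError(f"non-finite descriptor values for compound {bad!r}")
    return frame
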