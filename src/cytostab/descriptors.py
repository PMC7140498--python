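"""Molecular descriptor sets for the stability classifiers.

Two panels are provided:

``rdkit2d``
    The standard 2D physicochemical/topological descriptor panel (about 210
    named descriptors: logP, TPSA, counts, connectivity and E-state indices,
    fragment counts, ...).

``qna``
    120 descriptors built from per-atom quantities derived from atomic
    ionization potential (IP) and electron affinity (EA) propagated through
    the heavy-atom connectivity matrix. With A_k = ½(IP_k + EA_k) (Mulliken
    electronegativity) and B_k = (IP_k − EA_k)^(−1/2), the per-atom values

        P_i = B_i · [exp(−C/2) B]_i        Q_i = B_i · [exp(−C/2) (A ∘ B)]_i

    (C the adjacency matrix) are summarized into 110 joint moments
    mean_i(P_i^a · Q_i^b) for a = 0..10, b = 0..9 (the constant (0, 0) cell
    is removed later by the constant-descriptor filter, like any constant
    descriptor), plus 10 whole-molecule 2D descriptors. The atomic
    IP/EA values are a packaged element table (eV). This summarization is a
    reconstruction of the published QNA descriptor family, not a port of any
    particular implementation.

Both panels are invariant to input atom ordering.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from scipy.linalg import expm

logger = logging.getLogger(__name__)

DESCRIPTOR_SETS = ("rdkit2d", "qna")

# First ionization potential / electron affinity (eV), NIST values for the
# elements common in drug-like molecules. Slightly negative EAs (N) are kept:
# IP − EA stays positive, which is all B_k requires.
ATOMIC_IP_EA: dict[int, tuple[float, float]] = {
    1: (13.598, 0.754),   # H (used only if explicit)
    3: (5.392, 0.618),    # Li
    5: (8.298, 0.280),    # B
    6: (11.260, 1.262),   # C
    7: (14.534, -0.070),  # N
    8: (13.618, 1.461),   # O
    9: (17.423, 3.401),   # F
    11: (5.139, 0.548),   # Na
    14: (8.152, 1.390),   # Si
    15: (10.487, 0.746),  # P
    16: (10.360, 2.077),  # S
    17: (12.968, 3.613),  # Cl
    19: (4.341, 0.501),   # K
    34: (9.752, 2.021),   # Se
    35: (11.814, 3.364),  # Br
    53: (10.451, 3.059),  # I
}

# 110 joint moments; the (0, 0) cell is identically 1 and is removed by the
# downstream constant-descriptor filter, as constant descriptors always are.
QNA_POWERS = [(a, b) for a in range(11) for b in range(10)]

_WHOLE_MOL_2D = [
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Crippen.MolLogP),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("NumHAcceptors", rdMolDescriptors.CalcNumHBA),
    ("NumHDonors", rdMolDescriptors.CalcNumHBD),
    ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("RingCount", rdMolDescriptors.CalcNumRings),
    ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("HeavyAtomCount", lambda m: float(m.GetNumHeavyAtoms())),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
]


class DescriptorError(ValueError):
    """Descriptor computation failed for a molecule."""


def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise DescriptorError(f"unparseable SMILES: {mol!r}")
        return parsed
    return mol


def _rdkit2d(mol: Chem.Mol) -> dict[str, float]:
    values = Descriptors.CalcMolDescriptors(mol)
    return {name: float(values[name]) for name in sorted(values)}


def qna_atom_values(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    """Per-heavy-atom P and Q values (see module docstring)."""
    atoms = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    n = len(atoms)
    if n == 0:
        raise DescriptorError("no heavy atoms")
    ip_ea = []
    for a in atoms:
        z = a.GetAtomicNum()
        if z not in ATOMIC_IP_EA:
            raise DescriptorError(f"no IP/EA tabulated for element Z={z}")
        ip_ea.append(ATOMIC_IP_EA[z])
    ip = np.array([x[0] for x in ip_ea])
    ea = np.array([x[1] for x in ip_ea])
    A = 0.5 * (ip + ea)
    B = 1.0 / np.sqrt(ip - ea)
    idx = {a.GetIdx(): i for i, a in enumerate(atoms)}
    C = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in idx and j in idx:
            C[idx[i], idx[j]] = C[idx[j], idx[i]] = 1.0
    M = expm(-0.5 * C)
    P = B * (M @ B)
    Q = B * (M @ (A * B))
    return P, Q


def _qna(mol: Chem.Mol) -> dict[str, float]:
    P, Q = qna_atom_values(mol)
    out: dict[str, float] = {}
    for a, b in QNA_POWERS:
        out[f"QNA_P{a}Q{b}"] = float(np.mean(P**a * Q**b))
    for name, fn in _WHOLE_MOL_2D:
        out[name] = float(fn(mol))
    return out


def compute_descriptors(mol: Chem.Mol | str, set_tag: str = "rdkit2d") -> dict[str, float]:
    """Fixed-length named descriptor vector for one molecule.

    Raises :class:`DescriptorError` if the computation fails or produces
    non-finite values.
    """
    mol = _as_mol(mol)
    if set_tag == "rdkit2d":
        values = _rdkit2d(mol)
    elif set_tag == "qna":
        values = _qna(mol)
    else:
        raise ValueError(f"unknown descriptor set {set_tag!r}")
    if not all(np.isfinite(v) for v in values.values()):
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        raise DescriptorError(f"non-finite descriptors: {bad[:5]}")
    return values


def descriptor_matrix(
    records: Sequence, set_tag: str = "rdkit2d"
) -> tuple[pd.DataFrame, list[str]]:
    """Descriptor DataFrame (indexed by InChIKey) for a record set.

    Molecules whose computation fails are excluded with a log line; their
    keys are returned as the second element.
    """
    rows = {}
    failed = []
    for rec in records:
        try:
            rows[rec.inchikey] = compute_descriptors(rec.smiles_std, set_tag)
        except DescriptorError as err:
            logger.warning("descriptor failure for %s: %s", rec.inchikey, err)
            failed.append(rec.inchikey)
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    return matrix.reindex(sorted(matrix.columns), axis=1), failed
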