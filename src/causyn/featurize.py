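"""SMILES -> molecular graph conversion and the shared GCN adjacency operator.

A drug is represented as G = (X, A): X is an n x F_d atom-feature matrix over
heavy atoms, A the binary symmetric bond adjacency. All graph-convolution
stacks in the model share the symmetric normalization
A_hat = D^{-1/2} (A + I) D^{-1/2}, whose spectrum lies in [-1, 1].

Atom features (F_d = 29): one-hot element over a fixed 16-symbol vocabulary
(15 named elements plus a catch-all slot), one-hot heavy-atom degree 0-5,
formal charge, aromaticity flag, and one-hot total-H count 0-4. The scheme
is deliberately minimal and recorded here so it can be swapped without
touching the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = ["MolecularGraph", "smiles_to_graph", "normalize_adjacency", "ATOM_VOCAB"]

# 15 named elements + 1 catch-all slot
ATOM_VOCAB = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
              "Si", "Se", "Na", "K", "Li"]
_N_DEGREE = 6
_N_HS = 5
FEATURE_DIM = len(ATOM_VOCAB) + 1 + _N_DEGREE + 1 + 1 + _N_HS  # = 29


@dataclass(frozen=True)
class MolecularGraph:
    """Atom-feature matrix X (n x F_d) and bond adjacency A (n x n)."""

    X: np.ndarray
    A: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.A.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.X.shape[1]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    feat = np.zeros(FEATURE_DIM)
    sym = atom.GetSymbol()
    idx = ATOM_VOCAB.index(sym) if sym in ATOM_VOCAB else len(ATOM_VOCAB)
    feat[idx] = 1.0
    off = len(ATOM_VOCAB) + 1
    feat[off + min(atom.GetDegree(), _N_DEGREE - 1)] = 1.0
    off += _N_DEGREE
    feat[off] = float(atom.GetFormalCharge())
    feat[off + 1] = float(atom.GetIsAromatic())
    off += 2
    feat[off + min(atom.GetTotalNumHs(), _N_HS - 1)] = 1.0
    return feat


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom molecular graph.

    Node order follows RDKit atom order for the given input string, which is
    deterministic for a fixed string; canonicalization is never applied here.
    Raises ``ValueError`` (carrying the string) on unparsable input or
    molecules without heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n < 1:
        raise ValueError(f"SMILES has no heavy atoms: {smiles!r}")
    X = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    A = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return MolecularGraph(X=X, A=A)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization A_hat = D^{-1/2} (A + I) D^{-1/2}.

    ``A`` must be square, symmetric, binary-valued with zero diagonal; ``D``
    is the degree matrix of A + I (so every row has degree >= 1).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal")
    a_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
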