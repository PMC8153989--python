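"""Morgan circular fingerprints and the unified node attribute matrix.

Drugs are described by hashed binary circular fingerprints (ECFP-style)
computed from SMILES with RDKit; diseases by their row of the semantic
similarity matrix.  The two heterogeneous attribute sets are merged
into one n x k matrix X by zero-padded block concatenation: a drug row
is ``[fingerprint | 0]``, a disease row ``[0 | similarity row]``, so
k = n_bits + n_diseases and every node has an attribute vector of the
same length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "morgan_fingerprint",
    "fingerprint_matrix",
    "build_attribute_matrix",
    "AttributeLayout",
    "MorganFeaturizer",
]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 1024


def morgan_fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
    drug_id: str = "",
) -> np.ndarray:
    """Hashed binary circular fingerprint of one molecule.

    Raises on an unparseable SMILES rather than zero-filling, so a bad
    structure never silently becomes an all-zero attribute row.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for drug {drug_id or smiles!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.float64)
    arr[list(bv.GetOnBits())] = 1.0
    return arr


def fingerprint_matrix(
    smiles_table: Mapping[str, str],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[list[str], np.ndarray]:
    """Fingerprints for every drug, rows in canonical (sorted id) order."""
    drug_ids = sorted(smiles_table)
    rows = [
        morgan_fingerprint(smiles_table[d], radius, n_bits, drug_id=d) for d in drug_ids
    ]
    return drug_ids, np.vstack(rows)


@dataclass(frozen=True)
class AttributeLayout:
    """Block boundaries of the unified attribute matrix."""

    n_drugs: int
    n_diseases: int
    n_bits: int

    @property
    def k(self) -> int:
        return self.n_bits + self.n_diseases


def build_attribute_matrix(
    drug_ids: Sequence[str],
    fingerprints: np.ndarray,
    disease_ids: Sequence[str],
    similarity: np.ndarray,
) -> tuple[np.ndarray, AttributeLayout]:
    """Assemble X: drug rows carry fingerprints, disease rows similarity.

    Row order is the canonical node order (sorted drugs then sorted
    diseases); each block is zero in the other block's columns.
    """
    fingerprints = np.asarray(fingerprints, dtype=np.float64)
    similarity = np.asarray(similarity, dtype=np.float64)
    if len(drug_ids) == 0:
        raise ValueError("degenerate network: no drugs")
    if len(disease_ids) == 0:
        raise ValueError("degenerate network: no diseases")
    if fingerprints.shape[0] != len(drug_ids):
        raise ValueError("fingerprint rows do not match drug ids")
    if similarity.shape != (len(disease_ids), len(disease_ids)):
        raise ValueError("similarity matrix does not match disease ids")
    if list(drug_ids) != sorted(drug_ids) or list(disease_ids) != sorted(disease_ids):
        raise ValueError("ids must be in canonical sorted order")
    layout = AttributeLayout(len(drug_ids), len(disease_ids), fingerprints.shape[1])
    X = np.zeros((layout.n_drugs + layout.n_diseases, layout.k))
    X[: layout.n_drugs, : layout.n_bits] = fingerprints
    X[layout.n_drugs :, layout.n_bits :] = similarity
    return X, layout


class MorganFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer from SMILES strings to fingerprint bits.

    Parameters
    ----------
    radius : int, default 2
        Circular neighborhood radius (2 is the ECFP4 convention).
    n_bits : int, default 1024
        Folded fingerprint length.
    """

    def __init__(self, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X: Sequence[str], y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        return np.vstack([morgan_fingerprint(s, self.radius, self.n_bits) for s in X])
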