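"""Readers and writers for the pipeline's external table formats.

Every table is plain TSV; lines starting with ``#`` are comments.  Node
order is canonical throughout the package: drug identifiers sorted
lexicographically occupy matrix rows ``0 .. n_drugs-1``, disease
identifiers sorted lexicographically occupy rows ``n_drugs .. n-1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AssociationTable",
    "read_associations",
    "read_smiles_table",
    "read_tree_numbers",
    "read_fingerprint_table",
    "write_fingerprint_table",
    "read_embeddings",
    "write_embeddings",
    "write_similarity_matrix",
    "TREE_NUMBER_RE",
]

TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")


class ParseError(ValueError):
    """A file violated the expected table format."""


@dataclass(frozen=True)
class AssociationTable:
    """The bipartite drug-disease association list in canonical order.

    Attributes
    ----------
    pairs : list of (drug_id, disease_id)
        Deduplicated association pairs in first-seen order.
    drug_ids, disease_ids : list of str
        Sorted unique identifiers; their concatenation defines the
        canonical node order of every matrix in the pipeline.
    n_duplicates_dropped : int
        Count of exact duplicate pairs removed on construction.
    """

    pairs: tuple[tuple[str, str], ...]
    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    n_duplicates_dropped: int = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        seen: dict[tuple[str, str], None] = {}
        dropped = 0
        for p in pairs:
            if p in seen:
                dropped += 1
            else:
                seen[p] = None
        uniq = tuple(seen)
        if not uniq:
            raise ParseError("association table contains no pairs")
        drugs = tuple(sorted({d for d, _ in uniq}))
        diseases = tuple(sorted({z for _, z in uniq}))
        overlap = set(drugs) & set(diseases)
        if overlap:
            raise ParseError(
                f"identifiers used as both drug and disease: {sorted(overlap)[:5]}"
            )
        return cls(uniq, drugs, diseases, dropped)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_diseases

    def node_index(self) -> dict[str, int]:
        """Map every identifier to its canonical matrix row."""
        idx = {d: i for i, d in enumerate(self.drug_ids)}
        idx.update({z: self.n_drugs + j for j, z in enumerate(self.disease_ids)})
        return idx


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def read_associations(path: str | Path) -> AssociationTable:
    """Read a drug-disease edge list (TSV: drug_id, disease_id).

    Duplicate pairs are dropped (the count is kept on the returned
    table); identifier lists come back sorted, which fixes the node
    order for the whole run.
    """
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: expected 'drug<TAB>disease', got {line!r}")
        pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise ParseError(f"{path}: no association pairs found")
    return AssociationTable.from_pairs(pairs)


def read_smiles_table(path: str | Path) -> dict[str, str]:
    """Read a drug structure table (TSV: drug_id, SMILES)."""
    entries: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'id<TAB>smiles', got {line!r}")
        drug_id, smiles = fields[0].strip(), fields[1].strip()
        if not smiles:
            raise ParseError(f"{path}:{lineno}: empty SMILES for {drug_id!r}")
        if drug_id in entries:
            raise ParseError(f"{path}:{lineno}: duplicate drug id {drug_id!r}")
        entries[drug_id] = smiles
    if not entries:
        raise ParseError(f"{path}: no SMILES entries found")
    return entries


def read_tree_numbers(path: str | Path) -> dict[str, list[str]]:
    """Read a disease ontology table (TSV: disease_id, ``;``-joined tree numbers).

    Tree numbers are dot-separated hierarchy codes such as
    ``C04.557.337``; each is syntax-checked against
    ``[A-Z][0-9]+(\\.[0-9]+)*``.
    """
    entries: dict[str, list[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[1].strip():
            raise ParseError(f"{path}:{lineno}: missing tree numbers: {line!r}")
        disease_id = fields[0].strip()
        if disease_id in entries:
            raise ParseError(f"{path}:{lineno}: duplicate disease id {disease_id!r}")
        codes = [c.strip() for c in fields[1].split(";") if c.strip()]
        if not codes:
            raise ParseError(f"{path}:{lineno}: empty tree-number field")
        for code in codes:
            if not TREE_NUMBER_RE.match(code):
                raise ParseError(f"{path}:{lineno}: invalid tree number {code!r}")
        entries[disease_id] = codes
    if not entries:
        raise ParseError(f"{path}: no tree-number entries found")
    return entries


def read_fingerprint_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a precomputed fingerprint table (TSV: drug_id, 0/1 bit string)."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'id<TAB>bits'")
        drug_id, bits = fields[0].strip(), fields[1].strip()
        if drug_id in ids:
            raise ParseError(f"{path}:{lineno}: duplicate drug id {drug_id!r}")
        if not bits or set(bits) - {"0", "1"}:
            raise ParseError(f"{path}:{lineno}: bit string must be 0/1 only")
        ids.append(drug_id)
        rows.append(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
    if not ids:
        raise ParseError(f"{path}: empty fingerprint table")
    mat = np.vstack(rows).astype(np.float64)
    if len({r.size for r in rows}) != 1:
        raise ParseError(f"{path}: inconsistent fingerprint lengths")
    return ids, mat


def write_fingerprint_table(ids: Sequence[str], bits: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# drug_id\tbits\n")
        for drug_id, row in zip(ids, np.asarray(bits)):
            fh.write(drug_id + "\t" + "".join("1" if b else "0" for b in row) + "\n")


def write_embeddings(ids: Sequence[str], vectors: np.ndarray, path: str | Path) -> None:
    """Write node vectors in the word2vec text convention.

    First line is ``n_nodes dim``; each following line is an id and its
    coordinates, space-separated.  The round trip preserves at least
    8 significant digits.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or len(ids) != vectors.shape[0]:
        raise ValueError("ids and vector rows must correspond")
    with open(path, "w") as fh:
        fh.write(f"{vectors.shape[0]} {vectors.shape[1]}\n")
        for node_id, row in zip(ids, vectors):
            fh.write(node_id + " " + " ".join(f"{v:.12g}" for v in row) + "\n")


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty embedding file")
    header = lines[0].split()
    if len(header) != 2:
        raise ParseError(f"{path}:1: header must be 'n_nodes dim'")
    n, dim = int(header[0]), int(header[1])
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != dim + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {dim} values per row, got {len(fields) - 1}"
            )
        ids.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    if len(ids) != n:
        raise ParseError(f"{path}: header promises {n} rows, found {len(ids)}")
    mat = np.array(rows, dtype=np.float64) if rows else np.zeros((0, dim))
    return ids, mat


def write_similarity_matrix(
    disease_ids: Sequence[str], values: np.ndarray, path: str | Path
) -> None:
    """Write a disease-similarity matrix as TSV with id header row/column."""
    with open(path, "w") as fh:
        fh.write("disease_id\t" + "\t".join(disease_ids) + "\n")
        for disease_id, row in zip(disease_ids, np.asarray(values)):
            fh.write(disease_id + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
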