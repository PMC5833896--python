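"""Signature molecular descriptor: canonical atom-environment strings.

An atom signature of height *h* is a canonical string encoding the atom's
bonded neighborhood out to *h* bonds: a breadth-first expansion tree in
which an edge is never traversed straight back toward its immediate parent
(ring atoms may therefore reappear on different branches). Each node is
rendered ``[El]`` with a bond-order prefix on the edge that reaches it
("" single, ``=`` double, ``#`` triple), children are sorted
lexicographically by their fully rendered subtree strings, and child lists
are wrapped in ``(...)``. Two isomorphic rooted environments therefore
yield byte-identical text.

A molecule's feature vector is the multiset of its atom signatures over a
height range (1-3 by default), encoded as raw occurrence counts.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .molecules import MoleculeGraph

#: Bond-order prefixes; ``%`` is reserved for unkekulizable bonds should a
#: reader ever emit order 4 (the bundled readers downgrade those to single).
BOND_PREFIX = {1: "", 2: "=", 3: "#", 4: "%"}

DEFAULT_H_MIN = 1
DEFAULT_H_MAX = 3


@dataclass(frozen=True)
class AtomSignature:
    text: str
    height: int


@dataclass
class SignatureVector:
    """Sparse map from signature text to positive occurrence count."""

    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())


def _render(adj, elements, node: int, parent: int, depth: int, memo: dict) -> str:
    """Render the expansion subtree rooted at ``node`` reached from ``parent``."""
    key = (node, parent, depth)
    cached = memo.get(key)
    if cached is not None:
        return cached
    label = f"[{elements[node]}]"
    if depth > 0:
        parts = [
            BOND_PREFIX[order] + _render(adj, elements, nbr, node, depth - 1, memo)
            for nbr, order in adj[node]
            if nbr != parent
        ]
        if parts:
            parts.sort()
            label = f"{label}({''.join(parts)})"
    memo[key] = label
    return label


def atom_signature(graph: MoleculeGraph, root: int, height: int) -> AtomSignature:
    """Canonical signature of ``root``'s environment out to ``height`` bonds."""
    if not 0 <= root < graph.n_atoms:
        raise IndexError(f"root atom {root} out of range for {graph.id}")
    if height < 0:
        raise ValueError("height must be >= 0")
    adj = graph.adjacency()
    elements = [a.element for a in graph.atoms]
    text = _render(adj, elements, root, -1, height, {})
    return AtomSignature(text=text, height=height)


def molecule_signature_counts(graph: MoleculeGraph,
                              h_min: int = DEFAULT_H_MIN,
                              h_max: int = DEFAULT_H_MAX) -> SignatureVector:
    """Counts of all atom signatures of ``graph`` for heights in [h_min, h_max].

    Each atom contributes exactly one signature per height; signatures from
    different heights that render identically (small molecules) merge.
    """
    if not 0 <= h_min <= h_max:
        raise ValueError(f"invalid height range [{h_min}, {h_max}]")
    adj = graph.adjacency()
    elements = [a.element for a in graph.atoms]
    memo: dict = {}
    counts: Counter = Counter()
    for h in range(h_min, h_max + 1):
        for root in range(graph.n_atoms):
            counts[_render(adj, elements, root, -1, h, memo)] += 1
    return SignatureVector(counts=dict(counts))


@dataclass
class SignatureVocabulary:
    """First-seen-order mapping of signature text to a feature column.

    Once frozen, unseen signatures are dropped (tallied on ``n_dropped``)
    instead of growing the feature space — used when scoring molecules
    against a model trained on a fixed vocabulary.
    """

    index: dict[str, int] = field(default_factory=dict)
    frozen: bool = False
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.index)

    def add(self, text: str) -> int | None:
        col = self.index.get(text)
        if col is not None:
            return col
        if self.frozen:
            self.n_dropped += 1
            return None
        col = len(self.index)
        self.index[text] = col
        return col

    def freeze(self) -> "SignatureVocabulary":
        self.frozen = True
        return self

    def texts(self) -> list[str]:
        """Signature strings in column order."""
        return sorted(self.index, key=self.index.__getitem__)


def build_vocabulary(library: Iterable[MoleculeGraph],
                     h_min: int = DEFAULT_H_MIN,
                     h_max: int = DEFAULT_H_MAX) -> SignatureVocabulary:
    """One pass over the library; first-seen order assigns columns."""
    vocab = SignatureVocabulary()
    for graph in library:
        for text in molecule_signature_counts(graph, h_min, h_max).counts:
            vocab.add(text)
    return vocab


def vectorize(sig: SignatureVector, vocab: SignatureVocabulary) -> sparse.csr_matrix:
    """Encode one SignatureVector as a 1 x |vocab| sparse count row."""
    cols, vals = [], []
    for text, count in sig.counts.items():
        col = vocab.add(text)
        if col is not None:
            cols.append(col)
            vals.append(count)
    return sparse.csr_matrix(
        (np.asarray(vals, dtype=float), (np.zeros(len(cols), dtype=int), cols)),
        shape=(1, len(vocab)))


def signature_matrix(graphs: Iterable[MoleculeGraph],
                     vocab: SignatureVocabulary,
                     h_min: int = DEFAULT_H_MIN,
                     h_max: int = DEFAULT_H_MAX) -> sparse.csr_matrix:
    """Stack signature count rows for many molecules into one CSR matrix."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    n_rows = 0
    for graph in graphs:
        sig = molecule_signature_counts(graph, h_min, h_max)
        for text, count in sig.counts.items():
            col = vocab.add(text)
            if col is not None:
                indices.append(col)
                data.append(float(count))
        indptr.append(len(indices))
        n_rows += 1
    mat = sparse.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int64)),
        shape=(n_rows, len(vocab)))
    mat.sum_duplicates()
    return mat


# ---------------------------------------------------------------------------
# Plain-text export
# ---------------------------------------------------------------------------

def write_triplets_csv(ids: Iterable[str],
                       vectors: Iterable[SignatureVector],
                       path: str | Path) -> None:
    """Export features as (row_id, signature_text, count) triplets."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row_id", "signature_text", "count"])
        for mol_id, vec in zip(ids, vectors):
            for text, count in vec.counts.items():
                writer.writerow([mol_id, text, count])


def write_vocabulary_tsv(vocab: SignatureVocabulary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tsignature_text\n")
        for text in vocab.texts():
            fh.write(f"{vocab.index[text]}\t{text}\n")
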