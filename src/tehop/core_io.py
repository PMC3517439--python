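"""Domain types and I/O for the TE horizontal-transfer pipeline.

Sequences are plain nucleotide strings over ``{A, C, G, T, N, -}``;
alignments are equal-length gapped sequences. Trees are handled through
:mod:`dendropy`, with bootstrap supports stored as internal-node labels
(the MEGA convention). A :class:`SpeciesTree` adds node ages in MYA on
top of an ultrametric dendropy tree.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
BASES = "ACGT"

__all__ = [
    "Sequence",
    "Alignment",
    "DistanceMatrix",
    "SpeciesTree",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_newick",
    "read_newick",
    "tree_bipartitions",
]


class DuplicateIdError(ValueError):
    """Two FASTA records share an id."""


@dataclass
class Sequence:
    """A named nucleotide string over ``{A, C, G, T, N, -}``.

    ``id`` must contain no whitespace (it is the FASTA header token);
    ``residues`` must be non-empty before entering any computation.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token without whitespace: {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count("-")

    def ungapped(self) -> "Sequence":
        return Sequence(self.id, self.residues.replace("-", ""))

    def as_array(self) -> np.ndarray:
        """Residues as a 1-D array of single-byte strings (fast column ops)."""
        return np.frombuffer(self.residues.encode("ascii"), dtype="S1")


def normalize_residues(raw: str, *, source: str = "") -> str:
    """Uppercase, map U->T, and map anything outside the alphabet to N.

    Out-of-alphabet characters are replaced with ``N`` and counted in a
    single logged warning, so dirty downloads do not abort a run.
    """
    up = raw.upper().replace("U", "T")
    if set(up) <= ALPHABET:
        return up
    cleaned = []
    n_bad = 0
    for c in up:
        if c in ALPHABET:
            cleaned.append(c)
        else:
            cleaned.append("N")
            n_bad += 1
    logger.warning("mapped %d non-nucleotide character(s) to N%s", n_bad, f" in {source}" if source else "")
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (possibly gapped) FASTA file into a list of :class:`Sequence`.

    Residues are uppercased, U is mapped to T, and characters outside
    the alphabet are mapped to N with a logged warning. An empty file
    yields an empty list; duplicate ids raise :class:`DuplicateIdError`.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id: {rec.id}")
        seen.add(rec.id)
        seqs.append(Sequence(rec.id, normalize_residues(str(rec.seq), source=rec.id)))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, *, width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


@dataclass
class Alignment:
    """Equal-length gapped sequences; at least two members."""

    members: list[Sequence]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("alignment needs >=2 sequences")
        L = len(self.members[0].residues)
        for s in self.members:
            if len(s.residues) != L:
                raise ValueError(f"ragged alignment: sequence {s.id!r} has length {len(s.residues)}, expected {L}")
        if L == 0:
            raise ValueError("alignment has zero columns")

    @property
    def length(self) -> int:
        return len(self.members[0].residues)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def ids(self) -> list[str]:
        return [s.id for s in self.members]

    def get(self, seq_id: str) -> Sequence:
        for s in self.members:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def as_array(self) -> np.ndarray:
        """(n_members, length) array of single-byte strings."""
        return np.vstack([s.as_array() for s in self.members])

    def take_columns(self, idx: np.ndarray) -> "Alignment":
        """New alignment from the given column indices (bootstrap resampling)."""
        arr = self.as_array()[:, idx]
        return Alignment(
            [Sequence(s.id, arr[i].tobytes().decode("ascii")) for i, s in enumerate(self.members)]
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped FASTA as an :class:`Alignment`, verifying equal lengths."""
    return Alignment(read_fasta(path))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site).

    Missing entries (saturated or incomparable pairs) are NaN; ``missing``
    lists the offending label pairs.
    """

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def missing(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree as Newick with supports as internal-node labels.

    Branch lengths are written as ``:<float>`` with full precision so a
    read/write round-trip preserves them to well below 1e-6.
    """
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_leaf_node_labels=False,
        suppress_internal_node_labels=False,
        real_value_format_specifier="",
    )
    return text.strip() + "\n"


def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse Newick text (or a file path) into a dendropy tree.

    Internal-node labels are kept as labels (bootstrap supports in the
    MEGA convention), not converted to edge supports.
    """
    p = Path(str(text_or_path))
    if "(" not in str(text_or_path) and p.exists():
        data = p.read_text()
    else:
        data = str(text_or_path)
    return dendropy.Tree.get(
        data=data,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of leaf labels, orientation-free.

    Each bipartition is the two-element set ``{side, complement}`` of
    leaf-label frozensets, so rooting and edge orientation do not matter.
    """
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) > 1 and len(other) > 1:
            out.add(frozenset((side, other)))
    return out


@dataclass
class SpeciesTree:
    """An ultrametric species tree with node ages in MYA.

    Ages are reconstructed from branch lengths (interpreted as MY): every
    leaf sits at age 0 and each parent is older than its children. The
    tree must be ultrametric to within ``tol`` MY.
    """

    tree: dendropy.Tree
    ages: dict = field(default_factory=dict)
    tol: float = 1e-6

    def __post_init__(self) -> None:
        self.tree.is_rooted = True  # an aged species tree is rooted by definition
        self.ages = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self.ages[node] = 0.0
            else:
                candidate_ages = []
                for ch in node.child_nodes():
                    bl = ch.edge.length if ch.edge.length is not None else 0.0
                    candidate_ages.append(self.ages[ch] + bl)
                age = max(candidate_ages)
                if max(candidate_ages) - min(candidate_ages) > max(self.tol, 1e-9 * age):
                    raise ValueError(f"species tree is not ultrametric at node {node}")
                if age <= 0:
                    raise ValueError("internal node age must exceed child ages")
                self.ages[node] = age

    @classmethod
    def from_newick(cls, text_or_path: str | Path, tol: float = 1e-6) -> "SpeciesTree":
        return cls(read_newick(text_or_path), tol=tol)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def _leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise KeyError(f"unknown leaf label: {label}")

    def mrca(self, labels: TypingSequence[str]) -> dendropy.Node:
        nodes = {self._leaf(l) for l in labels}
        if len(nodes) == 1:
            return next(iter(nodes))
        taxa = [n.taxon for n in nodes]
        return self.tree.mrca(taxa=taxa)

    def split_age(self, a: str, b: str) -> float:
        """Age (MYA) of the most recent common ancestor of two species."""
        if a == b:
            return 0.0
        return self.ages[self.mrca([a, b])]
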