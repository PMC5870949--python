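"""Sequence, alignment, and tree I/O with validation.

All coordinates are 1-based alignment columns throughout the package
(protein residue numbering such as I1660 is 1-based). Foreground branches
in Newick input are flagged with the ``#1`` label convention used by branch
codon models: either an internal-node label ``#1`` or a ``#1`` suffix on a
leaf name marks the subtending branch as foreground.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# 20 canonical amino acids + ambiguity 'X' + gap
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X", "-", "*"}
NUCLEOTIDES = set("ACGT")
NUC_ALPHABET = NUCLEOTIDES | {"N", "-"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: the 61 sense codons of the standard genetic code, in fixed lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD_TABLE.forward_table))
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}


class Role(str, Enum):
    """Role of a record in a duplication trio."""

    OUTGROUP = "outgroup"
    PARALOG1 = "paralog1"
    PARALOG2 = "paralog2"
    OTHER = "other"


class AlignmentError(ValueError):
    """Raised for ragged alignments or length violations."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass
class ProteinAlignment:
    """An aligned set of protein sequences.

    records are (id, role, sequence) triples; sequences use the 20 amino
    acids, 'X' for unknown, and '-' for gaps, all of equal length ``L``.
    """

    records: list[tuple[str, Role, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)} differ"
            )
        if lengths == {0}:
            raise AlignmentError("alignment length must be >= 1")
        for rec_id, _, seq in self.records:
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {rec_id!r}: illegal protein characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns L."""
        return len(self.records[0][2])

    @property
    def ids(self) -> list[str]:
        return [rec_id for rec_id, _, _ in self.records]

    def by_role(self, role: Role | str) -> tuple[str, str]:
        """Return (id, sequence) of the unique record with the given role."""
        role = Role(role)
        hits = [(rid, seq) for rid, r, seq in self.records if r is role]
        if len(hits) != 1:
            raise ValueError(f"expected exactly one record with role {role.value}, "
                             f"found {len(hits)}")
        return hits[0]

    def with_roles(self, role_map: dict[str, Role | str]) -> "ProteinAlignment":
        """Return a copy with roles assigned from an id -> role mapping."""
        new = []
        for rec_id, role, seq in self.records:
            if rec_id in role_map:
                role = Role(role_map[rec_id])
            new.append((rec_id, role, seq))
        return ProteinAlignment(new)


@dataclass
class CodonAlignment:
    """An aligned set of in-frame coding sequences.

    Sequences are DNA whose length is divisible by 3, with no internal stop
    codons; gaps occur as whole ``---`` triplets. ``S`` is the number of
    codon columns.
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)} differ"
            )
        (length,) = lengths
        if length == 0 or length % 3 != 0:
            raise AlignmentError(
                f"codon alignment length {length} is not a positive multiple of 3"
            )
        for rec_id, seq in self.records:
            bad = set(seq) - NUC_ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {rec_id!r}: illegal nucleotide characters {sorted(bad)}"
                )
            for col in range(length // 3):
                codon = seq[3 * col : 3 * col + 3]
                if codon in STOP_CODONS:
                    raise AlignmentError(
                        f"record {rec_id!r}: internal stop codon {codon} "
                        f"at codon column {col + 1}"
                    )

    @property
    def n_codons(self) -> int:
        """Number of codon columns S."""
        return len(self.records[0][1]) // 3

    @property
    def ids(self) -> list[str]:
        return [rec_id for rec_id, _ in self.records]

    def codon(self, record: int, col: int) -> str:
        """Codon at 1-based codon column ``col`` of record index ``record``."""
        seq = self.records[record][1]
        return seq[3 * (col - 1) : 3 * (col - 1) + 3]


@dataclass
class LabeledTree:
    """A phylogeny with branch lengths and per-branch foreground flags.

    Wraps a dendropy tree; every edge carries a ``foreground`` annotation.
    Branch lengths are expected substitutions per codon.
    """

    tree: dendropy.Tree
    default_branch_length: float = 0.1

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label
            if name in seen:
                raise ValueError(f"duplicate leaf name {name!r}")
            seen.add(name)
        for edge in self.tree.preorder_edge_iter():
            if not hasattr(edge, "foreground"):
                edge.foreground = False
            if edge.head_node is not self.tree.seed_node and edge.length is None:
                warnings.warn(
                    "branch without length; defaulting to "
                    f"{self.default_branch_length}",
                    stacklevel=2,
                )
                edge.length = self.default_branch_length
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_foreground(self) -> int:
        return sum(
            1
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node and e.foreground
        )

    @property
    def n_branches(self) -> int:
        return sum(
            1 for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        )

    def validate_for_two_ratio(self) -> None:
        nf = self.n_foreground
        if nf == 0:
            raise ValueError("two-ratio model requires >= 1 foreground branch "
                             "(mark with '#1' in Newick)")
        if nf == self.n_branches:
            raise ValueError("two-ratio model requires >= 1 background branch")


def _looks_like_nucleotide(seqs: Iterable[str]) -> bool:
    chars = set("".join(seqs).upper()) - {"-"}
    return bool(chars) and chars <= (NUCLEOTIDES | {"N", "U"})


def read_fasta(
    path: str | Path, alphabet: str = "auto"
) -> ProteinAlignment | CodonAlignment:
    """Read an aligned FASTA file.

    Parameters
    ----------
    path:
        FASTA file of equal-length sequences.
    alphabet:
        ``"protein"``, ``"codon"``, or ``"auto"`` (codon if every character
        is a nucleotide code).

    Role assignment is deferred to the caller: all protein records start
    with role ``other``; use :meth:`ProteinAlignment.with_roles`.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    if alphabet == "auto":
        alphabet = "codon" if _looks_like_nucleotide(s for _, s in records) else "protein"
    if alphabet == "codon":
        return CodonAlignment(records)
    if alphabet == "protein":
        return ProteinAlignment([(rid, Role.OTHER, seq) for rid, seq in records])
    raise ValueError(f"unknown alphabet {alphabet!r}")


def write_fasta(
    alignment: ProteinAlignment | CodonAlignment, path: str | Path
) -> None:
    """Write an alignment to FASTA (sequence per record, file order kept)."""
    if isinstance(alignment, ProteinAlignment):
        recs = [
            SeqRecord(Seq(seq), id=rid, description="")
            for rid, _, seq in alignment.records
        ]
    else:
        recs = [
            SeqRecord(Seq(seq), id=rid, description="")
            for rid, seq in alignment.records
        ]
    SeqIO.write(recs, str(path), "fasta")


def translate_codons(alignment: CodonAlignment) -> ProteinAlignment:
    """Translate a codon alignment with the standard genetic code.

    Gap triplets become '-'; codons containing 'N' or a partial gap become
    'X'. An internal stop raises, naming the record and codon column.
    """
    out = []
    for rec_id, seq in alignment.records:
        aas = []
        for col in range(len(seq) // 3):
            codon = seq[3 * col : 3 * col + 3]
            if codon == "---":
                aas.append("-")
            elif codon in STOP_CODONS:
                raise AlignmentError(
                    f"record {rec_id!r}: stop codon {codon} at codon column {col + 1}"
                )
            elif codon in CODON_INDEX:
                aas.append(_STANDARD_TABLE.forward_table[codon])
            else:
                aas.append("X")
        out.append((rec_id, Role.OTHER, "".join(aas)))
    return ProteinAlignment(out)


def _mark_foreground(tree: dendropy.Tree) -> None:
    """Resolve '#1' labels into edge.foreground flags and strip them."""
    for node in tree.preorder_node_iter():
        node.edge.foreground = False
        if node.label is not None and node.label.strip() == "#1":
            node.edge.foreground = True
            node.label = None
        if node.taxon is not None and node.taxon.label.endswith("#1"):
            node.edge.foreground = True
            node.taxon.label = node.taxon.label[:-2].rstrip()
    # the seed-node "edge" is not a branch
    tree.seed_node.edge.foreground = False


def read_newick(path_or_string: str | Path, default_branch_length: float = 0.1
                ) -> LabeledTree:
    """Read a Newick tree, resolving '#1' foreground branch labels.

    Accepts either a path to a file or a Newick string (detected by the
    presence of '(' ). Missing branch lengths default to
    ``default_branch_length`` with a warning.
    """
    text = str(path_or_string)
    if "(" not in text:
        text = Path(path_or_string).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific parse errors
        raise ValueError(f"invalid Newick ({exc})") from exc
    _mark_foreground(tree)
    return LabeledTree(tree, default_branch_length=default_branch_length)


def write_newick(labeled: LabeledTree, path: str | Path) -> None:
    """Write a tree to Newick, re-emitting '#1' foreground labels."""
    tree = labeled.tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if getattr(node.edge, "foreground", False):
            if node.is_leaf():
                node.taxon.label = node.taxon.label + "#1"
            else:
                node.label = "#1"
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    )


def check_tree_alignment(labeled: LabeledTree,
                         alignment: ProteinAlignment | CodonAlignment) -> None:
    """Raise if tree leaves and alignment ids are not the same set."""
    leaves = set(labeled.leaf_names)
    ids = set(alignment.ids)
    if leaves != ids:
        raise ValueError(
            f"tree/alignment mismatch: only in tree {sorted(leaves - ids)}, "
            f"only in alignment {sorted(ids - leaves)}"
        )
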