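"""Reading and writing the two input formats: aligned FASTA and newick trees.

The alignment container is a thin immutable wrapper around a list of
equal-length rows; trees are dendropy trees wrapped together with a
"compiled" flat edge list that the simulator traverses cheaply.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import IO, Union

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"
#: gap glyphs normalized to '-' on read (alignment databases vary)
_ALT_GAPS = str.maketrans({".": "-", "*": "-"})


class MsaFormatError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


class TreeFormatError(ValueError):
    """Raised for malformed newick input or invalid branch lengths."""


@dataclass(frozen=True)
class MSA:
    """A rectangular multiple sequence alignment.

    ``rows`` are uppercase strings over residue characters plus ``'-'``;
    all rows have the same length and no row may be entirely gaps.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise MsaFormatError("names and rows differ in count")
        if len(self.rows) < 2:
            raise MsaFormatError("an alignment needs at least 2 sequences")
        ncol = len(self.rows[0])
        if ncol < 1:
            raise MsaFormatError("alignment has zero columns")
        for name, row in zip(self.names, self.rows):
            if len(row) != ncol:
                raise MsaFormatError(
                    f"input is not aligned: sequence {name!r} has length "
                    f"{len(row)}, expected {ncol}"
                )
        if any(set(row) <= {GAP} for row in self.rows):
            raise MsaFormatError("a row consists entirely of gap characters")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])


def read_msa(source: Union[str, IO[str]]) -> MSA:
    """Parse an aligned FASTA stream (or path) into an :class:`MSA`.

    Rows are uppercased and the gap glyphs ``'.'`` and ``'*'`` are
    normalized to ``'-'``. Unequal row lengths raise
    :class:`MsaFormatError` ("not aligned").
    """
    handle, close = _as_text_handle(source)
    try:
        names: list[str] = []
        rows: list[str] = []
        for rec in SeqIO.parse(handle, "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq).upper().translate(_ALT_GAPS))
    finally:
        if close:
            handle.close()
    if not names:
        raise MsaFormatError("no FASTA records found in input")
    if len(names) < 2:
        raise MsaFormatError("an alignment needs at least 2 sequences")
    return MSA(tuple(names), tuple(rows))


def write_msa(msa: MSA, sink: Union[str, IO[str]]) -> None:
    """Write an alignment as FASTA; ``read_msa`` round-trips it exactly."""
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(msa.names, msa.rows)
    ]
    if hasattr(sink, "write"):
        SeqIO.write(records, sink, "fasta")
    else:
        with open(sink, "w") as fh:
            SeqIO.write(records, fh, "fasta")


@dataclass(frozen=True)
class CompiledTree:
    """Flat, array-backed view of a phylogeny for fast repeated traversal.

    Edges are listed in a fixed preorder; index 0 is the root node, which
    has no incoming edge. ``parent[i]`` is the node index of the parent of
    node ``i`` (−1 for the root) and ``length[i]`` its incoming branch
    length in expected substitutions per site.
    """

    parent: np.ndarray  # int, shape (n_nodes,)
    length: np.ndarray  # float, shape (n_nodes,)
    leaf_indices: np.ndarray  # node indices that are leaves, preorder
    leaf_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_leaves(self) -> int:
        return self.leaf_indices.shape[0]


class PhyloTree:
    """A phylogeny with branch lengths, backed by a dendropy tree.

    The tree may be rooted or unrooted; an unrooted newick string is
    anchored at the (possibly multifurcating) internal node dendropy
    places at the top, which is recorded in the log. Only topology and
    branch lengths matter downstream.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self._compiled: CompiledTree | None = None
        self._validate()

    def _validate(self) -> None:
        leaves = [lf for lf in self._dtree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeFormatError("tree needs at least 2 leaves")
        labels = [lf.taxon.label if lf.taxon else None for lf in leaves]
        if any(lab is None for lab in labels):
            raise TreeFormatError("tree has unlabeled leaves")
        if len(set(labels)) != len(labels):
            raise TreeFormatError("leaf labels are not unique")
        root = self._dtree.seed_node
        for node in self._dtree.preorder_node_iter():
            bl = node.edge.length
            if node is root:
                continue
            if bl is None:
                raise TreeFormatError(
                    "branch without a length (only the root edge may omit one)"
                )
            if not math.isfinite(bl) or bl < 0:
                raise TreeFormatError(f"invalid branch length {bl!r}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self._dtree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        return sum(
            e.length for e in self._dtree.preorder_edge_iter() if e.length
        )

    def compile(self) -> CompiledTree:
        """Flatten to preorder arrays (cached)."""
        if self._compiled is None:
            parent: list[int] = []
            length: list[float] = []
            leaf_idx: list[int] = []
            leaf_labels: list[str] = []
            index: dict[int, int] = {}
            for node in self._dtree.preorder_node_iter():
                i = len(parent)
                index[id(node)] = i
                if node.parent_node is None:
                    parent.append(-1)
                    length.append(0.0)
                else:
                    parent.append(index[id(node.parent_node)])
                    length.append(float(node.edge.length))
                if node.is_leaf():
                    leaf_idx.append(i)
                    leaf_labels.append(node.taxon.label)
            self._compiled = CompiledTree(
                parent=np.asarray(parent, dtype=np.int64),
                length=np.asarray(length, dtype=np.float64),
                leaf_indices=np.asarray(leaf_idx, dtype=np.int64),
                leaf_labels=tuple(leaf_labels),
            )
        return self._compiled

    def as_newick(self) -> str:
        return self._dtree.as_string(schema="newick").strip()


def read_tree(source: Union[str, IO[str]]) -> PhyloTree:
    """Parse a newick stream (or path, or literal newick string).

    Branch lengths are required on every edge except the root edge and
    must be finite and non-negative.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        handle, close = _as_text_handle(source)
        try:
            text = handle.read()
        finally:
            if close:
                handle.close()
    if not text.strip():
        raise TreeFormatError("empty tree input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeFormatError(f"malformed newick: {exc}") from exc
    tree = PhyloTree(dtree)
    if not dtree.is_rooted:
        logger.info(
            "input tree is unrooted; anchoring simulation at dendropy's "
            "seed node (this does not affect the inference)"
        )
    return tree


def check_taxa_match(msa: MSA, tree: PhyloTree) -> bool:
    """Warn (do not fail) when MSA names and tree leaf labels differ.

    Inference only uses the tree's topology and branch lengths, so a
    mismatch is tolerated; it usually indicates the user swapped files.
    """
    msa_names = set(msa.names)
    tree_names = set(tree.leaf_labels)
    if msa_names != tree_names:
        logger.warning(
            "MSA names and tree leaf labels differ (%d names only in MSA, "
            "%d only in tree); proceeding — only the tree's branch lengths "
            "and topology are used",
            len(msa_names - tree_names),
            len(tree_names - msa_names),
        )
        return False
    return True


def _as_text_handle(source: Union[str, IO[str]]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    if isinstance(source, str) and (
        not source or "\n" in source or source.startswith(">")
    ):
        return io.StringIO(source), True
    return open(source), True
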