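"""Alignment and tree input/output plus clade resolution.

Alignments are stored as integer-coded taxa x columns matrices (see
:mod:`biasdiag.alphabet`); trees wrap :class:`dendropy.Tree` and expose
stable node identifiers so that downstream reports are reproducible
across runs.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import MISSING, decode_row, encode_sequence
from .errors import FormatError, TreeError

logger = logging.getLogger(__name__)

_BIO_FORMAT = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


@dataclass
class Alignment:
    """A taxa x columns amino-acid matrix with MISSING cells."""

    taxon_labels: list[str]
    matrix: np.ndarray  # uint8, codes 0..19 plus MISSING (=20)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be two-dimensional")
        if len(self.taxon_labels) != self.matrix.shape[0]:
            raise FormatError("label count does not match matrix rows")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            dupes = sorted(
                {t for t in self.taxon_labels if self.taxon_labels.count(t) > 1}
            )
            raise FormatError(f"duplicate taxon labels: {dupes}")
        if any(not t for t in self.taxon_labels):
            raise FormatError("empty taxon label")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean taxa x columns mask, True where the cell is MISSING."""
        return self.matrix == MISSING

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.taxon_labels.index(label)]

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """New alignment restricted to the given 0-based columns."""
        return Alignment(list(self.taxon_labels), self.matrix[:, list(columns)])

    def row_string(self, label: str, missing_char: str = "-") -> str:
        return decode_row(self.row(label), missing_char)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.taxon_labels == other.taxon_labels and np.array_equal(
            self.matrix, other.matrix
        )


@dataclass(frozen=True)
class CladeSpec:
    """A named focal clade given by its tip set."""

    name: str
    tips: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tips:
            raise TreeError("clade spec requires a non-empty tip set")


@dataclass(frozen=True)
class CladeResolution:
    node_id: str
    monophyletic: bool
    warning: str | None = None


def _tipset_hash(labels: Iterable[str]) -> str:
    joined = ",".join(sorted(labels)).encode()
    return hashlib.sha1(joined).hexdigest()[:8]


class RootedTree:
    """Labelled tree with stable node ids and MRCA queries.

    Internal node ids combine the preorder index with a hash of the
    subtended tip set; tips are identified by their label.  A tree whose
    root has exactly two children is treated as rooted; a basal
    polytomy is kept as read but rejected by operations that require a
    root (use :func:`root_with_outgroup`).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        # node-based semantics: the seed node is the root even when the
        # newick carried no [&R] flag (a basal polytomy still signals an
        # unrooted topology via `is_rooted` below)
        self._tree.is_rooted = True
        self._reindex()

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise FormatError(f"unreadable Newick: {exc}") from exc
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise FormatError(f"duplicate tip labels: {dupes}")
        return cls(tree)

    def clone(self) -> "RootedTree":
        return RootedTree(self._tree.clone(depth=1))

    def _reindex(self) -> None:
        self._nodes = list(self._tree.preorder_node_iter())
        self._id_of: dict[int, str] = {}
        self._node_of: dict[str, dendropy.Node] = {}
        for idx, node in enumerate(self._nodes):
            if node.is_leaf():
                nid = node.taxon.label
            else:
                tips = [lf.taxon.label for lf in node.leaf_iter()]
                nid = f"N{idx}_{_tipset_hash(tips)}"
            self._id_of[id(node)] = nid
            self._node_of[nid] = node

    # -- basic queries ------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [n.taxon.label for n in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def is_rooted(self) -> bool:
        return len(self._tree.seed_node.child_nodes()) == 2

    @property
    def root_id(self) -> str:
        return self._id_of[id(self._tree.seed_node)]

    def node_ids(self, internal_only: bool = False) -> list[str]:
        return [
            self._id_of[id(n)]
            for n in self._nodes
            if not (internal_only and n.is_leaf())
        ]

    def node(self, node_id: str) -> dendropy.Node:
        try:
            return self._node_of[node_id]
        except KeyError:
            raise TreeError(f"unknown node id {node_id!r}") from None

    def node_id(self, node: dendropy.Node) -> str:
        return self._id_of[id(node)]

    def parent_id(self, node_id: str) -> str | None:
        parent = self.node(node_id).parent_node
        return None if parent is None else self._id_of[id(parent)]

    def children_ids(self, node_id: str) -> list[str]:
        return [self._id_of[id(c)] for c in self.node(node_id).child_nodes()]

    def tips_below(self, node_id: str) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in self.node(node_id).leaf_iter())

    def support_of(self, node_id: str) -> str | None:
        """Internal-node label as read from the Newick (e.g. support value)."""
        return self.node(node_id).label

    def branch_length(self, node_id: str) -> float | None:
        return self.node(node_id).edge.length

    def postorder_ids(self) -> list[str]:
        return [self._id_of[id(n)] for n in self._tree.postorder_node_iter()]

    def mrca_id(self, tips: Iterable[str]) -> str:
        tips = set(tips)
        unknown = tips - set(self.tip_labels)
        if unknown:
            raise TreeError(f"unknown tip labels: {sorted(unknown)}")
        if len(tips) == 1:
            return next(iter(tips))
        taxa = [
            t for t in self._tree.taxon_namespace if t.label in tips
        ]
        node = self._tree.mrca(taxa=taxa)
        return self._id_of[id(node)]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each as its smaller-or-canonical side."""
        all_tips = frozenset(self.tip_labels)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_internal_node_iter():
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(below) < len(all_tips) - 1:
                other = all_tips - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return out

    def as_newick(self, **kwargs) -> str:
        defaults = dict(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        )
        defaults.update(kwargs)
        return self._tree.as_string(**defaults)

    def __len__(self) -> int:
        return len(self._nodes)


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

def _alignment_from_bio(bio_aln: MultipleSeqAlignment) -> Alignment:
    labels = [rec.id for rec in bio_aln]
    rows = []
    for rec in bio_aln:
        rows.append(encode_sequence(str(rec.seq), where=f"sequence {rec.id!r}"))
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise FormatError("ragged alignment: rows differ in length")
    return Alignment(labels, np.vstack(rows))


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment, normalizing symbols (see :mod:`biasdiag.alphabet`)."""
    if format not in _BIO_FORMAT:
        raise FormatError(f"unsupported alignment format {format!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty alignment file: {path}")
    if format == "fasta":
        # parse records by hand so ragged inputs give a clear error
        records = _parse_fasta(text)
        labels = [name for name, _ in records]
        rows = [encode_sequence(seq, where=f"sequence {name!r}") for name, seq in records]
        lengths = {r.size for r in rows}
        if len(lengths) > 1:
            raise FormatError("ragged alignment: rows differ in length")
        return Alignment(labels, np.vstack(rows))
    try:
        bio_aln = AlignIO.read(io.StringIO(text), _BIO_FORMAT[format])
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return _alignment_from_bio(bio_aln)


def _parse_fasta(text: str) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].strip() else ""
            records.append((name, []))
        else:
            if not records:
                raise FormatError("sequence data before first FASTA header")
            records[-1][1].append(line)
    if not records:
        raise FormatError("no FASTA records found")
    return [(name, "".join(chunks)) for name, chunks in records]


def write_alignment(
    aln: Alignment, path: str | Path, format: str = "fasta", missing_char: str = "-"
) -> None:
    """Write an alignment (FASTA, relaxed PHYLIP, or NEXUS)."""
    if format not in _BIO_FORMAT:
        raise FormatError(f"unsupported alignment format {format!r}")
    records = [
        SeqRecord(
            Seq(decode_row(aln.matrix[i], missing_char)),
            id=label,
            description="",
            annotations={"molecule_type": "protein"},
        )
        for i, label in enumerate(aln.taxon_labels)
    ]
    bio_aln = MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write(bio_aln, fh, _BIO_FORMAT[format])


# ---------------------------------------------------------------------------
# tree I/O and rooting
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> RootedTree:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"empty tree file: {path}")
    return RootedTree.from_newick(text)


def write_tree(tree: RootedTree, path: str | Path, **kwargs) -> None:
    Path(path).write_text(tree.as_newick(**kwargs))


def root_with_outgroup(tree: RootedTree, outgroup: Iterable[str]) -> RootedTree:
    """Root on the branch separating ``outgroup`` from the remaining tips."""
    og = frozenset(outgroup)
    tips = frozenset(tree.tip_labels)
    if not og:
        raise TreeError("empty outgroup")
    unknown = og - tips
    if unknown:
        raise TreeError(f"outgroup labels not in tree: {sorted(unknown)}")
    if og == tips:
        raise TreeError("outgroup cannot contain all tips")

    work = tree._tree.clone(depth=1)
    target_edge = None
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if below == og or below == tips - og:
            target_edge = node.edge
            break
    if target_edge is None:
        raise TreeError(
            "outgroup is not separable by a single branch (not monophyletic "
            "in the unrooted sense)"
        )
    length = target_edge.length
    if length is None:
        work.reroot_at_edge(target_edge, update_bipartitions=False)
    else:
        work.reroot_at_edge(
            target_edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
    work.suppress_unifurcations()
    return RootedTree(work)


def resolve_clade(tree: RootedTree, spec: CladeSpec) -> CladeResolution:
    """MRCA of the spec's tips plus an exact-monophyly flag."""
    unknown = set(spec.tips) - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"unknown tip labels in clade {spec.name!r}: {sorted(unknown)}")
    node_id = tree.mrca_id(spec.tips)
    mono = tree.tips_below(node_id) == frozenset(spec.tips)
    warning = None
    if node_id == tree.root_id:
        warning = (
            "MRCA is the root: no stem branch exists, stem-branch analyses "
            "are impossible for this clade"
        )
        logger.warning("%s (clade %r)", warning, spec.name)
    return CladeResolution(node_id=node_id, monophyletic=mono, warning=warning)
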