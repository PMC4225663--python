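"""Missing-data structure analytics for concatenated supermatrices.

Covers coverage accounting, the >=50% taxon-coverage position filter,
the gene admission rule (>=100 columns and >=25 taxa), shared-missing
overlap clustering, and binary presence/absence parsimony mapping of
missingness onto a tree (ACCTRAN, losses pulled rootward).

A cell is MISSING iff its normalized symbol is MISSING; indel gaps and
unsequenced genes are not distinguished (the concatenated input cannot
tell them apart).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import AnalysisError, TreeError
from .parsimony_mapping import acctran_reconstruct
from .seqtree_io import Alignment, RootedTree

logger = logging.getLogger(__name__)


@dataclass
class CoverageStats:
    per_taxon_missing: dict[str, float]  # fraction in [0, 1]
    per_column_present: np.ndarray  # non-MISSING count per column
    overall_coverage: float  # percentage of non-MISSING cells


@dataclass
class OverlapMatrix:
    labels: list[str]
    o: np.ndarray  # o(i,j) = fraction of columns MISSING in both i and j

    def off_diagonal(self) -> np.ndarray:
        return squareform(self.o - np.diag(np.diag(self.o)), checks=False)


@dataclass
class OverlapClustering:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[int]  # heat-map ordering (same on both axes)

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


@dataclass
class BranchMissingness:
    per_node_missing_pct: dict[str, float]
    tree: RootedTree

    def annotated_newick(self) -> str:
        """Newick with per-node missing percentages as node comments."""
        work = self.tree.clone()
        for nid, pct in self.per_node_missing_pct.items():
            node = work.node(nid)
            node.annotations.add_new("missing_pct", round(pct, 2))
        return work.as_newick(suppress_annotations=False)


def coverage_stats(alignment: Alignment) -> CoverageStats:
    """Per-taxon missing fractions, per-column presence, overall coverage %."""
    present = ~alignment.missing_mask
    per_col = present.sum(axis=0)
    per_taxon = 1.0 - present.mean(axis=1)
    overall = 100.0 * present.mean()
    return CoverageStats(
        per_taxon_missing=dict(zip(alignment.taxon_labels, per_taxon.tolist())),
        per_column_present=per_col,
        overall_coverage=float(overall),
    )


def position_coverage_filter(
    alignment: Alignment, min_fraction: float = 0.5
) -> tuple[Alignment, np.ndarray]:
    """Keep columns with data for at least ``min_fraction`` of the taxa.

    The threshold is inclusive: a column is kept when its non-MISSING
    count is >= min_fraction * n_taxa.  Returns the filtered alignment
    and the 0-based indices of the retained columns (provenance map).
    """
    if not 0 < min_fraction <= 1:
        raise AnalysisError("min_fraction must be in (0, 1]")
    present = (~alignment.missing_mask).sum(axis=0)
    keep = np.nonzero(present >= min_fraction * alignment.n_taxa)[0]
    if keep.size == 0:
        raise AnalysisError("position filter removed every column")
    return alignment.take_columns(keep.tolist()), keep


@dataclass
class GeneAdmissionReport:
    admitted: list[int]  # indices into the input list
    n_columns: list[int]
    n_taxa_with_data: list[int]


def gene_admission_filter(
    gene_alignments: list[Alignment], min_length: int = 100, min_taxa: int = 25
) -> tuple[list[Alignment], GeneAdmissionReport]:
    """Admit genes that are >= min_length columns and have >= min_taxa taxa
    with at least one observed residue (thresholds inclusive)."""
    admitted: list[Alignment] = []
    idxs: list[int] = []
    ncols: list[int] = []
    ntaxa: list[int] = []
    for i, g in enumerate(gene_alignments):
        taxa_with_data = int(((~g.missing_mask).sum(axis=1) > 0).sum())
        ncols.append(g.n_columns)
        ntaxa.append(taxa_with_data)
        if g.n_columns >= min_length and taxa_with_data >= min_taxa:
            admitted.append(g)
            idxs.append(i)
    return admitted, GeneAdmissionReport(idxs, ncols, ntaxa)


def shared_missing_overlap(alignment: Alignment) -> OverlapMatrix:
    """o(i,j) = fraction of columns MISSING in both taxa i and j.

    The diagonal holds each taxon's own missing fraction.
    """
    miss = alignment.missing_mask.astype(np.float64)
    o = (miss @ miss.T) / alignment.n_columns
    return OverlapMatrix(list(alignment.taxon_labels), o)


def cluster_overlap(o: OverlapMatrix, linkage_method: str = "average") -> OverlapClustering:
    """Hierarchical clustering of taxa on distance 1 - overlap.

    The leaf order of the dendrogram is used to sort the heat map on
    both axes.
    """
    n = len(o.labels)
    if n < 3:
        raise AnalysisError("need at least three taxa to cluster")
    dist = 1.0 - o.o
    np.fill_diagonal(dist, 0.0)
    cond = squareform(dist, checks=False)
    link = hierarchy.linkage(cond, method=linkage_method)
    order = hierarchy.leaves_list(link).tolist()
    return OverlapClustering(list(o.labels), link, order)


def missing_on_tree(alignment: Alignment, tree: RootedTree) -> BranchMissingness:
    """Binary presence/absence parsimony with ACCTRAN on the tree.

    Cells are recoded present(1)/absent(0); ancestral presence is
    reconstructed with the same machinery as the amino-acid mapping but
    on the two-state alphabet, breaking root ties in favour of
    'present' (a state observed anywhere in the tree is assumed present
    at the root unless lost).  Reports per node the percentage of
    columns reconstructed absent.
    """
    if not tree.is_rooted:
        raise TreeError("tree must be rooted; use root_with_outgroup()")
    # state 0 = absent, state 1 = present; prefer 'present' on ties
    binary = (~alignment.missing_mask).astype(np.uint8)
    recon = acctran_reconstruct(
        alignment,
        tree,
        matrix=binary,
        n_states=2,
        state_symbols="01",
        state_preference=[1, 0],
    )
    pct: dict[str, float] = {}
    for nid in tree.node_ids():
        row = recon.raw_states[recon.node_index[nid]]
        pct[nid] = 100.0 * float((row == 0).mean())
    return BranchMissingness(per_node_missing_pct=pct, tree=tree)


def plot_overlap_heatmap(
    o: OverlapMatrix, clustering: OverlapClustering, path: str
) -> None:
    """Heat map of shared missingness ordered by the dendrogram, with a
    density inset over the off-diagonal proportions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clustering.leaf_order
    mat = o.o[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(mat, origin="lower", cmap="YlOrRd")
    labels = clustering.ordered_labels()
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7, label="proportion shared missing")
    inset = fig.add_axes([0.15, 0.78, 0.2, 0.12])
    inset.hist(o.off_diagonal(), bins=30, density=True, color="0.4")
    inset.set_title("density", fontsize=7)
    inset.tick_params(labelsize=5)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_missing_tree(bm: BranchMissingness, path: str) -> None:
    """Simple rectangular tree plot with branches coloured by % missing."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.cm as cm
    import matplotlib.pyplot as plt

    tree = bm.tree
    ys: dict[str, float] = {}
    for i, lab in enumerate(tree.tip_labels):
        ys[lab] = float(i)
    for nid in tree.postorder_ids():
        if nid not in ys:
            kids = tree.children_ids(nid)
            ys[nid] = float(np.mean([ys[k] for k in kids]))
    xs: dict[str, float] = {tree.root_id: 0.0}
    for nid in reversed(tree.postorder_ids()):
        if nid == tree.root_id:
            continue
        parent = tree.parent_id(nid)
        bl = tree.branch_length(nid)
        xs[nid] = xs[parent] + (bl if bl is not None else 1.0)
    norm = plt.Normalize(0, 100)
    cmap = plt.get_cmap("coolwarm")
    fig, ax = plt.subplots(figsize=(7, max(3, tree.n_tips * 0.25)))
    for nid in tree.postorder_ids():
        if nid == tree.root_id:
            continue
        parent = tree.parent_id(nid)
        color = cmap(norm(bm.per_node_missing_pct[nid]))
        ax.plot([xs[parent], xs[nid]], [ys[nid], ys[nid]], color=color, lw=1.5)
        ax.plot([xs[parent], xs[parent]], [ys[parent], ys[nid]], color="0.6", lw=0.6)
        if nid in tree.tip_labels:
            ax.text(xs[nid], ys[nid], " " + nid, fontsize=6, va="center")
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, shrink=0.6, label="% missing")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
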