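"""Parsimony mapping on a fixed rooted tree.

Implements Fitch/Hartigan minimum-change counting (polytomies handled
natively), a single ACCTRAN-resolved most-parsimonious ancestral-state
assignment, apomorphy extraction for a focal clade's stem branch, and
the positional distribution of apomorphies along the alignment.

Two independent code paths compute change counts: ``fitch_length`` uses
Hartigan's bitmask downpass while ``acctran_reconstruct`` uses a
unit-cost Sankoff dynamic program; their totals must agree (asserted in
the test suite).

ACCTRAN is formalized as: among all most-parsimonious reconstructions,
assign states root-to-tip, preferring at every node a state *different*
from its parent whenever that choice is still optimal for the subtree
(changes are thereby pulled as close to the root as possible); ties are
broken by the state order (alphabetical for amino acids).  Tip states
always equal observed states; MISSING tips are free (cost 0 for every
state).  An internal node is reported as MISSING when no tip in its
subtree carries an observed state (the composition of an unobservable
state is undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, MISSING, N_STATES
from .errors import AnalysisError, TreeError
from .seqtree_io import Alignment, RootedTree

logger = logging.getLogger(__name__)

_CHUNK = 8192  # columns per DP block, bounds peak memory


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

class _IndexedTree:
    """Postorder arrays for vectorized passes over a RootedTree."""

    def __init__(self, tree: RootedTree, taxon_labels: list[str]):
        tree_tips = set(tree.tip_labels)
        aln_tips = set(taxon_labels)
        if tree_tips != aln_tips:
            raise TreeError(
                "tip labels do not match alignment labels; "
                f"only in tree: {sorted(tree_tips - aln_tips)[:5]}, "
                f"only in alignment: {sorted(aln_tips - tree_tips)[:5]}"
            )
        self.post_ids = tree.postorder_ids()
        self.index_of = {nid: i for i, nid in enumerate(self.post_ids)}
        row_of_label = {lab: i for i, lab in enumerate(taxon_labels)}
        self.children: list[list[int]] = []
        self.tip_row: list[int] = []  # alignment row, or -1 for internal
        self.parent = np.full(len(self.post_ids), -1, dtype=np.int64)
        for nid in self.post_ids:
            kids = tree.children_ids(nid)
            self.children.append([self.index_of[k] for k in kids])
            self.tip_row.append(row_of_label[nid] if not kids else -1)
        for i, kids in enumerate(self.children):
            for k in kids:
                self.parent[k] = i
        self.root = len(self.post_ids) - 1


# ---------------------------------------------------------------------------
# Fitch/Hartigan length
# ---------------------------------------------------------------------------

def fitch_length(
    alignment: Alignment,
    tree: RootedTree,
    *,
    matrix: np.ndarray | None = None,
    n_states: int = N_STATES,
) -> tuple[np.ndarray, int]:
    """Minimum number of state changes per column (Hartigan downpass).

    MISSING tips contribute the full state set at no cost; all-MISSING
    columns score 0.  Returns ``(per_column_changes, total)``.
    """
    mat = alignment.matrix if matrix is None else matrix
    missing_code = MISSING if matrix is None else n_states
    idx = _IndexedTree(tree, alignment.taxon_labels)
    ncol = mat.shape[1]
    full_mask = np.uint32((1 << n_states) - 1)
    bits = (np.uint32(1) << np.arange(n_states, dtype=np.uint32))

    masks: list[np.ndarray | None] = [None] * len(idx.post_ids)
    changes = np.zeros(ncol, dtype=np.int64)
    for i, kids in enumerate(idx.children):
        if not kids:
            row = mat[idx.tip_row[i]]
            m = np.where(
                row == missing_code, full_mask, np.uint32(1) << row.astype(np.uint32)
            )
            masks[i] = m.astype(np.uint32)
        else:
            counts = np.zeros((n_states, ncol), dtype=np.int32)
            for k in kids:
                child = masks[k]
                for s in range(n_states):
                    counts[s] += (child >> np.uint32(s)) & np.uint32(1)
                masks[k] = None  # free
            kmax = counts.max(axis=0)
            changes += len(kids) - kmax
            sel = counts == kmax  # (n_states, ncol)
            masks[i] = (sel * bits[:, None]).sum(axis=0, dtype=np.uint32)
    return changes, int(changes.sum())


# ---------------------------------------------------------------------------
# ACCTRAN reconstruction (unit-cost Sankoff DP + accelerated assignment)
# ---------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Per-node per-column state assignment with change accounting.

    ``states`` holds the reporting states (internal nodes over
    unobserved subtrees are MISSING); ``raw_states`` holds the plain
    most-parsimonious assignment used for change counting.
    """

    tree: RootedTree
    taxon_labels: list[str]
    node_index: dict[str, int]
    states: np.ndarray  # (n_nodes, n_columns) uint8, MISSING allowed
    raw_states: np.ndarray  # same shape, no MISSING at internal nodes
    per_column_changes: np.ndarray
    state_symbols: str = AMINO_ACIDS
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.length = int(self.per_column_changes.sum())

    def state_of(self, node_id: str, column: int) -> int:
        """State code at a node and 0-based column (MISSING possible)."""
        return int(self.states[self.node_index[node_id], column])

    def node_row(self, node_id: str) -> np.ndarray:
        return self.states[self.node_index[node_id]]

    def node_row_string(self, node_id: str, missing_char: str = "-") -> str:
        row = self.node_row(node_id)
        table = self.state_symbols + missing_char
        return "".join(table[min(c, len(self.state_symbols))] for c in row)


def acctran_reconstruct(
    alignment: Alignment,
    tree: RootedTree,
    *,
    matrix: np.ndarray | None = None,
    n_states: int = N_STATES,
    state_symbols: str | None = None,
    state_preference: list[int] | None = None,
    tie_break: str = "alphabetical",
    tie_seed: int = 0,
) -> AncestralReconstruction:
    """Single ACCTRAN-resolved most-parsimonious reconstruction.

    Ties remaining after the ACCTRAN criterion are resolved either by
    ``state_preference`` order (default: state code order, i.e.
    alphabetical amino acids) or, with ``tie_break='random'``, by a
    deterministic seeded draw per column.  A fixed state order couples
    tie resolution to state identity and therefore biases downstream
    composition statistics; the seeded-random mode keeps the pipeline
    equivariant under amino-acid relabeling while remaining exactly
    reproducible.  Requires a rooted tree.
    """
    if tie_break not in ("alphabetical", "random"):
        raise AnalysisError("tie_break must be 'alphabetical' or 'random'")
    if not tree.is_rooted:
        raise TreeError(
            "tree is unrooted (basal polytomy); root it first with "
            "root_with_outgroup()"
        )
    mat = alignment.matrix if matrix is None else matrix
    missing_code = MISSING if matrix is None else n_states
    idx = _IndexedTree(tree, alignment.taxon_labels)
    n_nodes = len(idx.post_ids)
    ncol = mat.shape[1]
    pref = np.arange(n_states) if state_preference is None else np.asarray(state_preference)
    if sorted(pref.tolist()) != list(range(n_states)):
        raise AnalysisError("state_preference must be a permutation of all states")

    BIG = np.int32(1 << 20)
    raw = np.empty((n_nodes, ncol), dtype=np.uint8)
    per_col = np.zeros(ncol, dtype=np.int64)
    tie_rng = np.random.default_rng(tie_seed) if tie_break == "random" else None

    for lo in range(0, ncol, _CHUNK):
        hi = min(lo + _CHUNK, ncol)
        width = hi - lo
        # --- downpass: L[v][s, c] = min changes in subtree(v) given state s
        L: list[np.ndarray | None] = [None] * n_nodes
        for i, kids in enumerate(idx.children):
            if not kids:
                row = mat[idx.tip_row[i], lo:hi]
                Lv = np.where(
                    (row[None, :] == np.arange(n_states)[:, None])
                    | (row[None, :] == missing_code),
                    np.int32(0),
                    BIG,
                ).astype(np.int32)
            else:
                Lv = np.zeros((n_states, width), dtype=np.int32)
                for k in kids:
                    Lc = L[k]
                    minall = Lc.min(axis=0)
                    Lv += np.minimum(Lc, minall + 1)
            L[i] = Lv
        # --- uppass: accelerated assignment
        order = np.argsort(np.argsort(pref))  # rank of each state in preference
        alpha_key = order[:, None].astype(np.float64) / n_states  # in [0, 1)

        def _tiebreak() -> np.ndarray:
            if tie_rng is None:
                return alpha_key
            return tie_rng.random((n_states, width))

        states_chunk = np.empty((n_nodes, width), dtype=np.uint8)
        root_L = L[idx.root]
        per_col[lo:hi] = root_L.min(axis=0)
        # argmin over (cost, tie key) realizes the tie-break
        key = root_L.astype(np.float64) * 2.0 + _tiebreak()
        states_chunk[idx.root] = np.argmin(key, axis=0).astype(np.uint8)
        for i in range(n_nodes - 2, -1, -1):  # preorder = reversed postorder
            p_states = states_chunk[idx.parent[i]]
            Lv = L[i]
            differs = (np.arange(n_states)[:, None] != p_states[None, :]).astype(np.int32)
            M = Lv + differs
            # prefer a change (s != parent) among optimal states, then the
            # tie key
            key = (
                M.astype(np.float64) * 2.0
                + (1 - differs).astype(np.float64)
                + _tiebreak()
            )
            states_chunk[i] = np.argmin(key, axis=0).astype(np.uint8)
        raw[:, lo:hi] = states_chunk

    # reporting states: tips show observations; internal nodes with no
    # observed tip below are MISSING
    states = raw.copy()
    has_data = np.zeros((n_nodes, ncol), dtype=bool)
    for i, kids in enumerate(idx.children):
        if not kids:
            row = mat[idx.tip_row[i]]
            observed = row != missing_code
            has_data[i] = observed
            states[i] = np.where(observed, row, MISSING if matrix is None else n_states)
        else:
            for k in kids:
                has_data[i] |= has_data[k]
            states[i][~has_data[i]] = MISSING if matrix is None else n_states

    symbols = state_symbols if state_symbols is not None else AMINO_ACIDS[:n_states]
    return AncestralReconstruction(
        tree=tree,
        taxon_labels=alignment.taxon_labels,
        node_index=dict(idx.index_of),
        states=states,
        raw_states=raw,
        per_column_changes=per_col,
        state_symbols=symbols,
    )


# ---------------------------------------------------------------------------
# apomorphies
# ---------------------------------------------------------------------------

@dataclass
class ApomorphyTable:
    """Columns whose state changes on a focal clade's stem branch."""

    clade_name: str
    node_id: str
    columns: list[int]  # 1-based, sorted
    changes: list[tuple[str, str]]  # (ancestor state, derived state) per column

    @property
    def count(self) -> int:
        return len(self.columns)

    def columns0(self) -> np.ndarray:
        """0-based column indices as an array."""
        return np.asarray(self.columns, dtype=np.int64) - 1


def extract_apomorphies(
    recon: AncestralReconstruction, clade_node: str
) -> ApomorphyTable:
    """Columns where the state changes on the stem branch of ``clade_node``.

    A column is included iff the reconstructed states at the node and at
    its direct ancestor differ and neither is MISSING.
    """
    parent = recon.tree.parent_id(clade_node)
    if parent is None:
        raise TreeError("focal node is the root: no stem branch to analyse")
    node = recon.tree.node(clade_node)
    if node.is_leaf():
        # a terminal taxon also has a stem branch; allowed
        pass
    missing_code = len(recon.state_symbols)
    s_node = recon.node_row(clade_node)
    s_anc = recon.node_row(parent)
    ok = (s_node != missing_code) & (s_anc != missing_code) & (s_node != s_anc)
    cols0 = np.nonzero(ok)[0]
    symbols = recon.state_symbols
    changes = [(symbols[s_anc[c]], symbols[s_node[c]]) for c in cols0]
    return ApomorphyTable(
        clade_name=clade_node,
        node_id=clade_node,
        columns=(cols0 + 1).tolist(),
        changes=changes,
    )


# ---------------------------------------------------------------------------
# positional distribution
# ---------------------------------------------------------------------------

@dataclass
class ApomorphyDistribution:
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    ks_statistic: float
    ks_pvalue: float


def apomorphy_distribution(
    table: ApomorphyTable, n_columns: int, n_bins: int = 50
) -> ApomorphyDistribution:
    """Histogram of apomorphy positions plus a KS uniformity diagnostic.

    The one-sample Kolmogorov-Smirnov statistic compares apomorphy
    column positions against the uniform distribution on [1, n_columns]
    (diagnostic only).
    """
    if n_bins < 2:
        raise AnalysisError("n_bins must be at least 2")
    if table.count == 0:
        raise AnalysisError("empty apomorphy table")
    pos = np.asarray(table.columns, dtype=float)
    counts, edges = np.histogram(pos, bins=n_bins, range=(0.5, n_columns + 0.5))
    ks = stats.kstest(pos, "uniform", args=(1.0, float(n_columns - 1)))
    return ApomorphyDistribution(
        bin_edges=edges,
        bin_counts=counts,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def plot_apomorphy_distribution(
    table: ApomorphyTable, n_columns: int, path: str, n_bins: int = 100
) -> None:
    """Write a histogram of apomorphy positions along the alignment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist = apomorphy_distribution(table, n_columns, n_bins)
    fig, ax = plt.subplots(figsize=(10, 2.5))
    centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
    ax.bar(centers, dist.bin_counts, width=np.diff(dist.bin_edges), color="0.3")
    ax.set_xlabel("alignment position")
    ax.set_ylabel("apomorphies")
    ax.set_title(f"{table.count} apomorphies; KS={dist.ks_statistic:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
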