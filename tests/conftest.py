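"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms:
parsimony scores come from exhaustive enumeration over internal-state
assignments, chi-square tail probabilities from numerical integration
of the density, and KS statistics from a hand-rolled ECDF.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import integrate

from biasdiag import Alignment, RootedTree, generate_tree
from biasdiag.alphabet import MISSING


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_alignment(
    rng: np.random.Generator,
    n_taxa: int,
    n_columns: int,
    n_states: int = 20,
    missing_prob: float = 0.0,
    labels: list[str] | None = None,
) -> Alignment:
    mat = rng.integers(0, n_states, size=(n_taxa, n_columns)).astype(np.uint8)
    if missing_prob > 0:
        mat[rng.random(mat.shape) < missing_prob] = MISSING
    if labels is None:
        labels = [f"t{i + 1:03d}" for i in range(n_taxa)]
    return Alignment(labels, mat)


def random_yule_tree(n_taxa: int, seed: int) -> RootedTree:
    return generate_tree(n_taxa, birth_rate=1.0, seed=seed)


# ---------------------------------------------------------------------------
# exhaustive parsimony oracle
# ---------------------------------------------------------------------------

class MPREnumerator:
    """Brute-force minimum-change scoring over all internal assignments.

    Edges to MISSING tips cost nothing (the tip may freely copy its
    parent); observed tips must match their observed state.  The minimum
    is enumerated over assignments drawn from the observed states of the
    column only — some most-parsimonious assignment always uses only
    observed states — while arbitrary candidate assignments are scored
    directly for membership checks.
    """

    def __init__(self, tree: RootedTree, n_states: int = 20):
        self.tree = tree
        self.n_states = n_states
        post = tree.postorder_ids()
        self.internals = [n for n in post if tree.children_ids(n)]
        self.pos_of = {n: i for i, n in enumerate(self.internals)}
        self.internal_edges: list[tuple[int, int]] = []
        self.tip_parent: dict[str, int] = {}
        for nid in post:
            parent = tree.parent_id(nid)
            if parent is None:
                continue
            if tree.children_ids(nid):
                self.internal_edges.append((self.pos_of[nid], self.pos_of[parent]))
            else:
                self.tip_parent[nid] = self.pos_of[parent]

    def assignment_cost(
        self,
        tip_states: dict[str, int],
        internal_states: dict[str, int],
        missing_code: int,
    ) -> int:
        assign = [internal_states[n] for n in self.internals]
        cost = sum(assign[a] != assign[b] for a, b in self.internal_edges)
        for tip, ppos in self.tip_parent.items():
            s = tip_states[tip]
            if s != missing_code:
                cost += assign[ppos] != s
        return int(cost)

    def min_changes(self, tip_states: dict[str, int], missing_code: int) -> int:
        observed = sorted({s for s in tip_states.values() if s != missing_code})
        if not observed:
            return 0
        best = None
        for combo in itertools.product(observed, repeat=len(self.internals)):
            assign = dict(zip(self.internals, combo))
            cost = self.assignment_cost(tip_states, assign, missing_code)
            if best is None or cost < best:
                best = cost
        return best

    def is_mpr(
        self,
        tip_states: dict[str, int],
        internal_states: dict[str, int],
        missing_code: int,
    ) -> bool:
        return self.assignment_cost(
            tip_states, internal_states, missing_code
        ) == self.min_changes(tip_states, missing_code)


# ---------------------------------------------------------------------------
# independent statistics oracles
# ---------------------------------------------------------------------------

def chi2_sf_by_quadrature(x: float, df: int) -> float:
    """Upper-tail chi-square probability by numerical integration."""
    if x <= 0:
        return 1.0

    def density(t: float) -> float:
        k = df / 2.0
        return t ** (k - 1) * math.exp(-t / 2.0) / (2**k * math.gamma(k))

    val, _ = integrate.quad(density, x, np.inf, limit=200)
    return float(val)


def ks_uniform_statistic(positions: np.ndarray, n_columns: int) -> float:
    """One-sample KS statistic vs the uniform distribution on [1, n_columns]."""
    x = np.sort(np.asarray(positions, dtype=float))
    n = x.size
    cdf = (x - 1.0) / (n_columns - 1.0)
    cdf = np.clip(cdf, 0.0, 1.0)
    upper = np.abs(np.arange(1, n + 1) / n - cdf)
    lower = np.abs(np.arange(0, n) / n - cdf)
    return float(max(upper.max(), lower.max()))


def unrooted_bipartitions(tree: RootedTree) -> set[frozenset[str]]:
    """Independent bipartition extraction via root-to-tip paths."""
    tips = set(tree.tip_labels)
    paths: dict[str, set[str]] = {}
    for tip in tips:
        node = tip
        chain = set()
        while node is not None:
            chain.add(node)
            node = tree.parent_id(node)
        paths[tip] = chain
    out: set[frozenset[str]] = set()
    for nid in tree.postorder_ids():
        if not tree.children_ids(nid) or tree.parent_id(nid) is None:
            continue
        below = frozenset(t for t in tips if nid in paths[t])
        if 1 < len(below) < len(tips) - 1:
            other = frozenset(tips - below)
            out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return out
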