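"""Amino-acid composition accounting and node-based chi-square testing.

The central question: does the reconstructed ancestral sequence of a
focal clade deviate in composition, at that clade's apomorphy columns,
from the pooled composition of all sequences in the subset?  The subset
comprises every terminal taxon plus the reconstructed ancestral rows of
the focal node and of its direct ancestor.

The chi-square test follows the TREE-PUZZLE convention: each sequence
is compared against the overall average composition of the subset (the
focal sequence included in the pool), with 19 degrees of freedom; amino
acids with zero expected count are dropped from the sum but df is not
reduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import MISSING, N_STATES
from .errors import AnalysisError, TreeError
from .parsimony_mapping import acctran_reconstruct, extract_apomorphies
from .seqtree_io import Alignment, CladeSpec, RootedTree, resolve_clade

logger = logging.getLogger(__name__)

DF = N_STATES - 1  # TREE-PUZZLE convention, fixed


@dataclass
class CompositionVector:
    """Residue counts over the 20 canonical amino acids."""

    counts: np.ndarray  # (20,) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_STATES,):
            raise AnalysisError("composition vector must have 20 entries")
        if (self.counts < 0).any():
            raise AnalysisError("negative residue count")

    @property
    def n_valid(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        n = self.n_valid
        return self.counts / n if n else np.zeros(N_STATES)

    def __add__(self, other: "CompositionVector") -> "CompositionVector":
        return CompositionVector(self.counts + other.counts)


@dataclass
class CompTestResult:
    chi2: float
    df: int
    p: float
    focal_label: str
    subset_size: int  # residues counted in the focal sequence

    def p_percent(self) -> float:
        return 100.0 * self.p


@dataclass
class NodeBiasReport:
    clade: CladeSpec
    clade_node: str
    ancestor_node: str
    apomorphy_count: int
    apomorphy_columns: list[int]  # 1-based
    test_focal: CompTestResult
    test_ancestor: CompTestResult
    per_taxon_tests: list[CompTestResult] | None = None


def composition_counts(seq: np.ndarray) -> CompositionVector:
    """Residue counts of a coded row; MISSING cells are skipped."""
    seq = np.asarray(seq)
    counts = np.bincount(seq[seq != MISSING], minlength=N_STATES)[:N_STATES]
    return CompositionVector(counts)


def chi_square_homogeneity(
    focal: CompositionVector, pool: CompositionVector, focal_label: str = ""
) -> CompTestResult:
    """Chi-square test of a sequence's composition against the pool average.

    Expected counts are ``focal.n_valid * pool_frequency``; states with
    zero expectation are dropped from the sum; df is fixed at 19.
    """
    if focal.n_valid == 0:
        raise AnalysisError(f"focal sequence {focal_label!r} has no residues")
    if pool.n_valid == 0:
        raise AnalysisError("pool has no residues")
    expected = focal.n_valid * pool.frequencies()
    keep = expected > 0
    observed = focal.counts[keep]
    chi2 = float(((observed - expected[keep]) ** 2 / expected[keep]).sum())
    p = float(stats.chi2.sf(chi2, DF))
    return CompTestResult(
        chi2=chi2, df=DF, p=p, focal_label=focal_label, subset_size=focal.n_valid
    )


def node_bias_evaluation(
    alignment: Alignment,
    tree: RootedTree,
    clade: CladeSpec,
    *,
    include_per_taxon: bool = False,
    tie_break: str = "random",
    tie_seed: int = 0,
) -> NodeBiasReport:
    """Table-1-style compositional test for one focal clade.

    Pipeline: ACCTRAN reconstruction -> apomorphy columns of the clade's
    stem branch -> restrict all terminal rows plus the two reconstructed
    ancestral rows to those columns -> chi-square of the focal ancestor
    and of its direct ancestor against the pooled composition.

    Parsimony ties are broken by a seeded deterministic draw by default
    (``tie_break='random'``): a fixed alphabetical tie order biases the
    reconstructed composition toward/away from particular residues and
    inflates the test's null rejection rate.
    """
    res = resolve_clade(tree, clade)
    if not res.monophyletic:
        raise TreeError(
            f"clade {clade.name!r} is not monophyletic on this tree; supply a "
            "topology constrained for its monophyly (tree inference is external)"
        )
    if res.node_id == tree.root_id:
        raise TreeError(f"clade {clade.name!r} resolves to the root: no stem branch")

    recon = acctran_reconstruct(alignment, tree, tie_break=tie_break, tie_seed=tie_seed)
    table = extract_apomorphies(recon, res.node_id)
    if table.count == 0:
        raise AnalysisError(f"no apomorphies for node of clade {clade.name!r}")
    cols = table.columns0()
    anc_id = tree.parent_id(res.node_id)

    focal_row = recon.node_row(res.node_id)[cols]
    anc_row = recon.node_row(anc_id)[cols]
    focal_vec = composition_counts(focal_row)
    anc_vec = composition_counts(anc_row)

    pool = focal_vec + anc_vec
    taxon_vecs: dict[str, CompositionVector] = {}
    for i, label in enumerate(alignment.taxon_labels):
        v = composition_counts(alignment.matrix[i, cols])
        taxon_vecs[label] = v
        pool = pool + v

    test_focal = chi_square_homogeneity(focal_vec, pool, f"{clade.name} (ancestor)")
    test_anc = chi_square_homogeneity(anc_vec, pool, f"{clade.name} (direct ancestor)")
    per_taxon = None
    if include_per_taxon:
        per_taxon = sorted(
            (
                chi_square_homogeneity(v, pool, label)
                for label, v in taxon_vecs.items()
                if v.n_valid > 0
            ),
            key=lambda r: r.p,
        )
    logger.info(
        "clade %s: %d apomorphies, focal p=%.4g, ancestor p=%.4g (raw p-values, "
        "no multiple-testing correction)",
        clade.name,
        table.count,
        test_focal.p,
        test_anc.p,
    )
    return NodeBiasReport(
        clade=clade,
        clade_node=res.node_id,
        ancestor_node=anc_id,
        apomorphy_count=table.count,
        apomorphy_columns=table.columns,
        test_focal=test_focal,
        test_ancestor=test_anc,
        per_taxon_tests=per_taxon,
    )


def per_taxon_composition_screen(alignment: Alignment) -> list[CompTestResult]:
    """Each taxon's full row tested against the whole-alignment pool.

    Results are sorted by ascending p so the most deviating taxa come
    first.  Rows with no residues are reported with p = NaN at the end.
    """
    vecs = [composition_counts(alignment.matrix[i]) for i in range(alignment.n_taxa)]
    pool = CompositionVector(np.sum([v.counts for v in vecs], axis=0))
    results: list[CompTestResult] = []
    empties: list[CompTestResult] = []
    for label, v in zip(alignment.taxon_labels, vecs):
        if v.n_valid == 0:
            empties.append(
                CompTestResult(
                    chi2=float("nan"), df=DF, p=float("nan"),
                    focal_label=label, subset_size=0,
                )
            )
        else:
            results.append(chi_square_homogeneity(v, pool, label))
    results.sort(key=lambda r: r.p)
    return results + empties
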