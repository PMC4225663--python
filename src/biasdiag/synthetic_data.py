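"""Synthetic benchmarks with planted compositional bias.

Generates Yule trees, nonstationary amino-acid alignments in which the
equilibrium frequencies switch on a designated internal branch (and all
branches below it), and EST-style gene-block missingness.  Every run
writes a machine-readable truth record so each diagnostic has an
independent recovery test.

The substitution process is an F81-style exchange model (rate into a
state proportional to its target frequency), which is all the
composition diagnostics need; exchangeabilities are out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .alphabet import AMINO_ACIDS, MISSING, N_STATES
from .errors import AnalysisError, TreeError
from .seqtree_io import Alignment, RootedTree, resolve_clade, write_alignment, write_tree
from .seqtree_io import CladeSpec

logger = logging.getLogger(__name__)

PRESETS = ("null_homogeneous", "planted_shift", "planted_block_missing", "paperlike")


@dataclass
class SimulationSpec:
    n_taxa: int = 16
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (60, 120)
    birth_rate: float = 1.0
    base_frequencies: np.ndarray | None = None  # defaults to uniform 1/20
    shift_clade: frozenset[str] | None = None  # None: no planted shift
    shift_tv: float = 0.0  # total-variation distance of the shifted simplex
    substitution_rate: float = 1.0
    stem_length: float | None = None  # override the shift clade's stem length
    missing_block_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_frequencies is None:
            self.base_frequencies = np.full(N_STATES, 1.0 / N_STATES)
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if abs(self.base_frequencies.sum() - 1.0) > 1e-9:
            raise AnalysisError("base frequencies must sum to 1")
        if (self.base_frequencies < 0).any():
            raise AnalysisError("negative base frequency")
        if self.substitution_rate < 0 or self.birth_rate <= 0:
            raise AnalysisError("rates must be non-negative (birth rate positive)")
        if not 0 <= self.missing_block_prob <= 1:
            raise AnalysisError("missing_block_prob must be in [0, 1]")
        if not 0 <= self.shift_tv <= 1:
            raise AnalysisError("shift_tv must be in [0, 1]")


@dataclass
class TruthRecord:
    spec: dict
    newick: str
    shifted_node: str | None
    shifted_frequencies: list[float] | None
    gene_boundaries: list[tuple[int, int]]  # half-open 0-based [start, end)
    ancestral_states: dict[str, str]  # internal node id -> state string
    missing_mask: list[list[bool]] | None  # taxa x genes block dropout
    realized_coverage: float | None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        payload = json.loads(text)
        payload["gene_boundaries"] = [tuple(b) for b in payload["gene_boundaries"]]
        return cls(**payload)


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def generate_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> RootedTree:
    """Yule (pure-birth) tree: with k lineages the waiting time to the
    next split is Exp(k * birth_rate); tips are contemporaneous."""
    if n_taxa < 3:
        raise AnalysisError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        active.append(child)
    k = 2
    while k < n_taxa:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += wait
        split = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = split.new_child(edge_length=0.0)
            active.append(child)
        k += 1
    wait = rng.exponential(1.0 / (k * birth_rate))
    for node in active:
        node.edge.length += wait
    # deterministic tip naming in left-to-right leaf order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"t{i + 1:03d}")
    return RootedTree(tree)


# ---------------------------------------------------------------------------
# frequency shift
# ---------------------------------------------------------------------------

def shifted_simplex(
    base: np.ndarray, tv: float, rng: np.random.Generator, concentration: float = 5.0
) -> np.ndarray:
    """Perturb a frequency simplex to a target total-variation distance.

    The direction is a Dirichlet draw centred on the base frequencies;
    the step is scaled so that 0.5 * sum(|shift - base|) equals ``tv``.
    """
    if tv == 0:
        return base.copy()
    for _ in range(100):
        direction = rng.dirichlet(concentration * N_STATES * base + 1e-3) - base
        half_l1 = 0.5 * np.abs(direction).sum()
        if half_l1 < 1e-12:
            continue
        shift = base + direction * (tv / half_l1)
        if (shift > 1e-6).all():
            return shift / shift.sum()
    raise AnalysisError(f"could not realize a shift of TV={tv} from the base simplex")


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _gene_lengths(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.gene_length_range
    return rng.integers(lo, hi + 1, size=spec.n_genes)


def simulate_alignment(
    tree: RootedTree, spec: SimulationSpec
) -> tuple[Alignment, TruthRecord]:
    """Evolve sequences down the tree under an F81-style process whose
    stationary frequencies switch on the shift clade's stem branch and
    all descendant branches."""
    rng = np.random.default_rng(spec.seed)
    labels = tree.tip_labels
    if spec.n_taxa != len(labels):
        raise AnalysisError("spec.n_taxa does not match the tree")
    gene_lengths = _gene_lengths(spec, rng)
    bounds: list[tuple[int, int]] = []
    start = 0
    for ln in gene_lengths:
        bounds.append((start, start + int(ln)))
        start += int(ln)
    ncol = start

    shifted_node = None
    pi_shift = None
    if spec.shift_clade is not None:
        res = resolve_clade(tree, CladeSpec("shift", frozenset(spec.shift_clade)))
        if not res.monophyletic:
            raise TreeError("shift_clade is not monophyletic on the tree")
        shifted_node = res.node_id
        pi_shift = shifted_simplex(spec.base_frequencies, spec.shift_tv, rng)
        if spec.stem_length is not None:
            tree.node(shifted_node).edge.length = spec.stem_length

    shifted_ids: set[str] = set()
    if shifted_node is not None:
        node = tree.node(shifted_node)
        for sub in node.preorder_iter():
            shifted_ids.add(tree.node_id(sub))

    base = spec.base_frequencies
    beta_base = 1.0 / max(1.0 - (base**2).sum(), 1e-12)
    if pi_shift is not None:
        beta_shift = 1.0 / max(1.0 - (pi_shift**2).sum(), 1e-12)

    states: dict[str, np.ndarray] = {}
    root_id = tree.root_id
    states[root_id] = rng.choice(N_STATES, size=ncol, p=base).astype(np.uint8)
    ancestral: dict[str, str] = {}
    for nid in reversed(tree.postorder_ids()):  # preorder
        if nid == root_id:
            continue
        parent_seq = states[tree.parent_id(nid)]
        bl = tree.branch_length(nid) or 0.0
        on_shift = nid in shifted_ids
        pi = pi_shift if on_shift else base
        beta = beta_shift if on_shift else beta_base
        p_event = 1.0 - np.exp(-beta * spec.substitution_rate * bl)
        seq = parent_seq.copy()
        if p_event > 0 and spec.substitution_rate > 0:
            hit = rng.random(ncol) < p_event
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = rng.choice(N_STATES, size=n_hit, p=pi).astype(np.uint8)
        states[nid] = seq
    for nid in tree.node_ids(internal_only=True):
        ancestral[nid] = "".join(AMINO_ACIDS[s] for s in states[nid])

    matrix = np.vstack([states[lab] for lab in labels])
    aln = Alignment(list(labels), matrix)
    spec_dict = dataclasses.asdict(spec)
    spec_dict["base_frequencies"] = spec.base_frequencies.tolist()
    spec_dict["shift_clade"] = sorted(spec.shift_clade) if spec.shift_clade else None
    truth = TruthRecord(
        spec=spec_dict,
        newick=tree.as_newick().strip(),
        shifted_node=shifted_node,
        shifted_frequencies=pi_shift.tolist() if pi_shift is not None else None,
        gene_boundaries=bounds,
        ancestral_states=ancestral,
        missing_mask=None,
        realized_coverage=None,
    )
    return aln, truth


def inject_missingness(
    alignment: Alignment,
    gene_boundaries: list[tuple[int, int]],
    missing_block_prob: float,
    seed: int = 0,
    forced_blocks: np.ndarray | None = None,
) -> tuple[Alignment, np.ndarray]:
    """Drop whole gene blocks per taxon with the given probability.

    ``forced_blocks`` (taxa x genes bool) marks blocks dropped
    unconditionally (used to plant structured missingness).  Returns the
    masked alignment and the realized taxa x genes dropout mask.
    """
    if not 0 <= missing_block_prob <= 1:
        raise AnalysisError("missing_block_prob must be in [0, 1]")
    ends = [e for _, e in gene_boundaries]
    starts = [s for s, _ in gene_boundaries]
    if starts[0] != 0 or ends[-1] != alignment.n_columns or any(
        e != s2 for e, s2 in zip(ends[:-1], starts[1:])
    ):
        raise AnalysisError("gene boundaries must partition the columns")
    rng = np.random.default_rng(seed)
    n_genes = len(gene_boundaries)
    mask = rng.random((alignment.n_taxa, n_genes)) < missing_block_prob
    if forced_blocks is not None:
        mask |= forced_blocks.astype(bool)
    matrix = alignment.matrix.copy()
    for g, (s, e) in enumerate(gene_boundaries):
        rows = np.nonzero(mask[:, g])[0]
        matrix[np.ix_(rows, range(s, e))] = MISSING
    return Alignment(list(alignment.taxon_labels), matrix), mask


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_spec(name: str, seed: int) -> SimulationSpec:
    # low-saturation regimes: ancestral reconstruction must be mostly
    # unambiguous or parsimony tie-breaking, not composition, drives the
    # chi-square tests
    if name == "null_homogeneous":
        return SimulationSpec(
            n_taxa=16, n_genes=24, gene_length_range=(70, 110),
            substitution_rate=0.15, shift_tv=0.0, stem_length=0.6,
            missing_block_prob=0.15, seed=seed,
        )
    if name == "planted_shift":
        return SimulationSpec(
            n_taxa=20, n_genes=30, gene_length_range=(70, 110),
            substitution_rate=0.15, shift_tv=0.25, stem_length=0.6,
            missing_block_prob=0.1, seed=seed,
        )
    if name == "planted_block_missing":
        return SimulationSpec(
            n_taxa=18, n_genes=30, gene_length_range=(60, 100),
            substitution_rate=0.2, missing_block_prob=0.08, seed=seed,
        )
    if name == "paperlike":
        return SimulationSpec(
            n_taxa=58, n_genes=196, gene_length_range=(110, 310),
            substitution_rate=0.12, shift_tv=0.15, stem_length=0.5,
            missing_block_prob=0.5, seed=seed,
        )
    raise AnalysisError(f"unknown preset {name!r}; choose from {PRESETS}")


def pick_shift_clade(tree: RootedTree, target_fraction: float = 0.25) -> frozenset[str]:
    """Internal node whose tip count is closest to a quarter of the taxa
    (ties resolved by node id for determinism)."""
    n = tree.n_tips
    best: tuple[float, str, frozenset[str]] | None = None
    for nid in tree.node_ids(internal_only=True):
        if nid == tree.root_id:
            continue
        tips = tree.tips_below(nid)
        if len(tips) < 2 or len(tips) > n - 2:
            continue
        score = abs(len(tips) / n - target_fraction)
        key = (score, nid, tips)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        raise AnalysisError("tree has no eligible internal node for a shift")
    return frozenset(best[2])


def make_benchmark(
    name: str, outdir: str | Path, seed: int = 0
) -> tuple[Alignment, RootedTree, TruthRecord]:
    """Generate a preset benchmark and write alignment/tree/truth files.

    Writes ``alignment.fasta``, ``tree.nwk``, ``truth.json`` and
    ``genes.tsv`` (gene, start, end; half-open 0-based) to ``outdir``.
    """
    if name not in PRESETS:
        raise AnalysisError(f"unknown preset {name!r}; choose from {PRESETS}")
    spec = preset_spec(name, seed)
    tree = generate_tree(spec.n_taxa, spec.birth_rate, seed=seed)
    if name in ("null_homogeneous", "planted_shift", "paperlike"):
        # the null preset plants the same stem geometry with a zero shift
        spec = dataclasses.replace(spec, shift_clade=pick_shift_clade(tree))
    aln, truth = simulate_alignment(tree, spec)

    forced = None
    if name == "planted_block_missing":
        rng = np.random.default_rng(seed + 1)
        planted_taxa = sorted(rng.choice(spec.n_taxa, size=5, replace=False).tolist())
        planted_genes = sorted(
            rng.choice(spec.n_genes, size=spec.n_genes // 2, replace=False).tolist()
        )
        forced = np.zeros((spec.n_taxa, spec.n_genes), dtype=bool)
        forced[np.ix_(planted_taxa, planted_genes)] = True
        truth.spec["planted_missing_taxa"] = [
            aln.taxon_labels[i] for i in planted_taxa
        ]
        truth.spec["planted_missing_genes"] = planted_genes
    masked, mask = inject_missingness(
        aln, truth.gene_boundaries, spec.missing_block_prob,
        seed=seed, forced_blocks=forced,
    )
    truth.missing_mask = mask.tolist()
    truth.realized_coverage = float(100.0 * (~masked.missing_mask).mean())

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_alignment(masked, outdir / "alignment.fasta", "fasta")
    write_tree(tree, outdir / "tree.nwk")
    (outdir / "truth.json").write_text(truth.to_json())
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene\tstart\tend\n")
        for g, (s, e) in enumerate(truth.gene_boundaries):
            fh.write(f"g{g + 1}\t{s}\t{e}\n")
    logger.info(
        "benchmark %s written to %s (coverage %.1f%%)",
        name, outdir, truth.realized_coverage,
    )
    return masked, tree, truth
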