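"""Compositional distances between taxa and non-metric MDS.

The distance between two taxa is one half the sum of squared
differences in their residue counts (raw counts by default; a
``normalize`` switch uses frequencies instead).  The NMDS is a SMACOF
iteration with Kruskal's primary approach to ties in the isotonic
regression and Kruskal stress-1 as the reported badness of fit, with
multiple random restarts keeping the best configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .composition_diagnostics import composition_counts
from .errors import AnalysisError
from .seqtree_io import Alignment


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise AnalysisError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise AnalysisError("distance matrix is not symmetric")
        if (np.diag(self.d) != 0).any():
            raise AnalysisError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise AnalysisError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Embedding:
    labels: list[str]
    coords: np.ndarray  # (n, k)
    stress: float  # Kruskal stress-1
    seed: int
    n_restarts: int
    restart_stresses: list[float] = field(default_factory=list)
    iteration_stresses: list[float] = field(default_factory=list)  # best restart


def compositional_distance_matrix(
    alignment: Alignment, normalize: bool = False
) -> DistanceMatrix:
    """d(i,j) = 1/2 * sum_a (counts_i(a) - counts_j(a))^2 over the 20 states.

    With ``normalize`` the counts are replaced by frequencies (not the
    published formula; off by default).
    """
    if alignment.n_taxa < 2:
        raise AnalysisError("need at least two taxa")
    vecs = np.vstack(
        [
            composition_counts(alignment.matrix[i]).counts
            if not normalize
            else composition_counts(alignment.matrix[i]).frequencies()
            for i in range(alignment.n_taxa)
        ]
    ).astype(float)
    diff = vecs[:, None, :] - vecs[None, :, :]
    d = 0.5 * (diff**2).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(alignment.taxon_labels), d)


# ---------------------------------------------------------------------------
# NMDS (SMACOF with isotonic disparities)
# ---------------------------------------------------------------------------

def stress1(coords: np.ndarray, d: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a distance matrix."""
    d_cond = squareform(np.asarray(d, float), checks=False)
    delta = pdist(coords)
    dhat = _isotonic_disparities(d_cond, delta)
    denom = (delta**2).sum()
    if denom == 0:
        return 1.0
    return float(np.sqrt(((delta - dhat) ** 2).sum() / denom))


def _isotonic_disparities(d_cond: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Monotone fit of configuration distances to the rank order of d.

    Kruskal's primary approach to ties: within a block of tied
    dissimilarities the current distances are pre-sorted ascending so
    the monotonicity constraint does not bind inside the block; pooled
    averaging then happens only where the isotonic constraint is
    violated.
    """
    order = np.lexsort((delta, d_cond))
    iso = IsotonicRegression()
    fitted = iso.fit_transform(np.arange(order.size, dtype=float), delta[order])
    dhat = np.empty_like(delta)
    dhat[order] = fitted
    return dhat


def _guttman_transform(coords: np.ndarray, dhat_cond: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    delta = squareform(pdist(coords))
    dhat = squareform(dhat_cond, checks=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, dhat / delta, 0.0)
    b = -ratio
    np.fill_diagonal(b, -b.sum(axis=1))
    return b @ coords / n


def _smacof_single(
    d_cond: np.ndarray, n: int, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, float, list[float]]:
    scale = d_cond.max() or 1.0
    coords = rng.normal(size=(n, k)) * scale
    trace: list[float] = []
    best_coords, best_stress = coords, np.inf
    prev = np.inf
    for _ in range(max_iter):
        delta = pdist(coords)
        if not delta.any():
            break
        dhat = _isotonic_disparities(d_cond, delta)
        s = float(np.sqrt(((delta - dhat) ** 2).sum() / (delta**2).sum()))
        if s < best_stress:
            best_stress, best_coords = s, coords.copy()
        if s > prev:  # SMACOF overshoot: keep the best seen and stop
            break
        trace.append(s)
        if prev - s < tol:
            break
        prev = s
        # rescale disparities to the configuration norm for the Guttman
        # step (stress-1 itself is scale-free)
        norm = np.sqrt((delta**2).sum() / max((dhat**2).sum(), 1e-300))
        coords = _guttman_transform(coords, dhat * norm)
    return best_coords, best_stress, trace


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> Embedding:
    """Best-of-restarts non-metric MDS embedding of a distance matrix."""
    n = d.n
    if k >= n:
        raise AnalysisError(f"embedding dimension k={k} must be < n_taxa={n}")
    d_cond = d.condensed()
    if not d_cond.any():
        raise AnalysisError("all distances are zero; nothing to embed")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    restart_stresses: list[float] = []
    for _ in range(n_restarts):
        coords, stress, trace = _smacof_single(d_cond, n, k, rng, max_iter, tol)
        restart_stresses.append(stress)
        if best is None or stress < best[1]:
            best = (coords, stress, trace)
    coords, stress, trace = best
    coords = coords - coords.mean(axis=0)  # centre for reproducible reports
    return Embedding(
        labels=list(d.labels),
        coords=coords,
        stress=stress,
        seed=seed,
        n_restarts=n_restarts,
        restart_stresses=restart_stresses,
        iteration_stresses=trace,
    )


def plot_embedding(
    emb: Embedding, path: str, groups: dict[str, str] | None = None
) -> None:
    """Scatter plot of a 2-D embedding, optionally coloured by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if groups:
        names = sorted(set(groups.values()))
        cmap = plt.get_cmap("tab10")
        for gi, g in enumerate(names):
            idx = [i for i, lab in enumerate(emb.labels) if groups.get(lab) == g]
            if not idx:
                continue
            pts = emb.coords[idx]
            ax.scatter(pts[:, 0], pts[:, 1], label=g, color=cmap(gi % 10), s=25)
            if len(idx) >= 3:
                try:
                    from scipy.spatial import ConvexHull

                    hull = ConvexHull(pts)
                    poly = pts[np.append(hull.vertices, hull.vertices[0])]
                    ax.plot(poly[:, 0], poly[:, 1], color=cmap(gi % 10), lw=0.8)
                except Exception:
                    pass
        ax.legend(fontsize=8)
    else:
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=25, color="0.3")
    ax.set_title(f"NMDS (stress-1 = {emb.stress:.4f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
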