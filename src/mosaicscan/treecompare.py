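"""Branch-length-aware tree comparison.

Implements the K tree score: the comparison tree is rescaled by the
factor K* that minimizes the squared branch-length difference to the
reference, with branches matched by bipartition and missing branches
treated as length 0.  Also provides the Robinson-Foulds topology
distance and the all-pairs window similarity matrix used to visualize
phylogenetic mosaicism along a locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .phylo import Window
from .trees import PhyloTree, Split


@dataclass(frozen=True)
class TreeComparison:
    k_factor: float
    k_score: float
    rf_distance: int
    n_shared_bipartitions: int
    n_unique_ref: int
    n_unique_comp: int


def k_tree_score(reference: PhyloTree, comparison: PhyloTree) -> TreeComparison:
    """Scale ``comparison`` onto ``reference`` and score the residual.

    Over the union of bipartitions of the two trees (missing branches
    length 0), the closed-form optimal scale is
    K* = sum(b_comp * b_ref) / sum(b_comp^2), and the score is
    sqrt(sum((K* b_comp - b_ref)^2)).  Terminal branches participate;
    the RF distance counts internal bipartitions unique to either tree.
    """
    if reference.leaf_labels != comparison.leaf_labels:
        raise ValueError("leaf sets differ; refusing to prune")
    br = reference.bipartitions()
    bc = comparison.bipartitions()
    union = set(br) | set(bc)
    r = np.array([br.get(s, 0.0) for s in union])
    c = np.array([bc.get(s, 0.0) for s in union])
    denom = float(c @ c)
    k = float(r @ c) / denom if denom > 0 else 0.0
    score = float(np.sqrt(((k * c - r) ** 2).sum()))
    n = reference.n_leaves
    ref_int = {s for s in br if 1 < len(s) < n - 1}
    comp_int = {s for s in bc if 1 < len(s) < n - 1}
    return TreeComparison(
        k_factor=k,
        k_score=score,
        rf_distance=len(ref_int ^ comp_int),
        n_shared_bipartitions=len(set(br) & set(bc)),
        n_unique_ref=len(ref_int - comp_int),
        n_unique_comp=len(comp_int - ref_int),
    )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: symmetric-difference count of internal
    bipartitions.  Zero-length internal branches are excluded (treated
    as polytomies)."""
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError("leaf sets differ; refusing to prune")
    s1 = set(t1.internal_bipartitions(min_length=0.0))
    s2 = set(t2.internal_bipartitions(min_length=0.0))
    return len(s1 ^ s2)


@dataclass
class WindowTreeSet:
    """One tree per sliding window, with per-window skip flags."""

    windows: List[Window]
    trees: List[Optional[PhyloTree]]
    skip_reasons: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.windows) != len(self.trees):
            raise ValueError("one tree (or skip) required per window")

    @property
    def active_indices(self) -> List[int]:
        return [i for i, t in enumerate(self.trees) if t is not None]


@dataclass
class SimilarityMatrix:
    """Window-by-window grid of symmetrized K scores (the mosaic heatmap)."""

    windows: List[Window]
    values: np.ndarray  # (w, w); NaN where either window was skipped
    mask: np.ndarray  # (w,) bool, True = skipped

    def to_tsv(self, path) -> None:
        starts = [str(w.start) for w in self.windows]
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(starts) + "\n")
            for i, s in enumerate(starts):
                row = "\t".join(
                    "NA" if np.isnan(v) else f"{v:.6f}" for v in self.values[i]
                )
                fh.write(f"{s}\t{row}\n")


def window_similarity_matrix(wts: WindowTreeSet) -> SimilarityMatrix:
    """All-pairs K scores between window trees.

    The K score is asymmetric (one tree is scaled onto the other), so
    the stored value for a pair is the mean of the two directions;
    skipped windows are masked with NaN.
    """
    active = wts.active_indices
    if len(active) < 2:
        raise ValueError("need at least 2 non-skipped windows")
    w = len(wts.windows)
    vals = np.full((w, w), np.nan)
    biparts = {i: wts.trees[i].bipartitions() for i in active}
    # flatten each tree's splits once; pair scoring works on dicts
    for ai, i in enumerate(active):
        vals[i, i] = 0.0
        bi = biparts[i]
        for j in active[ai + 1 :]:
            bj = biparts[j]
            s_ij = _pair_score(bi, bj)
            s_ji = _pair_score(bj, bi)
            m = 0.5 * (s_ij + s_ji)
            vals[i, j] = m
            vals[j, i] = m
    mask = np.array([t is None for t in wts.trees])
    return SimilarityMatrix(windows=list(wts.windows), values=vals, mask=mask)


def _pair_score(br: Dict[Split, float], bc: Dict[Split, float]) -> float:
    """K score of comparison splits ``bc`` against reference ``br``."""
    union = set(br) | set(bc)
    sum_rc = 0.0
    sum_cc = 0.0
    for s in union:
        c = bc.get(s, 0.0)
        if c:
            sum_cc += c * c
            sum_rc += br.get(s, 0.0) * c
    k = sum_rc / sum_cc if sum_cc > 0 else 0.0
    acc = 0.0
    for s in union:
        d = k * bc.get(s, 0.0) - br.get(s, 0.0)
        acc += d * d
    return float(np.sqrt(acc))


def plot_similarity_heatmap(
    sim: SimilarityMatrix,
    path,
    segment_sidecar: Optional[Sequence[Tuple[str, int, int, str]]] = None,
):  # pragma: no cover - plotting convenience
    """Render the window-by-window similarity grid to an image file.

    ``segment_sidecar`` rows are (name, start_bp, end_bp, tree_label)
    and draw gene-boundary lines.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    starts = [w.start for w in sim.windows]
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(
        sim.values,
        origin="lower",
        extent=[starts[0], starts[-1], starts[0], starts[-1]],
        cmap="viridis_r",
    )
    fig.colorbar(im, ax=ax, label="K tree score (symmetrized)")
    if segment_sidecar:
        for _name, s, _e, _lab in segment_sidecar:
            ax.axvline(s, color="w", lw=0.5)
            ax.axhline(s, color="w", lw=0.5)
    ax.set_xlabel("window start (bp)")
    ax.set_ylabel("window start (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
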