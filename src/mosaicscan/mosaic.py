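"""Mosaic-locus detection.

Turns per-window trees and their similarity matrix into biological
calls: which windows are phylogenetically incongruent with a reference
(species) tree, how the locus segments into regions of shared history,
where the recombination breakpoints fall, and whether the incongruent
region carries discrete alleles among the strains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .phylo import Alignment, Window, jc_distance_matrix
from .treecompare import SimilarityMatrix, WindowTreeSet, k_tree_score
from .trees import PhyloTree

__all__ = [
    "CongruenceProfile",
    "Segmentation",
    "SegmentCall",
    "AlleleAssignment",
    "congruence_profile",
    "segment_windows",
    "call_mosaic",
    "cluster_alleles",
]

# a robust z uses the normal-consistency constant for the MAD
_MAD_SCALE = 1.4826


@dataclass
class CongruenceProfile:
    """Per-window distance to the reference tree.

    A window is flagged incongruent only when it shows both a
    branch-length signal (robust z of the K score above ``z_threshold``)
    and a topological signal (normalized RF above
    ``rf_threshold_fraction``); requiring both avoids flagging windows
    that differ from the reference by rate variation alone.
    """

    window_indices: List[int]  # indices into the full window list
    windows: List[Window]
    k_scores: np.ndarray
    rf_distances: np.ndarray
    z_scores: np.ndarray
    rf_fractions: np.ndarray
    flags: np.ndarray  # bool
    z_threshold: float
    rf_threshold_fraction: float


def congruence_profile(
    wts: WindowTreeSet,
    reference: PhyloTree,
    z_threshold: float = 2.0,
    rf_threshold_fraction: float = 0.4,
) -> CongruenceProfile:
    """K score and RF distance of every non-skipped window tree to the
    reference, with robust z-scores (median/MAD over windows) and the
    two-signal incongruence flag."""
    active = wts.active_indices
    if not active:
        raise ValueError("all windows skipped")
    ref_leaves = reference.leaf_labels
    for i in active:
        if wts.trees[i].leaf_labels != ref_leaves:
            raise ValueError(f"window {i}: leaf set differs from reference")
    n = len(ref_leaves)
    ks, rfs = [], []
    for i in active:
        cmpres = k_tree_score(reference, wts.trees[i])
        ks.append(cmpres.k_score)
        rfs.append(cmpres.rf_distance)
    k_arr = np.asarray(ks)
    rf_arr = np.asarray(rfs, dtype=float)
    # Baseline from the least-divergent half of the windows: incongruence
    # can only increase the distance to the reference, and a plain
    # median/MAD breaks down when divergent plus boundary-straddling
    # windows approach half of the locus.
    lower = np.sort(k_arr)[: max(len(k_arr) // 2, 2)]
    med = float(np.median(lower))
    mad = float(np.median(np.abs(lower - med)))
    if mad > 0:
        z = (k_arr - med) / (_MAD_SCALE * mad)
    else:
        z = np.where(k_arr > med, np.inf, 0.0)
    denom = 2.0 * (n - 3) if n > 3 else 1.0
    rf_frac = rf_arr / denom
    flags = (z > z_threshold) & (rf_frac > rf_threshold_fraction)
    return CongruenceProfile(
        window_indices=list(active),
        windows=[wts.windows[i] for i in active],
        k_scores=k_arr,
        rf_distances=rf_arr.astype(int),
        z_scores=z,
        rf_fractions=rf_frac,
        flags=flags,
        z_threshold=z_threshold,
        rf_threshold_fraction=rf_threshold_fraction,
    )


@dataclass
class Segmentation:
    """Contiguous runs of windows sharing a phylogenetic signal.

    ``segments`` holds positions into the profile's active-window order;
    every non-skipped window belongs to exactly one segment.
    """

    segments: List[List[int]]
    windows: List[Window]  # active windows, in order
    merge_scores: List[float] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_span_bp(self, s: int) -> Tuple[int, int]:
        seg = self.segments[s]
        return self.windows[seg[0]].start, self.windows[seg[-1]].end


def segment_windows(sim: SimilarityMatrix, max_segments: int = 8) -> Segmentation:
    """Contiguity-constrained agglomerative segmentation.

    Every window starts as its own segment; the adjacent pair with the
    smallest mean between-segment K score is merged repeatedly.  Merging
    stops when the next candidate score exceeds mean + 2 SD of the
    scores already merged (an adaptive step-change criterion), but
    continues regardless while more than ``max_segments`` remain.
    """
    active = [i for i in range(len(sim.windows)) if not sim.mask[i]]
    windows = [sim.windows[i] for i in active]
    if len(active) == 0:
        raise ValueError("all windows skipped")
    S = sim.values[np.ix_(active, active)]
    segments: List[List[int]] = [[i] for i in range(len(active))]
    merged: List[float] = []

    def between(a: List[int], b: List[int]) -> float:
        return float(S[np.ix_(a, b)].mean())

    while len(segments) > 1:
        scores = [
            between(segments[s], segments[s + 1]) for s in range(len(segments) - 1)
        ]
        s_best = int(np.argmin(scores))
        s_min = scores[s_best]
        if (
            len(segments) <= max_segments
            and len(merged) >= 2
            and s_min > np.mean(merged) + 2.0 * np.std(merged, ddof=1)
        ):
            break
        segments[s_best] = segments[s_best] + segments.pop(s_best + 1)
        merged.append(s_min)
    return Segmentation(segments=segments, windows=windows, merge_scores=merged)


@dataclass(frozen=True)
class SegmentCall:
    start_bp: int
    end_bp: int
    status: str  # congruent | incongruent | mixed
    fraction_flagged: float
    mean_z: float
    mean_rf_fraction: float


def call_mosaic(
    profile: CongruenceProfile,
    seg: Segmentation,
    incongruent_fraction: float = 0.8,
    congruent_fraction: float = 0.2,
) -> Tuple[List[SegmentCall], List[float]]:
    """Vote each segment's windows into a status and report breakpoints.

    A segment is incongruent when more than 80% of its windows carry the
    incongruence flag, congruent below 20%, and mixed in between (the
    intermediate-phylogeny case).  Adjacent segments sharing a status are
    coalesced into regions, and breakpoints are the midpoints between the
    window centers flanking each transition into or out of an
    incongruent region, in alignment bp.
    """
    if len(profile.windows) != len(seg.windows):
        raise ValueError("profile and segmentation cover different windows")
    statuses: List[str] = []
    for s in range(seg.n_segments):
        frac = float(profile.flags[seg.segments[s]].mean())
        if frac > incongruent_fraction:
            statuses.append("incongruent")
        elif frac < congruent_fraction:
            statuses.append("congruent")
        else:
            statuses.append("mixed")
    # coalesce same-status neighbors into regions
    regions: List[Tuple[str, List[int]]] = []
    for s, status in enumerate(statuses):
        if regions and regions[-1][0] == status:
            regions[-1][1].extend(seg.segments[s])
        else:
            regions.append((status, list(seg.segments[s])))
    calls: List[SegmentCall] = []
    for status, idx in regions:
        finite_z = profile.z_scores[idx][np.isfinite(profile.z_scores[idx])]
        calls.append(
            SegmentCall(
                start_bp=seg.windows[idx[0]].start,
                end_bp=seg.windows[idx[-1]].end,
                status=status,
                fraction_flagged=float(profile.flags[idx].mean()),
                mean_z=float(finite_z.mean()) if finite_z.size else float("inf"),
                mean_rf_fraction=float(profile.rf_fractions[idx].mean()),
            )
        )
    breakpoints: List[float] = []
    for s in range(len(regions) - 1):
        one_incongruent = (regions[s][0] == "incongruent") != (
            regions[s + 1][0] == "incongruent"
        )
        if one_incongruent:
            left = seg.windows[regions[s][1][-1]]
            right = seg.windows[regions[s + 1][1][0]]
            breakpoints.append(0.5 * (left.center + right.center))
    return calls, breakpoints


@dataclass
class AlleleAssignment:
    region: Tuple[int, int]
    clusters: Dict[str, int]  # strain -> cluster index, 1 = largest
    n_clusters: int
    gap_statistic: float  # largest merge-height gap / median gap


def cluster_alleles(
    alignment: Alignment,
    region: Tuple[int, int],
    min_region_length: int = 100,
) -> AlleleAssignment:
    """Cluster strains by whole-region JC distance.

    Average-linkage hierarchical clustering of the strains on the JC
    distance matrix of the region; the dendrogram is cut at the largest
    gap between successive merge heights provided that gap exceeds twice
    the median gap — otherwise a single cluster (no discrete alleles) is
    reported.  Clusters are numbered by decreasing size.
    """
    start, end = region
    if end - start < min_region_length:
        raise ValueError(
            f"region [{start}, {end}) shorter than {min_region_length} bp"
        )
    if alignment.n_sequences < 4:
        raise ValueError("need >= 4 strains to call alleles")
    dm = jc_distance_matrix(alignment.slice(start, end))
    Z = hierarchy.linkage(squareform(dm.values, checks=False), method="average")
    heights = Z[:, 2]
    gaps = np.diff(heights)
    labels = np.ones(dm.n, dtype=int)
    gap_stat = 0.0
    if gaps.size > 0 and heights[-1] > 0:
        g = int(np.argmax(gaps))
        med = float(np.median(gaps))
        gap_stat = float(gaps[g] / med) if med > 0 else float("inf")
        if gaps[g] > 2.0 * med:
            cut = 0.5 * (heights[g] + heights[g + 1])
            labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    # relabel by decreasing cluster size (ties: lower original label first)
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    order = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    clusters = {dm.labels[i]: remap[labels[i]] for i in range(dm.n)}
    return AlleleAssignment(
        region=(start, end),
        clusters=clusters,
        n_clusters=len(order),
        gap_statistic=gap_stat,
    )
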