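"""End-to-end sliding-window incongruence scan.

Wires the primitives together: window the alignment, build a JC+NJ tree
per window, compare all window trees pairwise (K score), profile each
window against a reference tree, segment the locus, call
congruent/incongruent/mixed regions with breakpoints, and cluster the
strains of the incongruent region into alleles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .mosaic import (
    AlleleAssignment,
    CongruenceProfile,
    SegmentCall,
    Segmentation,
    call_mosaic,
    cluster_alleles,
    congruence_profile,
    segment_windows,
)
from .phylo import Alignment, WindowingParams, jc_distance_matrix, make_windows, nj_tree
from .treecompare import SimilarityMatrix, WindowTreeSet, window_similarity_matrix
from .trees import PhyloTree

__all__ = ["ScanResult", "build_window_trees", "scan"]


def build_window_trees(
    alignment: Alignment,
    params: WindowingParams | None = None,
    min_comparable_fraction: float = 0.5,
) -> WindowTreeSet:
    """One NJ tree per sliding window.

    A window is skipped (flagged, not dropped) when any sequence pair
    has fewer than ``min_comparable_fraction`` usable (A/C/G/T-vs-
    A/C/G/T) sites, or no usable sites at all.
    """
    params = params or WindowingParams()
    windows = make_windows(alignment.length, params)
    trees, skips = [], {}
    for w in windows:
        sub = alignment.slice(w.start, w.end)
        try:
            dm = jc_distance_matrix(sub)
        except ValueError as exc:
            trees.append(None)
            skips[w.index] = f"window [{w.start},{w.end}): {exc}"
            continue
        if dm.min_comparable_fraction() < min_comparable_fraction:
            trees.append(None)
            skips[w.index] = (
                f"window [{w.start},{w.end}): a pair has < "
                f"{min_comparable_fraction:.0%} comparable sites"
            )
            continue
        trees.append(nj_tree(dm))
    return WindowTreeSet(windows=windows, trees=trees, skip_reasons=skips)


@dataclass
class ScanResult:
    window_trees: WindowTreeSet
    similarity: SimilarityMatrix
    profile: CongruenceProfile
    segmentation: Segmentation
    calls: List[SegmentCall]
    breakpoints: List[float]
    alleles: Optional[AlleleAssignment]

    @property
    def incongruent_regions(self) -> List[Tuple[int, int]]:
        return [(c.start_bp, c.end_bp) for c in self.calls if c.status == "incongruent"]

    def summary(self) -> dict:
        return {
            "n_windows": len(self.window_trees.windows),
            "n_skipped": len(self.window_trees.skip_reasons),
            "n_segments": len(self.calls),
            "n_incongruent": sum(c.status == "incongruent" for c in self.calls),
            "breakpoints_bp": list(self.breakpoints),
            "n_allele_clusters": self.alleles.n_clusters if self.alleles else None,
        }

    def write_segments_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start_bp\tend_bp\tstatus\tfraction_flagged\tmean_z\tmean_rf\n")
            for c in self.calls:
                fh.write(
                    f"{c.start_bp}\t{c.end_bp}\t{c.status}\t"
                    f"{c.fraction_flagged:.4f}\t{c.mean_z:.4f}\t{c.mean_rf_fraction:.4f}\n"
                )

    def write_alleles_tsv(self, path) -> None:
        if self.alleles is None:
            raise ValueError("no incongruent region; no allele assignment to write")
        with open(path, "w") as fh:
            fh.write("strain\tcluster\n")
            for strain in sorted(self.alleles.clusters):
                fh.write(f"{strain}\t{self.alleles.clusters[strain]}\n")

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def scan(
    alignment: Alignment,
    reference: PhyloTree,
    params: WindowingParams | None = None,
    z_threshold: float = 2.0,
    rf_threshold_fraction: float = 0.4,
    max_segments: int = 8,
    min_comparable_fraction: float = 0.5,
    cluster_incongruent_region: bool = True,
) -> ScanResult:
    """Run the full scan of an alignment against a reference tree.

    When at least one incongruent segment is called and clustering is
    requested, strains are clustered into alleles over the union span of
    the incongruent segments.
    """
    wts = build_window_trees(alignment, params, min_comparable_fraction)
    sim = window_similarity_matrix(wts)
    profile = congruence_profile(wts, reference, z_threshold, rf_threshold_fraction)
    seg = segment_windows(sim, max_segments=max_segments)
    calls, breakpoints = call_mosaic(profile, seg)
    alleles = None
    if cluster_incongruent_region:
        inc = [c for c in calls if c.status == "incongruent"]
        if inc:
            region = (min(c.start_bp for c in inc), max(c.end_bp for c in inc))
            alleles = cluster_alleles(alignment, region)
    return ScanResult(
        window_trees=wts,
        similarity=sim,
        profile=profile,
        segmentation=seg,
        calls=calls,
        breakpoints=breakpoints,
        alleles=alleles,
    )
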