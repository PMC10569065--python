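"""Congruence profiling, segmentation, mosaic calling, allele clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import mosaicscan as ms
from mosaicscan.phylo import DistanceMatrix
from mosaicscan.treecompare import WindowTreeSet
from mosaicscan.synthetic import Segment, SegmentLayout

from oracles import random_additive_matrix


def _random_tree(n, seed):
    rng = np.random.default_rng(seed)
    D, _, _ = random_additive_matrix(n, rng)
    labels = [f"L{i}" for i in range(n)]
    return ms.nj_tree(DistanceMatrix(labels, D, np.zeros((n, n), bool)))


def _wts(trees):
    wins = [ms.Window(index=i, start=50 * i, end=50 * i + 500) for i in range(len(trees))]
    return WindowTreeSet(windows=wins, trees=list(trees))


# -------------------------------------------------------- congruence profile


def test_profile_reference_vs_itself_no_flags():
    ref = _random_tree(8, 1)
    prof = ms.congruence_profile(_wts([ref] * 6), ref)
    assert np.allclose(prof.k_scores, 0.0)
    assert not prof.flags.any()


def test_profile_leafset_mismatch():
    ref = _random_tree(8, 1)
    other = _random_tree(6, 2)
    with pytest.raises(ValueError):
        ms.congruence_profile(_wts([other] * 4), ref)


def test_profile_flags_fall_inside_donor_segment(mosaic_truth):
    mt = mosaic_truth
    wts = ms.build_window_trees(mt.alignment)
    prof = ms.congruence_profile(wts, mt.species_tree)
    flagged_windows = [w for w, f in zip(prof.windows, prof.flags) if f]
    assert flagged_windows, "donor windows should be flagged"
    # flagged windows fall inside the donor segment +- one window width
    for w in flagged_windows:
        assert w.start >= 2800 - 500 and w.end <= 5300 + 500
    # and the donor core is solidly flagged
    core = [f for w, f in zip(prof.windows, prof.flags) if w.start >= 2800 and w.end <= 5300]
    assert np.mean(core) > 0.9


def test_profile_null_false_positive_rate():
    """Windows simulated on the reference tree alone are essentially
    never flagged (both signals must fire)."""
    null_layout = SegmentLayout((Segment("g", 2000, "species"),))
    n_flagged = 0
    n_total = 0
    for seed in range(5):
        mt = ms.simulate_mosaic(
            ms.SeqSimConfig(n_strains=16, donor_divergence=0.3, layout=null_layout, seed=seed)
        )
        wts = ms.build_window_trees(mt.alignment)
        prof = ms.congruence_profile(wts, mt.species_tree)
        n_flagged += int(prof.flags.sum())
        n_total += len(prof.flags)
    assert n_flagged / n_total < 0.05


# ------------------------------------------------------------- segmentation


def test_segmentation_homogeneous_single_segment():
    t = _random_tree(6, 3)
    sim = ms.window_similarity_matrix(_wts([t] * 8))
    seg = ms.segment_windows(sim)
    assert seg.n_segments == 1


def test_segmentation_isolates_divergent_block():
    t1 = _random_tree(6, 4)
    t2 = _random_tree(6, 5)
    sim = ms.window_similarity_matrix(_wts([t1] * 8 + [t2] * 4 + [t1] * 8))
    seg = ms.segment_windows(sim)
    assert seg.n_segments == 3
    assert seg.segments[1] == list(range(8, 12))


def test_segmentation_single_window():
    t = _random_tree(6, 6)
    wins = [ms.Window(index=0, start=0, end=500)]
    sim = ms.SimilarityMatrix(windows=wins, values=np.zeros((1, 1)), mask=np.array([False]))
    seg = ms.segment_windows(sim)
    assert seg.n_segments == 1


def test_segmentation_respects_max_segments(mosaic_truth):
    wts = ms.build_window_trees(mosaic_truth.alignment)
    sim = ms.window_similarity_matrix(wts)
    seg = ms.segment_windows(sim, max_segments=8)
    assert seg.n_segments <= 8


# ------------------------------------------------------------- call_mosaic


def _profile_with_flags(flags):
    k = np.asarray(flags, dtype=float)
    wins = [ms.Window(index=i, start=50 * i, end=50 * i + 500) for i in range(len(flags))]
    return ms.CongruenceProfile(
        window_indices=list(range(len(flags))),
        windows=wins,
        k_scores=k,
        rf_distances=k.astype(int),
        z_scores=k * 10,
        rf_fractions=k,
        flags=np.asarray(flags, dtype=bool),
        z_threshold=2.0,
        rf_threshold_fraction=0.4,
    )


def _seg(windows, groups):
    return ms.Segmentation(segments=[list(g) for g in groups], windows=windows)


def test_call_all_flagged_single_region_no_breakpoints():
    prof = _profile_with_flags([True] * 10)
    seg = _seg(prof.windows, [range(0, 5), range(5, 10)])
    calls, bps = ms.call_mosaic(prof, seg)
    assert [c.status for c in calls] == ["incongruent"]
    assert bps == []


def test_call_half_flagged_is_mixed():
    prof = _profile_with_flags([True, False] * 5)
    seg = _seg(prof.windows, [range(10)])
    calls, _ = ms.call_mosaic(prof, seg)
    assert calls[0].status == "mixed"


def test_call_breakpoints_at_incongruent_boundaries():
    flags = [False] * 5 + [True] * 5 + [False] * 5
    prof = _profile_with_flags(flags)
    seg = _seg(prof.windows, [range(0, 5), range(5, 10), range(10, 15)])
    calls, bps = ms.call_mosaic(prof, seg)
    assert [c.status for c in calls] == ["congruent", "incongruent", "congruent"]
    # midpoints between adjacent window centers at each transition
    assert bps == [
        pytest.approx(0.5 * (prof.windows[4].center + prof.windows[5].center)),
        pytest.approx(0.5 * (prof.windows[9].center + prof.windows[10].center)),
    ]


# -------------------------------------------------------- allele clustering


def test_cluster_alleles_recovers_partition(mosaic_truth):
    mt = mosaic_truth
    res = ms.cluster_alleles(mt.alignment, (2800, 5300))
    assert res.n_clusters == 2
    ids = sorted(mt.partition.assignment)
    truth = [mt.partition.assignment[i] for i in ids]
    pred = [res.clusters[i] for i in ids]
    assert adjusted_rand_score(truth, pred) == 1.0


def test_cluster_alleles_gap_separates_alleles_from_null(mosaic_truth):
    """The merge-height gap behind a real two-allele split dwarfs
    whatever gap a species-tree-only region shows."""
    mt = mosaic_truth
    donor = ms.cluster_alleles(mt.alignment, (2800, 5300))
    null = ms.cluster_alleles(mt.alignment, (0, 1900))
    assert donor.n_clusters == 2
    assert donor.gap_statistic > 2 * null.gap_statistic


def test_cluster_alleles_identical_sequences():
    aln = ms.Alignment(["a", "b", "c", "d"], ["ACGT" * 50] * 4)
    res = ms.cluster_alleles(aln, (0, 200))
    assert res.n_clusters == 1


def test_cluster_alleles_region_too_short(mosaic_truth):
    with pytest.raises(ValueError):
        ms.cluster_alleles(mosaic_truth.alignment, (0, 50))


# ----------------------------------------------------------- full pipeline


def test_scan_end_to_end(mosaic_truth):
    mt = mosaic_truth
    res = ms.scan(mt.alignment, mt.species_tree)
    assert res.summary()["n_incongruent"] == 1
    assert len(res.breakpoints) == 2
    b1, b2 = sorted(res.breakpoints)
    assert abs(b1 - 2800) <= 250
    assert abs(b2 - 5300) <= 250
    assert res.alleles is not None and res.alleles.n_clusters == 2


def test_scan_report_outputs(tmp_path, mosaic_truth):
    mt = mosaic_truth
    res = ms.scan(mt.alignment, mt.species_tree)
    res.write_segments_tsv(tmp_path / "segments.tsv")
    res.write_alleles_tsv(tmp_path / "alleles.tsv")
    res.write_summary_json(tmp_path / "summary.json")
    import json

    seg_lines = (tmp_path / "segments.tsv").read_text().strip().splitlines()
    assert seg_lines[0].startswith("start_bp")
    summary = json.loads((tmp_path / "summary.json").read_text())
    assert summary["n_incongruent"] == 1
    allele_lines = (tmp_path / "alleles.tsv").read_text().strip().splitlines()
    assert len(allele_lines) == 1 + mt.alignment.n_sequences
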