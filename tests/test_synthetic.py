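"""Ground-truth generators: trees, mosaic alignments, dose tables,
efficiency replicates."""

import numpy as np
import pytest

import mosaicscan as ms
from mosaicscan.synthetic import Segment, SegmentLayout


# ------------------------------------------------------------ species tree


def test_species_tree_structure_and_determinism():
    t = ms.simulate_species_tree(4, seed=1)
    assert t.n_leaves == 4
    assert t.n_edges == 5  # unrooted binary 4-leaf tree
    assert all(v > 0 for v in t.bipartitions().values())
    assert t.to_newick() == ms.simulate_species_tree(4, seed=1).to_newick()
    assert t.to_newick() != ms.simulate_species_tree(4, seed=2).to_newick()


def test_species_tree_mean_depth_rescaled():
    # Yule trees grown in real time are ultrametric: every leaf-to-leaf
    # path through the root spans twice the target depth
    t = ms.simulate_species_tree(12, seed=9, mean_depth=0.1)
    labels = sorted(t.leaf_labels)
    d = t.leaf_path_distance(labels[0], labels[-1])
    assert d <= 0.2 + 1e-9


def test_species_tree_rejects_small():
    with pytest.raises(ValueError):
        ms.simulate_species_tree(3, seed=1)


# -------------------------------------------------------------- donor tree


def test_donor_tree_contains_allele_split(mosaic_truth):
    mt = mosaic_truth
    bip = mt.donor_tree.bipartitions()
    ga = frozenset(mt.partition.group("A"))
    gb = frozenset(mt.partition.group("B"))
    first = min(mt.donor_tree.leaf_labels)
    key = gb if first in ga else ga
    assert key in bip
    assert bip[key] == pytest.approx(0.3)


def test_donor_tree_discordant_with_species(mosaic_truth):
    mt = mosaic_truth
    assert ms.rf_distance(mt.species_tree, mt.donor_tree) > 0


def test_donor_tree_concordant_partition_gives_existing_split():
    species = ms.simulate_species_tree(8, seed=4)
    # pick an actual species clade as allele A
    internal = ms.tree_bipartitions(species)
    n = species.n_leaves
    clade = next(s for s in internal if 2 <= len(s) <= n - 2)
    part = ms.AllelePartition(
        {lab: ("A" if lab in clade else "B") for lab in species.leaf_labels}
    )
    donor = ms.derive_donor_tree(species, part, donor_divergence=0.25)
    # the A|B split is shared, so it contributes nothing to RF
    shared = set(species.internal_bipartitions()) & set(donor.internal_bipartitions())
    assert clade in shared or (species.leaf_labels - clade) in shared


def test_donor_tree_single_allele_rejected():
    species = ms.simulate_species_tree(6, seed=2)
    part = ms.AllelePartition({lab: "A" for lab in species.leaf_labels})
    with pytest.raises(ValueError):
        ms.derive_donor_tree(species, part, 0.3)


# ---------------------------------------------------------- seq evolution


def test_evolve_zero_branch_lengths_identical_sequences():
    t = ms.PhyloTree.from_newick("(A:0.0,B:0.0,(C:0.0,D:0.0):0.0);")
    layout = SegmentLayout((Segment("g", 200, "species"),))
    cfg = ms.SeqSimConfig(n_strains=4, donor_divergence=0.3, layout=layout, seed=1)
    aln = ms.evolve_alignment(cfg, t, t)
    seqs = {aln.sequence(i) for i in aln.ids}
    assert len(seqs) == 1


def test_evolve_length_conservation_and_determinism():
    layout = SegmentLayout(
        (
            Segment("left", 1000, "species"),
            Segment("mid", 2500, "donor"),
            Segment("right", 1000, "species"),
        )
    )
    cfg = ms.SeqSimConfig(n_strains=6, donor_divergence=0.3, layout=layout, seed=5)
    species = ms.simulate_species_tree(6, seed=5)
    part = ms.AllelePartition.random(sorted(species.leaf_labels), seed=6)
    donor = ms.derive_donor_tree(species, part, 0.3)
    a1 = ms.evolve_alignment(cfg, species, donor)
    a2 = ms.evolve_alignment(cfg, species, donor)
    assert a1.length == 4500
    assert np.array_equal(a1.matrix, a2.matrix)


def test_evolve_leafset_mismatch_rejected():
    t1 = ms.PhyloTree.from_newick("(A:0.1,B:0.1,(C:0.1,D:0.1):0.1);")
    t2 = ms.PhyloTree.from_newick("(A:0.1,B:0.1,(C:0.1,E:0.1):0.1);")
    cfg = ms.SeqSimConfig(
        n_strains=4,
        donor_divergence=0.3,
        layout=SegmentLayout((Segment("g", 100, "donor"),)),
        seed=1,
    )
    with pytest.raises(ValueError):
        ms.evolve_alignment(cfg, t1, t2)


def test_evolve_jc_expected_p_distance():
    """Observed p-distance matches the closed-form JC expectation
    0.75 (1 - exp(-4 d / 3)) within 3 binomial SEs at L = 10^4."""
    # two leaves at total path distance 0.3
    t = ms.PhyloTree.from_newick("(A:0.15,B:0.15,(C:0.1,D:0.1):0.1);")
    L = 10_000
    layout = SegmentLayout((Segment("g", L, "species"),))
    cfg = ms.SeqSimConfig(n_strains=4, donor_divergence=0.3, layout=layout, seed=11)
    aln = ms.evolve_alignment(cfg, t, t)
    sa = np.frombuffer(aln.sequence("A").encode(), dtype=np.uint8)
    sb = np.frombuffer(aln.sequence("B").encode(), dtype=np.uint8)
    p_obs = float((sa != sb).mean())
    p_exp = 0.75 * (1 - np.exp(-0.4))  # ~0.2473
    se = np.sqrt(p_exp * (1 - p_exp) / L)
    assert abs(p_obs - p_exp) < 3 * se


def test_layout_validation():
    with pytest.raises(ValueError):
        Segment("g", 0, "species")
    with pytest.raises(ValueError):
        Segment("g", 10, "other")
    with pytest.raises(ValueError):
        SegmentLayout((Segment("g", 10, "donor"), Segment("g", 20, "species")))
    lay = ms.default_layout()
    assert lay.total_length == 5800
    assert lay.donor_intervals() == [(2800, 4400), (4400, 5300)]


def test_layout_sidecar_roundtrip(tmp_path):
    p = tmp_path / "segments.tsv"
    ms.default_layout().write_sidecar(p)
    rows = [l.split("\t") for l in p.read_text().strip().splitlines()[1:]]
    assert [r[0] for r in rows] == ["appD", "appF", "appC", "appA", "appB", "yjbA"]
    assert int(rows[-1][2]) == 5800


# ------------------------------------------------------------- dose tables


def _model():
    return ms.DoseResponseModel(emin=1.0, emax=109.0, k=1.5, n=1.0)


def test_dose_noiseless_equals_prediction():
    cfg = ms.DoseSimConfig(
        model=_model(), concentrations=[0.1, 1.0, 10.0], replicates=2, noise_cv=0.0, seed=1
    )
    data = ms.simulate_dose_response(cfg)
    for _, row in data.frame.iterrows():
        assert row["value"] == pytest.approx(
            ms.predict_response(_model(), row["concentration_uM"])
        )


def test_dose_determinism_and_validation():
    cfg = ms.DoseSimConfig(model=_model(), concentrations=[0.1, 1.0], seed=7)
    d1 = ms.simulate_dose_response(cfg)
    d2 = ms.simulate_dose_response(cfg)
    assert d1.frame.equals(d2.frame)
    with pytest.raises(ValueError):
        ms.DoseSimConfig(model=_model(), concentrations=[1.0, 0.1], seed=1)
    with pytest.raises(ValueError):
        ms.DoseSimConfig(model=_model(), concentrations=[0.1], noise_cv=-0.1, seed=1)


def test_dose_noise_unbiased_clt():
    """Sample mean of many noisy replicates falls within 3 SEs of the
    model value (multiplicative noise has mean zero)."""
    n = 1000
    cfg = ms.DoseSimConfig(
        model=_model(), concentrations=[1.5], replicates=n, noise_cv=0.1, seed=3
    )
    data = ms.simulate_dose_response(cfg)
    y = ms.predict_response(_model(), 1.5)
    se = y * 0.1 / np.sqrt(n)
    assert abs(data.frame["value"].mean() - y) < 3 * se


# ------------------------------------------------------------ efficiencies


def test_efficiencies_noiseless_exact_ratio():
    g1, g2 = ms.simulate_efficiencies(
        ms.EfficiencySimConfig(true_ratio=30.0, log10_sd=0.0, n_per_group=4, seed=1)
    )
    fc = ms.log_fold_change(g1, g2)
    assert fc.ratio == pytest.approx(30.0, rel=1e-9)
    assert fc.se_log10 == pytest.approx(0.0, abs=1e-12)


def test_efficiencies_null_ratio_near_one():
    rng_seeds = np.random.default_rng(0).integers(0, 2**31 - 1, size=200)
    est = []
    for s in rng_seeds:
        g1, g2 = ms.simulate_efficiencies(
            ms.EfficiencySimConfig(true_ratio=1.0, log10_sd=0.2, n_per_group=8, seed=int(s))
        )
        est.append(ms.log_fold_change(g1, g2).ratio)
    assert np.median(est) == pytest.approx(1.0, rel=0.1)


def test_efficiencies_validation():
    with pytest.raises(ValueError):
        ms.EfficiencySimConfig(true_ratio=0.0, seed=1)
    with pytest.raises(ValueError):
        ms.EfficiencySimConfig(n_per_group=1, seed=1)
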