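"""Synthetic data with known ground truth.

Three generators feed the pipeline:

* mosaic alignments — a locus whose flanking segments evolve along a
  species tree while an internal segment follows a divergent two-allele
  "donor" tree, emulating a horizontally transferred allele pair;
* noisy dose-response tables from the erf import model;
* replicate sporulation-efficiency sets, log-normal by group.

Every generator takes a mandatory integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dose import DoseResponseData, DoseResponseModel, predict_response
from .phylo import Alignment
from .trees import PhyloTree

__all__ = [
    "AllelePartition",
    "Segment",
    "SegmentLayout",
    "SeqSimConfig",
    "DoseSimConfig",
    "EfficiencySimConfig",
    "simulate_species_tree",
    "derive_donor_tree",
    "evolve_alignment",
    "simulate_mosaic",
    "MosaicTruth",
    "simulate_dose_response",
    "simulate_efficiencies",
    "default_layout",
]


# ---------------------------------------------------------------- types


@dataclass(frozen=True)
class AllelePartition:
    """Strain -> allele label in {"A", "B"}."""

    assignment: Dict[str, str]

    def __post_init__(self):
        bad = {v for v in self.assignment.values()} - {"A", "B"}
        if bad:
            raise ValueError(f"allele labels must be 'A' or 'B', got {sorted(bad)}")

    def group(self, label: str) -> List[str]:
        return sorted(s for s, a in self.assignment.items() if a == label)

    @classmethod
    def random(cls, strain_ids: Sequence[str], seed: int) -> "AllelePartition":
        """Balanced random split of the strains into two alleles."""
        rng = np.random.default_rng(seed)
        ids = list(strain_ids)
        order = rng.permutation(len(ids))
        half = len(ids) // 2
        assign = {}
        for pos, idx in enumerate(order):
            assign[ids[idx]] = "A" if pos < half else "B"
        return cls(assign)


@dataclass(frozen=True)
class Segment:
    name: str
    length: int
    tree_label: str  # "species" | "donor"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be > 0")
        if self.tree_label not in ("species", "donor"):
            raise ValueError(f"segment {self.name!r}: tree_label must be species|donor")


@dataclass(frozen=True)
class SegmentLayout:
    segments: Tuple[Segment, ...]

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        if not self.segments:
            raise ValueError("layout needs at least one segment")

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def boundaries(self) -> List[Tuple[str, int, int, str]]:
        """(name, start, end, tree_label) rows, 0-based half-open."""
        out, pos = [], 0
        for s in self.segments:
            out.append((s.name, pos, pos + s.length, s.tree_label))
            pos += s.length
        return out

    def donor_intervals(self) -> List[Tuple[int, int]]:
        return [(a, b) for _n, a, b, lab in self.boundaries() if lab == "donor"]

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("segment\tstart\tend\ttree_label\n")
            for name, a, b, lab in self.boundaries():
                fh.write(f"{name}\t{a}\t{b}\t{lab}\n")


def default_layout() -> SegmentLayout:
    """Illustrative app-like operon layout: flanking genes on the species
    tree, a contiguous 2500 bp appA+appB block on the donor tree."""
    return SegmentLayout(
        (
            Segment("appD", 1000, "species"),
            Segment("appF", 900, "species"),
            Segment("appC", 900, "species"),
            Segment("appA", 1600, "donor"),
            Segment("appB", 900, "donor"),
            Segment("yjbA", 500, "species"),
        )
    )


@dataclass
class SeqSimConfig:
    n_strains: int = 24
    donor_divergence: float = 0.3  # expected subs/site across the A|B edge
    layout: SegmentLayout = field(default_factory=default_layout)
    substitution_rate_scale: float = 1.0
    mean_depth: float = 0.1  # mean root-to-tip depth of the species tree
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 4:
            raise ValueError("n_strains must be >= 4")
        if self.donor_divergence <= 0:
            raise ValueError("donor_divergence must be > 0")


@dataclass
class DoseSimConfig:
    model: DoseResponseModel
    concentrations: Sequence[float]
    replicates: int = 3
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(c) < 0):
            raise ValueError("concentrations must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class EfficiencySimConfig:
    true_ratio: float = 30.0
    log10_sd: float = 0.2
    n_per_group: int = 4
    baseline_log10_mean: float = -0.3  # ~50% sporulation efficiency
    seed: int = 0

    def __post_init__(self):
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        if self.log10_sd < 0:
            raise ValueError("log10_sd must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


# ----------------------------------------------------------- tree sims


class _YNode:
    __slots__ = ("children", "length", "label")

    def __init__(self):
        self.children: List["_YNode"] = []
        self.length = 0.0
        self.label: Optional[str] = None


def _yule_tree(n_leaves: int, rng: np.random.Generator) -> _YNode:
    root = _YNode()
    a, b = _YNode(), _YNode()
    root.children = [a, b]
    tips = [a, b]
    while True:
        k = len(tips)
        wait = rng.exponential(1.0 / k)
        for t in tips:
            t.length += wait
        if k == n_leaves:
            return root
        idx = int(rng.integers(k))
        parent = tips.pop(idx)
        c1, c2 = _YNode(), _YNode()
        parent.children = [c1, c2]
        tips.extend([c1, c2])


def _ynode_newick(node: _YNode, scale: float) -> str:
    if not node.children:
        return f"{node.label}:{node.length * scale:.17g}"
    inner = ",".join(_ynode_newick(c, scale) for c in node.children)
    if node.length:
        return f"({inner}):{node.length * scale:.17g}"
    return f"({inner})"


def simulate_species_tree(
    n_leaves: int, seed: int, mean_depth: float = 0.1
) -> PhyloTree:
    """Pure-birth (Yule) tree on ``n_leaves`` labelled tips, rescaled so
    the mean root-to-tip depth equals ``mean_depth`` substitutions/site.
    Returned unrooted (2n-3 edges, all lengths > 0)."""
    if n_leaves < 4:
        raise ValueError("n_leaves must be >= 4")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_leaves)))
    labels = [f"S{i + 1:0{width}d}" for i in range(n_leaves)]
    root = _yule_tree(n_leaves, rng)
    # depth is identical for every tip of a Yule tree grown in real time
    node, depth = root, 0.0
    while node.children:
        depth += node.children[0].length
        node = node.children[0]
    scale = mean_depth / depth
    # label tips in traversal order
    stack, li = [root], 0
    order: List[_YNode] = []
    while stack:
        nd = stack.pop()
        if nd.children:
            stack.extend(reversed(nd.children))
        else:
            order.append(nd)
    for nd in order:
        nd.label = labels[li]
        li += 1
    return PhyloTree.from_newick(_ynode_newick(root, scale) + ";")


def derive_donor_tree(
    species_tree: PhyloTree,
    partition: AllelePartition,
    donor_divergence: float,
) -> PhyloTree:
    """A tree whose deepest split separates allele-A strains from
    allele-B strains, with internal branch length ``donor_divergence``;
    within each allele the topology and branch lengths are the species
    tree restricted to that group."""
    leaves = species_tree.leaf_labels
    assigned = set(partition.assignment)
    if assigned != leaves:
        raise ValueError("partition must label exactly the species-tree leaves")
    group_a, group_b = partition.group("A"), partition.group("B")
    if not group_a or not group_b:
        raise ValueError("both alleles must be non-empty")
    frag_a = _clade_fragment(species_tree, group_a)
    frag_b = _clade_fragment(species_tree, group_b)
    newick = f"({frag_a}:{donor_divergence:.17g},{frag_b}:0.0);"
    return PhyloTree.from_newick(newick)


def _clade_fragment(tree: PhyloTree, labels: List[str]) -> str:
    """Newick fragment (no trailing ';') of the tree restricted to
    ``labels``, rooted so its top node is at most binary."""
    if len(labels) == 1:
        return f"{labels[0]}:0.0"
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=set(labels), suppress_unifurcations=True
    )
    if sub.seed_node.num_child_nodes() > 2:
        # subdivide the first child edge so the junction node is binary
        ch = sub.seed_node.child_nodes()[0]
        ln = ch.edge.length or 0.0
        sub.reroot_at_edge(ch.edge, length1=ln / 2.0, length2=ln / 2.0)
    s = sub.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    ).strip()
    return s.rstrip(";")


# ------------------------------------------------------ sequence evolution


def _evolve_segment(
    tree: PhyloTree, length: int, rate_scale: float, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Site-independent Jukes-Cantor evolution along ``tree``.

    Root sequence uniform over {A,C,G,T}; along a branch of length t the
    per-site substitution probability is (3/4)(1 - exp(-4t/3)), with a
    uniform choice among the three alternative bases.
    """
    dtree = tree.dendropy_tree
    seqs: Dict[int, np.ndarray] = {}
    out: Dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            seqs[id(node)] = rng.integers(0, 4, size=length, dtype=np.uint8)
        else:
            t = (node.edge.length or 0.0) * rate_scale
            p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            parent = seqs[id(node.parent_node)]
            child = parent.copy()
            if p > 0:
                hit = rng.random(length) < p
                n_hit = int(hit.sum())
                if n_hit:
                    shift = rng.integers(1, 4, size=n_hit).astype(np.uint8)
                    child[hit] = (child[hit] + shift) % 4
            seqs[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return out


def evolve_alignment(
    config: SeqSimConfig,
    species_tree: PhyloTree,
    donor_tree: PhyloTree,
) -> Alignment:
    """Concatenate segments evolved along the species or donor tree per
    the layout; all segments share one RNG stream seeded from config."""
    if species_tree.leaf_labels != donor_tree.leaf_labels:
        raise ValueError("species and donor trees must share a leaf set")
    rng = np.random.default_rng(config.seed)
    ids = sorted(species_tree.leaf_labels)
    parts: List[np.ndarray] = []
    for seg in config.layout.segments:
        tree = species_tree if seg.tree_label == "species" else donor_tree
        seqs = _evolve_segment(tree, seg.length, config.substitution_rate_scale, rng)
        parts.append(np.stack([seqs[i] for i in ids]))
    mat = np.concatenate(parts, axis=1)
    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Alignment(ids, [decode[mat[r]].tobytes().decode("ascii") for r in range(len(ids))])


@dataclass
class MosaicTruth:
    """A simulated mosaic locus bundled with its ground truth."""

    alignment: Alignment
    species_tree: PhyloTree
    donor_tree: PhyloTree
    partition: AllelePartition
    layout: SegmentLayout
    config: SeqSimConfig


def simulate_mosaic(config: SeqSimConfig) -> MosaicTruth:
    """End-to-end mosaic simulation: species tree, balanced two-allele
    partition, donor tree, and the evolved alignment."""
    species = simulate_species_tree(
        config.n_strains, seed=config.seed, mean_depth=config.mean_depth
    )
    partition = AllelePartition.random(sorted(species.leaf_labels), seed=config.seed + 1)
    donor = derive_donor_tree(species, partition, config.donor_divergence)
    aln = evolve_alignment(config, species, donor)
    return MosaicTruth(
        alignment=aln,
        species_tree=species,
        donor_tree=donor,
        partition=partition,
        layout=config.layout,
        config=config,
    )


# ---------------------------------------------------------- dose & ratios


def simulate_dose_response(config: DoseSimConfig) -> DoseResponseData:
    """Replicate responses Y*(1 + eps), eps ~ Normal(0, noise_cv),
    floored at 0."""
    rng = np.random.default_rng(config.seed)
    rows_c, rows_r, rows_v = [], [], []
    for c in config.concentrations:
        y = predict_response(config.model, c)
        eps = rng.normal(0.0, config.noise_cv, size=config.replicates) if config.noise_cv > 0 else np.zeros(config.replicates)
        vals = np.maximum(y * (1.0 + eps), 0.0)
        for r, v in enumerate(vals):
            rows_c.append(float(c))
            rows_r.append(r)
            rows_v.append(float(v))
    return DoseResponseData.from_arrays(rows_c, rows_r, rows_v)


def simulate_efficiencies(config: EfficiencySimConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Two replicate sets of positive efficiencies; group 1 log10-values
    ~ Normal(m, sd), group 2 ~ Normal(m - log10(true_ratio), sd)."""
    rng = np.random.default_rng(config.seed)
    m = config.baseline_log10_mean
    g1 = 10.0 ** rng.normal(m, config.log10_sd, size=config.n_per_group)
    g2 = 10.0 ** rng.normal(
        m - np.log10(config.true_ratio), config.log10_sd, size=config.n_per_group
    )
    return g1, g2
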