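"""Alignment and tree-building primitives.

FASTA-backed nucleotide alignments, sliding-window bookkeeping,
Jukes-Cantor distance matrices with pairwise deletion of non-ACGT
sites, and a deterministic neighbor-joining implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import PhyloTree, Split

# nucleotide codes: A=0 C=1 G=2 T=3, gap/other = 4, N = 5; only codes
# < 4 count as comparable sites
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_CODE[ord("N")] = _CODE[ord("n")] = 5
_DECODE = np.frombuffer(b"ACGT-N", dtype=np.uint8)

# the JC correction diverges at p = 3/4; saturated pairs are capped
P_CAP = 0.74999
D_MAX = 5.0


class AlignmentFormatError(ValueError):
    """Raised when an input alignment file is malformed."""


@dataclass(frozen=True)
class Window:
    """Half-open [start, end) slice of an alignment, 0-based."""

    index: int
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class WindowingParams:
    width: int = 500
    step: int = 50

    def __post_init__(self):
        if not (self.width >= self.step >= 1):
            raise ValueError(
                f"require width >= step >= 1, got width={self.width}, step={self.step}"
            )


class Alignment:
    """Equal-length nucleotide sequences keyed by strain identifier."""

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence identifiers")
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment: lengths {sorted(lengths)}")
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences differ in number")
        (L,) = lengths
        if L < 1:
            raise ValueError("zero-length alignment")
        self.ids: List[str] = ids
        mat = np.empty((len(ids), L), dtype=np.uint8)
        for r, s in enumerate(sequences):
            mat[r] = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        self.matrix = mat  # (n_seq, L) codes

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, strain_id: str) -> str:
        r = self.ids.index(strain_id)
        return self.row_str(r)

    def row_str(self, r: int) -> str:
        return _DECODE[self.matrix[r]].tobytes().decode("ascii")

    def slice(self, start: int, end: int) -> "Alignment":
        if not (0 <= start < end <= self.length):
            raise ValueError(f"slice [{start}, {end}) outside alignment of length {self.length}")
        sub = Alignment.__new__(Alignment)
        sub.ids = list(self.ids)
        sub.matrix = self.matrix[:, start:end]
        return sub

    def write_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(self.row_str(r)), id=sid, description="")
            for r, sid in enumerate(self.ids)
        ]
        SeqIO.write(recs, str(path), "fasta")


def read_alignment(path) -> Alignment:
    """Read an aligned multi-FASTA; sequences are uppercased and must be
    equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"no FASTA records in {path}")
    ref_len = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != ref_len:
            raise AlignmentFormatError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {ref_len}"
            )
    return Alignment([r.id for r in records], [str(r.seq).upper() for r in records])


def make_windows(alignment_length: int, params: WindowingParams | None = None) -> List[Window]:
    """Sliding windows at starts 0, step, 2*step, ...; a trailing partial
    window is dropped, so the count is floor((L - width)/step) + 1."""
    if alignment_length < 1:
        raise ValueError("alignment_length must be >= 1")
    params = params or WindowingParams()
    if alignment_length < params.width:
        return []
    n = (alignment_length - params.width) // params.step + 1
    return [
        Window(index=i, start=i * params.step, end=i * params.step + params.width)
        for i in range(n)
    ]


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray  # (n, n) substitutions/site, symmetric, zero diagonal
    saturated: np.ndarray  # (n, n) bool, True where p >= P_CAP
    comparable_fraction: np.ndarray | None = None  # (n, n) fraction of usable sites

    @property
    def n(self) -> int:
        return len(self.labels)

    def min_comparable_fraction(self) -> float:
        if self.comparable_fraction is None:
            return 1.0
        off = ~np.eye(self.n, dtype=bool)
        return float(self.comparable_fraction[off].min())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{lab}\t{row}\n")


def jc_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Jukes-Cantor distances with pairwise deletion.

    For each pair, sites where either sequence is not A/C/G/T are
    dropped; p = mismatches / comparable sites and
    d = -(3/4) ln(1 - (4/3) p).  Pairs with p >= 0.74999 are capped at
    d = 5.0 and flagged saturated.
    """
    X = alignment.matrix
    n, L = X.shape
    if n < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    valid = X < 4
    # pairwise comparable-site and mismatch counts
    both = valid[:, None, :] & valid[None, :, :]
    mism = (X[:, None, :] != X[None, :, :]) & both
    comp = both.sum(axis=2).astype(float)
    diff = mism.sum(axis=2).astype(float)
    off = ~np.eye(n, dtype=bool)
    if np.any(comp[off] == 0):
        i, j = np.argwhere((comp == 0) & off)[0]
        raise ValueError(
            f"no comparable sites between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(comp > 0, diff / comp, 0.0)
    saturated = (p >= P_CAP) & off
    p_safe = np.minimum(p, P_CAP)
    d = -0.75 * np.log1p(-(4.0 / 3.0) * p_safe)
    d[saturated] = D_MAX
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # symmetric by construction; guard rounding
    return DistanceMatrix(
        labels=list(alignment.ids),
        values=d,
        saturated=saturated | saturated.T,
        comparable_fraction=comp / L,
    )


def jc_correct(p: float) -> float:
    """Scalar JC correction with the saturation cap."""
    if p >= P_CAP:
        return D_MAX
    return -0.75 * float(np.log1p(-(4.0 / 3.0) * p))


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with the Q-matrix criterion.

    Ties in Q are broken by the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest member leaf),
    and negative branch-length estimates are clamped to zero; the count
    of clamped branches is exposed as ``tree.n_clamped``.  The result is
    unrooted.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(float).copy()
    # cluster state: newick fragment and lexicographic key per cluster
    frags = list(dm.labels)
    keys = list(dm.labels)
    n_clamped = 0

    def _fmt(x: float) -> str:
        return f"{x:.17g}"

    while len(frags) > 3:
        m = len(frags)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        # floating-point evaluation order makes Q slightly asymmetric;
        # decide on the upper triangle only
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin)
        i, j = min(
            ((int(a), int(b)) for a, b in cand),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            li, n_clamped = 0.0, n_clamped + 1
        if lj < 0:
            lj, n_clamped = 0.0, n_clamped + 1
        newfrag = f"({frags[i]}:{_fmt(li)},{frags[j]}:{_fmt(lj)})"
        newkey = min(keys[i], keys[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        frags = [frags[k] for k in keep] + [newfrag]
        keys = [keys[k] for k in keep] + [newkey]

    # final three-point join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = 0.5 * (d01 + d02 - d12)
    b1 = 0.5 * (d01 + d12 - d02)
    b2 = 0.5 * (d02 + d12 - d01)
    lens = []
    for b in (b0, b1, b2):
        if b < 0:
            b, n_clamped = 0.0, n_clamped + 1
        lens.append(b)
    newick = (
        f"({frags[0]}:{_fmt(lens[0])},{frags[1]}:{_fmt(lens[1])},"
        f"{frags[2]}:{_fmt(lens[2])});"
    )
    tree = PhyloTree.from_newick(newick)
    tree.n_clamped = n_clamped
    return tree


def tree_bipartitions(tree: PhyloTree) -> Dict[Split, float]:
    """One bipartition per edge, keyed canonically (the side not
    containing the lexicographically first leaf), valued by branch length."""
    return tree.bipartitions()
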