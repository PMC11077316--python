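"""Desk-scale gene phylogenies: progressive alignment, NJ, bootstrap.

The question these trees answer is topological - do the orthologs from
highly regenerative species form a cluster distinct from the diverged
paralogs of low-regenerative species? - so a deterministic distance method
(progressive alignment, protein p-distance with a Jukes-Cantor-style
correction, Saitou-Nei neighbor joining, nonparametric column-resampling
bootstrap) stands in for a maximum-likelihood run. An exporter to relaxed
PHYLIP is provided for anyone who wants to rerun a family with external ML
software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import TreeNode

from . import _alignment
from .similarity import AA_ALPHABET, ScoringScheme, local_align_score

GAP = "-"


class TreeError(ValueError):
    pass


@dataclass
class Msa:
    """Multiple sequence alignment; rows are gapped strings of equal length."""

    taxa: list[str]  # labels, conventionally "species|gene"
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise TreeError("taxa/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise TreeError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def resample_columns(self, idx: Sequence[int]) -> "Msa":
        rows = ["".join(r[j] for j in idx) for r in self.rows]
        return Msa(list(self.taxa), rows)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")

    def write_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP (name, two spaces, sequence)."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.taxa)} {self.n_columns}\n")
            for t, r in zip(self.taxa, self.rows):
                fh.write(f"{t.replace(' ', '_')}  {r}\n")


# ---------------------------------------------------------------------------
# progressive alignment

_GAP_CODE = len(AA_ALPHABET)  # column count vectors have one extra gap slot


def _profile_counts(rows: list[str]) -> np.ndarray:
    """(n_symbols+1) x L count matrix for a set of aligned rows."""
    L = len(rows[0])
    counts = np.zeros((_GAP_CODE + 1, L), dtype=np.float64)
    for r in rows:
        for j, c in enumerate(r):
            counts[_GAP_CODE if c == GAP else AA_ALPHABET.index(c), j] += 1
    return counts


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> list[str]:
    """Global affine-gap alignment of two profiles (sum-of-pairs columns)."""
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    # substitution matrix extended with a zero-scoring gap symbol row/col:
    # residues aligned against existing gaps contribute nothing.
    m = np.zeros((_GAP_CODE + 1, _GAP_CODE + 1), dtype=np.float64)
    m[:_GAP_CODE, :_GAP_CODE] = scheme.matrix
    S = (ca.T @ m @ cb) / (len(rows_a) * len(rows_b))
    steps = _alignment.nw_profile_steps(
        S.astype(np.float64), float(scheme.gap_first), float(scheme.gap_extend)
    )
    ia = ib = 0
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    for st in steps:
        if st == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ia += 1
            ib += 1
        elif st == 1:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[ia])
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[ib])
            ib += 1
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def progressive_align(
    sequences: Sequence[tuple[str, str]], scheme: ScoringScheme = ScoringScheme()
) -> Msa:
    """Progressive MSA with a UPGMA guide tree from pairwise SW score distances.

    Distance between sequences i and j is ``1 - S_ij / min(S_ii, S_jj)``
    (clipped at 0). Deterministic: scipy's linkage on the condensed matrix
    plus fixed merge order.
    """
    if not sequences:
        raise TreeError("progressive_align needs at least one sequence")
    taxa = [t for t, _ in sequences]
    if len(set(taxa)) != len(taxa):
        raise TreeError("duplicate taxon labels")
    seqs = [s for _, s in sequences]
    n = len(seqs)
    if n == 1:
        return Msa([taxa[0]], [seqs[0]])
    self_scores = [local_align_score(s, s, scheme) for s in seqs]
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            sij = local_align_score(seqs[i], seqs[j], scheme)
            denom = min(self_scores[i], self_scores[j])
            condensed.append(max(0.0, 1.0 - (sij / denom if denom > 0 else 0.0)))
    Z = linkage(np.asarray(condensed), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([taxa[i]], [seqs[i]]) for i in range(n)
    }
    for k, (a, b, _, _) in enumerate(Z):
        ta, ra = clusters.pop(int(a))
        tb, rb = clusters.pop(int(b))
        merged = _merge_profiles(ra, rb, scheme)
        clusters[n + k] = (ta + tb, merged)
    taxa_out, rows_out = clusters.popitem()[1]
    order = {t: i for i, t in enumerate(taxa_out)}
    rows_sorted = [rows_out[order[t]] for t in taxa]
    return Msa(list(taxa), rows_sorted)


# ---------------------------------------------------------------------------
# distances

#: default cap for saturated/undefined corrected distances
DISTANCE_CAP = 5.0


def distance_matrix(msa: Msa, cap: float = DISTANCE_CAP) -> np.ndarray:
    """Corrected pairwise distances with pairwise deletion of gap columns.

    p-distance over columns where neither row has a gap, corrected by the
    20-state Jukes-Cantor-style formula d = -(19/20) ln(1 - 20 p / 19) and
    capped at ``cap`` when saturated or when no comparable columns exist.
    """
    n = len(msa.taxa)
    codes = np.array(
        [[_GAP_CODE if c == GAP else AA_ALPHABET.index(c) for c in r] for r in msa.rows],
        dtype=np.int16,
    )
    is_res = codes < _GAP_CODE
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = is_res[i] & is_res[j]
            nc = int(both.sum())
            if nc == 0:
                warnings.warn(
                    f"no comparable columns between {msa.taxa[i]} and {msa.taxa[j]}; "
                    f"distance set to cap {cap}"
                )
                dij = cap
            else:
                p = float((codes[i][both] != codes[j][both]).sum()) / nc
                arg = 1.0 - 20.0 * p / 19.0
                dij = cap if arg <= 0 else min(cap, -19.0 / 20.0 * math.log(arg))
            d[i, j] = d[j, i] = dij
    return d


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(d: np.ndarray, taxa: Sequence[str]) -> TreeNode:
    """Saitou-Nei NJ with deterministic lowest-index tie-breaking.

    Returns an unrooted tree as a TreeNode with a trifurcating root (or the
    two-taxon edge). On an additive matrix this recovers the generating
    topology and branch lengths. Negative branch-length estimates are
    clamped to zero.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise TreeError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise TreeError("distance matrix must be symmetric")
    n = d.shape[0]
    if n != len(taxa):
        raise TreeError("taxa/matrix size mismatch")
    if n < 2:
        raise TreeError("need at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    D = d.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # reuse slot i for the new node
        for k in active:
            if k in (i, j):
                continue
            nd = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[i, k] = D[k, i] = max(0.0, nd)
        nodes[i] = parent
        active.remove(j)
    if len(active) == 2:
        i, j = active
        root = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = 0.0
        nodes[j].length = max(0.0, D[i, j])
    else:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        nodes[k].length = max(0.0, lk)
    return root


def _bipartitions(tree: TreeNode) -> dict[frozenset[str], TreeNode]:
    """Nontrivial bipartitions keyed by the side not containing the first leaf.

    Works on the unrooted interpretation of the (arbitrarily rooted) tree.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        key = side if ref not in side else leaves - side
        out[key] = node
    return out


def bootstrap_supports(
    msa: Msa,
    n_replicates: int = 100,
    seed: int = 0,
    scheme: ScoringScheme = ScoringScheme(),
    cap: float = DISTANCE_CAP,
) -> TreeNode:
    """Tree from the full alignment with % bootstrap support on internal edges.

    Columns are resampled with replacement per replicate; each replicate tree
    is rebuilt with distance_matrix + neighbor_joining; the support of an
    internal edge of the original tree is the percentage of replicates whose
    tree contains the same bipartition.
    """
    if n_replicates < 1:
        raise TreeError("n_replicates must be >= 1")
    tree = neighbor_joining(distance_matrix(msa, cap), msa.taxa)
    bips = _bipartitions(tree)
    counts = {key: 0 for key in bips}
    rng = np.random.default_rng(seed)
    L = msa.n_columns
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep = msa.resample_columns(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rtree = neighbor_joining(distance_matrix(rep, cap), rep.taxa)
        rbips = set(_bipartitions(rtree))
        for key in counts:
            if key in rbips:
                counts[key] += 1
    for key, node in bips.items():
        node.support = 100.0 * counts[key] / n_replicates
        node.name = f"{node.support:g}"
    return tree


def is_separated_cluster(tree: TreeNode, focal_taxa: set[str]) -> bool:
    """True iff some internal edge splits the leaves into exactly focal vs rest."""
    leaves = {t.name for t in tree.tips()}
    focal = set(focal_taxa)
    if not focal or focal == leaves:
        raise TreeError("focal taxa must be a proper nonempty subset of leaves")
    if not focal <= leaves:
        raise TreeError("focal taxa must be leaves of the tree")
    ref = min(leaves)
    key = frozenset(focal) if ref not in focal else frozenset(leaves - focal)
    return key in _bipartitions(tree)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Newick with bootstrap supports as internal node labels."""
    tree.write(str(path), format="newick")
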