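"""Protein distance matrices, neighbor-joining trees, bootstrap support.

Distances default to the p-distance with pairwise gap deletion (the common
default of distance-based phylogenetics packages); a Poisson-corrected
variant (-ln(1 - p)) is available. Multiple alignments are built with
biotite's progressive aligner when not supplied. The NJ implementation is
the standard Q-matrix agglomeration with deterministic tie-breaking and
recovers additive trees exactly; negative branch-length estimates are
clamped to zero and flagged. Bootstrap support resamples alignment columns
with replacement and reports, per internal edge, the percentage of replicate
NJ trees containing the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise PhyloError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise PhyloError("distances must be finite and non-negative")


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating root."""

    root: TreeNode
    negative_branches_clamped: int = 0

    def leaves(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical non-trivial bipartitions (one side per internal edge)."""
        all_leaves = frozenset(self.root.leaves())
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(_canonical(side, all_leaves))
                walk(child)

        walk(self.root)
        return out

    def supports(self) -> dict[frozenset[str], float]:
        all_leaves = frozenset(self.root.leaves())
        out = {}

        def walk(node: TreeNode):
            for child, _ in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1 and child.support is not None:
                    out[_canonical(side, all_leaves)] = child.support
                walk(child)

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.label
            inner = ",".join(f"{fmt(c)}:{ln:.6f}" for c, ln in node.children)
            sup = ""
            if with_support and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}"

        return fmt(self.root) + ";"


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    other = all_leaves - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


# ---------------------------------------------------------------------------
# alignment and distances
# ---------------------------------------------------------------------------

def align_proteins(proteins: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment (biotite); returns gapped sequences."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    labels = list(proteins)
    seqs = [bseq.ProteinSequence(proteins[l]) for l in labels]
    matrix = balign.SubstitutionMatrix.std_protein_matrix()
    alignment, *_ = balign.align_multiple(seqs, matrix, gap_penalty=(-10, -1))
    gapped = alignment.get_gapped_sequences()
    return dict(zip(labels, gapped))


def protein_distance_matrix(proteins: dict[str, str], model: str = "p_distance",
                            aligned: bool = False) -> DistanceMatrix:
    """Pairwise distances over a multiple alignment, pairwise gap deletion.

    ``model`` is "p_distance" or "poisson". With ``aligned=True`` the inputs
    are taken as pre-aligned gapped sequences of equal length.
    """
    if model not in ("p_distance", "poisson"):
        raise PhyloError(f"unknown distance model {model!r}")
    if len(proteins) < 3:
        raise PhyloError("need at least 3 sequences")
    gapped = dict(proteins) if aligned else align_proteins(proteins)
    labels = sorted(gapped)
    lengths = {len(s) for s in gapped.values()}
    if len(lengths) != 1:
        raise PhyloError("aligned sequences must have equal length")
    arr = np.array([list(gapped[l]) for l in labels])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            compared = int(ok.sum())
            if compared == 0:
                raise PhyloError(f"all-gap pair {labels[i]}/{labels[j]}")
            p = float((arr[i][ok] != arr[j][ok]).sum()) / compared
            if model == "poisson":
                if p >= 1:
                    raise PhyloError("poisson distance saturated (p = 1)")
                p = -log(1 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard NJ agglomeration; exact on additive inputs.

    Tie-breaking on the Q criterion is by the sorted label pair, so the
    output is deterministic and invariant to input label order.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("need at least 3 taxa")
    order = np.argsort(dm.labels)
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float)
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    names: list[str] = list(labels)
    clamped = 0
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        i, j = min((tuple(sorted((int(a), int(b)))) for a, b in ties),
                   key=lambda ij: (names[ij[0]], names[ij[1]]))
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        new = TreeNode(children=[(nodes[i], float(li)), (nodes[j], float(lj))])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [new]
        names = [names[x] for x in keep] + [min(names[i], names[j])]
    # final three-way join with closed-form branch lengths
    (a, b, c) = range(3)
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    lens = []
    for ln in (la, lb, lc):
        if ln < 0:
            clamped += 1
            ln = 0.0
        lens.append(float(ln))
    root = TreeNode(children=[(nodes[a], lens[0]), (nodes[b], lens[1]),
                              (nodes[c], lens[2])])
    return PhyloTree(root=root, negative_branches_clamped=clamped)


def bootstrap_support(proteins: dict[str, str], n_replicates: int = 1000,
                      seed: int = 0, model: str = "p_distance",
                      aligned: bool = False) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    With ``n_replicates=0`` the plain tree is returned with no supports.
    """
    gapped = dict(proteins) if aligned else align_proteins(proteins)
    dm = protein_distance_matrix(gapped, model=model, aligned=True)
    tree = neighbor_joining(dm)
    if n_replicates < 1:
        return tree
    labels = sorted(gapped)
    arr = np.array([list(gapped[l]) for l in labels])
    ncol = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = {l: "".join(arr[i, cols]) for i, l in enumerate(labels)}
        rep_dm = protein_distance_matrix(rep, model=model, aligned=True)
        rep_bps = neighbor_joining(rep_dm).bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_leaves = frozenset(labels)

    def annotate(node: TreeNode):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                child.support = 100.0 * counts[_canonical(side, all_leaves)] / n_replicates
            annotate(child)

    annotate(tree.root)
    return tree


def clade_mean_distance(dm: DistanceMatrix, membership: dict[str, str],
                        ) -> dict[str, float | None]:
    """Mean pairwise distance within each subfamily; singletons flagged None."""
    idx = {l: i for i, l in enumerate(dm.labels)}
    groups: dict[str, list[str]] = {}
    for gene, sub in membership.items():
        groups.setdefault(sub, []).append(gene)
    out: dict[str, float | None] = {}
    for sub, genes in sorted(groups.items()):
        if len(genes) < 2:
            out[sub] = None
            continue
        vals = [dm.d[idx[a], idx[b]]
                for k, a in enumerate(genes) for b in genes[k + 1 :]]
        out[sub] = float(np.mean(vals))
    return out
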