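"""Supermatrix assembly, gene-by-codon partitions, parsimony search,
bootstrap support, consensus trees, and interchange export for external
ML/coalescent tools.

The parsimony machinery is exact Fitch counting vectorised over site
patterns; the heuristic search is random stepwise addition followed by
NNI branch swapping, deterministic under a seed. Likelihood analyses are
exported (relaxed PHYLIP / NEXUS / partition files), not reimplemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import seqio
from .alignfilter import GeneAlignment, nj_tree
from .dna import STATE_MASK

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Supermatrix

@dataclass
class Supermatrix:
    taxa: list
    rows: list                      # one concatenated string per taxon
    boundaries: list                # (gene_id, start, end, codon_offset)
    missing_char: str = "?"
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gene_block(self, gene_id: str) -> GeneAlignment:
        for g, s, e, off in self.boundaries:
            if g == gene_id:
                return GeneAlignment(gene_id, list(self.taxa),
                                     [r[s:e] for r in self.rows], off)
        raise KeyError(gene_id)

    def state_masks(self) -> np.ndarray:
        """(n_taxa, L) uint8 Fitch state sets (A=1,C=2,G=4,T=8; unions
        for ambiguity; 15 for gap/missing)."""
        if "masks" not in self._cache:
            lut = np.full(256, 15, dtype=np.uint8)
            for ch, m in STATE_MASK.items():
                lut[ord(ch)] = m
            lut[ord(self.missing_char)] = 15
            mat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
            self._cache["masks"] = lut[mat.reshape(len(self.rows), -1)]
        return self._cache["masks"]

    def acgt_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, valid): 0..3 for A/C/G/T, anything else invalid."""
        if "codes" not in self._cache:
            lut = np.full(256, 255, dtype=np.uint8)
            for i, b in enumerate("ACGT"):
                lut[ord(b)] = i
            mat = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
            codes = lut[mat.reshape(len(self.rows), -1)]
            self._cache["codes"] = (codes, codes != 255)
        return self._cache["codes"]


def concatenate(gene_alignments, missing_char: str = "?") -> Supermatrix:
    """Concatenate gene alignments over the union of their taxa; taxa
    missing a gene get a block of missing characters."""
    taxa: list[str] = []
    for aln in gene_alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    seen = set()
    parts = {t: [] for t in taxa}
    boundaries = []
    pos = 0
    for aln in gene_alignments:
        if aln.gene_id in seen:
            raise ValueError(f"duplicate gene_id {aln.gene_id!r}")
        seen.add(aln.gene_id)
        L = aln.n_columns
        for t in taxa:
            parts[t].append(aln.row(t) if t in aln.taxa else missing_char * L)
        boundaries.append((aln.gene_id, pos, pos + L, aln.codon_offset))
        pos += L
    return Supermatrix(taxa, ["".join(parts[t]) for t in taxa], boundaries,
                       missing_char)


# ---------------------------------------------------------------------------
# Partitions

@dataclass
class PartitionScheme:
    """One named subset per (gene, codon position)."""
    subsets: list           # (name, gene_id, codon_position 1-3)

    def __len__(self):
        return len(self.subsets)


def initial_partitions(sm: Supermatrix) -> PartitionScheme:
    """Gene-by-codon partitions: 3 subsets per gene."""
    subsets = []
    for gene_id, s, e, off in sm.boundaries:
        if off not in (0, 1, 2):
            raise ValueError(f"{gene_id}: no codon frame assigned")
        for p in (1, 2, 3):
            subsets.append((f"{gene_id}_pos{p}", gene_id, p))
    return PartitionScheme(subsets)


def subset_columns(sm: Supermatrix, gene_id: str, codon_position: int
                   ) -> np.ndarray:
    """0-based supermatrix column indices of one gene x codon subset.
    Column j of a gene with codon_offset c has codon position
    ((j + c) % 3) + 1."""
    for g, s, e, off in sm.boundaries:
        if g == gene_id:
            first = (codon_position - 1 - off) % 3
            return np.arange(s + first, e, 3)
    raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# Fitch parsimony

def _as_nested(tree) -> tuple:
    """dendropy Tree or newick -> nested tuples of taxon labels."""
    if isinstance(tree, tuple):
        return tree
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)

    def conv(node):
        if node.is_leaf():
            return node.taxon.label
        kids = [conv(c) for c in node.child_nodes()]
        while len(kids) > 2:          # treat any basal polytomy as nested
            kids = [(kids[0], kids[1])] + kids[2:]
        return tuple(kids) if len(kids) == 2 else kids[0]

    return conv(tree.seed_node)


def _leaves(t):
    if isinstance(t, str):
        yield t
    else:
        yield from _leaves(t[0])
        yield from _leaves(t[1])


def _nested_to_newick(t) -> str:
    def s(x):
        return x if isinstance(x, str) else f"({s(x[0])},{s(x[1])})"
    return s(t) + ";"


def _fitch_vec(tree, mask_of: dict):
    """Vectorised Fitch over site patterns; returns (states, changes)."""
    if isinstance(tree, str):
        return mask_of[tree], 0
    ls, lc = _fitch_vec(tree[0], mask_of)
    rs, rc = _fitch_vec(tree[1], mask_of)
    inter = ls & rs
    union = ls | rs
    empty = inter == 0
    states = np.where(empty, union, inter)
    return states, lc + rc + empty.astype(np.int64)


def _patterns(sm: Supermatrix):
    if "patterns" not in sm._cache:
        masks = sm.state_masks()
        uniq, counts = np.unique(masks, axis=1, return_counts=True)
        sm._cache["patterns"] = (uniq, counts.astype(np.int64))
    return sm._cache["patterns"]


def fitch_score(tree, sm: Supermatrix, weights: np.ndarray | None = None) -> int:
    """Exact minimum number of state changes under Fitch parsimony.
    Ambiguity codes and missing data are full/partial state sets."""
    nested = _as_nested(tree)
    leaf_set = set(_leaves(nested))
    if leaf_set != set(sm.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    if weights is None:
        pats, w = _patterns(sm)
    else:
        pats, w = sm.state_masks(), np.asarray(weights, dtype=np.int64)
    mask_of = {t: pats[i] for i, t in enumerate(sm.taxa)}
    _, changes = _fitch_vec(nested, mask_of)
    return int((changes * w).sum())


# ---------------------------------------------------------------------------
# Parsimony heuristic search

def _insertions(tree, leaf):
    """All trees formed by attaching ``leaf`` on each unrooted edge.

    The rooted representation has a degree-2 root, so the edges above its
    two children are one and the same unrooted edge (covered once)."""
    a, b = tree
    out = [(a, (b, leaf))]

    def rec(t, build):
        if isinstance(t, str):
            return
        l, r = t
        out.append(build(((l, leaf), r)))
        out.append(build((l, (r, leaf))))
        rec(l, lambda x, _r=r, _b=build: _b((x, _r)))
        rec(r, lambda x, _l=l, _b=build: _b((_l, x)))

    rec(a, lambda x: (x, b))
    rec(b, lambda x: (a, x))
    return out


def _nni_neighbors(tree):
    """All NNI rearrangements of a rooted-representation binary tree:
    for every internal edge, swap one child across to the sibling."""
    out = []

    def rec(t, build):
        if isinstance(t, str):
            return
        l, r = t
        if not isinstance(r, str):
            out.append(build((r[0], (l, r[1]))))
            out.append(build((r[1], (r[0], l))))
        if not isinstance(l, str):
            out.append(build(((l[0], r), l[1])))
            out.append(build(((r, l[1]), l[0])))
        rec(l, lambda x, _r=r, _b=build: _b((x, _r)))
        rec(r, lambda x, _l=l, _b=build: _b((_l, x)))

    rec(tree, lambda x: x)
    return out


def mp_search(sm: Supermatrix, n_addition_replicates: int = 100,
              seed: int = 0, nni: bool = True):
    """Maximum-parsimony heuristic search: random stepwise addition then
    NNI swapping per replicate; returns (best trees as dendropy, score).
    Deterministic for a given seed."""
    taxa = list(sm.taxa)
    if len(taxa) < 4:
        t = taxa[0] if len(taxa) == 1 else tuple(taxa[:2]) \
            if len(taxa) == 2 else ((taxa[0], taxa[1]), taxa[2])
        tree = dendropy.Tree.get(data=_nested_to_newick(t), schema="newick", preserve_underscores=True)
        return [tree], fitch_score(t, sm) if len(taxa) >= 2 else 0
    rng = np.random.default_rng(seed)
    best_score = None
    best_trees: list[tuple] = []
    for _ in range(n_addition_replicates):
        order = [taxa[i] for i in rng.permutation(len(taxa))]
        tree = ((order[0], order[1]), order[2])
        for leaf in order[3:]:
            cands = _insertions(tree, leaf)
            sub = _submatrix(sm, set(_leaves(cands[0])))
            scores = [fitch_score(c, sub) for c in cands]
            tree = cands[int(np.argmin(scores))]
        score = fitch_score(tree, sm)
        if nni:
            improved = True
            while improved:
                improved = False
                for cand in _nni_neighbors(tree):
                    s = fitch_score(cand, sm)
                    if s < score:
                        tree, score = cand, s
                        improved = True
                        break
        if best_score is None or score < best_score:
            best_score, best_trees = score, [tree]
        elif score == best_score and all(
                _bipartitions_nested(tree, taxa) != _bipartitions_nested(t, taxa)
                for t in best_trees):
            best_trees.append(tree)
    trees = [dendropy.Tree.get(data=_nested_to_newick(t), schema="newick", preserve_underscores=True)
             for t in best_trees]
    return trees, int(best_score)


def _submatrix(sm: Supermatrix, taxa_subset) -> Supermatrix:
    """Row-subset view sharing the parent's site-pattern cache (the
    restricted patterns need not be minimal, only consistent)."""
    keep = [i for i, t in enumerate(sm.taxa) if t in set(taxa_subset)]
    sub = Supermatrix([sm.taxa[i] for i in keep], [sm.rows[i] for i in keep],
                      list(sm.boundaries), sm.missing_char)
    pats, w = _patterns(sm)
    sub._cache["patterns"] = (pats[keep], w)
    sub._cache["masks"] = sm.state_masks()[keep]
    return sub


# ---------------------------------------------------------------------------
# Bipartitions, bootstrap, consensus

def bipartitions(tree, taxa) -> set:
    """Non-trivial bipartitions as frozensets of the side not containing
    the anchor (first taxon in sorted order).

    On trees with branch lengths, internal edges of length <= 0 are
    treated as unresolved (a zero-length branch carries no grouping
    information); trees without lengths (e.g. parsimony topologies)
    contribute every internal edge.
    """
    taxa = sorted(taxa)
    anchor = taxa[0]
    full = set(taxa)
    out = set()

    def add(side_set):
        side = side_set if anchor not in side_set else full - side_set
        if 1 < len(side) < len(full) - 1:
            out.add(frozenset(side))

    if isinstance(tree, tuple):
        def rec(t):
            if isinstance(t, str):
                return {t}
            s = rec(t[0]) | rec(t[1])
            add(s)
            return s
        rec(tree)
        return out

    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        if node.edge.length is not None and node.edge.length <= 0:
            continue
        add({l.taxon.label for l in node.leaf_iter()})
    return out


def _bipartitions_nested(tree, taxa):
    return bipartitions(tree, taxa)


@dataclass
class SupportedTree:
    tree: dendropy.Tree
    supports: dict             # frozenset bipartition -> percent in [0, 100]

    def min_support(self) -> float:
        return min(self.supports.values()) if self.supports else 100.0


def nj_builder(sm: Supermatrix, weights: np.ndarray | None = None):
    """NJ on weighted JC distances; the default bootstrap tree builder."""
    codes, valid = sm.acgt_codes()
    n, L = codes.shape
    w = np.ones(L, dtype=np.float32) if weights is None \
        else weights.astype(np.float32)
    V = valid.astype(np.float32)
    Vw = V * w
    both = Vw @ V.T
    match = np.zeros((n, n), dtype=np.float32)
    for b in range(4):
        E = (codes == b).astype(np.float32)
        match += (E * w) @ E.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(both > 0, 1.0 - match / np.maximum(both, 1e-30), 0.0)
    np.fill_diagonal(p, 0.0)
    p = np.clip(p, 0.0, 0.999)
    d = np.where(p < 0.7499, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7498) / 3.0), 5.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return nj_tree(d.astype(float), sm.taxa)


def mp_builder(sm: Supermatrix, weights: np.ndarray | None = None,
               n_addition_replicates: int = 2, seed: int = 0):
    if weights is None:
        trees, _ = mp_search(sm, n_addition_replicates, seed)
        return trees[0]
    # weighted search: score candidate insertions under column weights
    sub = Supermatrix(sm.taxa, sm.rows, sm.boundaries, sm.missing_char)
    sub._cache["patterns"] = (sm.state_masks(), weights.astype(np.int64))
    trees, _ = mp_search(sub, n_addition_replicates, seed)
    return trees[0]


def bootstrap_support(sm: Supermatrix, tree_builder=nj_builder,
                      n_replicates: int = 1000, seed: int = 0,
                      reference_tree=None) -> SupportedTree:
    """Nonparametric bootstrap: resample columns with replacement,
    rebuild, and report for each internal bipartition of the reference
    tree the percentage of replicate trees containing it."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if reference_tree is None:
        reference_tree = tree_builder(sm)
    ref_bips = bipartitions(reference_tree, sm.taxa)
    tally = {b: 0 for b in ref_bips}
    L = sm.n_columns
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        weights = np.bincount(idx, minlength=L)
        rep_tree = tree_builder(sm, weights=weights)
        rep_bips = bipartitions(rep_tree, sm.taxa)
        for b in ref_bips & rep_bips:
            tally[b] += 1
    supports = {b: 100.0 * c / n_replicates for b, c in tally.items()}
    return SupportedTree(reference_tree, supports)


def majority_consensus(trees, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus: exactly the bipartitions occurring in
    more than ``threshold`` of the input trees."""
    trees = list(trees)
    leaf_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter())
                 for t in trees]
    if len(set(leaf_sets)) > 1:
        raise ValueError("trees have mixed leaf sets")
    tns = dendropy.TaxonNamespace(sorted(leaf_sets[0]))
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(dendropy.Tree.get(data=t.as_string(schema="newick"),
                                    schema="newick", taxon_namespace=tns))
    return tl.consensus(min_freq=threshold + 1e-9)


def bipartition_frequencies(trees, taxa) -> dict:
    """Fraction of trees containing each observed non-trivial bipartition."""
    trees = list(trees)
    tally: dict[frozenset, int] = {}
    for t in trees:
        for b in bipartitions(t, taxa):
            tally[b] = tally.get(b, 0) + 1
    return {b: c / len(trees) for b, c in tally.items()}


# ---------------------------------------------------------------------------
# Interchange export

def partition_lines(sm: Supermatrix, scheme: PartitionScheme) -> list[str]:
    """1-based inclusive column ranges with codon strides, e.g.
    ``gene1_pos1 = 1-300\\3``."""
    spans = {g: (s, e, off) for g, s, e, off in sm.boundaries}
    lines = []
    for name, gene_id, p in scheme.subsets:
        s, e, off = spans[gene_id]
        first = s + (p - 1 - off) % 3
        lines.append(f"{name} = {first + 1}-{e}\\3")
    return lines


def export_interchange(sm: Supermatrix, scheme: PartitionScheme, outdir) -> dict:
    """Write relaxed PHYLIP + NEXUS matrices, a partition definition
    file, and per-gene FASTA alignments; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["phylip"] = outdir / "supermatrix.phy"
    seqio.write_phylip(paths["phylip"], sm.taxa, sm.rows)
    lines = partition_lines(sm, scheme)
    charsets = [(l.split(" = ")[0], l.split(" = ")[1]) for l in lines]
    paths["nexus"] = outdir / "supermatrix.nex"
    seqio.write_nexus(paths["nexus"], sm.taxa, sm.rows, charsets,
                      missing=sm.missing_char)
    paths["partitions"] = outdir / "partitions.txt"
    with open(paths["partitions"], "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    gene_dir = outdir / "genes"
    gene_dir.mkdir(exist_ok=True)
    for gene_id, s, e, off in sm.boundaries:
        seqio.write_fasta(gene_dir / f"{gene_id}.fasta",
                          [(t, r[s:e]) for t, r in zip(sm.taxa, sm.rows)])
    paths["genes"] = gene_dir
    log.info("exported supermatrix (%d taxa x %d columns, %d subsets) to %s",
             len(sm.taxa), sm.n_columns, len(scheme), outdir)
    return paths
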