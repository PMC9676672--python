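"""Neighbor-joining trees, column-resampling bootstrap, and clade queries.

The tree role here is deliberately modest: the delimitation procedure needs
an unrooted topology whose internal edges carry bootstrap percentages, not a
model-based phylogeny.  Saitou–Nei neighbor joining on the p-distance matrix
provides that topology; externally inferred trees (e.g. maximum likelihood
with supports as internal Newick labels) are accepted interchangeably
through :meth:`SupportTree.from_newick`.

Determinism: when several pairs tie on the NJ Q-criterion the pair whose
(lexicographically sorted) cluster keys are smallest is joined, where a
cluster's key is the smallest leaf id it contains.  Negative branch-length
estimates are clamped to zero with the deficit logged.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np

from .distances import DistanceMatrix, encode_alignment, pdist_from_codes
from .io import Alignment, FormatError

logger = logging.getLogger(__name__)


@dataclass
class _Node:
    taxon: Optional[str] = None
    children: list = field(default_factory=list)  # [(child _Node, branch length)]


def _nj_core(D: np.ndarray, ids: tuple[str, ...], build_tree: bool = True):
    """Saitou–Nei agglomeration.

    Returns ``(root, internal_sides)`` where ``internal_sides`` is the list
    of leaf-id frozensets subtended by each internal edge created during
    agglomeration (sizes 2..n-2).  ``build_tree=False`` skips node-object
    construction and returns ``(None, internal_sides)`` — used by the
    bootstrap, which only counts bipartitions.
    """
    n0 = len(ids)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    size = 2 * n0
    big = np.zeros((size, size))
    big[:n0, :n0] = D

    act = list(range(n0))
    key = {i: ids[i] for i in range(n0)}
    leafset = {i: frozenset([ids[i]]) for i in range(n0)}
    node = {i: _Node(taxon=ids[i]) for i in range(n0)} if build_tree else None
    sides: list[frozenset] = []
    deficit = 0.0
    nxt = n0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(act) > 3:
        m = len(act)
        sub = big[np.ix_(act, act)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # Q[i, j] and Q[j, i] may differ by one ulp (subtraction order), so
        # normalize tie pairs to i < j rather than filtering on orientation
        ties = {(min(int(a), int(b)), max(int(a), int(b)))
                for a, b in np.argwhere(Q == qmin)}
        i, j = min(ties, key=lambda p: tuple(sorted((key[act[p[0]]],
                                                     key[act[p[1]]]))))
        gi, gj = act[i], act[j]
        dij = sub[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))))
        merged = leafset[gi] | leafset[gj]
        sides.append(merged)
        for k_local, gk in enumerate(act):
            if k_local in (i, j):
                continue
            dnew = 0.5 * (sub[i, k_local] + sub[j, k_local] - dij)
            big[nxt, gk] = big[gk, nxt] = dnew
        if build_tree:
            node[nxt] = _Node(children=[(node[gi], li), (node[gj], lj)])
        key[nxt] = min(key[gi], key[gj])
        leafset[nxt] = merged
        act = [g for g in act if g not in (gi, gj)] + [nxt]
        nxt += 1

    a, b, c = act
    dab, dac, dbc = big[a, b], big[a, c], big[b, c]
    if deficit:
        logger.debug("clamped %.6g of negative NJ branch length to zero", deficit)
    if not build_tree:
        return None, sides
    root = _Node(children=[
        (node[a], clamp((dab + dac - dbc) / 2)),
        (node[b], clamp((dab + dbc - dac) / 2)),
        (node[c], clamp((dac + dbc - dab) / 2)),
    ])
    return root, sides


def _to_dendropy(root: _Node, ids: Iterable[str]) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    taxa = {i: tns.new_taxon(label=i) for i in ids}
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(my: _Node, nd: dendropy.Node) -> None:
        if my.taxon is not None:
            nd.taxon = taxa[my.taxon]
        for child, bl in my.children:
            build(child, nd.new_child(edge_length=float(bl)))

    build(root, tree.seed_node)
    return tree


class SupportTree:
    """An unrooted tree whose internal edges may carry percent supports.

    Supports are held in a mapping from edge side (a frozenset of leaf ids)
    to a value in [0, 100]; both sides of an edge resolve to the same value.
    An edge with no recorded support reports ``None`` (ABSENT).
    """

    def __init__(self, tree: dendropy.Tree,
                 supports: Optional[dict[frozenset, float]] = None,
                 n_bootstrap_skipped: int = 0):
        self._tree = tree
        self.supports = dict(supports or {})
        self.n_bootstrap_skipped = n_bootstrap_skipped
        self._leafsets = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, support_scale: str = "auto",
                    strict: bool = True) -> "SupportTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        return cls._attach_label_supports(tree, support_scale, strict)

    @classmethod
    def from_newick_file(cls, path: str | Path, support_scale: str = "auto",
                         strict: bool = True) -> "SupportTree":
        return cls.from_newick(Path(path).read_text(), support_scale, strict)

    @classmethod
    def _attach_label_supports(cls, tree, support_scale, strict):
        self = cls(tree)
        labelled = []
        for nd in tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None or nd.label is None:
                continue
            try:
                val = float(nd.label)
            except ValueError:
                if strict:
                    raise FormatError(
                        f"non-numeric internal node label {nd.label!r}")
                logger.warning("ignoring non-numeric internal label %r", nd.label)
                continue
            labelled.append((nd, val))
        values = [v for _, v in labelled]
        if support_scale == "auto":
            scale = "fraction" if values and max(values) <= 1.0 else "percent"
        else:
            scale = support_scale
        if scale not in ("percent", "fraction"):
            raise ValueError(f"unknown support scale {support_scale!r}")
        factor = 100.0 if scale == "fraction" else 1.0
        ls = self._leafset_map()
        full = frozenset(self.leaf_ids)
        sided = []
        for nd, val in labelled:
            sup = val * factor
            if not 0.0 <= sup <= 100.0:
                raise FormatError(f"support {sup} outside [0, 100]")
            self.supports[ls[nd]] = sup
            sided.append((ls[nd], sup))
        # complements resolve to the same edge unless explicitly labelled
        # (a degree-2 root may label both sides of one unrooted edge)
        for side, sup in sided:
            self.supports.setdefault(full - side, sup)
        return self

    # -- structure ----------------------------------------------------------

    def _leafset_map(self):
        if self._leafsets is None:
            ls = {}
            for nd in self._tree.postorder_node_iter():
                if nd.is_leaf():
                    ls[nd] = frozenset([nd.taxon.label])
                else:
                    ls[nd] = frozenset().union(*(ls[c] for c in nd.child_nodes()))
            self._leafsets = ls
        return self._leafsets

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        return tuple(sorted(t.label for t in self._tree.taxon_namespace))

    def _internal_edges(self) -> list[tuple[frozenset, Optional[float]]]:
        """(child-side leafset, support) for each internal edge."""
        ls = self._leafset_map()
        out = []
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            out.append((ls[nd], self.support_of(ls[nd])))
        return out

    def support_of(self, side: frozenset) -> Optional[float]:
        if side in self.supports:
            return self.supports[side]
        return self.supports.get(frozenset(self.leaf_ids) - side)

    def bipartition_supports(self) -> dict[frozenset, Optional[float]]:
        """Canonical bipartition -> support; the canonical side of an edge is
        the one not containing the smallest leaf id."""
        ref = min(self.leaf_ids)
        full = frozenset(self.leaf_ids)
        out: dict[frozenset, Optional[float]] = {}
        for side, sup in self._internal_edges():
            canon = full - side if ref in side else side
            if len(canon) < 2 or len(canon) > len(full) - 2:
                continue
            prev = out.get(canon)
            out[canon] = sup if prev is None else prev
        return out

    def clades(self, outgroup: Optional[str] = None):
        """Candidate clades as ``(leafset, support)`` pairs.

        With an outgroup, the tree is rooted on its pendant edge and each
        internal edge contributes the side away from the outgroup; with
        ``None`` both sides of every internal edge are emitted.
        """
        full = frozenset(self.leaf_ids)
        if outgroup is not None and outgroup not in full:
            raise KeyError(f"unknown outgroup id {outgroup!r}")
        picked: dict[frozenset, Optional[float]] = {}

        def keep(side, sup):
            prev = picked.get(side)
            if prev is None or (sup is not None and sup > prev):
                picked[side] = sup

        for side, sup in self._internal_edges():
            comp = full - side
            if len(side) < 2 or len(comp) < 2:
                continue
            if outgroup is None:
                keep(side, sup)
                keep(comp, sup)
            else:
                keep(comp if outgroup in side else side, sup)
        return sorted(picked.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))

    # -- output -------------------------------------------------------------

    def to_newick(self, decimals: int = 3) -> str:
        ls = self._leafset_map()
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            sup = self.support_of(ls[nd])
            if sup is not None:
                txt = f"{sup:.{decimals}f}"
                if "." in txt:
                    txt = txt.rstrip("0").rstrip(".")
                nd.label = txt
        return self._tree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip() + "\n"


@dataclass(frozen=True)
class BootstrapConfig:
    """Nonparametric bootstrap settings: alignment columns are resampled with
    replacement ``replicates`` times (study default 1,000)."""

    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Neighbor-joining tree from a distance matrix (supports absent)."""
    undef = dm.undefined_pairs()
    if undef:
        raise ValueError(f"undefined distance entries for pairs: {undef[:5]}")
    # canonical internal order: results do not depend on input row order
    dm = dm.submatrix(sorted(dm.ids))
    root, _ = _nj_core(dm.d, dm.ids)
    return SupportTree(_to_dendropy(root, dm.ids))


def bootstrap_supports(aln: Alignment, cfg: BootstrapConfig = BootstrapConfig(),
                       gap_policy: str = "pairwise-exclude",
                       ambiguity_policy: str = "exclude") -> SupportTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement, recomputes
    the p-distance matrix and the NJ topology, and streams that topology's
    bipartitions into a counter; support is the percentage of successful
    replicates containing the bipartition.  Replicates that produce an
    undefined pairwise distance are skipped with a warning; the count of
    skips is kept on the returned tree.  Column draws depend only on the
    seed, so supports are invariant to the input order of sequences.
    """
    # canonical internal order (sorted ids): supports depend only on the
    # sequences and the seed, never on input row order
    order = np.argsort(np.array(aln.ids))
    ids = tuple(aln.ids[i] for i in order)
    codes = encode_alignment(aln)[order]
    dm = pdist_from_codes(codes, ids, gap_policy, ambiguity_policy)
    if dm.undefined_pairs():
        raise ValueError("point-estimate distances contain undefined pairs")
    root, point_sides = _nj_core(dm.d, ids)

    full = frozenset(ids)
    ref = min(ids)

    def canon(side: frozenset) -> frozenset:
        return full - side if ref in side else side

    rng = np.random.default_rng(cfg.seed)
    L = aln.length
    counts: Counter = Counter()
    skipped = 0
    for _ in range(cfg.replicates):
        idx = rng.integers(0, L, L)
        rep = pdist_from_codes(codes[:, idx], ids, gap_policy,
                               ambiguity_policy, warn_undefined=False)
        if np.isnan(rep.d).any():
            skipped += 1
            continue
        _, rep_sides = _nj_core(rep.d, ids, build_tree=False)
        counts.update(canon(s) for s in rep_sides)
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicate(s) skipped due to "
                      "undefined pairwise distances")
    effective = cfg.replicates - skipped
    if effective == 0:
        raise ValueError("all bootstrap replicates were skipped")

    supports: dict[frozenset, float] = {}
    for side in point_sides:
        sup = 100.0 * counts[canon(side)] / effective
        supports[side] = sup
        supports[full - side] = sup
    return SupportTree(_to_dendropy(root, ids), supports,
                       n_bootstrap_skipped=skipped)
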