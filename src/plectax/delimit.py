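"""Three-criterion haplotype-group delimitation and marker-resolution tools.

A candidate clade on the COI tree becomes a haplotype group when

1. its bootstrap support is at least ``min_support`` (default 99),
2. its within-group distance does not exceed ``max_within`` (default 6%,
   taken over the maximum pairwise distance by default), and
3. the distance from any member to its nearest non-member exceeds the
   within-group distance (single-linkage nearest neighbor).

Among nested qualifying clades the most inclusive one is kept; specimens
covered by no qualifying clade remain unassigned.  A clade of identical
sequences (within-distance exactly zero) qualifies regardless of support,
since zero-length internal edges carry no meaningful bootstrap signal.

The module also compares a fine partition against a coarser labelling (how
many COI groups collapse under one identical 18S sequence) and matches
metabarcode OTUs to Sanger references by overlap-alignment percent identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .distances import DistanceMatrix
from .io import UNASSIGNED, Alignment
from .tree import SupportTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DelimitationCriteria:
    min_support: float = 99.0
    max_within: float = 0.06
    nn_rule: bool = True
    within_statistic: str = "max"  # or "mean"

    def __post_init__(self):
        if not 0.0 <= self.max_within <= 1.0:
            raise ValueError("max_within must lie in [0, 1]")
        if self.within_statistic not in ("max", "mean"):
            raise ValueError("within_statistic must be 'max' or 'mean'")


@dataclass(frozen=True)
class GroupEvidence:
    support: Optional[float]
    within: float
    nn_distance: float


@dataclass
class GroupPartition:
    """Assignment of specimen ids to haplotype groups.

    ``assignment`` maps every input id to a group label or the
    ``UNASSIGNED`` sentinel; ``provenance`` records, per group, the support,
    within-group distance, and nearest-neighbor distance it qualified with.
    """

    assignment: dict[str, str]
    provenance: dict[str, GroupEvidence] = field(default_factory=dict)

    def groups(self) -> dict[str, frozenset]:
        out: dict[str, set] = {}
        for rid, grp in self.assignment.items():
            if grp != UNASSIGNED:
                out.setdefault(grp, set()).add(rid)
        return {g: frozenset(m) for g, m in out.items()}

    def unassigned(self) -> frozenset:
        return frozenset(r for r, g in self.assignment.items() if g == UNASSIGNED)

    @property
    def n_groups(self) -> int:
        return len(self.groups())

    @classmethod
    def from_groups(cls, groups: Mapping[str, frozenset],
                    all_ids=None) -> "GroupPartition":
        assignment = {}
        for g, members in groups.items():
            for m in members:
                if m in assignment:
                    raise ValueError(f"id {m!r} in more than one group")
                assignment[m] = g
        for rid in all_ids or ():
            assignment.setdefault(rid, UNASSIGNED)
        return cls(assignment)


def _within(dm: DistanceMatrix, idx: np.ndarray, statistic: str) -> float:
    if len(idx) < 2:
        return 0.0
    tri = dm.d[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
    return float(tri.max() if statistic == "max" else tri.mean())


def delimit(tree: SupportTree, dm: DistanceMatrix,
            criteria: DelimitationCriteria = DelimitationCriteria()
            ) -> GroupPartition:
    """Delimit haplotype groups on a supported tree.

    Candidate clades are both sides of every internal edge, the complement
    of every pendant edge (a trivial bipartition, present in every
    bootstrap replicate, hence support 100), and the full leaf set (no
    edge, support absent — it can only qualify when all sequences are
    identical).  Qualifying clades are reduced to the maximal (most
    inclusive) ones; remaining leaves are unassigned.
    """
    leaves = tree.leaf_ids
    missing = set(leaves) - set(dm.ids)
    if missing:
        raise KeyError(f"tree leaves absent from distance matrix: {sorted(missing)}")
    full = frozenset(leaves)
    pos = {rid: dm.index(rid) for rid in leaves}

    candidates: dict[frozenset, Optional[float]] = {}
    for side, sup in tree.clades(outgroup=None):
        candidates[side] = sup
    for leaf in leaves:
        comp = full - {leaf}
        if len(comp) >= 2:
            candidates.setdefault(comp, 100.0)
    candidates[full] = tree.support_of(full)

    qualifying: list[tuple[frozenset, GroupEvidence]] = []
    for side, sup in candidates.items():
        idx = np.array([pos[r] for r in side])
        within = _within(dm, idx, criteria.within_statistic)
        if within > criteria.max_within:
            continue
        if within > 0.0 and (sup is None or sup < criteria.min_support):
            continue
        outside = [pos[r] for r in full - side]
        nn = float(dm.d[np.ix_(idx, outside)].min()) if outside else float("inf")
        if criteria.nn_rule and not nn > within:
            continue
        qualifying.append((side, GroupEvidence(sup, within, nn)))

    # keep maximal clades; candidates from one tree are laminar once the
    # criteria hold, so any partial overlap indicates an internal error
    qualifying.sort(key=lambda q: (-len(q[0]), sorted(q[0])))
    kept: list[tuple[frozenset, GroupEvidence]] = []
    for side, ev in qualifying:
        nested = False
        for taken, _ in kept:
            inter = side & taken
            if not inter:
                continue
            if side <= taken:
                nested = True
                break
            raise AssertionError(
                f"overlapping non-nested qualifying clades: {sorted(side)} "
                f"vs {sorted(taken)}")
        if not nested:
            kept.append((side, ev))

    assignment = {rid: UNASSIGNED for rid in leaves}
    provenance = {}
    for k, (side, ev) in enumerate(kept, start=1):
        label = f"HG{k}"
        for rid in side:
            assignment[rid] = label
        provenance[label] = ev
    return GroupPartition(assignment, provenance)


# ---------------------------------------------------------------------------
# marker-resolution comparison


@dataclass(frozen=True)
class ResolutionReport:
    """How a fine partition collapses under a coarser labelling."""

    collapse: dict[str, tuple[str, ...]]  # coarse label -> fine groups under it
    n_fine_groups: int
    n_coarse_labels: int
    n_collapsed_fine_groups: int


def compare_partitions(fine: GroupPartition,
                       coarse: Mapping[str, str]) -> ResolutionReport:
    """Report which fine groups share a coarse label.

    ``coarse`` maps specimen ids to e.g. an identical-sequence class or an
    OTU label.  A fine group counts as collapsed when at least one other
    fine group shares a coarse label with it.
    """
    fine_groups = fine.groups()
    shared = {rid for members in fine_groups.values() for rid in members} & set(coarse)
    if not shared:
        raise ValueError("fine partition and coarse labelling share no ids")

    under: dict[str, set] = {}
    for g, members in fine_groups.items():
        for rid in members:
            if rid in coarse:
                under.setdefault(coarse[rid], set()).add(g)
    collapse = {lab: tuple(sorted(gs)) for lab, gs in under.items()}
    collapsed = {g for gs in under.values() if len(gs) > 1 for g in gs}
    return ResolutionReport(
        collapse=collapse,
        n_fine_groups=len(fine_groups),
        n_coarse_labels=len(under),
        n_collapsed_fine_groups=len(collapsed),
    )


def identity_labels(aln: Alignment, prefix: str = "seq") -> dict[str, str]:
    """Label each sequence by its identical-sequence class (18S collapse)."""
    classes: dict[str, str] = {}
    out = {}
    for rid, seq in aln.records:
        if seq not in classes:
            classes[seq] = f"{prefix}{len(classes) + 1}"
        out[rid] = classes[seq]
    return out


def adjusted_rand(a: GroupPartition | Mapping[str, str],
                  b: GroupPartition | Mapping[str, str]) -> float:
    """Adjusted Rand index between two partitions over their shared ids.

    Unassigned specimens count as singleton clusters, so a partition that
    leaves anything unassigned cannot score 1.0 against a full truth.
    """
    from sklearn.metrics import adjusted_rand_score

    def labels(p):
        m = p.assignment if isinstance(p, GroupPartition) else dict(p)
        return {
            rid: (f"__unassigned_{rid}" if lab == UNASSIGNED else lab)
            for rid, lab in m.items()
        }

    la, lb = labels(a), labels(b)
    ids = sorted(set(la) & set(lb))
    if not ids:
        raise ValueError("partitions share no ids")
    return float(adjusted_rand_score([la[i] for i in ids], [lb[i] for i in ids]))


# ---------------------------------------------------------------------------
# OTU matching by overlap-alignment identity


def overlap_identity(query: str, ref: str, band: Optional[int] = None
                     ) -> tuple[float, int, int]:
    """Percent identity of the best end-free (overlap) alignment.

    Global alignment with free leading and trailing gaps on both sequences
    (match +1, mismatch/gap -1), appropriate when the query is a
    subfragment of the reference region.  Returns ``(identity, matches,
    aligned_columns)`` where identity is matches divided by the number of
    alignment columns between the first and last aligned residue pair.

    ``band`` restricts the dynamic program to diagonals within ``band`` of
    the corridor spanned by the two sequence lengths; ``None`` runs the
    full matrix.
    """
    q = np.frombuffer(query.upper().encode("ascii"), dtype=np.uint8)
    r = np.frombuffer(ref.upper().encode("ascii"), dtype=np.uint8)
    m, n = len(q), len(r)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    NEG = np.int32(-(10 ** 6))
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    jidx = np.arange(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        s = np.where(r == q[i - 1], 1, -1).astype(np.int32)
        # candidates from the previous row (diagonal and vertical moves)
        B = np.empty(n + 1, dtype=np.int32)
        B[0] = H[i, 0]  # free leading gap in the reference
        B[1:] = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] - 1)
        if band is not None:
            # permitted diagonals: -band <= j - i <= (n - m) + band
            off = jidx[1:] - i
            B[1:] = np.where((off >= -band) & (off <= (n - m) + band), B[1:], NEG)
        # linear-gap closure of horizontal moves in one cumulative-max scan:
        # H[i, j] = max_{k <= j} (B[k] - (j - k))
        H[i] = np.maximum.accumulate(B + jidx) - jidx
    # free trailing gaps: best score on last row or last column
    end_candidates = [(H[m, j], m, j) for j in range(n + 1)]
    end_candidates += [(H[i, n], i, n) for i in range(m + 1)]
    _, ei, ej = max(end_candidates, key=lambda t: (t[0], t[1] + t[2]))
    # traceback over the core (stop at a free end)
    i, j = ei, ej
    matches = 0
    columns = 0
    while i > 0 and j > 0:
        h = H[i, j]
        s = 1 if q[i - 1] == r[j - 1] else -1
        if h == H[i - 1, j - 1] + s:
            matches += int(s == 1)
            columns += 1
            i, j = i - 1, j - 1
        elif h == H[i - 1, j] - 1:
            columns += 1
            i -= 1
        elif h == H[i, j - 1] - 1:
            columns += 1
            j -= 1
        else:  # free-end start (H reset by row/column 0 boundary)
            break
    if columns == 0:
        return 0.0, 0, 0
    return matches / columns, matches, columns


def match_otus(otus: Alignment, refs: Alignment, min_identity: float = 0.99,
               band: Optional[int] = None
               ) -> dict[str, tuple[Optional[str], float]]:
    """Match each OTU to its best reference by overlap identity.

    Returns otu id -> ``(ref id, identity)`` when the best identity reaches
    ``min_identity``, else ``(None, best identity)``.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    out = {}
    for oid, oseq in otus.records:
        scored = []
        for rid, rseq in refs.records:
            ident, matches, _ = overlap_identity(oseq.replace("-", ""),
                                                 rseq.replace("-", ""), band=band)
            scored.append((ident, matches, rid))
        ident, _, rid = max(scored, key=lambda t: (t[0], t[1], t[2]))
        out[oid] = (rid, ident) if ident >= min_identity else (None, ident)
    return out
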