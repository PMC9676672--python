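"""Pairwise p-distances and within/between-group distance summaries.

The p-distance between two aligned sequences is the proportion of compared
sites at which they differ, uncorrected for multiple substitutions.  By
default a site enters a pair's comparison only if both sequences carry an
unambiguous base there (pairwise deletion of gaps and IUPAC ambiguity
codes); both the gap and the ambiguity treatment are configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .io import UNASSIGNED, Alignment

logger = logging.getLogger(__name__)

# Bitmask encoding: one bit per base, ambiguity codes are unions, gap is 0.
_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE = {
    "-": 0, "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 3, "R": 5, "W": 9, "S": 6, "Y": 10, "K": 12,
    "V": 7, "H": 11, "D": 13, "B": 14, "N": 15,
}
_SINGLE = frozenset(_BITS.values())

GAP_POLICIES = ("pairwise-exclude", "include-as-mismatch")
AMBIGUITY_POLICIES = ("exclude", "compatible-match")


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode an alignment as a (n, L) uint8 bitmask matrix."""
    lut = np.zeros(128, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    rows = [np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in aln.records]
    return lut[np.vstack(rows)]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of p-distances with per-pair comparable-site counts.

    Entries with zero comparable sites are NaN (flagged undefined), never a
    silent zero; ``defined`` marks usable off-diagonal entries.
    """

    ids: tuple[str, ...]
    d: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n) and self.comparable_sites.shape == (n, n)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.d)

    def index(self, rid: str) -> int:
        return self.ids.index(rid)

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(self.d))
        return [(self.ids[a], self.ids[b]) for a, b in zip(i, j) if a < b]

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = np.array([self.index(i) for i in ids])
        return DistanceMatrix(tuple(ids), self.d[np.ix_(idx, idx)],
                              self.comparable_sites[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


def pdist_from_codes(codes: np.ndarray, ids: tuple[str, ...],
                     gap_policy: str = "pairwise-exclude",
                     ambiguity_policy: str = "exclude",
                     warn_undefined: bool = True) -> DistanceMatrix:
    """p-distance matrix from a pre-encoded bitmask alignment.

    Separated from :func:`p_distance_matrix` so the bootstrap can resample
    columns of the encoded matrix without re-encoding sequences.
    """
    if gap_policy not in GAP_POLICIES:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if ambiguity_policy not in AMBIGUITY_POLICIES:
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")

    if ambiguity_policy == "exclude":
        valid = np.isin(codes, list(_SINGLE))
    else:  # compatible-match: any non-gap character is informative
        valid = codes != 0
    if gap_policy == "include-as-mismatch":
        # every column is compared; a gap (or excluded ambiguity) opposite a
        # base is a mismatch, two gaps match as equal states
        comparable = np.full((len(ids), len(ids)), codes.shape[1], dtype=np.int64)
        eff = np.where(valid, codes, 0)
        if ambiguity_policy == "compatible-match":
            match = (eff[:, None, :] & eff[None, :, :]).astype(bool) | (
                (eff[:, None, :] == 0) & (eff[None, :, :] == 0))
        else:
            match = eff[:, None, :] == eff[None, :, :]
        mism = (~match).sum(axis=2)
    else:
        both = valid[:, None, :] & valid[None, :, :]
        comparable = both.sum(axis=2)
        if ambiguity_policy == "compatible-match":
            match = (codes[:, None, :] & codes[None, :, :]).astype(bool)
        else:
            match = codes[:, None, :] == codes[None, :, :]
        mism = (both & ~match).sum(axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, mism / np.maximum(comparable, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(ids, d, comparable)
    if warn_undefined:
        for a, b in dm.undefined_pairs():
            warnings.warn(f"pair ({a}, {b}) has no comparable sites; "
                          "distance undefined", stacklevel=2)
    return dm


def p_distance_matrix(aln: Alignment, gap_policy: str = "pairwise-exclude",
                      ambiguity_policy: str = "exclude") -> DistanceMatrix:
    """Pairwise p-distance matrix over all sequences of an alignment."""
    return pdist_from_codes(encode_alignment(aln), aln.ids, gap_policy,
                            ambiguity_policy)


# ---------------------------------------------------------------------------
# group summaries


@dataclass(frozen=True)
class WithinStats:
    mean: float
    max: float
    n_pairs: int
    defined: bool


@dataclass(frozen=True)
class GroupDistanceSummary:
    """Within-group mean/max and between-group mean pairwise distances.

    A singleton group has no within-group pairs; its statistics are flagged
    undefined rather than reported as zero (rendered "n/c" in reports).
    """

    within: dict[str, WithinStats]
    between: dict[tuple[str, str], float]

    def between_mean(self, a: str, b: str) -> float:
        return self.between[tuple(sorted((a, b)))]


def _as_groups(partition) -> dict[str, tuple[str, ...]]:
    if hasattr(partition, "groups"):
        return dict(partition.groups())
    groups: dict[str, list[str]] = {}
    for rid, grp in partition.items():
        if grp != UNASSIGNED:
            groups.setdefault(grp, []).append(rid)
    return {g: tuple(v) for g, v in groups.items()}


def group_distance_summary(dm: DistanceMatrix, partition) -> GroupDistanceSummary:
    """Summarize a distance matrix over a grouping of its sequence ids.

    ``partition`` is a mapping id -> group label (or a GroupPartition);
    unassigned specimens are excluded from all statistics.
    """
    groups = _as_groups(partition)
    idx: dict[str, np.ndarray] = {}
    for g, members in groups.items():
        try:
            idx[g] = np.array([dm.index(m) for m in members])
        except ValueError as exc:
            raise KeyError(f"group {g!r} has member absent from the "
                           f"distance matrix") from exc

    within: dict[str, WithinStats] = {}
    for g, ix in idx.items():
        if len(ix) < 2:
            within[g] = WithinStats(float("nan"), float("nan"), 0, False)
            continue
        sub = dm.d[np.ix_(ix, ix)]
        tri = sub[np.triu_indices(len(ix), k=1)]
        within[g] = WithinStats(float(np.mean(tri)), float(np.max(tri)),
                                tri.size, True)

    between: dict[tuple[str, str], float] = {}
    for a, b in combinations(sorted(idx), 2):
        cross = dm.d[np.ix_(idx[a], idx[b])]
        between[(a, b)] = float(np.mean(cross))
    return GroupDistanceSummary(within, between)


def distance_range(summary: GroupDistanceSummary):
    """Extrema of the between-group mean distances, with attaining pairs."""
    defined = {k: v for k, v in summary.between.items() if not np.isnan(v)}
    if len(summary.within) < 2 or not defined:
        raise ValueError("distance range requires at least two groups")
    argmin = min(defined, key=lambda k: (defined[k], k))
    argmax = max(defined, key=lambda k: (defined[k], tuple(reversed(k))))
    return defined[argmin], defined[argmax], argmin, argmax


def summary_table(summary: GroupDistanceSummary, decimals: int = 6) -> pd.DataFrame:
    """Lower-triangular report: within-group values on the diagonal (``n/c``
    when not calculable), between-group means below it."""
    labels = sorted(summary.within)
    tab = pd.DataFrame("", index=labels, columns=labels, dtype=object)
    for g in labels:
        w = summary.within[g]
        tab.loc[g, g] = round(w.mean, decimals) if w.defined else "n/c"
    for (a, b), v in summary.between.items():
        lo, hi = sorted((a, b), key=labels.index)
        tab.loc[hi, lo] = round(v, decimals)
    return tab
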