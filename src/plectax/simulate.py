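"""Synthetic barcode datasets with the structure the pipeline assumes.

The generator emulates the statistical shape of the study system rather
than a coalescent history: K sequence clusters on a fixed-length alignment
(default 393, the trimmed COI amplicon) with small within-cluster and large
between-cluster divergence; companion 18S-like sequences that are identical
across designated clusters (the observed resolution collapse of the NF1
region); and two-morphotype measurement draws whose c' distributions are
separated the way the short- and long-tailed voucher measurements are.

Cluster construction: a random ancestral sequence is mutated at
``ceil(d_between * L)`` sites per cluster — site sets disjoint across
clusters, so between-cluster divergence is controlled by construction — to
give one founder per cluster; each member then mutates its founder at
``Binomial(L, d_within)`` uniformly chosen sites.  Substitutions draw
uniformly from the three non-current bases (Jukes–Cantor-like); no indels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .delimit import GroupPartition
from .io import Alignment, write_alignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Per-morphotype measurement distributions, (mean, sd), micrometres except
#: the dimensionless ratios.  Drawn from the empirical ranges of the two
#: voucher morphotypes; edit here, never inside the operations.
MORPH_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "short": {
        "c_prime": (2.4, 0.25),
        "anal_body_width": (28.0, 4.0),
        "amphid_ratio": (0.14, 0.03),
        "neck_width": (16.5, 2.5),
    },
    "long": {
        "c_prime": (5.2, 0.4),
        "anal_body_width": (18.3, 1.7),
        "amphid_ratio": (0.26, 0.03),
        "neck_width": (14.6, 1.5),
    },
}

SSU_LENGTH = 600


def _default_collapse(k: int) -> dict[str, tuple[int, ...]]:
    # mirror the observed pattern: all clusters but the last share one
    # identical companion sequence, the last keeps its own
    if k == 1:
        return {"ssuA": (0,)}
    return {"ssuA": tuple(range(k - 1)), "ssuB": (k - 1,)}


@dataclass(frozen=True)
class SimParams:
    """Study-scale defaults: 6 clusters of 5, COI-length alignment, 1.5%
    within- and 15% between-cluster divergence."""

    k: int = 6
    n_per_group: tuple[int, ...] | int = 5
    seq_length: int = 393
    d_between: float = 0.15
    d_within: float = 0.015
    collapse_map: Optional[dict[str, tuple[int, ...]]] = None
    morph_params: dict = field(default_factory=lambda: MORPH_DEFAULTS)
    seed: int = 0

    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_group, int):
            return (self.n_per_group,) * self.k
        return tuple(self.n_per_group)

    def collapse(self) -> dict[str, tuple[int, ...]]:
        return self.collapse_map or _default_collapse(self.k)

    def __post_init__(self):
        if self.k < 1 or any(n < 1 for n in self.sizes()):
            raise ValueError("cluster counts must be positive")
        if len(self.sizes()) != self.k:
            raise ValueError("n_per_group length must equal k")
        if not 0.0 <= self.d_within < self.d_between <= 0.75:
            raise ValueError("require 0 <= d_within < d_between <= 0.75")
        covered = sorted(g for gs in self.collapse().values() for g in gs)
        if covered != list(range(self.k)):
            raise ValueError("collapse_map must cover each cluster exactly once")


@dataclass(frozen=True)
class SyntheticDataset:
    coi: Alignment
    ssu: Alignment
    truth: GroupPartition
    morph: pd.DataFrame
    params: SimParams


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator
            ) -> np.ndarray:
    """Substitute each site with a uniformly chosen different base."""
    out = seq.copy()
    cur = out[sites]
    # index among the three non-current bases
    pick = rng.integers(0, 3, sites.size)
    cur_idx = np.searchsorted(_BASES, cur)
    new_idx = pick + (pick >= cur_idx)
    out[sites] = _BASES[new_idx]
    return out


def expected_within_distance(params: SimParams) -> float:
    """Analytic expectation of the p-distance between two cluster members.

    Each member mutates the founder at iid-Bernoulli(w) sites (a Binomial
    count spread over a uniform site set is exactly per-site Bernoulli), so
    a site mismatches when exactly one member mutated it (probability
    2w(1-w)) or both did and landed on different bases (probability
    w^2 * 2/3, since two independent uniform draws from the three
    non-founder bases agree with probability 1/3):

        E[p] = 2 w (1 - w) + (2/3) w**2
    """
    w = params.d_within
    return 2.0 * w * (1.0 - w) + (2.0 / 3.0) * w * w


def simulate(params: SimParams = SimParams()) -> SyntheticDataset:
    """Draw a synthetic dataset; byte-reproducible for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    L, k = params.seq_length, params.k
    m = math.ceil(params.d_between * L)
    if k * m > L:
        raise ValueError(
            f"cannot allocate {k} disjoint founder site sets of {m} sites "
            f"in an alignment of length {L}")

    ancestor = _BASES[rng.integers(0, 4, L)]
    site_pool = rng.permutation(L)
    founders = [
        _mutate(ancestor, np.sort(site_pool[g * m:(g + 1) * m]), rng)
        for g in range(k)
    ]

    sizes = params.sizes()
    coi_records = []
    assignment: dict[str, str] = {}
    specimen_group: list[tuple[str, int]] = []
    for g, size in enumerate(sizes):
        for s in range(size):
            rid = f"g{g + 1}_s{s + 1}"
            n_mut = rng.binomial(L, params.d_within)
            sites = rng.choice(L, size=n_mut, replace=False)
            seq = _mutate(founders[g], np.sort(sites), rng)
            coi_records.append((rid, seq.tobytes().decode("ascii")))
            assignment[rid] = f"G{g + 1}"
            specimen_group.append((rid, g))
    coi = Alignment(tuple(coi_records))
    truth = GroupPartition(assignment)

    collapse = params.collapse()
    class_seq = {
        label: _BASES[rng.integers(0, 4, SSU_LENGTH)].tobytes().decode("ascii")
        for label in sorted(collapse)
    }
    group_class = {g: label for label, gs in collapse.items() for g in gs}
    ssu = Alignment(tuple(
        (rid, class_seq[group_class[g]]) for rid, g in specimen_group
    ))

    # first half of the clusters short-tailed, second half long-tailed
    morphotype_of = {g: ("short" if g < (k + 1) // 2 else "long") for g in range(k)}

    def positive_normal(mean: float, sd: float) -> float:
        for _ in range(100):
            v = rng.normal(mean, sd)
            if v > 0:
                return float(v)
        raise RuntimeError("truncated-normal draw failed")  # pragma: no cover

    morph_rows = []
    for rid, g in specimen_group:
        mp = params.morph_params[morphotype_of[g]]
        c_prime = positive_normal(*mp["c_prime"])
        abw = positive_normal(*mp["anal_body_width"])
        ratio = positive_normal(*mp["amphid_ratio"])
        neck = positive_normal(*mp["neck_width"])
        morph_rows.append({
            "nid": rid,
            "stage": "F" if rng.random() < 0.6 else "J",
            "tail_length": round(c_prime * abw, 1),
            "anal_body_width": round(abw, 1),
            "amphid_width": round(ratio * neck, 1),
            "neck_width": round(neck, 1),
            "true_morphotype": morphotype_of[g],
        })
    morph = pd.DataFrame(morph_rows)
    return SyntheticDataset(coi=coi, ssu=ssu, truth=truth, morph=morph,
                            params=params)


def write_fixture_bundle(ds: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write coi.fasta, ssu.fasta, truth_groups.tsv, morph.tsv, params.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in (
        ("coi", "coi.fasta"), ("ssu", "ssu.fasta"),
        ("truth", "truth_groups.tsv"), ("morph", "morph.tsv"),
        ("params", "params.json"))}
    write_alignment(ds.coi, paths["coi"])
    write_alignment(ds.ssu, paths["ssu"])
    pd.DataFrame(
        {"nid": list(ds.truth.assignment),
         "group": list(ds.truth.assignment.values())}
    ).to_csv(paths["truth"], sep="\t", index=False)
    ds.morph.to_csv(paths["morph"], sep="\t", index=False)
    p = ds.params
    payload = {
        "schema_version": 1,
        "k": p.k, "n_per_group": list(p.sizes()), "seq_length": p.seq_length,
        "d_between": p.d_between, "d_within": p.d_within,
        "collapse_map": {lab: list(gs) for lab, gs in p.collapse().items()},
        "seed": p.seed,
    }
    paths["params"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths
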