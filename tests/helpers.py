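"""Independent oracles used by the test suite.

Everything here is deliberately written the slow, obvious way (per-pair
python loops, explicit graph walks) and never calls the code paths it
checks.
"""

from __future__ import annotations

import numpy as np

VALID = set("ACGT")


def pdist_brute(seqs: list[tuple[str, str]], gap_policy: str = "pairwise-exclude"):
    """Per-pair, per-site p-distance count (ambiguities/gaps excluded)."""
    n = len(seqs)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                comp[i, j] = sum(
                    1 for a, b in zip(seqs[i][1], seqs[j][1])
                    if a in VALID and b in VALID)
                continue
            mism = 0
            c = 0
            for a, b in zip(seqs[i][1], seqs[j][1]):
                if gap_policy == "pairwise-exclude":
                    if a in VALID and b in VALID:
                        c += 1
                        mism += a != b
                else:
                    c += 1
                    aa = a if a in VALID else "-"
                    bb = b if b in VALID else "-"
                    mism += aa != bb
            comp[i, j] = c
            d[i, j] = mism / c if c else np.nan
    return d, comp


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns ``(ids, D, bipartitions)`` where ``D`` is the exact path-length
    matrix and ``bipartitions`` the canonical internal-edge leaf splits
    (side not containing the smallest id).
    """
    ids = [f"t{i:02d}" for i in range(n_leaves)]
    # adjacency: node -> {neighbor: branch length}; leaves are ids,
    # internal nodes are negative ints
    adj: dict = {}
    nxt_internal = -1

    def connect(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    center = nxt_internal
    nxt_internal -= 1
    for leaf in ids[:3]:
        connect(center, leaf, blen())
    edges = [(center, leaf) for leaf in ids[:3]]
    for leaf in ids[3:]:
        a, b = edges[rng.integers(0, len(edges))]
        w = adj[a][b]
        split = rng.uniform(0.25, 0.75) * w
        mid = nxt_internal
        nxt_internal -= 1
        del adj[a][b], adj[b][a]
        connect(a, mid, split)
        connect(mid, b, w - split)
        connect(mid, leaf, blen())
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (mid, leaf)]

    def paths_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(ids):
        dist = paths_from(a)
        for j, b in enumerate(ids):
            D[i, j] = dist[b]

    ref = min(ids)
    full = frozenset(ids)
    bipartitions = set()
    for u in list(adj):
        for v in adj[u]:
            if not (isinstance(u, int) and isinstance(v, int)):
                continue
            # leaves on v's side of edge (u, v)
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                if isinstance(x, str):
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            side = frozenset(side)
            canon = full - side if ref in side else side
            if 2 <= len(canon) <= n_leaves - 2:
                bipartitions.add(canon)
    return ids, D, bipartitions


def validate_partition(partition, tree, dm, criteria) -> list[str]:
    """Re-check every delimited group against all enabled criteria with
    plain loops; returns a list of violation messages (empty = valid)."""
    problems = []
    all_ids = list(tree.leaf_ids)
    for label, members in partition.groups().items():
        members = sorted(members)
        within_vals = [dm.pair(a, b) for i, a in enumerate(members)
                       for b in members[i + 1:]]
        if criteria.within_statistic == "max":
            within = max(within_vals) if within_vals else 0.0
        else:
            within = (sum(within_vals) / len(within_vals)) if within_vals else 0.0
        if within > criteria.max_within:
            problems.append(f"{label}: within {within} > {criteria.max_within}")
        if within > 0.0:
            sup = tree.support_of(frozenset(members))
            if len(members) < len(all_ids):
                if sup is None and len(members) == len(all_ids) - 1:
                    sup = 100.0  # pendant-edge complement: trivially present
                if sup is None or sup < criteria.min_support:
                    problems.append(f"{label}: support {sup} below "
                                    f"{criteria.min_support}")
        outside = [x for x in all_ids if x not in members]
        if criteria.nn_rule and outside:
            nn = min(dm.pair(a, b) for a in members for b in outside)
            if not nn > within:
                problems.append(f"{label}: nn {nn} <= within {within}")
    return problems
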