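"""Canonical labeling of small labeled graphs.

Compound identity in a reaction network requires a key with the property
``key(g1) == key(g2)  <=>  g1 and g2 are isomorphic`` (labels respected).
A Weisfeiler–Lehman style hash only guarantees the forward direction, so we
compute a true canonical form with the classic individualization–refinement
scheme (a miniature of the approach used by nauty and by InChI-style
canonical numbering):

1. fold degree-1 leaves into their neighbor's label (an
   isomorphism-invariant reduction that removes the dominant source of
   branching in molecular graphs: equivalent terminal hydrogens),
2. color the remaining vertices by their labels,
3. refine colors by iterated neighbor-color signatures until stable,
4. if the coloring is not discrete, branch over every vertex of the first
   non-singleton color class, individualize it, and recurse,
5. the certificate is the lexicographically minimal serialization of the
   relabeled graph over all branches.

Worst-case exponential, but after leaf folding molecular graphs refine
(nearly) completely, leaving at most a handful of tiny symmetric cells.
"""

from __future__ import annotations

from typing import Hashable, Sequence

__all__ = ["canonical_certificate"]


def _fold_leaves(adj: Sequence[Sequence[int]], labels: Sequence[Hashable]):
    """Collapse degree-1 vertices (whose neighbor has degree >= 2) into a
    sorted multiset annotation on the neighbor's label.  Single pass;
    isomorphism classes are preserved exactly."""
    n = len(labels)
    deg = [len(set(adj[v])) for v in range(n)]
    folded: dict[int, list] = {}
    keep: list[int] = []
    for v in range(n):
        if deg[v] == 1:
            u = adj[v][0]
            if deg[u] >= 2:
                folded.setdefault(u, []).append(repr(labels[v]))
                continue
        keep.append(v)
    local = {v: i for i, v in enumerate(keep)}
    radj: list[list[int]] = [[] for _ in keep]
    for v in keep:
        for u in adj[v]:
            if u in local and local[u] > local[v]:
                radj[local[v]].append(local[u])
                radj[local[u]].append(local[v])
    rlabels = [(repr(labels[v]), tuple(sorted(folded.get(v, []))))
               for v in keep]
    return radj, rlabels


def _refine(adj: Sequence[Sequence[int]], colors: list[int]) -> list[int]:
    """Stable partition refinement by neighbor-color multisets."""
    n = len(colors)
    while True:
        sigs = [
            (colors[v], tuple(sorted(colors[u] for u in adj[v])))
            for v in range(n)
        ]
        rank = {s: i for i, s in enumerate(sorted(set(sigs)))}
        new = [rank[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _cells(colors: list[int]) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for v, c in enumerate(colors):
        out.setdefault(c, []).append(v)
    return out


def _serialize(
    adj: Sequence[Sequence[int]],
    labels: Sequence[Hashable],
    order: Sequence[int],
) -> tuple:
    """Relabel graph by *order* (position -> vertex) and flatten."""
    pos = {v: i for i, v in enumerate(order)}
    edges = sorted(
        tuple(sorted((pos[v], pos[u])))
        for v in range(len(order))
        for u in adj[v]
        if v < u
    )
    return (tuple(repr(labels[v]) for v in order), tuple(edges))


def _search(
    adj: Sequence[Sequence[int]],
    labels: Sequence[Hashable],
    colors: list[int],
    best: list,
) -> None:
    colors = _refine(adj, colors)
    cells = _cells(colors)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        order = [v for _, v in sorted((c, v) for v, c in enumerate(colors))]
        cert = _serialize(adj, labels, order)
        if best[0] is None or cert < best[0]:
            best[0] = cert
        return
    for v in target:
        branched = list(colors)
        branched[v] = -1  # uniquely minimal -> individualized
        _search(adj, labels, branched, best)


def _initial_colors(labels: Sequence[Hashable]) -> list[int]:
    keyed = [repr(l) for l in labels]
    rank = {s: i for i, s in enumerate(sorted(set(keyed)))}
    return [rank[s] for s in keyed]


def canonical_certificate(
    adj: Sequence[Sequence[int]], labels: Sequence[Hashable]
) -> str:
    """Canonical, isomorphism-invariant serialization of a labeled graph.

    Parameters
    ----------
    adj : adjacency lists (undirected; both directions present).
    labels : one hashable, ``repr``-stable label per vertex.

    Two graphs yield equal certificates exactly when an edge- and
    label-preserving bijection between them exists.
    """
    if not labels:
        return "empty"
    radj, rlabels = _fold_leaves(adj, labels)
    if not rlabels:  # single-vertex graph folded away cannot happen, but
        radj, rlabels = adj, [repr(l) for l in labels]
    best: list = [None]
    _search(radj, rlabels, _initial_colors(rlabels), best)
    lab, edges = best[0]
    return "|".join(lab) + "#" + ";".join(f"{i},{j}" for i, j in edges)
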