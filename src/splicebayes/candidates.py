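"""Candidate transcript enumeration with coverage-ordered edge pruning.

Every source-to-sink path of a splicing graph is a candidate transcript.
When a graph admits more paths than the cap (default 100, matching the
transcript-calling stage's design load), the edge with minimum read
support is removed and paths are re-enumerated, one edge at a time.  An
edge is only prunable when both endpoints keep an alternative edge on the
affected side, so pruning never orphans a node.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import SplicingGraph


class CycleError(ValueError):
    """The splicing graph contains a directed cycle; paths are undefined."""

    def __init__(self, nodes: list[str]):
        self.nodes = nodes
        super().__init__(f"directed cycle through nodes {nodes}")


@dataclass
class CandidateTranscript:
    """A node path through one splicing graph with its spelled sequence.

    ``effective_length`` is the number of valid fragment start positions:
    length - mean fragment length + 1, floored at 1.
    """

    path: tuple[str, ...]
    sequence: str
    effective_length: float


def spell_path(graph: SplicingGraph, path: tuple[str, ...] | list[str]) -> str:
    """Concatenate node sequences, removing the k-1 overlap at each junction."""
    k = graph.k
    parts = [graph.nodes[path[0]].sequence]
    for nid in path[1:]:
        parts.append(graph.nodes[nid].sequence[k - 1 :])
    return "".join(parts)


def _adjacency(edges: dict[tuple[str, str], int]) -> tuple[dict, dict]:
    out: dict[str, list[str]] = {}
    indeg: dict[str, list[str]] = {}
    for (u, v) in edges:
        out.setdefault(u, []).append(v)
        indeg.setdefault(v, []).append(u)
    for lst in out.values():
        lst.sort()
    for lst in indeg.values():
        lst.sort()
    return out, indeg


def _check_acyclic(nodes: list[str], out: dict[str, list[str]]) -> None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in nodes}
    for start in nodes:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = GRAY
        trail = [start]
        while stack:
            node, idx = stack[-1]
            children = out.get(node, [])
            if idx < len(children):
                stack[-1] = (node, idx + 1)
                child = children[idx]
                if color[child] == GRAY:
                    ci = trail.index(child)
                    raise CycleError(trail[ci:] + [child])
                if color[child] == WHITE:
                    color[child] = GRAY
                    stack.append((child, 0))
                    trail.append(child)
            else:
                color[node] = BLACK
                stack.pop()
                trail.pop()


def _count_paths(
    nodes: list[str], edges: dict[tuple[str, str], int], cap: int
) -> int:
    """Number of source-to-sink paths, saturating at ``cap + 1``."""
    out, indeg = _adjacency(edges)
    # Kahn topological order
    remaining = {n: len(indeg.get(n, [])) for n in nodes}
    order = sorted(n for n in nodes if remaining[n] == 0)
    queue = list(order)
    topo: list[str] = []
    while queue:
        n = queue.pop(0)
        topo.append(n)
        for v in out.get(n, []):
            remaining[v] -= 1
            if remaining[v] == 0:
                queue.append(v)
    counts = {n: 0 for n in nodes}
    limit = cap + 1
    for n in topo:
        if not indeg.get(n):
            counts[n] = 1
        for v in out.get(n, []):
            counts[v] = min(limit, counts[v] + counts[n])
    return min(limit, sum(counts[n] for n in nodes if not out.get(n)))


def _enumerate_paths(
    nodes: list[str], edges: dict[tuple[str, str], int]
) -> list[tuple[str, ...]]:
    out, indeg = _adjacency(edges)
    sources = sorted(n for n in nodes if not indeg.get(n))
    paths: list[tuple[str, ...]] = []
    for src in sources:
        stack: list[list[str]] = [[src]]
        while stack:
            path = stack.pop()
            node = path[-1]
            children = out.get(node, [])
            if not children:
                paths.append(tuple(path))
            else:
                for child in reversed(children):
                    stack.append(path + [child])
    return paths


def enumerate_candidates(
    graph: SplicingGraph,
    max_candidates: int = 100,
    mean_fragment_length: float = 250.0,
    return_prune_log: bool = False,
):
    """Candidate transcripts of a graph, pruned to at most ``max_candidates``.

    Sources are nodes with in-degree 0, sinks out-degree 0.  While the path
    count exceeds the cap, the prunable edge with minimum support is removed
    (ties broken lexicographically by (from, to)); an edge is prunable only
    if its tail keeps another out-edge and its head another in-edge.  If no
    edge is prunable, the highest-support paths are kept.

    Raises :class:`CycleError` on cyclic graphs.
    """
    if max_candidates < 1:
        raise ValueError("max_candidates must be >= 1")
    nodes = sorted(graph.nodes)
    edges = dict(graph.edges)
    out, indeg = _adjacency(edges)
    _check_acyclic(nodes, out)

    prune_log: list[tuple[str, str, int]] = []
    while _count_paths(nodes, edges, max_candidates) > max_candidates:
        out, indeg = _adjacency(edges)
        prunable = [
            (sup, u, v)
            for (u, v), sup in edges.items()
            if len(out.get(u, [])) >= 2 and len(indeg.get(v, [])) >= 2
        ]
        if not prunable:
            break
        sup, u, v = min(prunable)
        del edges[(u, v)]
        prune_log.append((u, v, sup))

    paths = _enumerate_paths(nodes, edges)
    if len(paths) > max_candidates:
        # no prunable edge left: keep the best-supported paths
        def path_support(p: tuple[str, ...]) -> int:
            return sum(edges[(p[i], p[i + 1])] for i in range(len(p) - 1))

        paths.sort(key=lambda p: (-path_support(p), p))
        paths = sorted(paths[:max_candidates])

    candidates = []
    for path in paths:
        seq = spell_path(graph, path)
        eff = max(1.0, len(seq) - mean_fragment_length + 1.0)
        candidates.append(
            CandidateTranscript(path=path, sequence=seq, effective_length=eff)
        )
    if return_prune_log:
        return candidates, prune_log
    return candidates
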