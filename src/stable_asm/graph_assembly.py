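"""Overlap graph construction and pruned depth-first transcript enumeration.

Every read is a node; every valid head-tail overlap an arc.  Ideally each
source-to-sink path spells a transcript (or fragment), but at realistic
sequencing depths the same transcript is spelled by a combinatorial number of
near-identical paths, so the traversal prunes aggressively:

* a path is discarded the moment it becomes "too similar" to a prefix of an
  already-output path from the same source (same endpoints, same node count,
  at most ``sim_threshold`` node replacements);
* nodes of an output path are colored black; a new path is output only if it
  still contains at least ``white_threshold`` white (never-output) nodes;
* a path is output only if its merged nucleotide length exceeds
  ``min_length``.

Two implementation-side safeguards keep the search bounded on dense graphs:
descent is cut as soon as no white node is reachable (the coloring test could
never pass later — whites only ever decrease), and a deterministic per-source
expansion budget caps worst-case exploration.  Traversal order is fully
deterministic: sources ascending, children ascending by node id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_encoding import ReadSet, TwoBitSeq, decode_sequence
from .overlap import OverlapTriple

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraversalParams:
    #: minimum merged transcript length (nt) for a path to be reported
    min_length: int = 200
    #: max node replacements under which two same-endpoint paths are redundant
    sim_threshold: int = 2
    #: minimum white (never-output) nodes a path must contain to be output
    white_threshold: int = 1
    #: deterministic cap on DFS edge expansions per source (tractability)
    max_expansions_per_source: int = 200_000

    def __post_init__(self):
        if min(self.min_length, self.sim_threshold, self.white_threshold) < 0:
            raise ValueError("traversal parameters must be >= 0")
        if self.max_expansions_per_source < 1:
            raise ValueError("max_expansions_per_source must be >= 1")


@dataclass(frozen=True)
class NodePath:
    """A simple source-to-sink path through the overlap graph."""

    nodes: tuple[int, ...]

    @property
    def source(self) -> int:
        return self.nodes[0]

    @property
    def sink(self) -> int:
        return self.nodes[-1]

    def __len__(self) -> int:
        return len(self.nodes)


class OverlapGraph:
    """Unweighted directed graph over reads; arcs carry their overlap length."""

    def __init__(self, n_nodes: int, triples: Sequence[OverlapTriple]):
        self.n_nodes = n_nodes
        self.succ: list[list[tuple[int, int]]] = [[] for _ in range(n_nodes)]
        self.pred: list[list[int]] = [[] for _ in range(n_nodes)]
        self.arc_overlap: dict[tuple[int, int], int] = {}
        for t in triples:
            if not (0 <= t.i < n_nodes and 0 <= t.j < n_nodes):
                raise ValueError(f"triple {t} out of range for {n_nodes} nodes")
            if t.i == t.j:
                raise ValueError(f"self-arc rejected: {t}")
            if (t.i, t.j) in self.arc_overlap:
                raise ValueError(f"duplicate arc ({t.i}, {t.j})")
            self.arc_overlap[(t.i, t.j)] = t.k
            self.succ[t.i].append((t.j, t.k))
            self.pred[t.j].append(t.i)
        for adj in self.succ:
            adj.sort()
        for p in self.pred:
            p.sort()

    @property
    def n_arcs(self) -> int:
        return len(self.arc_overlap)

    def sources(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.pred[v]]

    def sinks(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.succ[v]]


def build_graph(n_reads: int, triples: Sequence[OverlapTriple]) -> OverlapGraph:
    return OverlapGraph(n_reads, triples)


def path_too_similar(p, q, sim_threshold: int) -> bool:
    """Whether two paths are redundant: same endpoints, same node count, and
    one obtainable from the other by replacing at most ``sim_threshold`` nodes.

    Replacement preserves length, so paths of different node counts are never
    too similar.
    """
    a = tuple(p.nodes) if isinstance(p, NodePath) else tuple(p)
    b = tuple(q.nodes) if isinstance(q, NodePath) else tuple(q)
    if len(a) != len(b) or a[0] != b[0] or a[-1] != b[-1]:
        return False
    diffs = 0
    for x, y in zip(a, b):
        if x != y:
            diffs += 1
            if diffs > sim_threshold:
                return False
    return True


def merge_path(path: NodePath, graph: OverlapGraph, reads: ReadSet) -> str:
    """Spell the transcript of a path: concatenate reads, collapsing each
    junction by its overlap length.  Where overlapping reads disagree the
    earlier read's bases win (each position takes its base from the first
    read covering it).  Output length is exactly sum(len) - sum(k).
    """
    nodes = path.nodes
    parts = [reads[nodes[0]].seq.codes]
    for a, b in zip(nodes, nodes[1:]):
        k = graph.arc_overlap[(a, b)]
        parts.append(reads[b].seq.codes[k:])
    return decode_sequence(TwoBitSeq(np.concatenate(parts)))


def _forward_reachable(graph: OverlapGraph, start: int) -> bytearray:
    seen = bytearray(graph.n_nodes)
    seen[start] = 1
    stack = [start]
    while stack:
        v = stack.pop()
        for w, _k in graph.succ[v]:
            if not seen[w]:
                seen[w] = 1
                stack.append(w)
    return seen


def _white_reachable(graph: OverlapGraph, comp: bytearray, black: bytearray) -> bytearray:
    """Nodes of ``comp`` from which some white node of ``comp`` is reachable."""
    reach = bytearray(graph.n_nodes)
    stack = [v for v in range(graph.n_nodes) if comp[v] and not black[v]]
    for v in stack:
        reach[v] = 1
    while stack:
        v = stack.pop()
        for u in graph.pred[v]:
            if comp[u] and not reach[u]:
                reach[u] = 1
                stack.append(u)
    return reach


def traverse(
    graph: OverlapGraph, reads: ReadSet, params: Optional[TraversalParams] = None
) -> list[NodePath]:
    """Enumerate retained source-to-sink paths under the pruning rules.

    Coloring persists across sources (sources are processed in ascending
    order); the too-similar test is scoped to outputs sharing the source, as
    only those can share a prefix.  Nodes unreachable from any source (cyclic
    regions with no external entry) yield no paths; their count is logged.
    """
    params = params or TraversalParams()
    n = graph.n_nodes
    black = bytearray(n)
    visited = bytearray(n)
    on_path = bytearray(n)
    rlen = [len(r) for r in reads]
    out: list[NodePath] = []

    for s in graph.sources():
        visited[s] = 1
        src_paths: list[tuple[int, ...]] = []
        prefix_at: dict[tuple[int, int], list[int]] = {}
        comp: Optional[bytearray] = None
        white_reach: Optional[bytearray] = None
        expansions = 0

        path = [s]
        on_path[s] = 1
        plen = [rlen[s]]
        wcum = [0 if black[s] else 1]

        def too_similar_prefix() -> bool:
            d = len(path)
            for idx in prefix_at.get((d - 1, path[-1]), ()):
                earlier = src_paths[idx]
                diffs = 0
                similar = True
                for x, y in zip(path, earlier):
                    if x != y:
                        diffs += 1
                        if diffs > params.sim_threshold:
                            similar = False
                            break
                if similar:
                    return True
            return False

        def white_possible(v: int) -> bool:
            # sound prune: whites never come back, so if the path has too few
            # and none is reachable ahead, no extension can ever be output
            nonlocal comp, white_reach
            if wcum[-1] >= params.white_threshold:
                return True
            if white_reach is None:
                if comp is None:
                    comp = _forward_reachable(graph, s)
                white_reach = _white_reachable(graph, comp, black)
            return bool(white_reach[v])

        def try_output() -> None:
            nonlocal white_reach
            if plen[-1] <= params.min_length:
                return
            if wcum[-1] < params.white_threshold:
                return
            pt = tuple(path)
            pid = len(src_paths)
            src_paths.append(pt)
            for d, v in enumerate(pt):
                prefix_at.setdefault((d, v), []).append(pid)
            out.append(NodePath(pt))
            for v in pt:
                black[v] = 1
            for d in range(len(wcum)):
                wcum[d] = 0
            white_reach = None

        if not graph.succ[s]:
            try_output()
            on_path[s] = 0
            continue

        iters = [iter(graph.succ[s])]
        while iters:
            step = next(iters[-1], None)
            if step is None:
                iters.pop()
                v = path.pop()
                on_path[v] = 0
                plen.pop()
                wcum.pop()
                continue
            v, k = step
            expansions += 1
            if expansions > params.max_expansions_per_source:
                logger.warning(
                    "source %d: traversal budget (%d expansions) exhausted",
                    s, params.max_expansions_per_source,
                )
                for u in path:
                    on_path[u] = 0
                break
            if on_path[v]:
                continue
            visited[v] = 1
            path.append(v)
            on_path[v] = 1
            plen.append(plen[-1] + rlen[v] - k)
            wcum.append(wcum[-1] + (0 if black[v] else 1))
            if too_similar_prefix() or not white_possible(v):
                path.pop()
                on_path[v] = 0
                plen.pop()
                wcum.pop()
                continue
            if not graph.succ[v]:
                try_output()
                path.pop()
                on_path[v] = 0
                plen.pop()
                wcum.pop()
                continue
            iters.append(iter(graph.succ[v]))

    unreached = n - sum(visited)
    if unreached:
        logger.info(
            "%d nodes unreachable from any source (cyclic regions); "
            "no paths emitted from them", unreached,
        )
    return out
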