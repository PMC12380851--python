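"""Transitive dependency resolution and deterministic install planning.

Bricks pin exact commits, so there is no version solving: two commits of
the same brick are two distinct graph nodes that coexist. Planning is a
topological sort with lexicographic tie-breaking on
``(organization, name, commit)`` so the plan — and hence install logs and
library trees — is a reproducible artifact of the registry state.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

from .errors import CycleError, UnresolvedDependencyError
from .refs import BrickRef, DependencyList

#: guard against pathological dependency chains
DEFAULT_MAX_DEPTH = 100


def _sort_key(ref: BrickRef) -> tuple[str, str, str]:
    return (ref.organization, ref.name, ref.commit or "")


@dataclass(frozen=True)
class DependencyGraph:
    """Nodes are pinned refs; an edge u -> v means u depends on v."""

    nodes: frozenset[BrickRef]
    edges: frozenset[tuple[BrickRef, BrickRef]]

    def dependencies_of(self, ref: BrickRef) -> set[BrickRef]:
        return {v for (u, v) in self.edges if u == ref}


@dataclass(frozen=True)
class InstallPlan:
    """Pinned refs in install order: dependencies before dependents."""

    refs: tuple[BrickRef, ...] = ()

    def __iter__(self) -> Iterator[BrickRef]:
        return iter(self.refs)

    def __len__(self) -> int:
        return len(self.refs)

    def __bool__(self) -> bool:
        return bool(self.refs)


def build_graph(
    roots: Iterable[BrickRef],
    lookup: Callable[[BrickRef], DependencyList],
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> DependencyGraph:
    """Breadth-first closure over dependency lists.

    *lookup* maps a pinned ref to its DependencyList (typically a registry
    metadata fetch). A lookup failure on any reachable ref raises
    :class:`UnresolvedDependencyError` naming the chain from a root.
    """
    roots = list(roots)
    for r in roots:
        if not r.pinned:
            raise UnresolvedDependencyError(f"root ref {r.slug} is not pinned")
    nodes: set[BrickRef] = set()
    edges: set[tuple[BrickRef, BrickRef]] = set()
    # queue of (ref, chain-from-root) for error reporting
    queue: list[tuple[BrickRef, tuple[BrickRef, ...]]] = [(r, (r,)) for r in roots]
    while queue:
        ref, chain = queue.pop(0)
        if len(chain) > max_depth:
            raise UnresolvedDependencyError(
                f"dependency chain exceeds depth {max_depth}: "
                + " -> ".join(r.slug for r in chain)
            )
        if ref in nodes:
            continue
        nodes.add(ref)
        try:
            deps = lookup(ref)
        except Exception as exc:
            raise UnresolvedDependencyError(
                "cannot resolve "
                + " -> ".join(r.slug for r in chain)
                + f": {exc}"
            ) from exc
        for dep in deps:
            edges.add((ref, dep))
            queue.append((dep, chain + (dep,)))
    return DependencyGraph(frozenset(nodes), frozenset(edges))


def _find_cycle(graph: DependencyGraph, candidates: set[BrickRef]) -> list[BrickRef]:
    """Return one cycle (in edge order) among *candidates* via DFS."""
    adj = {u: sorted(graph.dependencies_of(u) & candidates, key=_sort_key)
           for u in candidates}
    color: dict[BrickRef, int] = {}
    stack: list[BrickRef] = []

    def dfs(u: BrickRef) -> list[BrickRef] | None:
        color[u] = 1
        stack.append(u)
        for v in adj[u]:
            if color.get(v, 0) == 1:
                return stack[stack.index(v):]
            if color.get(v, 0) == 0:
                found = dfs(v)
                if found:
                    return found
        stack.pop()
        color[u] = 2
        return None

    for start in sorted(candidates, key=_sort_key):
        if color.get(start, 0) == 0:
            cycle = dfs(start)
            if cycle:
                return cycle
    return []  # pragma: no cover - callers only ask when a cycle exists


def plan(graph: DependencyGraph) -> InstallPlan:
    """Unique topological order: Kahn's algorithm with a lexicographic heap.

    Raises :class:`CycleError` listing one offending cycle's refs in order.
    """
    remaining_deps = {u: len(graph.dependencies_of(u)) for u in graph.nodes}
    dependents: dict[BrickRef, list[BrickRef]] = {u: [] for u in graph.nodes}
    for u, v in graph.edges:
        dependents[v].append(u)
    ready = [(_sort_key(u), u) for u, n in remaining_deps.items() if n == 0]
    heapq.heapify(ready)
    order: list[BrickRef] = []
    while ready:
        _, u = heapq.heappop(ready)
        order.append(u)
        for w in dependents[u]:
            remaining_deps[w] -= 1
            if remaining_deps[w] == 0:
                heapq.heappush(ready, (_sort_key(w), w))
    if len(order) != len(graph.nodes):
        stuck = {u for u, n in remaining_deps.items() if n > 0}
        cycle = _find_cycle(graph, stuck)
        raise CycleError(
            "dependency cycle: " + " -> ".join(r.slug for r in cycle + cycle[:1])
        )
    return InstallPlan(tuple(order))


def diff(install_plan: InstallPlan, installed: set[BrickRef]) -> InstallPlan:
    """Subsequence of the plan excluding already-installed refs."""
    return InstallPlan(tuple(r for r in install_plan if r not in installed))
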