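"""Rooted-DAG representation of the Gene Ontology and its path statistics.

The ontology is modelled as a rooted directed acyclic graph (rDAG): terms are
nodes, ``is_a`` / ``part_of`` edges point from child to parent, and a single
virtual global root is materialised as the parent of the aspect-specific roots
(biological process, molecular function, cellular component).  Because a term
can have several parents, it can lie on several root paths, have several depth
values (we use the maximal one), and a pair of terms can have several lowest
common ancestors.  This module computes, for any term pair:

* ``depth`` — length in edges of the longest root path (dynamic programming
  over a topological order);
* ``lca_set`` — the common ancestors of maximal depth;
* ``min_spl`` — the shortest path length between two terms through one of
  their lowest common ancestors;
* ``term_dot`` — the generalized-cosine dot product between the basis vectors
  of two terms, ``2*Depth(LCA) / (MinSPL + 2*Depth(LCA))``.

``term_dot`` is the edge-based term-term similarity that makes the gene
vector space non-orthogonal; everything else in the package builds on it.
"""

from __future__ import annotations

import hashlib
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import (
    CacheStaleError,
    GraphStructureError,
    NotAnAncestorError,
    ParseError,
    UnknownTermError,
)

logger = logging.getLogger(__name__)

#: Identifier of the materialised global root node.
GLOBAL_ROOT = "Root"

#: Ontology aspects; ROOT is reserved for the global root node itself.
ASPECTS = ("BP", "MF", "CC")

#: Edge relation types retained from the ontology.
RELATIONS = ("is_a", "part_of")

_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: accession, label, aspect, obsolescence flag."""

    id: str
    name: str = ""
    aspect: str = "BP"
    obsolete: bool = False


@dataclass(frozen=True)
class TermPairStats:
    """Cached per-pair quantities: Depth(LCA), MinSPL and the dot product."""

    term_a: str
    term_b: str
    lca_depth: int
    min_spl: int
    dot: float


class GOGraph:
    """A rooted DAG of ontology terms with typed child->parent edges.

    Parameters
    ----------
    terms:
        Iterable of :class:`TermRecord`; must include the root.
    edges:
        Iterable of ``(child, parent, relation)`` triples with relation in
        ``{"is_a", "part_of"}``.
    root:
        Identifier of the global root (default ``"Root"``).

    Structural invariants are checked at construction time: term ids are
    unique, the edge set is acyclic, the root is the only parentless node
    (hence every term has a directed path to the root), and the aspect roots
    are direct children of the global root.
    """

    def __init__(
        self,
        terms: Iterable[TermRecord],
        edges: Iterable[tuple[str, str, str]],
        root: str = GLOBAL_ROOT,
        alt_ids: Mapping[str, str] | None = None,
    ):
        self._terms: dict[str, TermRecord] = {}
        for rec in terms:
            if rec.id in self._terms:
                raise GraphStructureError(f"duplicate term id: {rec.id!r}")
            self._terms[rec.id] = rec
        if root not in self._terms:
            raise GraphStructureError(f"root {root!r} is not among the terms")
        self.root = root
        self._alt_ids = dict(alt_ids or {})

        # child -> parent digraph; relation kept as an edge attribute.
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        self._edges: list[tuple[str, str, str]] = []
        for child, parent, rel in edges:
            for endpoint in (child, parent):
                if endpoint not in self._terms:
                    raise UnknownTermError(endpoint)
            if rel not in RELATIONS:
                raise GraphStructureError(f"unsupported relation {rel!r}")
            self._edges.append((child, parent, rel))
            g.add_edge(child, parent, relation=rel)
        self._g = g
        self._validate()
        self._depth: dict[str, int] | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            raise GraphStructureError(f"cycle over child->parent edges: {cycle}")
        if self._g.out_degree(self.root) != 0:
            raise GraphStructureError("the root must have no parents")
        orphans = [
            t for t in self._terms
            if t != self.root and self._g.out_degree(t) == 0
        ]
        if orphans:
            raise GraphStructureError(
                f"terms with no path to the root: {sorted(orphans)[:5]}"
            )

    @property
    def terms(self) -> Mapping[str, TermRecord]:
        return self._terms

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        return list(self._edges)

    @property
    def aspect_roots(self) -> dict[str, str]:
        """Aspect -> term id of the aspect-specific root (child of the root)."""
        out: dict[str, str] = {}
        for child in sorted(self._g.predecessors(self.root)):
            out[self._terms[child].aspect] = child
        return out

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    def _check(self, term_id: str) -> str:
        if term_id not in self._terms:
            raise UnknownTermError(term_id)
        return term_id

    def resolve(self, term_id: str) -> str:
        """Map an (alternate) accession to its canonical graph id."""
        if term_id in self._terms:
            return term_id
        if term_id in self._alt_ids:
            return self._alt_ids[term_id]
        raise UnknownTermError(term_id)

    def checksum(self) -> str:
        """SHA-256 over the sorted edge set and root; identifies the graph."""
        h = hashlib.sha256()
        h.update(self.root.encode())
        for child, parent, rel in sorted(self._edges):
            h.update(f"\x00{child}\x01{parent}\x01{rel}".encode())
        return h.hexdigest()

    # -- path statistics ---------------------------------------------------

    def parents(self, t: str) -> set[str]:
        """Direct parents of *t* over is_a/part_of edges; empty for the root."""
        self._check(t)
        return set(self._g.successors(t))

    def children(self, t: str) -> set[str]:
        self._check(t)
        return set(self._g.predecessors(t))

    def ancestors(self, t: str) -> set[str]:
        """All terms on any root path of *t*, including *t* and the root."""
        self._check(t)
        return nx.descendants(self._g, t) | {t}

    def descendants(self, t: str) -> set[str]:
        """All terms having *t* on one of their root paths, including *t*."""
        self._check(t)
        return nx.ancestors(self._g, t) | {t}

    def depth(self, t: str) -> int:
        """Maximal depth: edges on the longest root path of *t*."""
        self._check(t)
        if self._depth is None:
            depth = {self.root: 0}
            # topological order of the child->parent digraph lists children
            # before parents; reverse it so parents are settled first.
            for node in reversed(list(nx.topological_sort(self._g))):
                if node == self.root:
                    continue
                depth[node] = 1 + max(depth[p] for p in self._g.successors(node))
            self._depth = depth
        return self._depth[t]

    def common_ancestors(self, ta: str, tb: str) -> set[str]:
        return self.ancestors(ta) & self.ancestors(tb)

    def lca_set(self, ta: str, tb: str) -> tuple[set[str], int]:
        """Common ancestors of maximal depth, and that shared depth.

        The depth value is unique but may be attained by several terms, so a
        set is returned.
        """
        common = self.common_ancestors(ta, tb)
        best = max(self.depth(a) for a in common)
        return {a for a in common if self.depth(a) == best}, best

    def min_path_length(self, t: str, s: str) -> int:
        """Shortest ascending child->parent path length from *t* to *s*.

        Equals the minimum, over root paths of *t* whose root-to-*s* prefix is
        a longest root path of *s*, of the path length below *s*.  Requires
        *s* to be an ancestor of *t*.
        """
        self._check(t)
        self._check(s)
        if s == t:
            return 0
        # breadth-first ascent over parent edges
        seen = {t}
        frontier = deque([(t, 0)])
        while frontier:
            node, dist = frontier.popleft()
            for p in self._g.successors(node):
                if p == s:
                    return dist + 1
                if p not in seen:
                    seen.add(p)
                    frontier.append((p, dist + 1))
        raise NotAnAncestorError(f"{s!r} is not an ancestor of {t!r}")

    def min_spl(self, ta: str, tb: str) -> tuple[int, str]:
        """Minimal shortest path length between two terms through an LCA.

        For each lowest common ancestor the SPL is the sum of the two
        shortest ascents; the minimum over LCAs is returned together with one
        minimising ancestor (ties broken by lexicographically smallest id).
        """
        lcas, _ = self.lca_set(ta, tb)
        best_spl: int | None = None
        best_via: str | None = None
        for lca in sorted(lcas):
            spl = self.min_path_length(ta, lca) + self.min_path_length(tb, lca)
            if best_spl is None or spl < best_spl:
                best_spl, best_via = spl, lca
        assert best_spl is not None and best_via is not None
        return best_spl, best_via

    def term_dot(self, ta: str, tb: str) -> float:
        """Generalized-cosine dot product between two basis vectors.

        ``2*Depth(LCA) / (MinSPL + 2*Depth(LCA))``; 1 for identical terms, 0
        when the only common ancestor is the global root (depth 0).
        """
        self._check(ta)
        self._check(tb)
        if ta == tb:
            return 1.0
        lcas, d = self.lca_set(ta, tb)
        if d == 0:
            return 0.0
        spl, _ = self.min_spl(ta, tb)
        return 2.0 * d / (spl + 2.0 * d)

    def pair_stats(self, ta: str, tb: str) -> TermPairStats:
        """Depth(LCA), MinSPL and dot product for one unordered pair."""
        a, b = sorted((self._check(ta), self._check(tb)))
        _, d = self.lca_set(a, b)
        spl, _ = self.min_spl(a, b)
        dot = 1.0 if a == b else (0.0 if d == 0 else 2.0 * d / (spl + 2.0 * d))
        return TermPairStats(a, b, d, spl, dot)


# -- precomputed pair-statistics table -------------------------------------


@dataclass
class PairStatsTable:
    """Cache of :class:`TermPairStats` keyed by unordered term pair.

    The table carries the checksum of the graph it was computed from; loading
    it against a different graph raises :class:`CacheStaleError` rather than
    silently reusing stale values.  Values stored are exactly the ones the
    direct computation produces, so downstream similarities are bit-identical
    with or without the cache.
    """

    graph_checksum: str
    stats: dict[tuple[str, str], TermPairStats] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stats)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = sorted(pair)
        return (a, b) in self.stats

    def get(self, ta: str, tb: str) -> TermPairStats:
        a, b = sorted((ta, tb))
        try:
            return self.stats[(a, b)]
        except KeyError:
            from .errors import CacheIncompleteError

            raise CacheIncompleteError(f"pair ({ta!r}, {tb!r}) not in cache") from None

    def dot(self, ta: str, tb: str) -> float:
        return self.get(ta, tb).dot

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#graph_checksum={self.graph_checksum}\n")
            fh.write("term_a\tterm_b\tlca_depth\tmin_spl\tdot\n")
            for (a, b), st in sorted(self.stats.items()):
                fh.write(f"{a}\t{b}\t{st.lca_depth}\t{st.min_spl}\t{st.dot!r}\n")

    @classmethod
    def read(cls, path: str | Path, graph: GOGraph | None = None) -> "PairStatsTable":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().strip()
            if not header.startswith("#graph_checksum="):
                raise ParseError("missing #graph_checksum= header", 1)
            checksum = header.split("=", 1)[1]
            if graph is not None and checksum != graph.checksum():
                raise CacheStaleError(
                    "pair-statistics cache was computed from a different graph"
                )
            table = cls(graph_checksum=checksum)
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line or line.startswith("term_a\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ParseError(f"expected 5 columns, got {len(parts)}", lineno)
                a, b, d, spl, dot = parts
                table.stats[(a, b)] = TermPairStats(a, b, int(d), int(spl), float(dot))
        return table


def precompute_pair_stats(graph: GOGraph, terms: Iterable[str]) -> PairStatsTable:
    """Precompute pair statistics for every unordered pair (incl. self-pairs)."""
    term_list = sorted({graph.resolve(t) for t in terms})
    table = PairStatsTable(graph_checksum=graph.checksum())
    for i, a in enumerate(term_list):
        for b in term_list[i:]:
            table.stats[(a, b)] = graph.pair_stats(a, b)
    return table


# -- readers ---------------------------------------------------------------


def read_obo(path: str | Path, root: str = GLOBAL_ROOT) -> GOGraph:
    """Read an OBO 1.2/1.4 ontology file into a :class:`GOGraph`.

    Only ``is_a`` and ``part_of`` relations are retained; other relation
    types (e.g. ``regulates``) are dropped with a logged count.  Obsolete
    terms are excluded.  ``alt_id`` accessions map to their canonical id.
    A virtual global root is materialised as the parent of each namespace
    root, so cross-aspect term pairs meet only at depth 0.
    """
    import obonet

    g = obonet.read_obo(str(path))  # ignores obsolete stanzas by default
    terms: list[TermRecord] = [TermRecord(root, "global root", "ROOT")]
    alt_ids: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    dropped = 0

    aspect_of: dict[str, str] = {}
    for node, data in g.nodes(data=True):
        aspect = _NAMESPACE_TO_ASPECT.get(data.get("namespace", ""), "BP")
        aspect_of[node] = aspect
        terms.append(TermRecord(node, data.get("name", ""), aspect))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    for child, parent, rel in g.edges(keys=True):
        if rel in RELATIONS:
            edges.append((child, parent, rel))
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d edges with unsupported relation types", dropped)

    # attach parentless namespace roots under the global root
    with_parent = {c for c, _p, _r in edges}
    for node in g.nodes:
        if node not in with_parent:
            edges.append((node, root, "is_a"))
    return GOGraph(terms, edges, root=root, alt_ids=alt_ids)


def read_edge_tsv(path: str | Path) -> GOGraph:
    """Read a synthetic-graph edge list: ``#root=<id>`` header, then
    ``child<TAB>parent<TAB>relation`` rows.

    Aspects are assigned by subtree: the sorted children of the root receive
    BP, MF, CC in order and pass their aspect to their descendants.
    """
    path = Path(path)
    edges: list[tuple[str, str, str]] = []
    root: str | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#root="):
                root = line.split("=", 1)[1]
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"expected 3 columns, got {len(parts)}", lineno)
            edges.append((parts[0], parts[1], parts[2]))
    if root is None:
        raise ParseError("missing #root= header line")
    return _graph_from_edges(edges, root)


def _graph_from_edges(
    edges: list[tuple[str, str, str]], root: str
) -> GOGraph:
    """Build a GOGraph from bare edges, inferring aspects by root subtree."""
    parent_map: dict[str, set[str]] = {}
    nodes: set[str] = {root}
    for child, parent, _rel in edges:
        nodes.add(child)
        nodes.add(parent)
        parent_map.setdefault(child, set()).add(parent)

    aspect_roots = sorted(c for c, ps in parent_map.items() if root in ps)
    aspect_of: dict[str, str] = {root: "ROOT"}
    for i, ar in enumerate(aspect_roots):
        aspect_of[ar] = ASPECTS[i % len(ASPECTS)]
    # propagate aspects downward (child inherits its first parent's aspect)
    children_map: dict[str, set[str]] = {}
    for child, parent, _rel in edges:
        children_map.setdefault(parent, set()).add(child)
    frontier = deque(aspect_roots)
    while frontier:
        node = frontier.popleft()
        for child in children_map.get(node, ()):
            if child not in aspect_of:
                aspect_of[child] = aspect_of[node]
                frontier.append(child)
    terms = [TermRecord(n, "", aspect_of.get(n, "BP")) for n in sorted(nodes)]
    return GOGraph(terms, edges, root=root)


def write_edge_tsv(graph: GOGraph, path: str | Path) -> None:
    """Serialise a graph in the edge-list dialect read by :func:`read_edge_tsv`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#root={graph.root}\n")
        for child, parent, rel in sorted(graph.edges):
            fh.write(f"{child}\t{parent}\t{rel}\n")
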