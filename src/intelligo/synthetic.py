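"""Deterministic synthetic ontologies and annotation corpora.

Real ontology releases are large and annotation corpora are moving targets,
so the test bed is generated: small rooted DAGs with a controllable rate of
multi-parent terms under up to three aspect roots, and annotation corpora
with a configurable evidence-code mixture and optional assignment of gene
sets to disjoint ontology branches (which makes the sets functionally
coherent by construction, the regime where a discriminating measure should
score intra > inter).

The module also houses the exhaustive root-path enumeration oracle.  The
fast graph operations use dynamic programming and breadth-first search; the
oracle instead literally enumerates every directed root path of every term
and derives depth, ancestors, LCA sets and shortest path lengths by set
arithmetic over those paths.  It is exponential and guarded, and exists
solely to cross-check the fast implementations on small random graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping

import numpy as np

from .corpus import EVIDENCE_CODES, AnnotationRecord
from .graph import ASPECTS, GLOBAL_ROOT, GOGraph, TermRecord

#: Default taxon id stamped on synthetic annotation records.
SYNTHETIC_TAXON = 9999


def fixture_a() -> GOGraph:
    """The hand-built ten-term reference graph used by the worked examples.

    Two aspect roots A (BP) and H (MF) under the global root.  The BP branch
    exhibits every structural case the rDAG formalism distinguishes:
    multiple root paths (D: via B and via C), a term pair with two lowest
    common ancestors at equal depth (F, G), ancestor-descendant pairs
    (E below D), and a cross-aspect pair meeting only at the root (B, I).
    """
    terms = [
        TermRecord(GLOBAL_ROOT, "global root", "ROOT"),
        TermRecord("A", "aspect root 1", "BP"),
        TermRecord("H", "aspect root 2", "MF"),
        TermRecord("B", "", "BP"),
        TermRecord("C", "", "BP"),
        TermRecord("D", "", "BP"),
        TermRecord("E", "", "BP"),
        TermRecord("F", "", "BP"),
        TermRecord("G", "", "BP"),
        TermRecord("I", "", "MF"),
    ]
    edges = [
        ("A", GLOBAL_ROOT, "is_a"),
        ("H", GLOBAL_ROOT, "is_a"),
        ("B", "A", "is_a"),
        ("C", "A", "is_a"),
        ("D", "B", "is_a"),
        ("D", "C", "part_of"),
        ("E", "D", "is_a"),
        ("F", "B", "is_a"),
        ("F", "C", "is_a"),
        ("G", "B", "is_a"),
        ("G", "C", "is_a"),
        ("I", "H", "is_a"),
    ]
    return GOGraph(terms, edges)


# -- random rDAG generation ------------------------------------------------


@dataclass(frozen=True)
class RDAGSpec:
    """Parameters of a random rooted DAG.

    ``p_extra_parent`` is the probability that a term receives a second
    parent (within its own aspect subtree, keeping aspects disjoint); 0
    yields a tree.  ``max_depth_target`` caps term depth during generation.
    """

    n_terms: int = 12
    n_aspects: int = 2
    p_extra_parent: float = 0.3
    max_depth_target: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be positive")
        if not 1 <= self.n_aspects <= 3:
            raise ValueError("n_aspects must be in 1..3")
        if not 0.0 <= self.p_extra_parent < 1.0:
            raise ValueError("p_extra_parent must be in [0, 1)")
        if self.max_depth_target < 2 or self.max_depth_target > self.n_terms + 1:
            raise ValueError("max_depth_target infeasible for n_terms")


def generate_rdag(spec: RDAGSpec) -> GOGraph:
    """Random rooted DAG, acyclic by construction.

    Terms are created in a fixed generation order and may only choose
    parents among earlier terms of the same aspect, so no cycle can arise.
    Deterministic for a given spec (single seeded stream, no global state).
    """
    rng = np.random.default_rng(spec.seed)
    terms = [TermRecord(GLOBAL_ROOT, "global root", "ROOT")]
    edges: list[tuple[str, str, str]] = []
    aspect_names = ASPECTS[: spec.n_aspects]
    depth: dict[str, int] = {}
    by_aspect: dict[str, list[str]] = {}
    for i, aspect in enumerate(aspect_names):
        ar = f"{aspect}root"
        terms.append(TermRecord(ar, f"aspect root {aspect}", aspect))
        edges.append((ar, GLOBAL_ROOT, "is_a"))
        depth[ar] = 1
        by_aspect[aspect] = [ar]

    for i in range(spec.n_terms):
        tid = f"T{i:04d}"
        aspect = aspect_names[int(rng.integers(len(aspect_names)))]
        pool = [t for t in by_aspect[aspect] if depth[t] < spec.max_depth_target]
        parent = pool[int(rng.integers(len(pool)))]
        relation = "is_a" if rng.random() < 0.8 else "part_of"
        edges.append((tid, parent, relation))
        depth[tid] = depth[parent] + 1
        extras = [t for t in pool if t != parent]
        if extras and rng.random() < spec.p_extra_parent:
            extra = extras[int(rng.integers(len(extras)))]
            edges.append((tid, extra, "is_a"))
            depth[tid] = max(depth[tid], depth[extra] + 1)
        terms.append(TermRecord(tid, "", aspect))
        by_aspect[aspect].append(tid)
    return GOGraph(terms, edges)


# -- random corpus generation ----------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a random annotation corpus.

    ``ec_distribution`` is the evidence-code mixture each record's code is
    drawn from; the default mirrors an IEA-dominated corpus with a
    substantial curated fraction, as in real genome annotation.  With
    ``branch_assignment``, genes are split evenly over the named sets and
    each set draws its terms only from the descendants of its branch term.
    """

    n_genes: int = 20
    terms_per_gene: tuple[int, int] = (2, 4)
    ec_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"IEA": 0.5, "IDA": 0.2, "ISS": 0.15,
                                 "TAS": 0.1, "IMP": 0.05}
    )
    branch_assignment: Mapping[str, str] | None = None
    aspect: str = "BP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.terms_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("terms_per_gene must be a non-empty 1-based range")
        total = sum(self.ec_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ec_distribution sums to {total}, not 1")
        unknown = set(self.ec_distribution) - set(EVIDENCE_CODES)
        if unknown:
            raise ValueError(f"unknown evidence codes: {sorted(unknown)}")


def assign_genes_to_sets(spec: CorpusSpec) -> dict[str, list[str]]:
    """Deterministic even split of gene ids over the branch-assigned sets."""
    if not spec.branch_assignment:
        return {}
    set_ids = sorted(spec.branch_assignment)
    out: dict[str, list[str]] = {sid: [] for sid in set_ids}
    for i in range(spec.n_genes):
        out[set_ids[i % len(set_ids)]].append(f"G{i:04d}")
    return out


def generate_corpus(spec: CorpusSpec, graph: GOGraph) -> list[AnnotationRecord]:
    """Random annotation records over the terms of one aspect of *graph*.

    Deterministic per seed.  Each gene draws a number of terms uniform in
    ``terms_per_gene`` (without replacement when possible) and an evidence
    code per record from ``ec_distribution``.
    """
    rng = np.random.default_rng(spec.seed)
    aspect_root = graph.aspect_roots.get(spec.aspect)
    if aspect_root is None:
        raise ValueError(f"graph has no aspect {spec.aspect!r}")
    default_pool = sorted(graph.descendants(aspect_root) - {aspect_root})
    if not default_pool:
        raise ValueError(f"aspect {spec.aspect!r} has no annotatable terms")

    pools: dict[str, list[str]] = {}
    if spec.branch_assignment:
        for sid, branch in sorted(spec.branch_assignment.items()):
            pool = sorted(graph.descendants(graph.resolve(branch)))
            if not pool:
                raise ValueError(f"branch {branch!r} of set {sid!r} is empty")
            pools[sid] = pool
    gene_to_set = {
        g: sid for sid, genes in assign_genes_to_sets(spec).items() for g in genes
    }

    codes = sorted(spec.ec_distribution)
    probs = np.array([spec.ec_distribution[c] for c in codes])
    probs = probs / probs.sum()

    records: list[AnnotationRecord] = []
    lo, hi = spec.terms_per_gene
    for i in range(spec.n_genes):
        gene = f"G{i:04d}"
        pool = pools.get(gene_to_set.get(gene, ""), default_pool)
        k = int(rng.integers(lo, hi + 1))
        if k <= len(pool):
            terms = [pool[j] for j in sorted(rng.choice(len(pool), k, replace=False))]
        else:
            terms = [pool[int(j)] for j in rng.integers(len(pool), size=k)]
        for term in terms:
            ec = codes[int(rng.choice(len(codes), p=probs))]
            records.append(AnnotationRecord(
                gene=gene, term=term, evidence=ec, aspect=spec.aspect,
                taxon=SYNTHETIC_TAXON,
            ))
    return records


def disjoint_branch_pair(graph: GOGraph, aspect: str = "BP") -> tuple[str, str]:
    """Two same-aspect terms with disjoint descendant subtrees.

    Among all candidate pairs the one maximising the smaller subtree (ties:
    larger total, then lexicographic) is returned, so gene sets annotated
    from the two branches draw from the richest disjoint term pools the
    graph offers.  Raises if the aspect has no such pair (e.g. a pure path).
    """
    aspect_root = graph.aspect_roots.get(aspect)
    if aspect_root is None:
        raise ValueError(f"graph has no aspect {aspect!r}")
    candidates = sorted(graph.descendants(aspect_root) - {aspect_root})
    subtree = {t: graph.descendants(t) for t in candidates}
    best_key: tuple[int, int] | None = None
    best_pair: tuple[str, str] | None = None
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            if subtree[a] & subtree[b]:
                continue
            key = (min(len(subtree[a]), len(subtree[b])),
                   len(subtree[a]) + len(subtree[b]))
            if best_key is None or key > best_key:
                best_key, best_pair = key, (a, b)
    if best_pair is None:
        raise ValueError(f"aspect {aspect!r} has no disjoint branch pair")
    return best_pair


# -- the exhaustive enumeration oracle -------------------------------------


@dataclass
class OracleStats:
    """Exhaustive per-term and per-pair graph statistics."""

    root_paths: dict[str, list[tuple[str, ...]]]
    depth: dict[str, int]
    ancestors: dict[str, set[str]]
    lca: dict[tuple[str, str], tuple[set[str], int]]
    min_spl: dict[tuple[str, str], int]

    def pair(self, ta: str, tb: str) -> tuple[str, str]:
        return (ta, tb) if ta <= tb else (tb, ta)


def oracle_graph_stats(graph: GOGraph, max_paths: int = 10**5) -> OracleStats:
    """Literal enumeration of every directed root path of every term.

    Depth is the maximal path length; ancestors the union over path members;
    the LCA set the deepest common ancestors; and the shortest path length
    between a pair, through a given LCA, is minimised over root paths whose
    prefix up to the LCA is itself a longest root path of the LCA.  Refuses
    graphs whose total path count exceeds *max_paths*.
    """
    root_paths: dict[str, list[tuple[str, ...]]] = {}
    total = 0
    for t in sorted(graph.terms):
        paths = _enumerate_root_paths(graph, t)
        total += len(paths)
        if total > max_paths:
            raise ValueError(f"path count exceeds the {max_paths} guard")
        root_paths[t] = paths

    depth = {t: max(len(p) for p in paths) - 1 for t, paths in root_paths.items()}
    ancestors = {
        t: {a for p in paths for a in p} for t, paths in root_paths.items()
    }

    lca: dict[tuple[str, str], tuple[set[str], int]] = {}
    min_spl: dict[tuple[str, str], int] = {}
    for ta, tb in combinations_with_replacement(sorted(graph.terms), 2):
        common = ancestors[ta] & ancestors[tb]
        d = max(depth[a] for a in common)
        lcas = {a for a in common if depth[a] == d}
        lca[(ta, tb)] = (lcas, d)
        min_spl[(ta, tb)] = min(
            _oracle_min_pl(root_paths, depth, ta, a)
            + _oracle_min_pl(root_paths, depth, tb, a)
            for a in lcas
        )
    return OracleStats(root_paths, depth, ancestors, lca, min_spl)


def _enumerate_root_paths(graph: GOGraph, t: str) -> list[tuple[str, ...]]:
    """All directed paths from the root down to *t*, as node sequences."""
    if t == graph.root:
        return [(graph.root,)]
    paths: list[tuple[str, ...]] = []
    for parent in sorted(graph.parents(t)):
        for prefix in _enumerate_root_paths(graph, parent):
            paths.append(prefix + (t,))
    return paths


def _oracle_min_pl(
    root_paths: Mapping[str, list[tuple[str, ...]]],
    depth: Mapping[str, int],
    t: str,
    s: str,
) -> int:
    """Min path length from *t* up to ancestor *s* over constrained paths.

    A root path of *t* is constrained w.r.t. *s* when it passes through *s*
    with its root-to-*s* prefix of maximal length (``Depth(s) + 1`` nodes);
    the path length is then the number of edges below *s*.
    """
    best: int | None = None
    for path in root_paths[t]:
        if s not in path:
            continue
        prefix_nodes = path.index(s) + 1
        if prefix_nodes != depth[s] + 1:
            continue
        pl = len(path) - 1 - depth[s]
        if best is None or pl < best:
            best = pl
    if best is None:
        raise ValueError(f"no constrained root path of {t!r} through {s!r}")
    return best
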