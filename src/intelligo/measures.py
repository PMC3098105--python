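"""Gene-gene semantic similarity measures.

The central measure is the generalized cosine over the non-orthogonal term
basis: ``sim(g, h) = g.h / (sqrt(g.g) * sqrt(h.h))`` with
``g.h = sum_ij alpha_i beta_j (e_i . e_j)`` and the basis dot products taken
from the ontology graph (or a precomputed cache).  Four reference measures
are provided for comparison:

* Lord — mean Resnik term similarity (IC of the lowest common ancestor) over
  all cross pairs, normalised afterwards by the collection maximum;
* Al-Mubaid — a decreasing exponential transfer of the mean shortest path
  length between annotation terms;
* weighted cosine — the classical orthogonal cosine with IAF coefficients,
  where only shared terms contribute to the dot product;
* SimGIC — IC-weighted Jaccard over ancestor-extended annotation sets.

A gene without usable annotation under the active configuration yields the
``MISSING`` marker, never 0: absence of evidence is accounted separately
from dissimilarity.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

from .corpus import AnnotationRecord, GeneVector
from .errors import UndefinedICError, UndefinedSimilarityError
from .graph import GOGraph, PairStatsTable

logger = logging.getLogger(__name__)


class _Missing:
    """Singleton marker for a similarity that cannot be computed."""

    _instance: "_Missing | None" = None

    def __new__(cls) -> "_Missing":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


#: Marker returned when a gene pair has no usable annotation.
MISSING = _Missing()


def is_missing(value: object) -> bool:
    return value is MISSING


# -- information content ---------------------------------------------------


class ICTable:
    """Descendant-inclusive information content of corpus terms.

    ``p(t)`` is the fraction of corpus genes annotated by ``t`` or any of its
    descendants; ``IC(t) = -log10 p(t)``.  A term that covers every gene
    (e.g. the aspect root of a single-aspect corpus) has IC 0.  Terms never
    reached by any annotation have no defined IC and raise
    :class:`UndefinedICError` when queried.
    """

    def __init__(self, probabilities: Mapping[str, float]):
        self._p = dict(probabilities)

    def __contains__(self, term: str) -> bool:
        return term in self._p

    def __len__(self) -> int:
        return len(self._p)

    def probability(self, term: str) -> float:
        try:
            return self._p[term]
        except KeyError:
            raise UndefinedICError(
                f"term {term!r} has no corpus-derived information content"
            ) from None

    def __getitem__(self, term: str) -> float:
        return -math.log10(self.probability(term))


def term_ic(records: Iterable[AnnotationRecord], graph: GOGraph) -> ICTable:
    """Information content from descendant-inclusive annotation counts.

    A gene counts towards every ancestor of each of its annotation terms, so
    general terms approach probability 1 and IC 0.  Records whose term is not
    in the graph are skipped with a warning.
    """
    gene_terms: dict[str, set[str]] = {}
    for rec in records:
        try:
            term = graph.resolve(rec.term)
        except KeyError:
            logger.warning("IC: term %s not in graph, record skipped", rec.term)
            continue
        gene_terms.setdefault(rec.gene, set()).add(term)
    if not gene_terms:
        raise ValueError("cannot compute IC over an empty corpus")
    g_tot = len(gene_terms)
    counts: dict[str, int] = {}
    for terms in gene_terms.values():
        covered: set[str] = set()
        for t in terms:
            covered |= graph.ancestors(t)
        for t in covered:
            counts[t] = counts.get(t, 0) + 1
    return ICTable({t: c / g_tot for t, c in counts.items()})


def resnik_term_sim(ta: str, tb: str, ic: ICTable, graph: GOGraph) -> float:
    """IC of the lowest common ancestor; max IC when several LCAs exist."""
    lcas, _ = graph.lca_set(ta, tb)
    return max(ic[l] for l in lcas)


# -- the generalized-cosine gene similarity --------------------------------


def intelligo_sim(
    g: GeneVector,
    h: GeneVector,
    graph: GOGraph,
    cache: PairStatsTable | None = None,
) -> float | _Missing:
    """Generalized cosine between two gene vectors.

    Basis dot products come from *cache* when given (raising if a needed
    pair is absent) and are otherwise computed from the graph directly; both
    routes produce bit-identical results.
    """
    if g.is_empty or h.is_empty:
        return MISSING
    dot = cache.dot if cache is not None else graph.term_dot

    def inner(u: Mapping[str, float], v: Mapping[str, float]) -> float:
        total = 0.0
        for ti, a in sorted(u.items()):
            for tj, b in sorted(v.items()):
                total += a * b * dot(ti, tj)
        return total

    return inner(g.coeffs, h.coeffs) / (
        math.sqrt(inner(g.coeffs, g.coeffs)) * math.sqrt(inner(h.coeffs, h.coeffs))
    )


# -- reference measures ----------------------------------------------------


def lord_sim(
    g1_terms: Iterable[str],
    g2_terms: Iterable[str],
    ic: ICTable,
    graph: GOGraph,
) -> float | _Missing:
    """Mean Resnik term similarity over all cross pairs (unnormalised)."""
    t1, t2 = sorted(set(g1_terms)), sorted(set(g2_terms))
    if not t1 or not t2:
        return MISSING
    total = sum(resnik_term_sim(a, b, ic, graph) for a in t1 for b in t2)
    return total / (len(t1) * len(t2))


def lord_normalize(values: Sequence[float | _Missing]) -> list[float | _Missing]:
    """Scale a collection of raw Lord values by its maximum.

    The maximum maps to 1.0 and MISSING entries are preserved.  An all-zero
    collection is returned unscaled with a warning; an all-MISSING collection
    is an error.
    """
    finite = [v for v in values if not is_missing(v)]
    if not finite:
        raise UndefinedSimilarityError("cannot normalise an all-MISSING collection")
    peak = max(finite)
    if peak == 0.0:
        logger.warning("Lord normalisation: collection maximum is 0, left unscaled")
        return list(values)
    return [v if is_missing(v) else v / peak for v in values]


def almubaid_sim(
    g1_terms: Iterable[str],
    g2_terms: Iterable[str],
    graph: GOGraph,
    f: float = 0.2,
) -> float | _Missing:
    """Exponential transfer of the mean shortest path length.

    ``exp(-f * mean PL)`` with the path length between two terms taken as
    the minimal shortest path through a lowest common ancestor.  The decay
    factor defaults to 0.2 as originally proposed.
    """
    t1, t2 = sorted(set(g1_terms)), sorted(set(g2_terms))
    if not t1 or not t2:
        return MISSING
    total = sum(graph.min_spl(a, b)[0] for a in t1 for b in t2)
    return math.exp(-f * total / (len(t1) * len(t2)))


def weighted_cosine_sim(g: GeneVector, h: GeneVector) -> float | _Missing:
    """Classical cosine in an orthogonal basis: only shared terms contribute.

    Coefficients are expected to be bare IAF values (see
    :func:`intelligo.corpus.iaf_vector`).  Two genes without a common term
    score 0 even if their terms are semantically close.
    """
    if g.is_empty or h.is_empty:
        return MISSING
    shared = g.terms & h.terms
    num = sum(g.coeffs[t] * h.coeffs[t] for t in sorted(shared))
    if num == 0.0:
        return 0.0
    norm_g = math.sqrt(sum(w * w for w in g.coeffs.values()))
    norm_h = math.sqrt(sum(w * w for w in h.coeffs.values()))
    # Cauchy-Schwarz bounds the cosine at 1; strip float round-off
    return min(1.0, num / (norm_g * norm_h))


def extend_with_ancestors(terms: Iterable[str], graph: GOGraph) -> set[str]:
    """Union of the ancestor closures of the terms, minus the global root."""
    out: set[str] = set()
    for t in terms:
        out |= graph.ancestors(t)
    out.discard(graph.root)
    return out


def simgic_sim(
    g1_terms: Iterable[str],
    g2_terms: Iterable[str],
    ic: ICTable,
    graph: GOGraph,
) -> float | _Missing:
    """IC-weighted Jaccard over ancestor-extended annotation sets.

    The ratio of summed IC over the intersection to summed IC over the union
    of the two extended sets.  A union of total IC zero (every shared or
    private term maximally general) is undefined and returns MISSING.
    """
    t1, t2 = set(g1_terms), set(g2_terms)
    if not t1 or not t2:
        return MISSING
    e1 = extend_with_ancestors(t1, graph)
    e2 = extend_with_ancestors(t2, graph)
    union_ic = sum(ic[t] for t in sorted(e1 | e2))
    if union_ic == 0.0:
        logger.warning("SimGIC: union has zero total IC, similarity undefined")
        return MISSING
    inter_ic = sum(ic[t] for t in sorted(e1 & e2))
    # the intersection is a subset of the union; strip float round-off
    return min(1.0, inter_ic / union_ic)
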