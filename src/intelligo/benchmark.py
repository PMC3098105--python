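"""Intra-set / inter-set similarity and discriminating power over gene sets.

A gene set is any externally defined group expected to be functionally
coherent (a metabolic pathway, a domain clan, a cluster).  For a pairwise
gene similarity ``Sim``:

* intra-set similarity of a set of n genes is the mean of ``Sim`` over all
  n^2 ordered pairs, the diagonal included;
* inter-set similarity between sets of n and m genes is the mean over the
  n*m cross pairs;
* the discriminating power of ``Sim`` for set ``S_k`` within a collection of
  p sets is ``(p-1) * intra(S_k) / sum_{i != k} inter(S_k, S_i)`` — above 1
  when the measure scores the set as more coherent than its surroundings.

Pairs whose similarity is MISSING (a gene without usable annotation) are
excluded from both numerator and denominator and counted separately, so a
sparsely annotated set reports fewer evaluated pairs rather than a deflated
mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .corpus import (
    AnnotationRecord,
    EvidenceWeightList,
    GeneVector,
    build_vectors,
    compute_iaf,
    curate,
    iaf_vector,
)
from .errors import ParseError, UndefinedSimilarityError
from .graph import GOGraph, PairStatsTable
from .measures import (
    MISSING,
    almubaid_sim,
    intelligo_sim,
    is_missing,
    lord_normalize,
    lord_sim,
    simgic_sim,
    term_ic,
    weighted_cosine_sim,
)

logger = logging.getLogger(__name__)

#: Names of the pairwise measures understood by :func:`benchmark_report`.
MEASURES = ("intelligo", "lord", "almubaid", "wcosine", "simgic")

PairwiseSim = Callable[[str, str], object]


@dataclass(frozen=True)
class GeneSet:
    """An externally defined gene group (pathway, clan, cluster...)."""

    id: str
    genes: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.id!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SetStats:
    """Benchmark statistics for one gene set under one measure."""

    set_id: str
    intra: object = MISSING
    inter: dict[str, object] = field(default_factory=dict)
    dp: object = MISSING
    mv_count: int = 0


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read ``set_id<TAB>gene_id`` membership lines, preserving order."""
    members: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"expected 2 columns, got {len(parts)}", lineno)
            members.setdefault(parts[0], []).append(parts[1])
    return [GeneSet(sid, tuple(genes)) for sid, genes in members.items()]


# -- the three statistics --------------------------------------------------


def intra_set_sim(
    s: GeneSet,
    sim: PairwiseSim,
    exclude_diagonal: bool = False,
) -> tuple[object, int]:
    """Mean similarity over the n^2 ordered pairs of a set.

    The diagonal (self-pairs) is included by default; ``exclude_diagonal``
    drops it for callers who prefer the off-diagonal mean.  Returns
    ``(value, mv_count)`` where MISSING pairs are dropped from the mean and
    counted; the value itself is MISSING when no pair is computable.
    """
    values, mv = [], 0
    for gi in s.genes:
        for gj in s.genes:
            if exclude_diagonal and gi == gj:
                continue
            v = sim(gi, gj)
            if is_missing(v):
                mv += 1
            else:
                values.append(v)
    if not values:
        return MISSING, mv
    # fsum: the mean does not depend on pair enumeration order
    return math.fsum(values) / len(values), mv


def inter_set_sim(
    sa: GeneSet,
    sb: GeneSet,
    sim: PairwiseSim,
) -> tuple[object, int]:
    """Mean similarity over the n*m cross pairs of two sets.

    ``inter_set_sim(S, S)`` coincides with ``intra_set_sim(S)`` by
    construction.
    """
    values, mv = [], 0
    for gi in sa.genes:
        for gj in sb.genes:
            v = sim(gi, gj)
            if is_missing(v):
                mv += 1
            else:
                values.append(v)
    if not values:
        return MISSING, mv
    return math.fsum(values) / len(values), mv


def discriminating_power(
    collection: Sequence[GeneSet],
    k: str,
    sim: PairwiseSim,
    exclude_diagonal: bool = False,
) -> object:
    """Ratio of a set's intra-set similarity to its mean inter-set similarity.

    ``(p-1) * intra(S_k) / sum_{i != k} inter(S_k, S_i)`` over a collection
    of p >= 2 sets.  MISSING inter values are dropped and the count adjusted
    (the statistic stays intra / mean-of-available-inters); the result is
    MISSING when the intra value or every inter value is MISSING.
    """
    if len(collection) < 2:
        raise ValueError("discriminating power needs a collection of >= 2 sets")
    by_id = {s.id: s for s in collection}
    if k not in by_id:
        raise KeyError(f"set {k!r} not in collection")
    sk = by_id[k]
    intra, _ = intra_set_sim(sk, sim, exclude_diagonal=exclude_diagonal)
    if is_missing(intra):
        return MISSING
    inters = [
        inter_set_sim(sk, s, sim)[0] for s in collection if s.id != k
    ]
    finite = [v for v in inters if not is_missing(v)]
    if not finite:
        return MISSING
    denom = math.fsum(finite)
    if denom == 0.0:
        raise UndefinedSimilarityError(
            f"discriminating power of {k!r} undefined: every inter-set "
            f"similarity is 0"
        )
    return len(finite) * intra / denom


# -- end-to-end report -----------------------------------------------------


def make_pairwise(
    measure: str,
    graph: GOGraph,
    records: Sequence[AnnotationRecord],
    weights: EvidenceWeightList,
    cache: PairStatsTable | None = None,
) -> PairwiseSim:
    """Build a memoised symmetric pairwise similarity for one measure.

    The full corpus pipeline is run once (curation, IAF, vectors, IC) and a
    closure over gene ids is returned.  For the Lord measure the raw,
    unnormalised values are produced; normalisation over a collection is the
    caller's step (see :func:`benchmark_report`).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r} (choose from {MEASURES})")
    curated = curate(records, weights)
    iaf = compute_iaf(records)
    memo: dict[tuple[str, str], object] = {}

    if measure == "intelligo":
        vectors = build_vectors(curated, iaf)

        def pair(a: str, b: str) -> object:
            ga = vectors.get(a, GeneVector(a, {}))
            gb = vectors.get(b, GeneVector(b, {}))
            return intelligo_sim(ga, gb, graph, cache=cache)

    elif measure == "wcosine":
        vectors = {
            g: iaf_vector(g, terms, iaf) for g, terms in curated.items()
        }

        def pair(a: str, b: str) -> object:
            ga = vectors.get(a, GeneVector(a, {}))
            gb = vectors.get(b, GeneVector(b, {}))
            return weighted_cosine_sim(ga, gb)

    else:
        ic = term_ic(records, graph)
        term_sets = {g: frozenset(t) for g, t in curated.items()}

        def pair(a: str, b: str) -> object:
            ta = term_sets.get(a, frozenset())
            tb = term_sets.get(b, frozenset())
            if measure == "lord":
                return lord_sim(ta, tb, ic, graph)
            if measure == "almubaid":
                return almubaid_sim(ta, tb, graph)
            return simgic_sim(ta, tb, ic, graph)

    def memoised(a: str, b: str) -> object:
        key = (a, b) if a <= b else (b, a)
        if key not in memo:
            memo[key] = pair(*key)
        return memo[key]

    return memoised


def benchmark_report(
    collection: Sequence[GeneSet],
    measures: Sequence[str],
    graph: GOGraph,
    records: Sequence[AnnotationRecord],
    weights: EvidenceWeightList,
    cache: PairStatsTable | None = None,
    exclude_diagonal: bool = False,
) -> pd.DataFrame:
    """Intra, inter, discriminating power and MV count per set x measure.

    One row per (set, measure) in the input orders, with an ``inter_<id>``
    column per other set.  Lord values are normalised by the maximum raw
    value over every gene pair of the whole collection before any averaging.
    MISSING statistics appear as NaN.
    """
    ids = [s.id for s in collection]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene-set ids in collection")
    rows = []
    for measure in measures:
        sim = make_pairwise(measure, graph, records, weights, cache=cache)
        if measure == "lord":
            sim = _collection_normalized(sim, collection)
        for s in collection:
            stats = SetStats(set_id=s.id)
            stats.intra, stats.mv_count = intra_set_sim(
                s, sim, exclude_diagonal=exclude_diagonal
            )
            for other in collection:
                if other.id != s.id:
                    stats.inter[other.id], _ = inter_set_sim(s, other, sim)
            if len(collection) >= 2:
                stats.dp = discriminating_power(
                    collection, s.id, sim, exclude_diagonal=exclude_diagonal
                )
            row: dict[str, object] = {
                "set_id": s.id,
                "measure": measure,
                "n_genes": len(s),
                "intra": _na(stats.intra),
                "dp": _na(stats.dp),
                "mv_count": stats.mv_count,
            }
            for other_id in ids:
                if other_id != s.id:
                    row[f"inter_{other_id}"] = _na(stats.inter[other_id])
            rows.append(row)
    columns = ["set_id", "measure", "n_genes", "intra", "dp", "mv_count"]
    columns += [f"inter_{i}" for i in ids]
    return pd.DataFrame(rows).reindex(columns=columns)


def _na(value: object) -> object:
    return float("nan") if is_missing(value) else value


def _collection_normalized(
    sim: PairwiseSim, collection: Sequence[GeneSet]
) -> PairwiseSim:
    """Normalise a raw Lord pairwise function over a whole collection."""
    genes = sorted({g for s in collection for g in s.genes})
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i:]]
    raw = [sim(a, b) for a, b in pairs]
    normed = lord_normalize(raw)
    table: dict[tuple[str, str], object] = dict(zip(pairs, normed))

    def normalised(a: str, b: str) -> object:
        key = (a, b) if a <= b else (b, a)
        return table[key]

    return normalised
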