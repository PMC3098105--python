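"""Gene annotation corpora: parsing, evidence-code weighting, IAF, gene vectors.

Each gene annotation carries an evidence code (EC) recording how it was
assigned — experimentally, computationally, by author or curator statement,
or automatically (IEA).  A weight list maps each of the 17 ECs to a weight in
[0, 1]; built-in lists reproduce the four configurations studied with the
measure (all-equal, curation-graded, IEA-excluded, IEA-only).

A term's Inverse Annotation Frequency over a corpus is
``IAF(t) = log10(G_tot / G_t)`` with ``G_tot`` the number of annotated genes
and ``G_t`` the number of genes annotated by ``t``.  The coefficient of term
``t`` in the vector of gene ``g`` is ``w(g, t) * IAF(t)``, where ``w`` is the
largest weight among the ECs linking ``g`` to ``t``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigError, ParseError

logger = logging.getLogger(__name__)

#: The 17 evidence codes supported by the weighting scheme.
EVIDENCE_CODES = (
    "TAS", "NAS",                                  # author statement
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",      # experimental
    "ISS", "RCA", "ISA", "ISO", "ISM", "IGC",      # computational (supervised)
    "IC", "ND",                                    # curatorial
    "IEA",                                         # automatic
)

_GENE2GO_CATEGORY = {"Process": "BP", "Function": "MF", "Component": "CC"}
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term annotation with its evidence code."""

    gene: str
    term: str
    evidence: str
    aspect: str
    taxon: int
    qualifier: str | None = None


@dataclass(frozen=True)
class EvidenceWeightList:
    """Named mapping from evidence code to a weight in [0, 1]."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in EVIDENCE_CODES if c not in self.weights]
        if missing:
            raise ConfigError(f"weight list {self.name!r} lacks codes: {missing}")
        bad = {c: w for c, w in self.weights.items() if not 0.0 <= w <= 1.0}
        if bad:
            raise ConfigError(f"weights outside [0, 1] in {self.name!r}: {bad}")

    def __getitem__(self, code: str) -> float:
        try:
            return self.weights[code]
        except KeyError:
            raise ConfigError(f"evidence code {code!r} not in weight list "
                              f"{self.name!r}") from None

    def scaled(self, factor: float) -> "EvidenceWeightList":
        """Every weight multiplied by *factor* (must stay within [0, 1])."""
        return EvidenceWeightList(
            f"{self.name}*{factor}",
            {c: w * factor for c, w in self.weights.items()},
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EvidenceWeightList":
        data = json.loads(Path(path).read_text())
        return cls(data["name"], {str(k): float(v) for k, v in data["weights"].items()})


def _wl(name: str, default: float, **overrides: float) -> EvidenceWeightList:
    weights = {c: default for c in EVIDENCE_CODES}
    weights.update(overrides)
    return EvidenceWeightList(name, weights)


#: Built-in weight lists.  list1: every code weighs 1 (unweighted baseline).
#: list2: curation-graded weights.  list3: list2 with IEA excluded.
#: list4: IEA-only.
BUILTIN_WEIGHT_LISTS: dict[str, EvidenceWeightList] = {
    "list1": _wl("list1", 1.0),
    "list2": _wl(
        "list2", 0.8,
        TAS=1.0, NAS=0.5,
        ISS=0.6, RCA=0.6, ISA=0.6, ISO=0.6, ISM=0.6, IGC=0.6,
        IC=0.5, ND=0.0, IEA=0.4,
    ),
    "list3": _wl(
        "list3", 0.8,
        TAS=1.0, NAS=0.5,
        ISS=0.6, RCA=0.6, ISA=0.6, ISO=0.6, ISM=0.6, IGC=0.6,
        IC=0.5, ND=0.0, IEA=0.0,
    ),
    "list4": _wl("list4", 0.0, IEA=1.0),
}


def get_weight_list(name_or_path: str) -> EvidenceWeightList:
    """Resolve a built-in list name (case-insensitive) or a JSON config path."""
    key = name_or_path.lower()
    if key in BUILTIN_WEIGHT_LISTS:
        return BUILTIN_WEIGHT_LISTS[key]
    path = Path(name_or_path)
    if path.exists():
        return EvidenceWeightList.from_json(path)
    raise ConfigError(f"unknown weight list {name_or_path!r} "
                      f"(built-ins: {sorted(BUILTIN_WEIGHT_LISTS)})")


# -- readers ---------------------------------------------------------------


def read_annotations(
    path: str | Path,
    format: str,
    taxon: int | None = None,
    aspect: str | None = None,
) -> list[AnnotationRecord]:
    """Parse a gene2go or GAF 2.x annotation file.

    Records are filtered to the requested taxon and aspect; annotations
    qualified with ``NOT`` are dropped (negated function is not evidence of
    function) with a logged count, records with unknown evidence codes are
    skipped with a warning, and duplicate ``(gene, term, evidence)`` triples
    are de-duplicated.
    """
    if format == "gene2go":
        records, not_dropped = _read_gene2go(Path(path))
    elif format == "gaf":
        records, not_dropped = _read_gaf(Path(path))
    else:
        raise ConfigError(f"unknown annotation format {format!r}")
    if not_dropped:
        logger.info("dropped %d NOT-qualified annotations", not_dropped)

    out: list[AnnotationRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        if taxon is not None and rec.taxon != taxon:
            continue
        if aspect is not None and rec.aspect != aspect:
            continue
        key = (rec.gene, rec.term, rec.evidence)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def _read_gene2go(path: Path) -> tuple[list[AnnotationRecord], int]:
    # NCBI gene2go: tax_id GeneID GO_ID Evidence Qualifier GO_term PubMed Category
    records: list[AnnotationRecord] = []
    dropped_not = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ParseError(f"gene2go expects 8 columns, got {len(parts)}",
                                 lineno)
            tax, gene, term, evidence, qualifier, _name, _pubmed, category = parts
            try:
                taxon = int(tax)
            except ValueError:
                raise ParseError(f"bad tax_id {tax!r}", lineno) from None
            if "NOT" in qualifier.split("|"):
                dropped_not += 1
                continue
            if evidence not in EVIDENCE_CODES:
                logger.warning("line %d: unknown evidence code %r, skipped",
                               lineno, evidence)
                continue
            aspect = _GENE2GO_CATEGORY.get(category)
            if aspect is None:
                raise ParseError(f"bad category {category!r}", lineno)
            records.append(AnnotationRecord(
                gene=gene, term=term, evidence=evidence, aspect=aspect,
                taxon=taxon, qualifier=qualifier if qualifier != "-" else None,
            ))
    return records, dropped_not


def _read_gaf(path: Path) -> tuple[list[AnnotationRecord], int]:
    # GAF 2.x: 17 tab-separated columns; gene id from DB Object ID (col 2),
    # aspect from col 9 (P/F/C), taxon from col 13 ("taxon:NNNN[|taxon:...]").
    records: list[AnnotationRecord] = []
    dropped_not = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 15:
                raise ParseError(f"GAF expects >=15 columns, got {len(parts)}",
                                 lineno)
            qualifier = parts[3]
            if "NOT" in qualifier.split("|"):
                dropped_not += 1
                continue
            evidence = parts[6]
            if evidence not in EVIDENCE_CODES:
                logger.warning("line %d: unknown evidence code %r, skipped",
                               lineno, evidence)
                continue
            aspect = _GAF_ASPECT.get(parts[8])
            if aspect is None:
                raise ParseError(f"bad aspect {parts[8]!r}", lineno)
            taxon_field = parts[12].split("|")[0]
            if not taxon_field.startswith("taxon:"):
                raise ParseError(f"bad taxon field {parts[12]!r}", lineno)
            records.append(AnnotationRecord(
                gene=parts[1], term=parts[4], evidence=evidence, aspect=aspect,
                taxon=int(taxon_field.split(":", 1)[1]),
                qualifier=qualifier or None,
            ))
    return records, dropped_not


# -- curation and IAF ------------------------------------------------------


def curate(
    records: Iterable[AnnotationRecord],
    wl: EvidenceWeightList,
) -> dict[str, dict[str, float]]:
    """Retain, for each (gene, term), the greatest weight over its ECs.

    Pairs whose retained weight is zero are pruned from the sparse map; a
    gene whose every pair prunes away maps to an empty dict — the missing
    value marker used downstream.
    """
    out: dict[str, dict[str, float]] = {}
    for rec in records:
        w = wl[rec.evidence]
        gene_map = out.setdefault(rec.gene, {})
        if w > gene_map.get(rec.term, 0.0):
            gene_map[rec.term] = w
    for gene, gene_map in out.items():
        out[gene] = {t: w for t, w in gene_map.items() if w > 0.0}
    return out


@dataclass
class IAFTable:
    """Per-term Inverse Annotation Frequency over one corpus.

    ``iaf(t) = log10(g_tot / counts(t))``: frequent terms score low, rare
    terms score high.  Counts use all evidence codes — the weight list only
    enters the vector coefficients, never the corpus statistics.
    """

    g_tot: int
    counts: dict[str, int] = field(default_factory=dict)
    log_base: float = 10.0

    @property
    def iaf(self) -> dict[str, float]:
        return {t: self.value(t) for t in self.counts}

    def value(self, term: str) -> float:
        return math.log(self.g_tot / self.counts[term], self.log_base)

    def __contains__(self, term: str) -> bool:
        return term in self.counts

    def rebased(self, base: float) -> "IAFTable":
        """Same counts under a different logarithm base (scales all IAFs)."""
        return IAFTable(self.g_tot, dict(self.counts), log_base=base)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#g_tot={self.g_tot}\n")
            fh.write("term\tcount\tiaf\n")
            for t in sorted(self.counts):
                fh.write(f"{t}\t{self.counts[t]}\t{self.value(t)!r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "IAFTable":
        with Path(path).open() as fh:
            header = fh.readline().strip()
            if not header.startswith("#g_tot="):
                raise ParseError("missing #g_tot= header", 1)
            table = cls(g_tot=int(header.split("=", 1)[1]))
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line or line.startswith("term\t"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(f"expected 3 columns, got {len(parts)}",
                                     lineno)
                table.counts[parts[0]] = int(parts[1])
        return table


def compute_iaf(records: Iterable[AnnotationRecord]) -> IAFTable:
    """Inverse Annotation Frequency table from raw (uncurated) records."""
    genes: set[str] = set()
    term_genes: dict[str, set[str]] = {}
    for rec in records:
        genes.add(rec.gene)
        term_genes.setdefault(rec.term, set()).add(rec.gene)
    if not genes:
        raise ValueError("cannot compute IAF over an empty record list")
    return IAFTable(
        g_tot=len(genes),
        counts={t: len(gs) for t, gs in term_genes.items()},
    )


# -- gene vectors ----------------------------------------------------------


@dataclass(frozen=True)
class GeneVector:
    """Sparse term -> coefficient map for one gene; empty means unusable."""

    gene: str
    coeffs: Mapping[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.coeffs

    @property
    def terms(self) -> set[str]:
        return set(self.coeffs)


def build_gene_vector(
    gene: str,
    curated: Mapping[str, Mapping[str, float]],
    iaf: IAFTable,
) -> GeneVector:
    """Coefficients ``retained_weight * IAF`` for one gene.

    Terms absent from the IAF table are skipped with a warning; zero
    coefficients are pruned so an all-zero gene yields an empty vector.
    """
    coeffs: dict[str, float] = {}
    for term, weight in curated.get(gene, {}).items():
        if term not in iaf:
            logger.warning("gene %s: term %s absent from IAF table, skipped",
                           gene, term)
            continue
        coeff = weight * iaf.value(term)
        if coeff > 0.0:
            coeffs[term] = coeff
    return GeneVector(gene, coeffs)


def build_vectors(
    curated: Mapping[str, Mapping[str, float]],
    iaf: IAFTable,
) -> dict[str, GeneVector]:
    """Gene vectors for every curated gene."""
    return {g: build_gene_vector(g, curated, iaf) for g in curated}


def iaf_vector(gene: str, terms: Iterable[str], iaf: IAFTable) -> GeneVector:
    """Vector whose coefficients are the bare IAF values (no EC weighting).

    This is the representation used by the orthogonal weighted-cosine
    reference measure.
    """
    coeffs = {t: iaf.value(t) for t in terms if t in iaf and iaf.value(t) > 0.0}
    return GeneVector(gene, coeffs)
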