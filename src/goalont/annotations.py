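"""Annotation ingestion: GAF files, genotype-disease reports, OMIM mapping.

Produces normalized :class:`AnnotationRecord` rows and applies the corpus
filters (RIKEN cDNA genes, root-term annotations, unresolvable terms,
exact duplicates) with full arithmetic accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import IO, Iterable, Mapping, Optional, Sequence

from .model import normalize_curie
from .obo import Ontology

log = logging.getLogger(__name__)


class Aspect(str, Enum):
    FUNCTION = "function"
    PROCESS = "process"
    COMPONENT = "component"
    PHENOTYPE = "phenotype"
    DISEASE = "disease"


GAF_ASPECT = {"F": Aspect.FUNCTION, "P": Aspect.PROCESS, "C": Aspect.COMPONENT}

# The three GO namespace roots; annotations directly to these carry no
# information and are filtered (configurable in FilterConfig).
GO_ROOT_TERMS = frozenset({"GO:0008150", "GO:0003674", "GO:0005575"})


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    gene_symbol: str
    gene_name: str
    aspect: Aspect
    term_id: str
    evidence_code: str = ""
    source: str = ""


@dataclass
class GafReport:
    """Per-file accounting for GAF ingestion."""
    rows: int = 0
    skipped_not: int = 0
    skipped_short: int = 0


def read_gaf(source: IO[str] | str, filename: str = "gaf") -> tuple[list[AnnotationRecord], GafReport]:
    """Read a GAF 2.0 tab-separated annotation file.

    Comment lines start with ``!``.  Rows with fewer than 15 columns are
    skipped (and counted); rows whose qualifier contains ``NOT`` are skipped
    (and counted) — the representation has no negation to map them onto.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    records: list[AnnotationRecord] = []
    report = GafReport()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            report.skipped_short += 1
            log.debug("%s:%d: %d columns, skipping", filename, lineno, len(cols))
            continue
        report.rows += 1
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            report.skipped_not += 1
            continue
        db, db_id, symbol = cols[0], cols[1], cols[2]
        gene_id = normalize_curie(db_id if ":" in db_id else f"{db}:{db_id}")
        aspect = GAF_ASPECT.get(cols[8].strip())
        if aspect is None:
            report.skipped_short += 1
            log.debug("%s:%d: unknown aspect %r", filename, lineno, cols[8])
            continue
        records.append(
            AnnotationRecord(
                gene_id=gene_id,
                gene_symbol=symbol,
                gene_name=cols[9],
                aspect=aspect,
                term_id=normalize_curie(cols[4]),
                evidence_code=cols[6].strip(),
                source=f"{filename}:{lineno}",
            )
        )
    return records, report


@dataclass
class ReportColumnMap:
    """Which 0-based columns of a genotype-disease report hold what.

    The report layout is release-dependent, so it is configuration rather
    than hard-coded.  The default matches a compact
    (gene id, gene symbol, phenotype terms, OMIM ids) extract.
    """
    gene_id: int = 0
    gene_symbol: int = 1
    mp_terms: int = 2
    omim_ids: int = 3
    delimiter: str = ";"


def read_geno_disease_report(
    source: IO[str] | str,
    column_map: Optional[ReportColumnMap] = None,
    filename: str = "geno_disease",
) -> tuple[list[AnnotationRecord], list[tuple[str, str]]]:
    """Extract phenotype annotations and gene→OMIM pairs from a report.

    Emits one phenotype record per (gene, MP term) pair and one
    (gene id, OMIM id) pair per disease association; multi-valued cells are
    split on the configured delimiter.
    """
    cm = column_map or ReportColumnMap()
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    phenotype: list[AnnotationRecord] = []
    omim: list[tuple[str, str]] = []
    needed = max(cm.gene_id, cm.gene_symbol, cm.mp_terms, cm.omim_ids)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#") or line.startswith("!"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) <= needed:
            raise ValueError(
                f"{filename}:{lineno}: expected at least {needed + 1} columns "
                f"(column map {cm}), got {len(cols)}"
            )
        gene_id = normalize_curie(cols[cm.gene_id])
        symbol = cols[cm.gene_symbol].strip()
        for raw in cols[cm.mp_terms].split(cm.delimiter):
            raw = raw.strip()
            if not raw:
                continue
            phenotype.append(
                AnnotationRecord(
                    gene_id=gene_id,
                    gene_symbol=symbol,
                    gene_name="",
                    aspect=Aspect.PHENOTYPE,
                    term_id=normalize_curie(raw),
                    evidence_code="",
                    source=f"{filename}:{lineno}",
                )
            )
        for raw in cols[cm.omim_ids].split(cm.delimiter):
            raw = raw.strip()
            if raw:
                omim.append((gene_id, normalize_curie(raw)))
    return phenotype, omim


def read_omim_mapping(source: IO[str] | str) -> dict[str, str]:
    """Two-column TSV: OMIM id → disease-ontology term id."""
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    mapping: dict[str, str] = {}
    for line in lines:
        if not line.strip() or line.startswith("#") or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            continue
        mapping[normalize_curie(cols[0])] = normalize_curie(cols[1])
    return mapping


def map_omim_to_disease(
    omim_pairs: Sequence[tuple[str, str]],
    mapping: Mapping[str, str],
    symbols: Optional[Mapping[str, str]] = None,
) -> tuple[list[AnnotationRecord], int]:
    """Turn (gene, OMIM) pairs into disease annotations via the OMIM map.

    The mapping is expected to be partial: unmapped pairs are counted and
    logged, never fatal.
    """
    records: list[AnnotationRecord] = []
    unmapped = 0
    for gene_id, omim_id in omim_pairs:
        disease = mapping.get(omim_id)
        if disease is None:
            unmapped += 1
            log.debug("no disease-ontology mapping for %s", omim_id)
            continue
        records.append(
            AnnotationRecord(
                gene_id=gene_id,
                gene_symbol=(symbols or {}).get(gene_id, ""),
                gene_name="",
                aspect=Aspect.DISEASE,
                term_id=disease,
                evidence_code="",
                source=f"omim:{omim_id}",
            )
        )
    return records, unmapped


@dataclass
class FilterConfig:
    """Corpus filter rules.

    The RIKEN predicate matches MGI naming conventions for RIKEN cDNA
    clones; both clauses are configurable because the convention is a
    database habit, not a standard.
    """
    riken_name_substring: str = "RIKEN cDNA"
    riken_symbol_suffix: str = "Rik"
    root_terms: frozenset[str] = GO_ROOT_TERMS
    evidence_allowlist: Optional[frozenset[str]] = None  # None = keep all

    def is_riken(self, record: AnnotationRecord) -> bool:
        return (
            bool(self.riken_name_substring)
            and self.riken_name_substring in record.gene_name
        ) or (
            bool(self.riken_symbol_suffix)
            and record.gene_symbol.endswith(self.riken_symbol_suffix)
        )


@dataclass
class FilterReport:
    input_count: int = 0
    removed_riken: int = 0
    removed_root_terms: int = 0
    removed_unresolvable: int = 0
    removed_evidence: int = 0
    merged_duplicates: int = 0
    surviving: int = 0

    def check(self) -> None:
        assert self.surviving == (
            self.input_count
            - self.removed_riken
            - self.removed_root_terms
            - self.removed_unresolvable
            - self.removed_evidence
            - self.merged_duplicates
        ), f"filter arithmetic broken: {self}"


def filter_annotations(
    records: Sequence[AnnotationRecord],
    ontologies: Mapping[Aspect, Ontology],
    rules: Optional[FilterConfig] = None,
) -> tuple[list[AnnotationRecord], FilterReport]:
    """Apply the corpus filters and merge exact duplicates.

    Removes RIKEN cDNA genes, annotations to the GO namespace roots, and
    records whose term does not resolve (or is obsolete) in the ontology of
    its aspect.  Exact (gene, aspect, term) duplicates are merged into one
    record whose evidence code is the union of the duplicates'.
    Idempotent: filtering the output again changes nothing.
    """
    rules = rules or FilterConfig()
    report = FilterReport(input_count=len(records))
    kept: dict[tuple[str, Aspect, str], AnnotationRecord] = {}
    for rec in records:
        if rules.is_riken(rec):
            report.removed_riken += 1
            continue
        if rec.term_id in rules.root_terms:
            report.removed_root_terms += 1
            continue
        ontology = ontologies.get(rec.aspect)
        term = ontology.terms.get(rec.term_id) if ontology is not None else None
        if term is None or term.is_obsolete:
            report.removed_unresolvable += 1
            continue
        if (
            rules.evidence_allowlist is not None
            and rec.evidence_code
            and rec.evidence_code not in rules.evidence_allowlist
        ):
            report.removed_evidence += 1
            continue
        key = (rec.gene_id, rec.aspect, rec.term_id)
        if key in kept:
            report.merged_duplicates += 1
            prev = kept[key]
            codes = [c for c in prev.evidence_code.split("|") if c]
            for c in rec.evidence_code.split("|"):
                if c and c not in codes:
                    codes.append(c)
            kept[key] = replace(prev, evidence_code="|".join(codes))
        else:
            kept[key] = rec
    report.surviving = len(kept)
    report.check()
    return list(kept.values()), report
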