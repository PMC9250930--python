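"""Merge candidate-evidence streams and curate the final gene-family
catalogue.

Candidates arrive from two in-silico evidence streams -- conserved-domain
retrieval and profile (HMM) search -- each tagging hits as high or low
confidence and optionally as splice variants of a canonical gene.  Curation
is deliberately mechanical and auditable: low-confidence hits are removed,
splice variants collapse onto their canonical gene, duplicates collapse by
gene id, and everything dropped is listed in a report for human review.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import GeneModel, gene_family

logger = logging.getLogger("triadkit")

EVIDENCE_SOURCES = ("domain_retrieval", "profile_search")
_TRANSCRIPT_SUFFIX = re.compile(r"\.\d+$")


class CurationError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateHit:
    """One candidate gene from one (or, after merging, both) evidence streams."""

    gene_id: str
    evidence: tuple[str, ...]
    confidence: str = "high"
    is_splice_variant_of: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise CurationError("empty gene_id")
        ev = (self.evidence,) if isinstance(self.evidence, str) else tuple(
            self.evidence)
        object.__setattr__(self, "evidence", ev)
        for e in ev:
            if e not in EVIDENCE_SOURCES:
                raise CurationError(f"{self.gene_id}: unknown evidence {e!r}")
        if self.confidence not in ("high", "low"):
            raise CurationError(
                f"{self.gene_id}: confidence {self.confidence!r}")

    @property
    def dual_evidence(self) -> bool:
        return len(set(self.evidence)) > 1

    def canonical_id(self) -> str:
        base = self.is_splice_variant_of or self.gene_id
        return _TRANSCRIPT_SUFFIX.sub("", base)


@dataclass
class CatalogueEntry:
    gene_id: str
    family: str
    subfamily: str | None = None
    model: GeneModel | None = None
    evidence: tuple[str, ...] = ()


@dataclass
class Catalogue:
    """The curated catalogue plus an audit report of everything dropped."""

    entries: dict[str, CatalogueEntry] = field(default_factory=dict)
    dropped_low_confidence: list[str] = field(default_factory=list)
    collapsed_variants: dict[str, list[str]] = field(default_factory=dict)
    missing_model: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_ids(self) -> list[str]:
        return list(self.entries)


def merge_evidence(domain_hits: Iterable[CandidateHit],
                   profile_hits: Iterable[CandidateHit]) -> list[CandidateHit]:
    """Set union of the two evidence streams on gene id.

    A gene present in both streams is flagged dual-evidence; confidence is
    the maximum across streams (high beats low).  Conflicting splice-variant
    annotations for one gene are an error naming the gene.
    """
    merged: dict[str, CandidateHit] = {}
    for hit in list(domain_hits) + list(profile_hits):
        prev = merged.get(hit.gene_id)
        if prev is None:
            merged[hit.gene_id] = hit
            continue
        if (prev.is_splice_variant_of and hit.is_splice_variant_of
                and prev.is_splice_variant_of != hit.is_splice_variant_of):
            raise CurationError(
                f"conflicting splice-variant annotations for {hit.gene_id}: "
                f"{prev.is_splice_variant_of!r} vs "
                f"{hit.is_splice_variant_of!r}")
        evidence = tuple(dict.fromkeys(prev.evidence + hit.evidence))
        confidence = ("high" if "high" in (prev.confidence, hit.confidence)
                      else "low")
        merged[hit.gene_id] = CandidateHit(
            hit.gene_id, evidence, confidence,
            prev.is_splice_variant_of or hit.is_splice_variant_of)
    return list(merged.values())


def curate(candidates: Iterable[CandidateHit],
           gene_models: Mapping[str, GeneModel] | None = None,
           family_of=None) -> Catalogue:
    """Apply the published filtering logic to merged candidates.

    Low-confidence candidates are removed, splice variants collapse to their
    canonical gene, duplicates collapse by gene id, and candidates without a
    gene model (when models are supplied) are excluded and reported.
    ``family_of`` maps a canonical gene id to its family/(family, subfamily);
    when absent the family is taken from the gene model's annotation.
    Curation is idempotent.
    """
    cat = Catalogue()
    for hit in candidates:
        if hit.confidence == "low":
            cat.dropped_low_confidence.append(hit.gene_id)
            continue
        canonical = hit.canonical_id()
        if canonical != hit.gene_id:
            cat.collapsed_variants.setdefault(canonical, []).append(
                hit.gene_id)
        model = None
        if gene_models is not None:
            model = gene_models.get(canonical)
            if model is None:
                cat.missing_model.append(canonical)
                continue
        family, subfamily = _resolve_family(canonical, model, family_of)
        prev = cat.entries.get(canonical)
        if prev is None:
            cat.entries[canonical] = CatalogueEntry(
                canonical, family, subfamily, model,
                tuple(dict.fromkeys(hit.evidence)))
        else:
            prev.evidence = tuple(dict.fromkeys(prev.evidence + hit.evidence))
    if not cat.entries:
        logger.warning("curation produced an empty catalogue")
    # report duplicates of missing models only once
    cat.missing_model = sorted(set(cat.missing_model))
    return cat


def _resolve_family(gene_id: str, model: GeneModel | None,
                    family_of) -> tuple[str, str | None]:
    if family_of is not None:
        res = family_of(gene_id)
        if isinstance(res, tuple):
            return res
        return res, None
    if model is not None and model.subfamily:
        return gene_family(model.subfamily), model.subfamily
    if model is not None and model.family:
        return model.family, None
    raise CurationError(f"no family assignment for {gene_id}")


def count_by_family(catalogue: Catalogue) -> tuple[pd.Series, pd.Series]:
    """Gene counts per family and per subfamily (a partition of the catalogue)."""
    fam = pd.Series(
        [e.family for e in catalogue.entries.values()],
        dtype="object").value_counts().sort_index()
    sub = pd.Series(
        [e.subfamily for e in catalogue.entries.values()
         if e.subfamily is not None],
        dtype="object").value_counts().sort_index()
    return fam, sub


def catalogue_from_names(names: Iterable[str]) -> Catalogue:
    """Build a catalogue from rendered gene names (e.g. the packaged
    catalogue transcription), deriving family and subfamily from each name."""
    from .formats_io import parse_gene_name

    cat = Catalogue()
    for name in names:
        parsed = parse_gene_name(name)
        if name in cat.entries:
            raise CurationError(f"duplicate gene name {name}")
        cat.entries[name] = CatalogueEntry(name, parsed.family,
                                           parsed.subfamily)
    return cat


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

def read_candidate_hits(path: str | Path) -> list[CandidateHit]:
    """Read candidate hits from TSV (gene_id, evidence, confidence,
    canonical_id; the last column may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"gene_id", "evidence", "confidence"} - set(df.columns)
    if missing:
        raise CurationError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        canonical = getattr(row, "canonical_id", "") or None
        out.append(CandidateHit(row.gene_id, tuple(row.evidence.split("+")),
                                row.confidence, canonical))
    return out


def write_catalogue(catalogue: Catalogue, path: str | Path) -> None:
    rows = [(e.gene_id, e.family, e.subfamily or "",
             "+".join(e.evidence)) for e in catalogue.entries.values()]
    pd.DataFrame(rows, columns=["gene_id", "family", "subfamily",
                                "evidence"]).to_csv(path, sep="\t",
                                                    index=False)
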