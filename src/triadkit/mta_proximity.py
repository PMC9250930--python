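"""SNP-to-gene proximity in megabases for marker-trait association
follow-up.

Distances are computed on raw 1-based coordinates as |gene - snp| / 10^6 and
reported at full precision (printed to six decimals, which is exact for
integer coordinates below 2^40).  "Close proximity" has no canonical
definition; the window is a required, logged parameter defaulting to 15 Mb.
Consecutive same-subfamily genes can be reported as a range token with a
[min, max] distance interval, and range tokens expand back over consecutive
serial integers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .formats_io import (
    GeneModel,
    ProximityTableRow,
    SNPMarker,
    gene_family,
    read_table4_fixture,
)

logger = logging.getLogger("triadkit")

DEFAULT_WINDOW_MB = 15.0

_NAME = r"Ta[A-Za-z]+\d*-(?:[1-7][ABD]|Un)\d+"
_RANGE_RE = re.compile(rf"^({_NAME})\s*[-–—]\s*({_NAME})$")
_TOKEN_RE = re.compile(r"^(Ta[A-Za-z]+\d*)-?([1-7][ABD]|Un)(\d+)$")


class ChromosomeMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class NamedPosition:
    """A gene (or representative position) addressable by proximity search."""

    name: str
    chrom_group: int | str
    subgenome: str
    position: int


@dataclass(frozen=True)
class ProximityHit:
    marker: SNPMarker
    gene: str
    gene_position: int
    distance_mb: float


def distance_mb(snp: SNPMarker, gene: NamedPosition | GeneModel,
                gene_position: int | None = None) -> float:
    """|gene position - SNP position| / 1e6, same chromosome required.

    Passing a gene on a different chromosome raises
    :class:`ChromosomeMismatchError` -- never a silent large distance.
    """
    if (snp.chrom_group, snp.subgenome) != (gene.chrom_group, gene.subgenome):
        name = getattr(gene, "name", None) or getattr(gene, "gene_id", "?")
        raise ChromosomeMismatchError(
            f"{snp.marker_id} on {snp.chromosome} vs {name} on "
            f"{gene.chrom_group}{gene.subgenome}")
    pos = gene_position if gene_position is not None else (
        gene.position if isinstance(gene, NamedPosition) else gene.start)
    return abs(pos - snp.position) / 1e6


def as_named_positions(
        genes: Iterable[GeneModel | NamedPosition]) -> list[NamedPosition]:
    out = []
    for g in genes:
        if isinstance(g, NamedPosition):
            out.append(g)
        else:
            out.append(NamedPosition(g.gene_id, g.chrom_group, g.subgenome,
                                     g.start))
    return out


def find_nearby_genes(
    snps: Iterable[SNPMarker],
    genes: Iterable[GeneModel | NamedPosition],
    window_mb: float = DEFAULT_WINDOW_MB,
) -> list[ProximityHit]:
    """All (SNP, gene) pairs on the same chromosome within the window."""
    logger.info("proximity search with window %.3f Mb", window_mb)
    targets = as_named_positions(genes)
    by_chrom: dict[tuple, list[NamedPosition]] = {}
    for t in targets:
        by_chrom.setdefault((t.chrom_group, t.subgenome), []).append(t)
    hits = []
    for snp in snps:
        for t in by_chrom.get((snp.chrom_group, snp.subgenome), ()):
            d = distance_mb(snp, t)
            if d <= window_mb:
                hits.append(ProximityHit(snp, t.name, t.position, d))
    return hits


# ---------------------------------------------------------------------------
# printed-token handling
# ---------------------------------------------------------------------------

def expand_gene_token(token: str) -> list[str]:
    """Expand a printed gene token; range tokens cover consecutive serials.

    ``"TaNPF5-3B3–TaNPF5-3B10"`` (any dash variant) expands to the eight
    serials 3..10.  Non-range tokens are returned verbatim, including the
    table's typographic variants; nothing is corrected silently.
    """
    token = token.strip()
    m = _RANGE_RE.match(token)
    if not m:
        return [token]
    a, b = _TOKEN_RE.match(m.group(1)), _TOKEN_RE.match(m.group(2))
    if not (a and b and a.group(1) == b.group(1)
            and a.group(2) == b.group(2)):
        raise ValueError(f"range endpoints disagree: {token!r}")
    lo, hi = int(a.group(3)), int(b.group(3))
    if hi < lo:
        raise ValueError(f"descending range: {token!r}")
    return [f"{a.group(1)}-{a.group(2)}{s}" for s in range(lo, hi + 1)]


def token_family(token: str) -> str:
    """Family of a printed gene token, tolerant of typographic variants."""
    for fam in ("NRT2", "CLC", "SLAC"):
        if token.startswith(f"Ta{fam}"):
            return fam
    if token.startswith("TaNPF"):
        return "NPF"
    return gene_family(token)


def summarize_hits(hits: Iterable[ProximityHit]) -> dict:
    """Distinct SNPs, distinct genes, and genes per family."""
    hits = list(hits)
    snps = {h.marker.marker_id for h in hits}
    genes = sorted({h.gene for h in hits})
    per_family: dict[str, int] = {}
    for g in genes:
        try:
            fam = token_family(g)
        except Exception:
            fam = "other"
        per_family[fam] = per_family.get(fam, 0) + 1
    return {"n_snps": len(snps), "n_genes": len(genes),
            "genes_per_family": per_family}


# ---------------------------------------------------------------------------
# reproduction of the published proximity table
# ---------------------------------------------------------------------------

def _printed_match(exact_mb: float, printed: str) -> bool:
    """Does the recomputed distance reproduce the printed one?

    The table prints up to six decimals, drops trailing zeros, and rounds or
    truncates the last digit inconsistently; a value matches when it equals
    the printed string after either rounding or truncation to the printed
    precision.
    """
    nd = len(printed.partition(".")[2])
    scaled = exact_mb * 10 ** nd
    rounded = f"{exact_mb:.{nd}f}"
    truncated = f"{int(scaled) / 10 ** nd:.{nd}f}"
    return printed in (rounded, truncated)


def reproduce_table_distances(
        rows: Sequence[ProximityTableRow] | None = None) -> pd.DataFrame:
    """Re-derive every printed distance from printed coordinates.

    Each printed distance must equal |p - snp| / 1e6 for a gene position
    printed on the same chromosome (interval rows print only the interval
    endpoints, so the minimum distance of a multi-gene row can refer to an
    interior gene whose position is printed on another row of the same
    chromosome; positions are therefore pooled per chromosome).
    """
    rows = list(rows) if rows is not None else read_table4_fixture()
    pool: dict[str, set[int]] = {}
    for row in rows:
        pool.setdefault(row.marker.chromosome, set()).update(row.positions)
    out = []
    for row in rows:
        for printed in row.distances:
            candidates = pool[row.marker.chromosome]
            matches = [p for p in candidates
                       if _printed_match(abs(p - row.marker.position) / 1e6,
                                         printed)]
            out.append((row.marker.marker_id, row.marker.chromosome,
                        row.marker.position, printed,
                        matches[0] if matches else None,
                        bool(matches)))
    return pd.DataFrame(out, columns=[
        "marker_id", "chromosome", "snp_position", "printed_distance",
        "matching_gene_position", "reproduced"])


def table_positions(
        rows: Sequence[ProximityTableRow] | None = None) -> list[NamedPosition]:
    """Gene name -> printed position pairs, where a row pairs them 1:1."""
    rows = list(rows) if rows is not None else read_table4_fixture()
    seen: dict[str, NamedPosition] = {}
    for row in rows:
        if len(row.gene_tokens) != len(row.positions):
            continue
        if row.positions_are_range and len(row.gene_tokens) == 1:
            continue
        for token, pos in zip(row.gene_tokens, row.positions):
            if _RANGE_RE.match(token):
                continue
            np_ = NamedPosition(token, row.marker.chrom_group,
                                row.marker.subgenome, pos)
            prev = seen.get(token)
            if prev is not None and prev.position != pos:
                logger.warning("gene %s printed at both %d and %d",
                               token, prev.position, pos)
                continue
            seen[token] = np_
    return list(seen.values())


def summarize_table(
        rows: Sequence[ProximityTableRow] | None = None) -> dict:
    """Distinct SNP / distinct gene summaries of the printed table, with
    range tokens expanded over consecutive serials."""
    rows = list(rows) if rows is not None else read_table4_fixture()
    snps = {row.marker.marker_id for row in rows}
    genes: set[str] = set()
    for row in rows:
        for token in row.gene_tokens:
            genes.update(expand_gene_token(token))
    per_family: dict[str, int] = {}
    for g in sorted(genes):
        fam = token_family(g)
        per_family[fam] = per_family.get(fam, 0) + 1
    return {"n_snps": len(snps), "n_genes": len(genes),
            "genes_per_family": per_family}


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def hits_table(hits: Iterable[ProximityHit]) -> pd.DataFrame:
    rows = [(h.marker.marker_id, h.marker.chromosome, h.marker.position,
             h.gene, h.gene_position, f"{h.distance_mb:.6f}")
            for h in hits]
    return pd.DataFrame(rows, columns=[
        "marker_id", "chromosome", "snp_position", "gene", "gene_position",
        "distance_mb"])


def window_bed(snps: Iterable[SNPMarker], window_mb: float,
               path: str | Path) -> None:
    """BED (0-based half-open) window intervals around SNPs for browser use."""
    half = int(window_mb * 1e6)
    lines = []
    for s in snps:
        start = max(0, s.position - 1 - half)
        lines.append(f"{s.chromosome}\t{start}\t{s.position + half}\t"
                     f"{s.marker_id}")
    Path(path).write_text("\n".join(lines) + "\n")
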