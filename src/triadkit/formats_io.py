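"""Readers and writers for every external representation the pipeline touches.

The pipeline works on an allohexaploid genome with three subgenomes (A, B, D)
arranged in seven homoeologous chromosome groups, plus the unplaced-scaffold
pseudo-chromosome ``Un``.  Chromosome tokens therefore follow the grammar
``<digit 1-7><letter A|B|D>`` or the literal ``Un``; anything else is
rejected.  Coordinates are 1-based inclusive throughout (GFF3 convention) and
expression is stored as linear TPM (log transforms are applied only at
export time).

Two fixtures transcribed from the published catalogue ship with the package:

* ``table2_catalogue.tsv`` -- the full gene catalogue with homoeolog group
  ids and subgenome-aware gene names (412 named genes).
* ``table4_proximity.tsv`` -- the SNP-to-gene proximity table with printed
  marker positions, gene positions and distances in Mb.

Both carry a recorded SHA-256 checksum (``data/CHECKSUMS``) which is verified
on read.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

logger = logging.getLogger("triadkit")

SUBGENOMES = ("A", "B", "D")
TISSUES = ("root", "leaf_shoot", "spike", "grain")
STAGES = ("seedling", "vegetative", "reproductive")
FAMILIES = ("NPF", "NRT2", "CLC", "SLAC")

_CHROM_RE = re.compile(r"^([1-7])([ABD])$|^Un$")
_GENE_NAME_RE = re.compile(
    r"^(?P<prefix>[A-Z][a-z]*)"
    r"(?P<subfamily>NPF\d?|NRT2|CLC|SLAC)"
    r"-(?:(?P<chrom>[1-7])(?P<subg>[ABD])|(?P<un>Un))"
    r"(?P<serial>\d+)(?P<copy>[xy])?$"
)


class FormatError(ValueError):
    """Malformed input file or record."""


class FixtureError(RuntimeError):
    """A packaged fixture is missing or corrupted (fatal configuration error)."""


def parse_chromosome(token: str) -> tuple[int | str, str]:
    """Split a chromosome token into (chromosome group, subgenome).

    ``"3A" -> (3, "A")``; the unplaced sentinel ``"Un" -> ("Un", "Un")``.
    """
    m = _CHROM_RE.match(token)
    if not m:
        raise FormatError(f"unrecognised chromosome token {token!r}")
    if token == "Un":
        return "Un", "Un"
    return int(m.group(1)), m.group(2)


def chromosome_token(chrom_group: int | str, subgenome: str) -> str:
    return "Un" if chrom_group == "Un" else f"{chrom_group}{subgenome}"


def gene_family(subfamily: str) -> str:
    """Family token (NPF/NRT2/CLC/SLAC) for a subfamily token such as NPF5."""
    for fam in ("NRT2", "CLC", "SLAC"):
        if subfamily.startswith(fam):
            return fam
    if subfamily.startswith("NPF"):
        return "NPF"
    raise FormatError(f"unknown subfamily token {subfamily!r}")


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene model.

    ``exons`` is an ordered tuple of 1-based inclusive ``(start, end)``
    intervals; they must be sorted, non-overlapping and contained in
    ``[start, end]``.
    """

    gene_id: str
    chrom_group: int | str
    subgenome: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    family: str | None = None
    subfamily: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("empty gene_id")
        if self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: end ({self.end}) < start ({self.start})")
        if self.start < 1:
            raise FormatError(f"{self.gene_id}: coordinates are 1-based")
        if self.chrom_group == "Un" and self.subgenome != "Un":
            raise FormatError(
                f"{self.gene_id}: chromosome Un forces subgenome Un")
        if self.chrom_group != "Un" and self.chrom_group not in range(1, 8):
            raise FormatError(
                f"{self.gene_id}: chromosome group {self.chrom_group!r}")
        if self.subgenome not in ("A", "B", "D", "Un"):
            raise FormatError(f"{self.gene_id}: subgenome {self.subgenome!r}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise FormatError(f"{self.gene_id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def chromosome(self) -> str:
        return chromosome_token(self.chrom_group, self.subgenome)


@dataclass(frozen=True)
class ExpressionRecord:
    """One TPM measurement for a gene in a tissue/stage/cultivar sample."""

    gene_id: str
    tissue: str
    stage: str
    cultivar: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise FormatError(f"{self.gene_id}: unknown tissue {self.tissue!r}")
        if self.stage not in STAGES:
            raise FormatError(f"{self.gene_id}: unknown stage {self.stage!r}")
        if self.tpm < 0:
            raise FormatError(f"{self.gene_id}: negative tpm {self.tpm}")


@dataclass(frozen=True)
class SNPMarker:
    """A SNP marker at a 1-based position on one chromosome."""

    marker_id: str
    chrom_group: int | str
    subgenome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"{self.marker_id}: position must be >= 1")

    @property
    def chromosome(self) -> str:
        return chromosome_token(self.chrom_group, self.subgenome)


@dataclass(frozen=True)
class ParsedGeneName:
    """Components of a rendered subgenome-aware gene name."""

    prefix: str
    subfamily: str
    chrom_group: int | str
    subgenome: str
    serial: int
    copy_suffix: str | None = None

    def render(self) -> str:
        chrom = "Un" if self.chrom_group == "Un" else (
            f"{self.chrom_group}{self.subgenome}")
        return (f"{self.prefix}{self.subfamily}-{chrom}{self.serial}"
                f"{self.copy_suffix or ''}")

    @property
    def family(self) -> str:
        return gene_family(self.subfamily)


def parse_gene_name(name: str) -> ParsedGeneName:
    """Parse a rendered name such as ``TaNPF1-3A1`` or ``TaNRT2-6D11x``."""
    m = _GENE_NAME_RE.match(name)
    if not m:
        raise FormatError(f"unparseable gene name {name!r}")
    if m.group("un"):
        chrom: int | str = "Un"
        subg = "Un"
    else:
        chrom, subg = int(m.group("chrom")), m.group("subg")
    return ParsedGeneName(m.group("prefix"), m.group("subfamily"), chrom,
                          subg, int(m.group("serial")), m.group("copy"))


@dataclass
class NamedGroupRecord:
    """One catalogue row: a homoeolog group with its members and their names.

    ``members`` / ``names`` map subgenome -> ordered list; the two lists have
    equal length per subgenome (duplicated copies carry x/y name suffixes).
    """

    group_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sg in self.members:
            if len(self.members[sg]) != len(self.names.get(sg, [])):
                raise FormatError(
                    f"{self.group_id}: member/name lists differ for {sg}")

    @property
    def subfamily(self) -> str:
        stem, _, _ = self.group_id.partition("-")
        m = re.match(r"^[A-Z][a-z]*(NPF\d?|NRT2|CLC|SLAC)$", stem)
        if not m:
            raise FormatError(f"bad group id {self.group_id!r}")
        return m.group(1)

    @property
    def family(self) -> str:
        return gene_family(self.subfamily)

    @property
    def category(self) -> str:
        tag = self.group_id.rpartition("-")[2]
        letter = re.match(r"(TT|T|D|S)\d+$", tag)
        if not letter:
            raise FormatError(f"bad group id {self.group_id!r}")
        return {"T": "triad", "TT": "tetrad", "D": "diad",
                "S": "singleton"}[letter.group(1)]

    def all_names(self) -> list[str]:
        return [n for sg in ("A", "B", "D", "Un")
                for n in self.names.get(sg, [])]

    def all_members(self) -> list[str]:
        return [n for sg in ("A", "B", "D", "Un")
                for n in self.members.get(sg, [])]


@dataclass(frozen=True)
class ProximityTableRow:
    """One printed row of the SNP-proximity table, typography preserved.

    ``gene_tokens`` keeps the printed tokens (including en-dash range tokens
    such as ``TaNPF5-3B3–TaNPF5-3B10`` and the table's typographic variants);
    ``positions``/``distances`` carry the parsed numbers and
    ``positions_are_range``/``distances_are_range`` record whether the row
    printed them as an interval.
    """

    marker: SNPMarker
    gene_tokens: tuple[str, ...]
    positions: tuple[int, ...]
    distances: tuple[str, ...]
    positions_are_range: bool
    distances_are_range: bool

    @property
    def distance_values(self) -> tuple[float, ...]:
        return tuple(float(d) for d in self.distances)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file.

    Exons are attached to their gene through ``Parent`` linkage (directly or
    via an mRNA).  A malformed coordinate raises :class:`FormatError` naming
    the line; a gene on an unrecognised chromosome is skipped with a warning.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    id_to_gene: dict[str, str] = {}
    deferred_exons: list[tuple[int, str, int, int]] = []
    errors: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                errors.append(f"line {lineno}: expected 9 columns")
                continue
            seqid, _, ftype, start_s, end_s, _, strand, _, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if end < start:
                errors.append(f"line {lineno}: end ({end}) < start ({start})")
                continue
            attrs = _parse_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    errors.append(f"line {lineno}: gene without ID")
                    continue
                try:
                    chrom_group, subgenome = parse_chromosome(seqid)
                except FormatError:
                    logger.warning("%s line %d: unknown chromosome %r; "
                                   "gene %s skipped", path.name, lineno,
                                   seqid, gid)
                    continue
                genes[gid] = dict(
                    gene_id=gid, chrom_group=chrom_group, subgenome=subgenome,
                    start=start, end=end, strand=strand, exons=[],
                    family=attrs.get("family"),
                    subfamily=attrs.get("subfamily"))
                id_to_gene[gid] = gid
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid and parent in id_to_gene:
                    id_to_gene[mid] = id_to_gene[parent]
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    errors.append(f"line {lineno}: exon without Parent")
                    continue
                deferred_exons.append((lineno, parent, start, end))
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))

    for lineno, parent, start, end in deferred_exons:
        gid = id_to_gene.get(parent)
        if gid is None:
            logger.warning("%s line %d: exon parent %r unknown; skipped",
                           path.name, lineno, parent)
            continue
        genes[gid]["exons"].append((start, end))

    out = []
    for spec in genes.values():
        spec["exons"] = tuple(sorted(spec["exons"]))
        out.append(GeneModel(**spec))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene, mRNA and exon features)."""
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = [f"ID={g.gene_id}"]
        if g.family:
            attrs.append(f"family={g.family}")
        if g.subfamily:
            attrs.append(f"subfamily={g.subfamily}")
        lines.append("\t".join([g.chromosome, "triadkit", "gene",
                                str(g.start), str(g.end), ".", g.strand, ".",
                                ";".join(attrs)]))
        mrna_id = f"{g.gene_id}.1"
        lines.append("\t".join([g.chromosome, "triadkit", "mRNA",
                                str(g.start), str(g.end), ".", g.strand, ".",
                                f"ID={mrna_id};Parent={g.gene_id}"]))
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append("\t".join([
                g.chromosome, "triadkit", "exon", str(s), str(e), ".",
                g.strand, ".", f"ID={mrna_id}.exon{i};Parent={mrna_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV expression table (gene_id/tissue/stage/cultivar/tpm)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "tissue", "stage", "cultivar", "tpm"]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = ExpressionRecord(row.gene_id, row.tissue, row.stage,
                                   row.cultivar, float(row.tpm))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
        key = (rec.gene_id, rec.tissue, rec.stage, rec.cultivar)
        if key in seen:
            raise FormatError(f"{path} row {i}: duplicate sample {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_expression_table(records: Iterable[ExpressionRecord],
                           path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["gene_id", "tissue", "stage", "cultivar", "tpm"])
    df.to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> list[SNPMarker]:
    """Read a TSV SNP table (marker_id/chromosome/position)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"marker_id", "chromosome", "position"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cg, sg = parse_chromosome(row.chromosome)
            out.append(SNPMarker(row.marker_id, cg, sg, int(row.position)))
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path} row {i}: {exc}") from exc
    return out


def write_snp_table(snps: Iterable[SNPMarker], path: str | Path) -> None:
    rows = [(s.marker_id, s.chromosome, s.position) for s in snps]
    pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read one or more Newick trees from a file (one tree per statement)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    return list(trees)


def reconcile_leaves(tree: dendropy.Tree,
                     genes: Mapping[str, GeneModel]) -> list[str]:
    """Leaf labels with no corresponding gene model (reconciliation report)."""
    return sorted(t.label for t in tree.taxon_namespace
                  if t.label not in genes)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("triadkit.data").joinpath(name)
    try:
        data = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError(f"packaged fixture {name} is missing") from exc
    checksums = resources.files("triadkit.data").joinpath("CHECKSUMS")
    try:
        recorded = dict(line.split()[::-1] for line in
                        checksums.read_text().splitlines() if line.strip())
    except FileNotFoundError as exc:
        raise FixtureError("fixture checksum file is missing") from exc
    digest = hashlib.sha256(data).hexdigest()
    if recorded.get(name) != digest:
        raise FixtureError(f"fixture {name} checksum mismatch "
                           f"({digest} != {recorded.get(name)})")
    return data


def read_table2_fixture() -> list[NamedGroupRecord]:
    """The packaged full-catalogue transcription: one record per group."""
    text = _fixture_bytes("table2_catalogue.tsv").decode()
    rows = [l.split("\t") for l in text.splitlines()
            if l and not l.startswith("#")][1:]
    records: dict[str, NamedGroupRecord] = {}
    for group_id, refseq, chrom, name in rows:
        rec = records.setdefault(group_id, NamedGroupRecord(group_id))
        _, sg = parse_chromosome(chrom)
        rec.members.setdefault(sg, []).append(refseq)
        rec.names.setdefault(sg, []).append(name)
    for rec in records.values():
        rec.__post_init__()
    return list(records.values())


def read_table4_fixture() -> list[ProximityTableRow]:
    """The packaged SNP-proximity transcription, printed typography kept."""
    text = _fixture_bytes("table4_proximity.tsv").decode()
    rows = [l.split("\t") for l in text.splitlines()
            if l and not l.startswith("#")][1:]
    out = []
    for marker_id, chrom, snp_pos, genes, positions, distances in rows:
        cg, sg = parse_chromosome(chrom)
        marker = SNPMarker(marker_id, cg, sg, int(snp_pos))
        pos_range = "–" in positions
        dist_range = "–" in distances
        pos = tuple(int(p) for p in re.split(r"–|, ", positions))
        dist = tuple(re.split(r"–|, ", distances))
        out.append(ProximityTableRow(
            marker, tuple(t.strip() for t in genes.split(", ")),
            pos, dist, pos_range, dist_range))
    return out
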