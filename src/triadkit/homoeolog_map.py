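"""Homoeolog group inference from per-subfamily gene trees plus gene
locations, composition coding, group tabulation and intron counting.

A homoeolog group is a set of 1-4 genes from one subfamily: a triad carries
one gene per subgenome (A:B:D = 1:1:1), a diad has two subgenomes present, a
tetrad is a triad with one subgenome duplicated (1:1:2 patterns), and
anything ungrouped is a singleton.  Groups are extracted from the subfamily
gene tree as clades whose leaves satisfy the composition constraints and
share a chromosome group; among all clade selections the one grouping the
most genes wins, with deterministic tie-breaking (more distinct subgenomes,
then the smaller clade, then the lexicographically smallest member id).
Genes on the unplaced ``Un`` scaffold cannot satisfy the shared-chromosome
constraint and always become singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .formats_io import GeneModel, NamedGroupRecord, gene_family

logger = logging.getLogger("triadkit")

#: Composition classes of the published tabulation, in its column order.
COMPOSITION_CLASSES = (
    ("triad", "1:1:1"),
    ("diad", "1:1:0"), ("diad", "1:0:1"), ("diad", "0:1:1"),
    ("tetrad", "1:1:2"), ("tetrad", "1:2:1"), ("tetrad", "2:1:1"),
    ("singleton", "1:0:0"), ("singleton", "0:0:1"), ("singleton", "0:1:0"),
    ("singleton", "Un"),
)


class ReconciliationError(ValueError):
    """Tree leaves and gene models do not match."""


@dataclass(frozen=True)
class HomoeologGroup:
    """A set of 1-4 genes keyed by subgenome, with its A:B:D composition."""

    subfamily: str
    chrom_group: int | str
    members: tuple[tuple[str, tuple[str, ...]], ...]  # (subgenome, gene ids)

    @classmethod
    def build(cls, subfamily: str, chrom_group: int | str,
              members: Mapping[str, Sequence[str]]) -> "HomoeologGroup":
        ordered = tuple(
            (sg, tuple(members[sg])) for sg in ("A", "B", "D", "Un")
            if members.get(sg))
        return cls(subfamily, chrom_group, ordered)

    @property
    def family(self) -> str:
        return gene_family(self.subfamily)

    def members_of(self, subgenome: str) -> tuple[str, ...]:
        return dict(self.members).get(subgenome, ())

    def all_members(self) -> list[str]:
        return [g for _, ids in self.members for g in ids]

    @property
    def size(self) -> int:
        return sum(len(ids) for _, ids in self.members)

    @property
    def composition(self) -> tuple[int, int, int]:
        d = dict(self.members)
        return tuple(len(d.get(sg, ())) for sg in ("A", "B", "D"))

    @property
    def composition_code(self) -> str:
        """The composition as ``"a:b:d"``; ``Un`` members are not counted
        here and are reported separately."""
        return ":".join(str(c) for c in self.composition)

    @property
    def category(self) -> str:
        n = self.size
        if n == 1:
            return "singleton"
        if n == 4:
            return "tetrad"
        return "triad" if n == 3 else "diad"

    @property
    def n_un(self) -> int:
        return len(self.members_of("Un"))


def composition_code(group: HomoeologGroup) -> str:
    return group.composition_code


def count_introns(gene: GeneModel) -> int:
    """Number of introns = number of exons - 1 (zero exons is an error)."""
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: no exon structure")
    return len(gene.exons) - 1


# ---------------------------------------------------------------------------
# clade extraction
# ---------------------------------------------------------------------------

def _valid_clade(leaves: Sequence[GeneModel]) -> bool:
    """Can this leaf set stand as one homoeolog group?"""
    n = len(leaves)
    if not 2 <= n <= 4:
        return False
    if any(g.chrom_group == "Un" for g in leaves):
        return False
    if len({g.chrom_group for g in leaves}) != 1:
        return False
    counts: dict[str, int] = {}
    for g in leaves:
        counts[g.subgenome] = counts.get(g.subgenome, 0) + 1
    if n <= 3:
        return all(c == 1 for c in counts.values())
    return sorted(counts.values()) == [1, 1, 2]


def _clade_key(leaves: Sequence[GeneModel]) -> tuple:
    subgenomes = {g.subgenome for g in leaves}
    return (-len(subgenomes), len(leaves),
            min(g.gene_id for g in leaves))


def infer_homoeolog_groups(
    tree: dendropy.Tree,
    genes: Iterable[GeneModel],
) -> list[HomoeologGroup]:
    """Partition one subfamily's genes into homoeolog groups.

    Every tree leaf must name a gene model (else
    :class:`ReconciliationError`); every gene ends up in exactly one group,
    leaves not captured by any extracted clade becoming singletons.  The
    result is independent of leaf input order.
    """
    by_id = {g.gene_id: g for g in genes}
    subfamilies = {g.subfamily for g in by_id.values() if g.subfamily}
    subfamily = sorted(subfamilies)[0] if subfamilies else ""

    labels = [(lf.taxon.label if lf.taxon is not None else None)
              for lf in tree.leaf_node_iter()]
    missing = [lb or "<unlabelled>" for lb in labels
               if lb is None or lb not in by_id]
    if missing:
        raise ReconciliationError(
            "tree leaves without gene models: " + ", ".join(sorted(missing)))

    seed = tree.seed_node
    chosen = _best_selection(seed, by_id)[2]

    grouped_ids = {g for clade in chosen for g in clade}
    groups: list[HomoeologGroup] = []
    for clade in chosen:
        members: dict[str, list[str]] = {}
        for gid in sorted(clade):
            members.setdefault(by_id[gid].subgenome, []).append(gid)
        for sg in members:
            members[sg].sort(key=lambda gid: (by_id[gid].start, gid))
        chrom = by_id[next(iter(clade))].chrom_group
        groups.append(HomoeologGroup.build(
            by_id[next(iter(clade))].subfamily or subfamily, chrom, members))
    for gid in sorted(set(by_id) - grouped_ids):
        g = by_id[gid]
        groups.append(HomoeologGroup.build(
            g.subfamily or subfamily, g.chrom_group, {g.subgenome: [gid]}))
    groups.sort(key=lambda g: min(g.all_members()))
    return groups


def _best_selection(node, by_id):
    """Post-order DP: maximise the number of grouped genes in the subtree.

    Returns (grouped_count, tie_key_list, chosen_clades) where chosen_clades
    is a list of frozensets of gene ids.  Ties between taking a whole clade
    and decomposing it are broken by comparing the sorted lists of clade
    keys (more distinct subgenomes first, then smaller, then smallest id).
    """
    if node.is_leaf():
        return 0, [], []
    child_count, child_keys, child_clades = 0, [], []
    for ch in node.child_nodes():
        c, k, cl = _best_selection(ch, by_id)
        child_count += c
        child_keys.extend(k)
        child_clades.extend(cl)
    leaves = [by_id[lf.taxon.label] for lf in node.leaf_iter()]
    if _valid_clade(leaves):
        own = frozenset(g.gene_id for g in leaves)
        own_key = [_clade_key(leaves)]
        if (len(leaves) > child_count
                or (len(leaves) == child_count
                    and own_key < sorted(child_keys))):
            return len(leaves), own_key, [own]
    return child_count, sorted(child_keys), child_clades


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def _group_class(group: HomoeologGroup) -> tuple[str, str]:
    if group.n_un:
        if group.size == group.n_un == 1:
            return ("singleton", "Un")
        # mixed groups with Un members are tabulated by their placed part
    code = group.composition_code
    return (group.category, "Un" if code == "0:0:0" else code)


def tabulate_groups(groups: Iterable[HomoeologGroup]) -> pd.DataFrame:
    """Counts of each composition class per family, with an overall total.

    Columns follow the published tabulation: triads (1:1:1), diads by
    missing subgenome, tetrads by duplicated subgenome, singletons by
    subgenome plus unplaced.  The sum of members over all groups equals the
    catalogue size.
    """
    groups = list(groups)
    index = sorted({g.family for g in groups})
    cols = [f"{cat} {code}" for cat, code in COMPOSITION_CLASSES]
    table = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    for g in groups:
        cat, code = _group_class(g)
        col = f"{cat} {code}"
        if col not in table.columns:      # compositions outside the scheme
            table[col] = 0
        table.loc[g.family, col] += 1
    table.loc["Total"] = table.sum()
    return table


def category_counts(groups: Iterable[HomoeologGroup]) -> pd.Series:
    return pd.Series([g.category for g in groups],
                     dtype="object").value_counts()


def triad_gene_fraction(groups: Iterable[HomoeologGroup],
                        family: str | None = None) -> float:
    """Fraction of genes (optionally of one family) that sit in triads."""
    groups = [g for g in groups if family is None or g.family == family]
    total = sum(g.size for g in groups)
    in_triads = sum(g.size for g in groups if g.category == "triad")
    return in_triads / total if total else 0.0


def groups_from_records(
        records: Iterable[NamedGroupRecord]) -> list[HomoeologGroup]:
    """Materialise groups from catalogue records (fixture transcription).

    The chromosome group is read from the members' assigned names (their
    chromosome token), falling back to ``Un`` for fully unplaced groups.
    Conflicting chromosome groups among placed members are logged, and the
    majority chromosome is used.
    """
    from .formats_io import parse_gene_name

    out = []
    for rec in records:
        chroms = []
        for sg in ("A", "B", "D"):
            for name in rec.names.get(sg, []):
                parsed = parse_gene_name(name)
                if parsed.chrom_group != "Un":
                    chroms.append(parsed.chrom_group)
        if chroms:
            chrom = max(set(chroms), key=chroms.count)
            if len(set(chroms)) > 1:
                logger.warning("group %s: members on several chromosome "
                               "groups %s", rec.group_id, sorted(set(chroms)))
        else:
            chrom = "Un"
        out.append(HomoeologGroup.build(rec.subfamily, chrom, rec.members))
    return out


def ideogram_track(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """A plain (chromosome, position, label) track for external ideogram
    plotting."""
    rows = [(g.chromosome, g.start, g.gene_id) for g in genes]
    return pd.DataFrame(rows, columns=["chromosome", "position", "label"])
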