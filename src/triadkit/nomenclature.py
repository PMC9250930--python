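"""Subgenome-aware systematic gene naming for allopolyploid catalogues.

Group-level ids render as ``<prefix><subfamily>-<letter><ordinal>`` with
letter T (triad), D (diad), S (singleton) or TT (tetrad), numbered per
(subfamily, category) in positional order.  Gene names render as
``<prefix><subfamily>-<chromosome group><subgenome><serial>`` with optional
``x``/``y`` suffixes for duplicated copies within one subgenome.  Serial
counters run per (subfamily, chromosome group) and are shared across
subgenomes: homoeologs of one group differ only in the subgenome letter, a
group missing a subgenome still advances the shared counter, and numbering
restarts at 1 within each chromosome group.  Names therefore depend only on
subfamily, chromosome group, positions and group membership -- never on
input file order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import GeneModel, ParsedGeneName
from .homoeolog_map import HomoeologGroup

CATEGORY_LETTERS = {"triad": "T", "diad": "D", "singleton": "S",
                    "tetrad": "TT"}


class NamingError(ValueError):
    pass


@dataclass(frozen=True)
class GroupId:
    prefix: str
    subfamily: str
    category_letter: str
    ordinal: int

    def render(self) -> str:
        return (f"{self.prefix}{self.subfamily}-"
                f"{self.category_letter}{self.ordinal}")


def _chrom_sort_key(chrom_group) -> tuple:
    return (1, 0) if chrom_group == "Un" else (0, chrom_group)


def _group_order_key(group: HomoeologGroup,
                     genes: Mapping[str, GeneModel] | None):
    members = group.all_members()
    if genes:
        start = min(genes[m].start for m in members if m in genes)
    else:
        start = 0
    return (*_chrom_sort_key(group.chrom_group), start, min(members))


def assign_group_ids(
    groups: Iterable[HomoeologGroup],
    genes: Mapping[str, GeneModel] | None = None,
    prefix: str = "Ta",
) -> dict[HomoeologGroup, GroupId]:
    """Per-(subfamily, category) ordinals in positional order.

    Groups are ordered by chromosome group (``Un`` last), then by the
    minimum member start position, then by the smallest member id, so the
    assignment is invariant to input order.
    """
    ordered = sorted(groups, key=lambda g: (g.subfamily,
                                            _group_order_key(g, genes)))
    counters: dict[tuple[str, str], int] = {}
    out: dict[HomoeologGroup, GroupId] = {}
    for g in ordered:
        letter = CATEGORY_LETTERS[g.category]
        key = (g.subfamily, letter)
        counters[key] = counters.get(key, 0) + 1
        out[g] = GroupId(prefix, g.subfamily, letter, counters[key])
    return out


def assign_gene_names(
    groups: Iterable[HomoeologGroup],
    genes: Mapping[str, GeneModel] | None = None,
    prefix: str = "Ta",
) -> dict[str, ParsedGeneName]:
    """Assign one rendered name per gene.

    Each group consumes one serial from the shared (subfamily, chromosome
    group) counter for its placed members; members differ only in the
    subgenome letter.  Duplicated copies within one subgenome get ``x``/``y``
    suffixes by ascending start position.  Members on ``Un`` draw from the
    subfamily's own ``Un`` counter, one serial per gene.  A rendered-name
    collision is fatal and names the offending genes.
    """
    ordered = sorted(groups, key=lambda g: (g.subfamily,
                                            _group_order_key(g, genes)))
    serial: dict[tuple[str, int | str], int] = {}
    names: dict[str, ParsedGeneName] = {}
    for g in ordered:
        placed = [(sg, ids) for sg, ids in g.members if sg != "Un"]
        if placed:
            key = (g.subfamily, g.chrom_group)
            serial[key] = serial.get(key, 0) + 1
            n = serial[key]
            for sg, ids in placed:
                ordered_ids = sorted(
                    ids, key=lambda i: (genes[i].start if genes and i in genes
                                        else 0, i))
                suffixes = [None] if len(ids) == 1 else ["x", "y"][:len(ids)]
                for gid, suffix in zip(ordered_ids, suffixes):
                    names[gid] = ParsedGeneName(prefix, g.subfamily,
                                                g.chrom_group, sg, n, suffix)
        for gid in g.members_of("Un"):
            key = (g.subfamily, "Un")
            serial[key] = serial.get(key, 0) + 1
            names[gid] = ParsedGeneName(prefix, g.subfamily, "Un", "Un",
                                        serial[key], None)

    rendered: dict[str, str] = {}
    for gid, name in names.items():
        r = name.render()
        if r in rendered:
            raise NamingError(
                f"name collision: {r} assigned to both {rendered[r]} "
                f"and {gid}")
        rendered[r] = gid
    return names


def name_table(names: Mapping[str, ParsedGeneName],
               group_ids: Mapping[HomoeologGroup, GroupId],
               groups: Iterable[HomoeologGroup]) -> pd.DataFrame:
    """Flat (gene_id, name, group_id) export table."""
    gene_to_group = {}
    for g in groups:
        for gid in g.all_members():
            gene_to_group[gid] = group_ids[g].render()
    rows = [(gid, name.render(), gene_to_group.get(gid, ""))
            for gid, name in sorted(names.items())]
    return pd.DataFrame(rows, columns=["gene_id", "name", "group_id"])


def write_name_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
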