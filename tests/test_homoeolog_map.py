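"""Clade extraction against a brute-force oracle, composition coding,
tabulation and intron counting."""

import itertools
import random

import pytest

from triadkit import (
    HomoeologGroup,
    count_introns,
    groups_from_records,
    infer_homoeolog_groups,
    tabulate_groups,
    triad_gene_fraction,
)
from triadkit.homoeolog_map import ReconciliationError, _valid_clade

from conftest import make_gene, tree_from_newick


def test_canonical_triad_is_extracted():
    genes = [make_gene("gA", "3A"), make_gene("gB", "3B"),
             make_gene("gD", "3D")]
    (group,) = infer_homoeolog_groups(tree_from_newick("((gA,gB),gD);"),
                                      genes)
    assert group.category == "triad"
    assert group.composition_code == "1:1:1"


def test_single_leaf_tree_gives_singleton():
    (group,) = infer_homoeolog_groups(tree_from_newick("(gA);"),
                                      [make_gene("gA", "5B")])
    assert group.category == "singleton"
    assert group.composition_code == "0:1:0"


def test_unplaced_genes_are_always_singletons():
    genes = [make_gene("gA", "3A"), make_gene("gU", "Un")]
    groups = infer_homoeolog_groups(tree_from_newick("(gA,gU);"), genes)
    assert sorted(g.category for g in groups) == ["singleton", "singleton"]


def test_leaf_without_gene_model_is_a_reconciliation_error():
    with pytest.raises(ReconciliationError, match="ghost"):
        infer_homoeolog_groups(tree_from_newick("(gA,ghost);"),
                               [make_gene("gA", "3A")])


def test_chromosome_group_must_be_shared():
    genes = [make_gene("gA", "3A"), make_gene("gB", "4B"),
             make_gene("gD", "3D")]
    # (gA,gB) clade spans chromosome groups 3 and 4; no valid clade exists
    groups = infer_homoeolog_groups(tree_from_newick("((gA,gB),gD);"), genes)
    assert sorted(g.category for g in groups) == ["singleton"] * 3
    # with gA sister to gD the shared-chromosome diad is extracted
    groups = infer_homoeolog_groups(tree_from_newick("((gA,gD),gB);"), genes)
    diad = next(g for g in groups if g.category == "diad")
    assert set(diad.all_members()) == {"gA", "gD"}
    assert diad.composition_code == "1:0:1"


def test_published_clc_subfamily_topology(table2_records):
    """The chloride-channel subfamily: 10 triads plus one tetrad whose
    duplicated copies sit on the D subgenome of chromosome group 3."""
    recs = [r for r in table2_records if r.subfamily == "CLC"]
    genes, clades = [], []
    for rec in recs:
        ids = {sg: list(v) for sg, v in rec.members.items()}
        start = 1000
        for sg in ("A", "B", "D"):
            for i, gid in enumerate(ids.get(sg, [])):
                chrom = next(n for n in rec.names[sg])
                from triadkit import parse_gene_name
                parsed = parse_gene_name(
                    rec.names[sg][ids[sg].index(gid)])
                genes.append(make_gene(
                    gid, f"{parsed.chrom_group}{sg}", start=start + 500 * i,
                    subfamily="CLC"))
        if rec.category == "triad":
            clades.append(f"(({ids['A'][0]},{ids['B'][0]}),{ids['D'][0]})")
        else:
            clades.append(f"(({ids['D'][0]},{ids['D'][1]}),"
                          f"({ids['A'][0]},{ids['B'][0]}))")
    newick = clades[0]
    for c in clades[1:]:
        newick = f"({newick},{c})"
    groups = infer_homoeolog_groups(tree_from_newick(newick + ";"), genes)
    cats = [g.category for g in groups]
    assert cats.count("triad") == 10
    assert cats.count("tetrad") == 1
    tetrad = next(g for g in groups if g.category == "tetrad")
    assert tetrad.composition_code == "1:1:2"
    assert tetrad.chrom_group == 3
    assert set(tetrad.members_of("D")) == {"TraesCS3D02G126700",
                                           "TraesCS3D02G126600"}


@pytest.mark.parametrize("members,code", [
    ({"A": ["a"], "B": ["b"], "D": ["d"]}, "1:1:1"),
    ({"A": ["a"], "D": ["d"]}, "1:0:1"),
    ({"A": ["a"], "B": ["b"], "D": ["d1", "d2"]}, "1:1:2"),
])
def test_composition_codes(members, code):
    group = HomoeologGroup.build("NPF1", 3, members)
    assert group.composition_code == code


def test_published_tetrad_composition(table2_records):
    rec = next(r for r in table2_records if r.group_id == "TaNRT2-TT1")
    (group,) = groups_from_records([rec])
    assert group.composition_code == "1:1:2"


def test_tabulation_of_published_catalogue(table2_records):
    groups = groups_from_records(table2_records)
    npf_t = sum(1 for r in table2_records
                if r.family == "NPF" and r.category == "triad")
    assert npf_t == 72
    frac = triad_gene_fraction(groups, "NPF")
    assert round(100 * frac) == 74        # 216 of 292 genes
    table = tabulate_groups(groups)
    assert table.loc["Total", "triad 1:1:1"] >= 100
    assert int(table.drop(index="Total").sum().sum()) == len(groups)


def test_tabulation_recovers_planted_counts():
    genes, groups = [], []
    for i in range(10):
        for sg in "ABD":
            genes.append(make_gene(f"t{i}{sg}", f"2{sg}", subfamily="NPF1"))
        groups.append(HomoeologGroup.build(
            "NPF1", 2, {sg: [f"t{i}{sg}"] for sg in "ABD"}))
    for i in range(5):
        genes.append(make_gene(f"s{i}", "4A", subfamily="NPF1"))
        groups.append(HomoeologGroup.build("NPF1", 4, {"A": [f"s{i}"]}))
    table = tabulate_groups(groups)
    assert table.loc["NPF", "triad 1:1:1"] == 10
    assert table.loc["NPF", "singleton 1:0:0"] == 5
    assert sum(g.size for g in groups) == len(genes)


@pytest.mark.parametrize("n_exons,introns", [(1, 0), (4, 3)])
def test_intron_count(n_exons, introns):
    length = 100 * (2 * n_exons - 1)
    exons = tuple((100 + 200 * i, 199 + 200 * i) for i in range(n_exons))
    gene = make_gene("g", start=100, length=length, exons=exons)
    assert count_introns(gene) == introns


def test_intron_count_requires_exons():
    gene = make_gene("g", exons=())
    with pytest.raises(ValueError):
        count_introns(gene)


# ---------------------------------------------------------------------------
# brute-force oracle for the clade extraction
# ---------------------------------------------------------------------------

def _random_instance(rng):
    n = rng.randint(2, 12)
    genes = []
    for i in range(n):
        chrom = rng.choice(["2", "3"]) + rng.choice("ABD")
        genes.append(make_gene(f"g{i:02d}", chrom, subfamily="NPF1"))
    labels = [g.gene_id for g in genes]
    rng.shuffle(labels)
    while len(labels) > 1:
        i = rng.randrange(len(labels) - 1)
        merged = f"({labels[i]},{labels[i + 1]})"
        labels[i:i + 2] = [merged]
    return genes, labels[0] + ";"


def _oracle_max_grouped(tree, genes):
    """Exhaustive search over disjoint valid clades, maximising the number
    of grouped genes."""
    by_id = {g.gene_id: g for g in genes}
    clades = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if _valid_clade([by_id[l] for l in leaves]):
            clades.append(leaves)
    best = 0
    for r in range(len(clades) + 1):
        for combo in itertools.combinations(clades, r):
            union = set()
            ok = True
            for c in combo:
                if union & c:
                    ok = False
                    break
                union |= c
            if ok:
                best = max(best, len(union))
    return best


def test_greedy_extraction_matches_exhaustive_oracle():
    rng = random.Random(2024)
    for _ in range(40):
        genes, newick = _random_instance(rng)
        tree = tree_from_newick(newick)
        groups = infer_homoeolog_groups(tree, genes)
        grouped = sum(g.size for g in groups if g.size >= 2)
        assert grouped == _oracle_max_grouped(tree_from_newick(newick), genes)
        # partition property
        members = [m for g in groups for m in g.all_members()]
        assert sorted(members) == sorted(g.gene_id for g in genes)


def test_extraction_is_independent_of_leaf_input_order():
    rng = random.Random(7)
    genes, newick = _random_instance(rng)
    tree = tree_from_newick(newick)
    a = infer_homoeolog_groups(tree, genes)
    b = infer_homoeolog_groups(tree_from_newick(newick),
                               list(reversed(genes)))
    assert [g.members for g in a] == [g.members for g in b]
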