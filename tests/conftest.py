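import dendropy
import pytest

from triadkit import GeneModel, HomoeologGroup


def make_gene(gene_id, chrom="3A", start=100, length=400, exons=None,
              subfamily="NPF1", strand="+"):
    from triadkit import parse_chromosome

    cg, sg = parse_chromosome(chrom)
    end = start + length - 1
    if exons is None:
        exons = ((start, end),)
    return GeneModel(gene_id=gene_id, chrom_group=cg, subgenome=sg,
                     start=start, end=end, strand=strand, exons=tuple(exons),
                     family=None, subfamily=subfamily)


def make_triad(stem="g", chrom_group=3, subfamily="NPF1", start=100):
    genes = [make_gene(f"{stem}{sg}", f"{chrom_group}{sg}", start=start,
                       subfamily=subfamily) for sg in ("A", "B", "D")]
    group = HomoeologGroup.build(subfamily, chrom_group,
                                 {sg: [f"{stem}{sg}"] for sg in "ABD"})
    return genes, group


def tree_from_newick(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def table2_records():
    from triadkit import read_table2_fixture

    return read_table2_fixture()


@pytest.fixture(scope="session")
def table4_rows():
    from triadkit import read_table4_fixture

    return read_table4_fixture()
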