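"""Synthetic allopolyploid genomes, gene trees, expression matrices and SNP
panels with known ground truth.

The generator emulates a hexaploid genome: three subgenomes (A/B/D) in seven
homoeologous chromosome groups plus an unplaced ``Un`` scaffold pool.  Genes
come in homoeolog groups drawn from configurable triad/diad/tetrad/singleton
proportions (defaults follow the published catalogue's totals of
103:26:2:48).  Triad expression is drawn around the seven bias-category
centroids with Dirichlet noise, so the zero-noise limit lands exactly on the
centroid and classification becomes exactly invertible.  SNPs are planted at
known offsets from genes so proximity calls can be checked against truth.

Randomness: a single integer seed governs everything.  Each stage draws from
its own stream derived as ``SeedSequence((seed, STREAM_ID))`` with stream ids
0 (catalogue), 1 (expression) and 2 (SNP panel), so stages are reproducible
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats_io import (
    ExpressionRecord,
    GeneModel,
    SNPMarker,
    TISSUES,
    write_expression_table,
    write_gene_models,
    write_snp_table,
)

_STREAM_CATALOG, _STREAM_EXPRESSION, _STREAM_SNPS = 0, 1, 2

GROUP_CATEGORIES = ("triad", "diad", "tetrad", "singleton")

#: Ternary centroids of the seven homoeolog expression bias categories.
CENTROIDS: dict[str, tuple[float, float, float]] = {
    "Balanced": (1 / 3, 1 / 3, 1 / 3),
    "A_dominant": (1.0, 0.0, 0.0),
    "B_dominant": (0.0, 1.0, 0.0),
    "D_dominant": (0.0, 0.0, 1.0),
    "A_suppressed": (0.0, 0.5, 0.5),
    "B_suppressed": (0.5, 0.0, 0.5),
    "D_suppressed": (0.5, 0.5, 0.0),
}
BIAS_CATEGORIES = tuple(CENTROIDS)

SPECIFICITY_CLASSES = ("root_specific", "leaf_shoot_specific",
                       "spike_grain_specific", "ubiquitous", "not_expressed")

#: Tissues in which a gene of a given specificity class is active.
_ACTIVE_TISSUES = {
    "root_specific": ("root",),
    "leaf_shoot_specific": ("leaf_shoot",),
    "spike_grain_specific": ("spike", "grain"),
    "ubiquitous": TISSUES,
    "not_expressed": (),
}

_TISSUE_STAGE = {"root": "seedling", "leaf_shoot": "vegetative",
                 "spike": "reproductive", "grain": "reproductive"}

_CANONICAL_SUBFAMILIES = ("NPF1", "NPF2", "NPF3", "NPF4", "NPF5", "NPF6",
                          "NPF7", "NPF8", "NRT2", "CLC", "SLAC")


class ConfigError(ValueError):
    """Impossible or inconsistent simulation configuration."""


def _normalize(props: Mapping[str, float], keys: Sequence[str],
               what: str) -> dict[str, float]:
    unknown = set(props) - set(keys)
    if unknown:
        raise ConfigError(f"unknown {what} keys {sorted(unknown)}")
    total = float(sum(props.values()))
    if total <= 0 or any(v < 0 for v in props.values()):
        raise ConfigError(f"{what} proportions must be non-negative and "
                          "sum to a positive value")
    return {k: props.get(k, 0.0) / total for k in keys}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults mirror the study conditions of the catalogue being emulated:
    group categories in 103:26:2:48 proportions, a balanced-dominated bias
    mix, log-normal TPM magnitudes spanning roughly 1-100 TPM, and a marker
    panel in which roughly a fifth of the SNPs fall within the 15 Mb
    proximity window of some gene.
    """

    seed: int = 0
    n_subfamilies: int = 4
    groups_per_subfamily: int = 45
    group_category_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"triad": 103, "diad": 26, "tetrad": 2,
                                 "singleton": 48})
    bias_category_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "Balanced": 0.60, "A_dominant": 0.4 / 6, "B_dominant": 0.4 / 6,
            "D_dominant": 0.4 / 6, "A_suppressed": 0.4 / 6,
            "B_suppressed": 0.4 / 6, "D_suppressed": 0.4 / 6})
    specificity_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "root_specific": 0.05, "leaf_shoot_specific": 0.03,
            "spike_grain_specific": 0.04, "ubiquitous": 0.58,
            "not_expressed": 0.30})
    concentration: float = 200.0
    tpm_log_mean: float = 2.3   # natural log of TPM; exp(2.3) ~ 10 TPM
    tpm_log_sd: float = 1.0
    n_snps: int = 322
    snp_window_mix: float = 0.2
    window_mb: float = 15.0
    planted_offsets_bp: tuple[int, ...] | None = None
    chromosome_length_bp: int = 750_000_000
    gene_length_range_bp: tuple[int, int] = (1_000, 25_000)
    exon_count_range: tuple[int, int] = (1, 12)
    single_exon_subfamilies: tuple[str, ...] = ("NRT2",)
    tetrad_copy_spacing_bp: int = 100_000
    un_singleton_fraction: float = 0.19
    subfamily_names: tuple[str, ...] | None = None
    cultivar: str = "SYN"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ConfigError("concentration must be > 0")
        if self.n_subfamilies < 1 or self.groups_per_subfamily < 1:
            raise ConfigError("need at least one subfamily and one group")
        if not 0 <= self.snp_window_mix <= 1:
            raise ConfigError("snp_window_mix must be in [0, 1]")
        _normalize(self.group_category_proportions, GROUP_CATEGORIES,
                   "group category")
        _normalize(self.bias_category_proportions, BIAS_CATEGORIES,
                   "bias category")
        _normalize(self.specificity_proportions, SPECIFICITY_CLASSES,
                   "specificity class")

    def subfamilies(self) -> tuple[str, ...]:
        if self.subfamily_names is not None:
            if len(self.subfamily_names) != self.n_subfamilies:
                raise ConfigError("subfamily_names length must equal "
                                  "n_subfamilies")
            return self.subfamily_names
        names = []
        for i in range(self.n_subfamilies):
            base = _CANONICAL_SUBFAMILIES[i % len(_CANONICAL_SUBFAMILIES)]
            suffix = i // len(_CANONICAL_SUBFAMILIES)
            names.append(base if suffix == 0 else f"{base}v{suffix + 1}")
        return tuple(names)


@dataclass
class PlantedGroup:
    group_key: str
    subfamily: str
    chrom_group: int | str
    category: str
    members: dict[str, tuple[str, ...]]   # subgenome -> gene ids

    def all_members(self) -> list[str]:
        return [g for sg in ("A", "B", "D", "Un")
                for g in self.members.get(sg, ())]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    groups: list[PlantedGroup] = field(default_factory=list)
    group_of: dict[str, str] = field(default_factory=dict)
    bias: dict[tuple[str, str], str] = field(default_factory=dict)
    specificity: dict[str, str] = field(default_factory=dict)
    snp_distances: dict[str, tuple[str, float]] = field(default_factory=dict)

    def triads(self) -> list[PlantedGroup]:
        return [g for g in self.groups if g.category == "triad"]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed), stream)))


def _make_exons(rng: np.random.Generator, start: int, end: int,
                n_exons: int) -> tuple[tuple[int, int], ...]:
    """Partition [start, end] into n exons separated by introns (all >= 1 bp)."""
    length = end - start + 1
    n_parts = 2 * n_exons - 1
    if n_parts > length:
        n_exons = max(1, (length + 1) // 2)
        n_parts = 2 * n_exons - 1
    if n_exons == 1:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_parts - 1,
                              replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    pos = start
    for i in range(n_parts):
        seg = int(bounds[i + 1] - bounds[i])
        if i % 2 == 0:
            exons.append((pos, pos + seg - 1))
        pos += seg
    return tuple(exons)


def simulate_catalog(
    config: SimulationConfig,
) -> tuple[list[GeneModel], dict[str, str], SyntheticTruth]:
    """Generate gene models, one Newick tree per subfamily, and truth.

    Group members share a chromosome group, one gene per subgenome; a tetrad
    places its duplicated copies adjacently (within
    ``tetrad_copy_spacing_bp``) on one subgenome, and the per-subfamily tree
    contains each group as a clade with duplicated copies as sister leaves.
    """
    rng = _rng(config, _STREAM_CATALOG)
    cat_props = _normalize(config.group_category_proportions,
                           GROUP_CATEGORIES, "group category")
    probs = [cat_props[c] for c in GROUP_CATEGORIES]

    genes: list[GeneModel] = []
    trees: dict[str, str] = {}
    truth = SyntheticTruth()

    for subfamily in config.subfamilies():
        single_exon = subfamily in config.single_exon_subfamilies
        clades: list[str] = []
        prev_chrom: int | str | None = None
        for gi in range(config.groups_per_subfamily):
            category = GROUP_CATEGORIES[
                rng.choice(len(GROUP_CATEGORIES), p=probs)]
            group_key = f"{subfamily}.g{gi + 1}"
            on_un = (category == "singleton"
                     and rng.random() < config.un_singleton_fraction)
            if on_un:
                chrom_group: int | str = "Un"
            else:
                # consecutive groups of a subfamily sit on different
                # chromosome groups, so no clade spanning two planted groups
                # can satisfy the shared-chromosome constraint
                chrom_group = int(rng.integers(1, 8))
                while chrom_group == prev_chrom:
                    chrom_group = int(rng.integers(1, 8))
            prev_chrom = chrom_group
            if category == "triad":
                subgs = ["A", "B", "D"]
            elif category == "diad":
                subgs = sorted(rng.choice(["A", "B", "D"], size=2,
                                          replace=False))
            elif category == "tetrad":
                dup = str(rng.choice(["A", "B", "D"]))
                subgs = ["A", "B", "D", dup]
            else:
                subgs = ["Un" if on_un else str(rng.choice(["A", "B", "D"]))]

            lo, hi = config.gene_length_range_bp
            anchor = int(rng.integers(1, config.chromosome_length_bp - 4 * hi
                                      - 2 * config.tetrad_copy_spacing_bp))
            members: dict[str, list[str]] = {}
            copies = {}
            for sg in subgs:
                copies[sg] = copies.get(sg, 0) + 1
                copy = copies[sg]
                gid = f"Syn{subfamily}g{gi + 1:03d}{sg}" + (
                    str(copy) if sg in subgs and subgs.count(sg) > 1 else "")
                length = int(rng.integers(lo, hi + 1))
                if copy == 1:
                    start = anchor + int(rng.integers(0, 2_000_000))
                else:
                    prev = next(g for g in reversed(genes)
                                if g.gene_id == members[sg][-1])
                    start = prev.end + int(rng.integers(
                        1, max(2, config.tetrad_copy_spacing_bp - length)))
                n_exons = 1 if single_exon else int(
                    rng.integers(*config.exon_count_range))
                gene = GeneModel(
                    gene_id=gid,
                    chrom_group=chrom_group,
                    subgenome=sg,
                    start=start, end=start + length - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=_make_exons(rng, start, start + length - 1,
                                      n_exons),
                    family=None, subfamily=subfamily)
                # family token for synthetic subfamilies reuses the catalogue
                # grammar where possible
                genes.append(gene)
                members.setdefault(sg, []).append(gid)
                truth.group_of[gid] = group_key

            planted = PlantedGroup(group_key, subfamily, chrom_group,
                                   category,
                                   {sg: tuple(v) for sg, v in members.items()})
            truth.groups.append(planted)
            clades.append(_group_clade(planted))
        trees[subfamily] = _join_clades(clades) + ";"
    return genes, trees, truth


def _group_clade(group: PlantedGroup) -> str:
    ids = {sg: list(v) for sg, v in group.members.items()}
    flat = group.all_members()
    if group.category == "singleton":
        return flat[0]
    if group.category == "diad":
        return f"({flat[0]},{flat[1]})"
    if group.category == "triad":
        return f"(({ids['A'][0]},{ids['B'][0]}),{ids['D'][0]})"
    dup_sg = next(sg for sg, v in ids.items() if len(v) == 2)
    others = [ids[sg][0] for sg in ("A", "B", "D") if sg != dup_sg]
    return (f"(({ids[dup_sg][0]},{ids[dup_sg][1]}),"
            f"({others[0]},{others[1]}))")


def _join_clades(clades: list[str]) -> str:
    out = clades[0]
    for c in clades[1:]:
        out = f"({out},{c})"
    return out


def _draw_fractions(rng: np.random.Generator, category: str,
                    concentration: float) -> np.ndarray:
    centroid = np.array(CENTROIDS[category])
    if math.isinf(concentration):
        return centroid
    support = centroid > 0
    out = np.zeros(3)
    if support.sum() == 1:
        out[support] = 1.0
        return out
    out[support] = rng.dirichlet(concentration * centroid[support])
    return out


def simulate_expression(truth: SyntheticTruth,
                        config: SimulationConfig) -> list[ExpressionRecord]:
    """Generate the TPM matrix implied by the planted truth.

    Each group draws a tissue-specificity class.  In its active tissues a
    triad draws a bias category and splits a log-normal total TPM by
    Dirichlet fractions around that category's centroid; non-triad genes get
    independent log-normal magnitudes.  Inactive tissues receive
    sub-threshold noise (< 1 TPM).  ``truth.specificity`` records, per gene,
    the class implied by the values actually emitted -- a strongly biased
    triad can silence one homoeolog even in an active tissue, and the truth
    label reflects that.
    """
    rng = _rng(config, _STREAM_EXPRESSION)
    bias_props = _normalize(config.bias_category_proportions, BIAS_CATEGORIES,
                            "bias category")
    bias_p = [bias_props[c] for c in BIAS_CATEGORIES]
    spec_props = _normalize(config.specificity_proportions,
                            SPECIFICITY_CLASSES, "specificity class")
    spec_p = [spec_props[c] for c in SPECIFICITY_CLASSES]

    tpm: dict[tuple[str, str], float] = {}
    for group in truth.groups:
        spec_class = SPECIFICITY_CLASSES[
            rng.choice(len(SPECIFICITY_CLASSES), p=spec_p)]
        active = set(_ACTIVE_TISSUES[spec_class])
        members = group.all_members()
        for tissue in TISSUES:
            if group.category == "triad":
                ids = [group.members[sg][0] for sg in ("A", "B", "D")]
                if tissue in active:
                    category = BIAS_CATEGORIES[
                        rng.choice(len(BIAS_CATEGORIES), p=bias_p)]
                    truth.bias[(group.group_key, tissue)] = category
                    fractions = _draw_fractions(rng, category,
                                                config.concentration)
                    # floored just above 1 TPM so an active pair can never
                    # fall below the expression filter through fraction
                    # arithmetic or 6-decimal rounding
                    total = max(1.0001, float(rng.lognormal(
                        config.tpm_log_mean, config.tpm_log_sd)))
                    for gid, f in zip(ids, fractions):
                        tpm[(gid, tissue)] = total * float(f)
                else:
                    noise = rng.uniform(0, 0.3, size=3)
                    for gid, v in zip(ids, noise):
                        tpm[(gid, tissue)] = float(v)
            else:
                for gid in members:
                    if tissue in active:
                        tpm[(gid, tissue)] = max(1.0001, float(
                            rng.lognormal(config.tpm_log_mean,
                                          config.tpm_log_sd)))
                    else:
                        tpm[(gid, tissue)] = float(rng.uniform(0, 0.5))

    # the recoverable specificity label per gene, from the emitted values
    classes = {"root": "root_specific", "leaf_shoot": "leaf_shoot_specific",
               "spike_grain": "spike_grain_specific"}
    tclass = {"root": ("root",), "leaf_shoot": ("leaf_shoot",),
              "spike_grain": ("spike", "grain")}
    for gid in truth.group_of:
        expressed = {cls for cls, tissues in tclass.items()
                     if max(tpm[(gid, t)] for t in tissues) >= 1.0}
        if not expressed:
            truth.specificity[gid] = "not_expressed"
        elif len(expressed) == 1:
            truth.specificity[gid] = classes[expressed.pop()]
        else:
            truth.specificity[gid] = "ubiquitous"

    return [ExpressionRecord(gid, tissue, _TISSUE_STAGE[tissue],
                             config.cultivar, round(value, 6))
            for (gid, tissue), value in tpm.items()]


def simulate_snps(
    genes: Sequence[GeneModel], config: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> tuple[list[SNPMarker], SyntheticTruth]:
    """Generate a marker panel; a configured fraction is planted in-window.

    Planted markers sit at known offsets (uniform within the window, or the
    explicit ``planted_offsets_bp``) from the start coordinate of randomly
    chosen placed genes; the rest are uniform over the chromosomes.  True
    planted distances (Mb) are recorded in ``truth.snp_distances``.
    """
    if not genes:
        raise ConfigError("simulate_snps needs a non-empty gene set")
    rng = _rng(config, _STREAM_SNPS)
    truth = truth if truth is not None else SyntheticTruth()
    placed = [g for g in genes if g.chrom_group != "Un"]
    if not placed:
        raise ConfigError("no genes on placed chromosomes")
    n_planted = round(config.n_snps * config.snp_window_mix)
    snps: list[SNPMarker] = []
    window_bp = int(config.window_mb * 1e6)
    for i in range(config.n_snps):
        marker_id = f"SYNSNP{i + 1:05d}"
        if i < n_planted:
            gene = placed[int(rng.integers(len(placed)))]
            if config.planted_offsets_bp is not None:
                offset = int(config.planted_offsets_bp[
                    i % len(config.planted_offsets_bp)])
            else:
                offset = int(rng.integers(0, window_bp + 1))
            sign = 1 if rng.random() < 0.5 else -1
            pos = max(1, gene.start + sign * offset)
            truth.snp_distances[marker_id] = (
                gene.gene_id, abs(pos - gene.start) / 1e6)
            snps.append(SNPMarker(marker_id, gene.chrom_group,
                                  gene.subgenome, pos))
        else:
            cg = int(rng.integers(1, 8))
            sg = str(rng.choice(["A", "B", "D"]))
            pos = int(rng.integers(1, config.chromosome_length_bp))
            snps.append(SNPMarker(marker_id, cg, sg, pos))
    return snps, truth


def simulate_all(config: SimulationConfig):
    """Catalogue, trees, expression and SNPs in one call."""
    genes, trees, truth = simulate_catalog(config)
    expression = simulate_expression(truth, config)
    snps, truth = simulate_snps(genes, config, truth)
    return genes, trees, truth, expression, snps


def write_simulation(outdir: str | Path, genes, trees, truth, expression,
                     snps) -> dict[str, Path]:
    """Write a simulated study in the same dialects the readers consume.

    Truth is written as TSV sidecars so downstream recovery can be audited
    without re-running the generator.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genes"] = outdir / "genes.gff3"
    write_gene_models(genes, paths["genes"])
    treedir = outdir / "trees"
    treedir.mkdir(exist_ok=True)
    for sf, newick in trees.items():
        p = treedir / f"{sf}.nwk"
        p.write_text(newick + "\n")
        paths[f"tree:{sf}"] = p
    paths["expression"] = outdir / "expression.tsv"
    write_expression_table(expression, paths["expression"])
    paths["snps"] = outdir / "snps.tsv"
    write_snp_table(snps, paths["snps"])

    lines = ["gene_id\tgroup_key\tsubfamily\tchrom_group\tcategory"]
    for g in truth.groups:
        for gid in g.all_members():
            lines.append(f"{gid}\t{g.group_key}\t{g.subfamily}\t"
                         f"{g.chrom_group}\t{g.category}")
    (outdir / "truth_groups.tsv").write_text("\n".join(lines) + "\n")
    lines = ["group_key\ttissue\tcategory"]
    for (gk, tissue), cat in truth.bias.items():
        lines.append(f"{gk}\t{tissue}\t{cat}")
    (outdir / "truth_bias.tsv").write_text("\n".join(lines) + "\n")
    lines = ["gene_id\tclass"]
    for gid, cls in truth.specificity.items():
        lines.append(f"{gid}\t{cls}")
    (outdir / "truth_specificity.tsv").write_text("\n".join(lines) + "\n")
    lines = ["marker_id\tgene_id\tdistance_mb"]
    for mid, (gid, d) in truth.snp_distances.items():
        lines.append(f"{mid}\t{gid}\t{d:.6f}")
    (outdir / "truth_snps.tsv").write_text("\n".join(lines) + "\n")
    paths["truth_groups"] = outdir / "truth_groups.tsv"
    return paths
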