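"""Ternary bias classification, TPM filtering, per-tissue summaries and
tissue-specificity calls."""

import math

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from triadkit import (
    ExpressionRecord,
    classify_triad,
    call_tissue_specificity,
    filter_triads,
    normalize_triad,
    summarize_by_tissue,
    triad_profiles,
)

from conftest import make_triad


def records_for(group, tissue_tpms, cultivar="CS"):
    """tissue_tpms: {tissue: (tpm_A, tpm_B, tpm_D)}"""
    stage = {"root": "seedling", "leaf_shoot": "vegetative",
             "spike": "reproductive", "grain": "reproductive"}
    out = []
    for tissue, (ta, tb, td) in tissue_tpms.items():
        for sg, tpm in zip("ABD", (ta, tb, td)):
            gid = group.members_of(sg)[0]
            out.append(ExpressionRecord(gid, tissue, stage[tissue],
                                        cultivar, tpm))
    return out


class TestFilter:
    def test_sum_below_threshold_is_excluded(self):
        _, triad = make_triad()
        recs = records_for(triad, {"root": (0.2, 0.3, 0.4)})
        assert filter_triads(recs, [triad]) == []

    def test_sum_at_threshold_is_retained(self):
        _, triad = make_triad()
        recs = records_for(triad, {"root": (1.0, 0.0, 0.0)})
        retained = filter_triads(recs, [triad])
        assert [(t, v) for _, t, v in retained] == [("root",
                                                     (1.0, 0.0, 0.0))]

    def test_per_homoeolog_option_is_stricter(self):
        _, triad = make_triad()
        recs = records_for(triad, {"root": (5.0, 0.5, 2.0)})
        assert len(filter_triads(recs, [triad])) == 1
        assert filter_triads(recs, [triad], per_homoeolog=True) == []

    def test_missing_member_counts_as_zero(self):
        _, triad = make_triad()
        recs = [r for r in records_for(triad, {"root": (0.4, 0.3, 5.0)})
                if r.gene_id != triad.members_of("D")[0]]
        assert filter_triads(recs, [triad]) == []

    def test_planted_subthreshold_triads_are_exactly_the_excluded_ones(self):
        from triadkit import SimulationConfig, simulate_catalog
        from triadkit import simulate_expression

        cfg = SimulationConfig(
            seed=13, n_subfamilies=1, groups_per_subfamily=60,
            group_category_proportions={"triad": 1.0},
            specificity_proportions={"ubiquitous": 0.5,
                                     "not_expressed": 0.5})
        _, _, truth = simulate_catalog(cfg)
        expr = simulate_expression(truth, cfg)
        from triadkit import HomoeologGroup

        triads = [HomoeologGroup.build(pg.subfamily, pg.chrom_group,
                                       {sg: list(v) for sg, v
                                        in pg.members.items()})
                  for pg in truth.groups]
        retained = filter_triads(expr, triads)
        retained_keys = {(min(g.all_members()), t) for g, t, _ in retained}
        planted = {(min(pg.all_members()), tissue)
                   for pg in truth.groups
                   for (gk, tissue) in truth.bias
                   if gk == pg.group_key}
        assert retained_keys == planted


class TestNormalizeAndClassify:
    @pytest.mark.parametrize("tpms,expected", [
        ((10, 10, 10), (1 / 3, 1 / 3, 1 / 3)),
        ((3, 0, 0), (1.0, 0.0, 0.0)),
        ((5, 4, 1), (0.5, 0.4, 0.1)),
    ])
    def test_normalization_is_exact(self, tpms, expected):
        assert normalize_triad(*tpms) == pytest.approx(expected)

    def test_all_zero_input_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_triad(0.0, 0.0, 0.0)

    @pytest.mark.parametrize("point,expected", [
        ((1 / 3, 1 / 3, 1 / 3), "Balanced"),
        ((1, 0, 0), "A_dominant"),
        ((0, 1, 0), "B_dominant"),
        ((0, 0.5, 0.5), "A_suppressed"),
        ((0.5, 0.4, 0.1), "D_suppressed"),
    ])
    def test_nearest_centroid(self, point, expected):
        from triadkit import BIAS_CATEGORIES

        category, dists = classify_triad(*point)
        assert category == expected
        # the winning distance really is the minimum of all seven
        assert min(dists) == dists[BIAS_CATEGORIES.index(expected)]

    def test_exact_centroid_has_zero_distance(self):
        _, dists = classify_triad(1, 0, 0)
        assert dists[1] == 0.0

    @given(st.tuples(st.floats(0.01, 100), st.floats(0.01, 100),
                     st.floats(0.01, 100)),
           st.floats(0.001, 1000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, tpms, scale):
        a = classify_triad(*normalize_triad(*tpms))[0]
        b = classify_triad(*normalize_triad(*(t * scale for t in tpms)))[0]
        assert a == b

    @given(st.tuples(st.floats(0.01, 100), st.floats(0.01, 100),
                     st.floats(0.01, 100)))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_swapping_a_and_b_swaps_the_category(self, tpms):
        ta, tb, td = tpms
        assume(ta != tb)   # on the mirror plane the tie-break order differs
        swap = {"Balanced": "Balanced", "D_dominant": "D_dominant",
                "D_suppressed": "D_suppressed",
                "A_dominant": "B_dominant", "B_dominant": "A_dominant",
                "A_suppressed": "B_suppressed",
                "B_suppressed": "A_suppressed"}
        cat = classify_triad(*normalize_triad(ta, tb, td))[0]
        swapped = classify_triad(*normalize_triad(tb, ta, td))[0]
        assert swapped == swap[cat]


class TestSummaries:
    def test_published_percentage_arithmetic(self):
        """30 balanced of 54 expressed root triads reports 55.6%."""
        profiles = []
        cats = ["Balanced"] * 30 + ["A_suppressed"] * 10 + \
            ["D_suppressed"] * 6 + ["B_suppressed"] * 5 + \
            ["A_dominant", "B_dominant", "D_dominant"]
        for i, cat in enumerate(cats):
            _, triad = make_triad(stem=f"t{i}")
            profiles.append(type("P", (), {"tissue": "root",
                                           "category": cat})())
        df = summarize_by_tissue(profiles)
        assert df.loc[0, "n_triads"] == 54
        assert df.loc[0, "pct_Balanced"] == 55.6

    def test_single_category_reports_100_percent(self):
        profiles = [type("P", (), {"tissue": "spike",
                                   "category": "Balanced"})()
                    for _ in range(7)]
        df = summarize_by_tissue(profiles)
        assert df.loc[0, "pct_Balanced"] == 100.0

    def test_zero_noise_mix_recovered_exactly(self):
        from triadkit import (HomoeologGroup, SimulationConfig,
                              simulate_catalog, simulate_expression)

        mix = {"Balanced": 0.6, "A_dominant": 0.1, "B_dominant": 0.1,
               "D_dominant": 0.1, "A_suppressed": 0.1,
               "B_suppressed": 0.0, "D_suppressed": 0.0}
        cfg = SimulationConfig(seed=21, n_subfamilies=1,
                               groups_per_subfamily=300,
                               group_category_proportions={"triad": 1.0},
                               bias_category_proportions=mix,
                               specificity_proportions={"ubiquitous": 1.0},
                               concentration=float("inf"))
        _, _, truth = simulate_catalog(cfg)
        expr = simulate_expression(truth, cfg)
        triads = [HomoeologGroup.build(pg.subfamily, pg.chrom_group,
                                       {sg: list(v) for sg, v
                                        in pg.members.items()})
                  for pg in truth.groups]
        profiles = triad_profiles(expr, triads)
        planted = list(truth.bias.values())
        got = [p.category for p in profiles]
        for cat in mix:
            assert got.count(cat) == planted.count(cat)


class TestTissueSpecificity:
    def _records(self, gid, root=0.0, leaf=0.0, spike=0.0, grain=0.0):
        vals = {"root": ("seedling", root), "leaf_shoot": ("vegetative", leaf),
                "spike": ("reproductive", spike),
                "grain": ("reproductive", grain)}
        return [ExpressionRecord(gid, t, s, "CS", v)
                for t, (s, v) in vals.items()]

    def test_root_specific(self):
        (call,) = call_tissue_specificity(self._records("g", root=5.0,
                                                        leaf=0.5))
        assert call.call == "root_specific"

    def test_expression_in_two_classes_is_ubiquitous(self):
        (call,) = call_tissue_specificity(self._records("g", root=2.0,
                                                        grain=1.5))
        assert call.call == "ubiquitous"

    def test_spike_and_grain_form_one_class(self):
        (call,) = call_tissue_specificity(self._records("g", spike=3.0,
                                                        grain=8.0))
        assert call.call == "spike_grain_specific"

    def test_never_expressed(self):
        (call,) = call_tissue_specificity(self._records("g", root=0.9))
        assert call.call == "not_expressed"

    def test_gene_without_records_is_not_expressed(self):
        calls = call_tissue_specificity(self._records("g", root=5.0),
                                        gene_ids=["g", "missing"])
        assert {c.gene_id: c.call for c in calls}["missing"] == \
            "not_expressed"

    def test_planted_root_specific_genes_recovered_exactly(self):
        from triadkit import SimulationConfig, simulate_catalog
        from triadkit import simulate_expression

        cfg = SimulationConfig(
            seed=31, n_subfamilies=1, groups_per_subfamily=40,
            group_category_proportions={"singleton": 1.0},
            un_singleton_fraction=0.0,
            specificity_proportions={"root_specific": 0.5,
                                     "ubiquitous": 0.5})
        _, _, truth = simulate_catalog(cfg)
        expr = simulate_expression(truth, cfg)
        calls = call_tissue_specificity(expr)
        got_root = {c.gene_id for c in calls if c.call == "root_specific"}
        planted_root = {g for g, cls in truth.specificity.items()
                        if cls == "root_specific"}
        assert got_root == planted_root
        assert all(truth.specificity[c.gene_id] == c.call for c in calls)
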