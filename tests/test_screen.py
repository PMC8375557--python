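"""Fisher exact test, presence screening, pattern classification, system call."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twobrad.genotype import parse_genotype
from twobrad.report import load_candidate_snps
from twobrad.screen import (
    PresenceMatrix,
    classify_pattern,
    find_sex_specific_tags,
    fisher_exact_2x2,
    infer_system,
    snp_sex_association,
)

PERFECT_SPLIT_P = 2 / 184756  # [[10,0],[0,10]]: 2 of C(20,10) tables


def fisher_oracle(a, b, c, d):
    """Independent brute-force two-sided enumeration with exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2) or c1 in (0, n):
        return 1.0
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestFisher:
    def test_perfect_10v10_split(self):
        p = fisher_exact_2x2(((10, 0), (0, 10)))
        assert p == pytest.approx(PERFECT_SPLIT_P, rel=1e-12)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_no_association_gives_p_of_one(self):
        assert fisher_exact_2x2(((5, 5), (5, 5))) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(((-1, 5), (5, 5)))

    def test_degenerate_margins_give_one(self):
        assert fisher_exact_2x2(((0, 0), (3, 4))) == 1.0
        assert fisher_exact_2x2(((2, 0), (3, 0))) == 1.0

    @given(st.tuples(*[st.integers(0, 15)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_enumeration_oracle(self, table):
        a, b, c, d = table
        p = fisher_exact_2x2(((a, b), (c, d)))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4))
            ours = fisher_exact_2x2(((a, b), (c, d)))
            theirs = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


def make_matrix(depths, sexes, min_depth=3):
    return PresenceMatrix(depth=pd.DataFrame(depths).T, sexes=sexes,
                          min_locus_depth=min_depth)


SEXES_10_10 = {f"F{i}": "F" for i in range(10)} | {f"M{i}": "M" for i in range(10)}


class TestSexSpecificTags:
    def test_strict_female_specific_tag(self):
        depths = {"t1": {**{f"F{i}": 30 for i in range(10)},
                         **{f"M{i}": 0 for i in range(10)}}}
        res = find_sex_specific_tags(make_matrix(depths, SEXES_10_10))
        assert res[0].pattern == "female_specific"
        assert res[0].p_value == pytest.approx(PERFECT_SPLIT_P, rel=1e-12)

    def test_ubiquitous_tag_is_uninformative(self):
        depths = {"t1": {ind: 30 for ind in SEXES_10_10}}
        res = find_sex_specific_tags(make_matrix(depths, SEXES_10_10))
        assert res[0].pattern == "uninformative" and not res[0].candidate

    def test_single_sex_sheet_is_an_error(self):
        depths = {"t1": {f"F{i}": 30 for i in range(10)}}
        with pytest.raises(ValueError):
            find_sex_specific_tags(
                make_matrix(depths, {f"F{i}": "F" for i in range(10)})
            )

    def test_label_swap_maps_female_to_male_patterns(self):
        depths = {"t1": {**{f"F{i}": 30 for i in range(10)},
                         **{f"M{i}": 0 for i in range(10)}},
                  "t2": {**{f"F{i}": 0 for i in range(10)},
                         **{f"M{i}": 30 for i in range(10)}}}
        res = find_sex_specific_tags(make_matrix(depths, SEXES_10_10))
        swapped_sexes = {k: ("M" if v == "F" else "F") for k, v in SEXES_10_10.items()}
        res_sw = find_sex_specific_tags(make_matrix(depths, swapped_sexes))
        pat = {r.marker_id: r.pattern for r in res}
        pat_sw = {r.marker_id: r.pattern for r in res_sw}
        assert pat["t1"] == "female_specific" and pat_sw["t1"] == "male_specific"
        assert pat["t2"] == "male_specific" and pat_sw["t2"] == "female_specific"

    def test_presence_threshold_is_depth_three(self):
        depths = {"t1": {**{f"F{i}": 3 for i in range(10)},
                         **{f"M{i}": 2 for i in range(10)}}}
        res = find_sex_specific_tags(make_matrix(depths, SEXES_10_10))
        assert res[0].pattern == "female_specific"

    def test_all_planted_w_tags_recovered_no_false_positives(self, zw_noisy):
        cand = [r for r in zw_noisy.tag_results if r.candidate]
        assert len(cand) == len(zw_noisy.truth.sex_limited_tag_ids) == 3
        assert all(r.pattern == "female_specific" for r in cand)


class TestClassifyPattern:
    @pytest.mark.parametrize("female,male,expected", [
        (("A", "G"), ("A", "A"), "female_heterogametic"),  # published row 1
        (("T", "T"), ("T", "A"), "male_heterogametic"),    # published row 7
        (("C", "C"), ("A", "A"), "fixed_difference"),      # published row 6
        (("A", "A"), ("A", "A"), "uninformative"),
    ])
    def test_published_genotype_patterns(self, female, male, expected):
        assert classify_pattern([female], [male]) == expected

    def test_mixed_female_calls_are_uninformative(self):
        fem = [("A", "G")] * 5 + [("A", "A")] * 5
        mal = [("A", "A")] * 10
        assert classify_pattern(fem, mal) == "uninformative"

    def test_absent_calls_are_dropped(self):
        assert classify_pattern([None, ("A", "G")], [("A", "A")]) == \
            "female_heterogametic"
        assert classify_pattern([None], [("A", "A")]) == "uninformative"

    def test_fixture_table_counts(self):
        snps = load_candidate_snps()
        patterns = [
            classify_pattern([parse_genotype(r["female"])],
                             [parse_genotype(r["male"])])
            for _, r in snps.iterrows()
        ]
        from collections import Counter

        assert Counter(patterns) == {
            "female_heterogametic": 7, "male_heterogametic": 2,
            "fixed_difference": 1,
        }


def snp_frame(genos_by_marker):
    rows = []
    for marker, genos in genos_by_marker.items():
        row = {"ref_id": marker, "snp_position": 1, "ref_base": "A", "alt_base": "G"}
        row.update(genos)
        rows.append(row)
    return pd.DataFrame(rows)


class TestSnpAssociation:
    def test_perfect_pattern_is_rank_one(self):
        table = snp_frame({
            "m_weak": {**{f"F{i}": "A/G" for i in range(5)},
                       **{f"F{i}": "A/A" for i in range(5, 10)},
                       **{f"M{i}": "A/A" for i in range(10)}},
            "m_perfect": {**{f"F{i}": "A/G" for i in range(10)},
                          **{f"M{i}": "A/A" for i in range(10)}},
        })
        res = snp_sex_association(table, SEXES_10_10)
        assert res.iloc[0]["marker_id"].startswith("m_perfect")
        assert res.iloc[0]["p_value"] == pytest.approx(PERFECT_SPLIT_P, rel=1e-12)
        assert res.iloc[0]["pattern"] == "female_heterogametic"
        assert res.iloc[1]["p_value"] > res.iloc[0]["p_value"]

    def test_monomorphic_marker_gets_p_one(self):
        table = snp_frame({"m1": {ind: "A/A" for ind in SEXES_10_10}})
        res = snp_sex_association(table, SEXES_10_10)
        assert res.iloc[0]["p_value"] == 1.0
        assert res.iloc[0]["pattern"] == "uninformative"

    def test_p_invariant_under_individual_reordering(self):
        table = snp_frame({
            "m1": {**{f"F{i}": "A/G" for i in range(7)},
                   **{f"F{i}": "A/A" for i in range(7, 10)},
                   **{f"M{i}": "A/A" for i in range(10)}},
        })
        shuffled = table[list(table.columns[:4]) +
                         list(reversed(table.columns[4:]))]
        p1 = snp_sex_association(table, SEXES_10_10).iloc[0]["p_value"]
        p2 = snp_sex_association(shuffled, SEXES_10_10).iloc[0]["p_value"]
        assert p1 == p2

    def test_multiple_testing_columns_present(self):
        table = snp_frame({
            f"m{j}": {**{f"F{i}": "A/G" for i in range(10)},
                      **{f"M{i}": "A/A" for i in range(10)}}
            for j in range(4)
        })
        res = snp_sex_association(table, SEXES_10_10)
        assert (res["p_bonferroni"] >= res["p_value"]).all()
        assert (res["p_bh"] >= res["p_value"]).all()
        assert res["p_bonferroni"].iloc[0] == pytest.approx(4 * PERFECT_SPLIT_P)

    def test_planted_gametologs_rank_above_all_autosomal(self, zw_noisy):
        from twobrad.pipeline import truth_locus_map

        t2l = truth_locus_map(zw_noisy)
        gam_loci = {t2l[s.tag_id].locus_id
                    for s in zw_noisy.truth.gametolog_snps.values()}
        ranked = list(zw_noisy.snp_results["ref_id"])
        positions = [i for i, r in enumerate(ranked) if r in gam_loci]
        assert len(positions) == 10
        assert max(positions) < min(
            i for i in range(len(ranked)) if i not in positions
        )


class TestInferSystem:
    def test_zw_and_xy_simulations_are_called_correctly(self, zw_noisy):
        assert zw_noisy.inference.call == "ZW"
        assert zw_noisy.inference.evidence["female_specific_tags"] == 3

    def test_no_candidates_is_undetermined(self):
        inf = infer_system([], pd.DataFrame())
        assert inf.call == "undetermined"

    def test_female_evidence_dominance_calls_zw(self):
        table = snp_frame({
            "m1": {**{f"F{i}": "A/G" for i in range(10)},
                   **{f"M{i}": "A/A" for i in range(10)}},
        })
        snp_res = snp_sex_association(table, SEXES_10_10)
        depths = {"t1": {**{f"F{i}": 30 for i in range(10)},
                         **{f"M{i}": 0 for i in range(10)}}}
        tag_res = find_sex_specific_tags(make_matrix(depths, SEXES_10_10))
        assert infer_system(tag_res, snp_res).call == "ZW"
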