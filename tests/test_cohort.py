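"""Cohort reading, exclusion pipeline, stratification and summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ironavail as ia
from ironavail.cohort import cohort_to_frame

from conftest import make_cohort, make_individual

CSV_HEADER = (
    "id,study,sex,menopausal_status,age,weight_kg,bmi,iron_intake_mg_d,"
    "iron_meat_mg_d,sf_ug_l,hb_g_dl,crp_mg_l,act_g_l,iron_supplement\n"
)


class TestReadCohort:
    def test_round_trip_identity(self, tmp_path):
        rows = (
            "a,S1,male,not_applicable,40,80,25,13.5,2.1,120,15.1,1.2,0.3,false\n"
            "b,S1,female,premenopausal,30,65,22,9.8,1.4,45,13.2,0.8,0.4,true\n"
            "c,S1,female,postmenopausal,60,70,27,10.9,1.5,90,13.5,2.0,,false\n"
        )
        path = tmp_path / "c.csv"
        path.write_text(CSV_HEADER + rows)
        cohort = ia.read_cohort(path)
        assert len(cohort) == 3
        a = cohort.individuals[0]
        assert (a.id, a.sex, a.iron_intake, a.sf) == ("a", "male", 13.5, 120.0)
        assert cohort.individuals[1].iron_supplement_user is True
        assert cohort.individuals[2].act is None

        out = tmp_path / "out.csv"
        ia.write_cohort(cohort, out)
        again = ia.read_cohort(out)
        assert cohort_to_frame(again).equals(cohort_to_frame(cohort))

    def test_empty_sf_is_missing_not_zero(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(CSV_HEADER + "a,S,male,,40,,,12.0,,,,,,\n")
        ind = ia.read_cohort(path).individuals[0]
        assert ind.sf is None and ind.sf != 0

    def test_missing_mandatory_column_errors(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,sex\na,male\n")
        with pytest.raises(ia.DataError, match="iron_intake"):
            ia.read_cohort(path)

    def test_unparseable_numeric_reports_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(CSV_HEADER + "a,S,male,,40,,,12.0,,,,,,\nb,S,male,,40,,,oops,,,,,,\n")
        with pytest.raises(ia.DataError, match="row 3"):
            ia.read_cohort(path)

    def test_column_map_for_arbitrary_headers(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("subject,gender,fe_mg\ns1,male,11.5\n")
        cohort = ia.read_cohort(
            path, column_map={"subject": "id", "gender": "sex", "fe_mg": "iron_intake"}
        )
        assert cohort.individuals[0].iron_intake == 11.5


def nuage_roster():
    """246 complete records: 13 raised CRP, 37 supplement users, disjoint."""
    inds = []
    for i in range(246):
        crp = 6.5 if i < 13 else 1.0
        suppl = 13 <= i < 50
        inds.append(
            make_individual(f"p{i}", "male", 12.0, crp=crp, sf=100.0,
                            iron_supplement_user=suppl)
        )
    return make_cohort(inds, "NU-AGE")


def nans_roster():
    """849 CRP-measured: 130 CRP>5, then 63 supplement users, then 6 missing SF."""
    inds = []
    for i in range(849):
        crp = 7.0 if i < 130 else 2.0
        suppl = 130 <= i < 193
        sf = None if 193 <= i < 199 else 110.0
        inds.append(
            make_individual(f"q{i}", "male", 13.0, crp=crp, sf=sf,
                            iron_supplement_user=suppl)
        )
    return make_cohort(inds, "NANS")


class TestApplyExclusions:
    def test_nuage_margins_leave_196(self):
        filtered, report = ia.apply_exclusions(nuage_roster())
        assert report.n_input == 246
        assert report.n_excluded_inflammation == 13
        assert report.n_excluded_supplements == 37
        assert report.n_retained == len(filtered) == 196

    def test_nans_margins_leave_650(self):
        filtered, report = ia.apply_exclusions(nans_roster())
        assert report.n_excluded_inflammation == 130
        assert report.n_excluded_supplements == 63
        assert report.n_excluded_missing_sf == 6
        assert report.n_retained == len(filtered) == 650

    def test_no_exclusions_is_identity(self, small_cohort):
        filtered, report = ia.apply_exclusions(small_cohort)
        assert len(filtered) == report.n_input == len(small_cohort)
        assert report.n_excluded_inflammation == 0
        assert report.n_excluded_supplements == 0
        assert report.n_excluded_missing_sf == 0
        assert [i.id for i in filtered] == [i.id for i in small_cohort]

    def test_idempotent(self):
        once, _ = ia.apply_exclusions(nans_roster())
        twice, rep2 = ia.apply_exclusions(once)
        assert [i.id for i in twice] == [i.id for i in once]
        assert rep2.n_retained == rep2.n_input

    def test_threshold_is_strict(self):
        cohort = make_cohort(
            [
                make_individual("at", "male", 10, crp=5.0, sf=50.0),
                make_individual("above", "male", 10, crp=5.0001, sf=50.0),
                make_individual("act_at", "male", 10, act=0.65, sf=50.0),
                make_individual("act_above", "male", 10, act=0.66, sf=50.0),
            ]
        )
        _, report = ia.apply_exclusions(cohort)
        assert set(report.excluded_inflammation_ids) == {"above", "act_above"}

    def test_absent_markers_retained(self):
        cohort = make_cohort([make_individual("n1", "male", 10, sf=40.0)])
        filtered, _ = ia.apply_exclusions(cohort)
        assert len(filtered) == 1

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.floats(0.0, 20.0)),  # crp
                st.booleans(),  # supplement
                st.one_of(st.none(), st.floats(0.0, 300.0)),  # sf
            ),
            min_size=1,
            max_size=60,
        )
    )
    def test_counts_conserve_sequentially(self, rows):
        cohort = make_cohort(
            [
                make_individual(f"i{k}", "male", 10.0, crp=crp, sf=sf,
                                iron_supplement_user=suppl)
                for k, (crp, suppl, sf) in enumerate(rows)
            ]
        )
        _, rep = ia.apply_exclusions(cohort)
        assert (
            rep.n_retained
            + rep.n_excluded_inflammation
            + rep.n_excluded_supplements
            + rep.n_excluded_missing_sf
            == rep.n_input
            == len(rows)
        )


class TestStratify:
    def test_partition(self, small_cohort):
        groups = ia.stratify(small_cohort)
        assert {g: len(c) for g, c in groups.items()} == {
            "men": 2, "premenopausal": 1, "postmenopausal": 1
        }

    def test_all_male_leaves_women_groups_empty(self):
        cohort = make_cohort([make_individual(f"m{i}", "male", 10) for i in range(3)])
        groups = ia.stratify(cohort)
        assert len(groups["premenopausal"]) == len(groups["postmenopausal"]) == 0

    def test_unclassified_female_errors_with_ids(self):
        cohort = make_cohort(
            [make_individual("f9", "female", 10, menopausal_status="not_applicable")]
        )
        with pytest.raises(ia.DataError, match="f9"):
            ia.stratify(cohort)

    def test_stratify_then_combine_preserves_individuals(self, small_cohort):
        groups = ia.stratify(small_cohort)
        recombined = ia.combine_cohorts(list(groups.values()))
        assert sorted(i.id for i in recombined) == sorted(i.id for i in small_cohort)


class TestCombineCohorts:
    def test_sizes_add_up_to_survey_total(self):
        sizes = (907, 560, 394)
        cohorts = [
            make_cohort([make_individual(f"{s}-{i}", "male", 10) for i in range(s)], f"c{s}")
            for s in sizes
        ]
        assert len(ia.combine_cohorts(cohorts)) == 1861

    def test_single_cohort_identity(self, small_cohort):
        combined = ia.combine_cohorts([small_cohort])
        assert [i.id for i in combined] == [i.id for i in small_cohort]
        assert combined.provenance

    def test_id_collision_prefixed(self):
        a = make_cohort([make_individual("dup", "male", 10)], "A")
        b = make_cohort([make_individual("dup", "male", 11)], "B")
        combined = ia.combine_cohorts([a, b])
        assert sorted(i.id for i in combined) == ["B:dup", "dup"]

    def test_empty_list_errors(self):
        with pytest.raises(ia.DataError):
            ia.combine_cohorts([])


class TestGroupSummary:
    def test_hand_computed_mean_sd(self):
        cohort = make_cohort(
            [make_individual(f"m{i}", "male", v) for i, v in enumerate((10.0, 12.0, 14.0))]
        )
        (summ,) = ia.group_summary(cohort)
        mean, sd, n = summ.stats["iron_intake"]
        assert (mean, sd, n) == (12.0, 2.0, 3)

    def test_synthetic_group_mean_matches_drawn_values(self):
        spec = ia.GroupSpec(group="men", n=5000, intake_mean=13.8, intake_sd=5.7,
                            sf_mean=172.0, sf_sd=135.0, seed=11)
        cohort = ia.generate_group(spec)
        (summ,) = [s for s in ia.group_summary(cohort) if s.group == "men"]
        direct = np.mean([ind.iron_intake for ind in cohort])
        assert summ.stats["iron_intake"][0] == pytest.approx(float(direct), abs=1e-12)
        # and the draw itself honors the spec within sampling error
        assert summ.stats["iron_intake"][0] == pytest.approx(13.8, abs=3 * 5.7 / np.sqrt(5000))

    def test_all_missing_variable_is_absent_not_zero(self):
        cohort = make_cohort([make_individual("m", "male", 10)])
        (summ,) = ia.group_summary(cohort)
        assert "sf" not in summ.stats


class TestPooledMean:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            ([(13.8, 336), (13.4, 494), (14.3, 77)], 13.6),  # men, iron intake mg/d
            ([(10.2, 117), (10.9, 158), (11.6, 119)], 10.9),  # postmenopausal intake
        ],
    )
    def test_survey_pooled_intakes(self, entries, expected):
        assert round(ia.pooled_mean(entries), 1) == expected

    def test_single_study_identity(self):
        assert ia.pooled_mean([(12.3, 57)]) == 12.3

    def test_agrees_with_direct_grand_mean(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(10, 2, 40), rng.normal(12, 2, 25)
        pooled = ia.pooled_mean([(float(a.mean()), 40), (float(b.mean()), 25)])
        assert pooled == pytest.approx(float(np.concatenate([a, b]).mean()), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ia.DataError):
            ia.pooled_mean([])
        with pytest.raises(ia.DataError):
            ia.pooled_mean([(10.0, 0)])


class TestSfCumulativeDistribution:
    def test_direct_count(self):
        cohort = make_cohort(
            [make_individual(f"m{i}", "male", 10, sf=s) for i, s in enumerate((10, 20, 30))]
        )
        cdf = ia.sf_cumulative_distribution(cohort, [15.0])
        assert cdf.prevalence_below[0] == pytest.approx(100 / 3)

    def test_boundaries_and_strictness(self):
        cohort = make_cohort(
            [make_individual(f"m{i}", "male", 10, sf=s) for i, s in enumerate((10, 15, 30))]
        )
        cdf = ia.sf_cumulative_distribution(cohort, [5.0, 15.0, 100.0])
        assert cdf.prevalence_below[0] == 0.0
        # SF exactly at the cutoff counts as sufficient (not below)
        assert cdf.prevalence_below[1] == pytest.approx(100 / 3)
        assert cdf.prevalence_below[2] == 100.0

    def test_permutation_invariant_and_monotone(self):
        rng = np.random.default_rng(7)
        sf = rng.lognormal(3.5, 0.9, 50)
        cutoffs = [5.0, 15.0, 30.0, 60.0, 120.0]
        cohorts = [
            make_cohort([make_individual(f"m{i}", "male", 10, sf=float(s))
                         for i, s in enumerate(order)])
            for order in (sf, sf[::-1])
        ]
        a, b = (ia.sf_cumulative_distribution(c, cutoffs) for c in cohorts)
        np.testing.assert_array_equal(a.prevalence_below, b.prevalence_below)
        assert np.all(np.diff(a.prevalence_below) >= 0)

    def test_missing_sf_errors(self):
        cohort = make_cohort([make_individual("m", "male", 10)])
        with pytest.raises(ia.DataError, match="filter"):
            ia.sf_cumulative_distribution(cohort, [15.0])
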