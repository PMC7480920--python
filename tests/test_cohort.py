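"""Group construction, composites, standardization, eligibility, overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trialpower import cohort


class TestAmyloidIntercept:
    def test_single_point_is_its_own_intercept(self):
        assert cohort.estimate_amyloid_intercept([(0, 0.85)]) == 0.85

    def test_line_through_two_points(self):
        assert cohort.estimate_amyloid_intercept(
            [(0, 0.70), (24, 0.90)]
        ) == pytest.approx(0.70, abs=1e-12)

    def test_three_point_ols(self):
        # independent hand OLS via centered sums:
        # slope = sum((t-12)(v-0.84)) / sum((t-12)^2) = 1.2/288,
        # intercept = 0.84 - slope*12 = 0.79
        got = cohort.estimate_amyloid_intercept([(0, 0.80), (12, 0.82), (24, 0.90)])
        assert got == pytest.approx(0.84 - (1.2 / 288) * 12, abs=1e-12)

    def test_repeated_time_returns_mean(self):
        assert cohort.estimate_amyloid_intercept(
            [(6, 0.8), (6, 0.9)]
        ) == pytest.approx(0.85)

    def test_empty_series_signals_missing(self):
        with pytest.raises(ValueError):
            cohort.estimate_amyloid_intercept([])


class TestClassifyAmyloid:
    def test_pet_takes_precedence(self):
        assert cohort.classify_amyloid(0.85, 1500.0) == ("positive", "pet_intercept")

    def test_boundary_is_strict(self):
        assert cohort.classify_amyloid(0.79, None) == ("negative", "pet_intercept")
        assert cohort.classify_amyloid(None, 880.0) == ("negative", "csf")

    def test_csf_fallback(self):
        assert cohort.classify_amyloid(None, 500.0) == ("positive", "csf")

    def test_both_missing_unknown(self):
        assert cohort.classify_amyloid(None, None) == ("unknown", "none")

    @given(lo=st.floats(0.3, 2.0), hi=st.floats(0.3, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_intercept(self, lo, hi):
        lo, hi = sorted((lo, hi))
        s_lo = cohort.classify_amyloid(lo, None)[0]
        s_hi = cohort.classify_amyloid(hi, None)[0]
        assert not (s_lo == "positive" and s_hi == "negative")

    @given(lo=st.floats(100, 2000), hi=st.floats(100, 2000))
    @settings(max_examples=100, deadline=None)
    def test_antitone_in_csf(self, lo, hi):
        lo, hi = sorted((lo, hi))
        s_lo = cohort.classify_amyloid(None, lo)[0]
        s_hi = cohort.classify_amyloid(None, hi)[0]
        assert not (s_lo == "negative" and s_hi == "positive")


class TestAssignGroup:
    @pytest.mark.parametrize(
        "cdr, status, ptau, group",
        [
            (0.0, "negative", None, "control"),
            (0.0, "positive", None, "preclinical_ad"),
            (0.5, "positive", 30.0, "mild_ad"),
            (1.0, "positive", None, "mild_ad"),
            (0.5, "negative", None, "excluded"),
            (2.0, "positive", None, "excluded"),
            (0.0, "unknown", None, "excluded"),
        ],
    )
    def test_mapping(self, cdr, status, ptau, group):
        a = cohort.assign_group("s", cdr, status, "pet_intercept", ptau)
        assert a.group == group
        assert a.eligible == (group != "excluded")
        if group == "excluded":
            assert a.exclusion_reason

    def test_ptau_threshold_strict(self):
        assert cohort.assign_group("s", 0.5, "positive", csf_ptau=30.0).ptau_positive
        assert not cohort.assign_group("s", 0.5, "positive", csf_ptau=27.0).ptau_positive
        assert cohort.assign_group("s", 0.5, "positive").ptau_positive is None

    @given(
        cdr=st.sampled_from([0.0, 0.5, 1.0, 2.0, 3.0, float("nan")]),
        status=st.sampled_from(["positive", "negative", "unknown"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_partition(self, cdr, status):
        a = cohort.assign_group("s", cdr, status)
        assert a.group in {"control", "preclinical_ad", "mild_ad", "excluded"}


class TestPacc:
    STATS = {k: (10.0, 2.0) for k in cohort.PACC_COMPONENTS}

    def test_all_at_reference_mean_is_zero(self):
        comps = {k: 10.0 for k in cohort.PACC_COMPONENTS}
        assert cohort.compute_pacc(comps, self.STATS) == pytest.approx(0.0)

    def test_one_sd_better_everywhere_is_four(self):
        comps = {"mmse": 12.0, "dmemory": 12.0, "trailsb": 8.0, "dadasc": 12.0}
        assert cohort.compute_pacc(comps, self.STATS) == pytest.approx(4.0)

    def test_trailsb_orientation(self):
        comps = {"mmse": 10.0, "dmemory": 10.0, "trailsb": 12.0, "dadasc": 10.0}
        assert cohort.compute_pacc(comps, self.STATS) == pytest.approx(-1.0)

    def test_partial_components_yield_nan(self):
        comps = {"mmse": 10.0, "dmemory": 10.0, "trailsb": float("nan"), "dadasc": 10.0}
        assert math.isnan(cohort.compute_pacc(comps, self.STATS))

    def test_zero_reference_sd_is_config_error(self):
        stats = dict(self.STATS, mmse=(10.0, 0.0))
        with pytest.raises(ValueError):
            cohort.compute_pacc({k: 10.0 for k in cohort.PACC_COMPONENTS}, stats)


class TestTemporalComposite:
    def test_constant_thickness(self):
        regional = {f"r{i}": (3.0, 100.0 + 13 * i) for i in range(8)}
        assert cohort.compute_temporal_composite(regional) == pytest.approx(3.0)

    def test_toy_two_region_weighting(self):
        assert cohort.compute_temporal_composite(
            {"a": (2.0, 1.0), "b": (4.0, 3.0)}
        ) == pytest.approx(3.5)

    def test_equal_areas_arithmetic_mean(self):
        th = [2.1, 2.5, 2.8, 3.0, 2.2, 2.6, 2.9, 3.1]
        regional = {f"r{i}": (v, 50.0) for i, v in enumerate(th)}
        assert cohort.compute_temporal_composite(regional) == pytest.approx(np.mean(th))

    def test_missing_region_yields_nan(self):
        assert math.isnan(
            cohort.compute_temporal_composite({"a": (2.0, 1.0), "b": None})
        )

    @given(
        th=st.lists(st.floats(1.0, 5.0), min_size=2, max_size=8),
        ar=st.lists(st.floats(1.0, 500.0), min_size=8, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_within_input_bounds(self, th, ar):
        regional = {f"r{i}": (t, a) for i, (t, a) in enumerate(zip(th, ar))}
        v = cohort.compute_temporal_composite(regional)
        assert min(th) - 1e-9 <= v <= max(th) + 1e-9


def _std_table():
    return pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "a"],
            "visit_month": [0.0, 0.0, 0.0, 12.0],
            "bio": [1.0, 2.0, 3.0, 4.0],
        }
    )


class TestStandardize:
    def test_reference_baseline_becomes_mean0_sd1(self):
        out, std = cohort.standardize_biomarker(_std_table(), "bio")
        base = out[out.visit_month == 0].bio
        assert base.mean() == pytest.approx(0.0, abs=1e-12)
        assert base.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert std.baseline_mean == 2.0 and std.baseline_sd == 1.0

    def test_mean_maps_to_zero_and_sd_to_one(self):
        out, std = cohort.standardize_biomarker(_std_table(), "bio")
        assert out.bio.iloc[1] == pytest.approx(0.0)  # value == baseline mean
        assert out.bio.iloc[2] == pytest.approx(1.0)  # mean + 1 SD

    def test_restandardization_is_stable(self):
        once, _ = cohort.standardize_biomarker(_std_table(), "bio")
        twice, std2 = cohort.standardize_biomarker(once, "bio")
        assert std2.baseline_mean == pytest.approx(0.0, abs=1e-12)
        assert std2.baseline_sd == pytest.approx(1.0, abs=1e-12)
        pd.testing.assert_frame_equal(once, twice)

    @given(a=st.floats(0.1, 5.0), b=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        # z-scores are invariant to positive affine rescaling of the raw scale
        t1 = _std_table()
        t2 = t1.assign(bio=a * t1.bio + b)
        z1, _ = cohort.standardize_biomarker(t1, "bio")
        z2, _ = cohort.standardize_biomarker(t2, "bio")
        np.testing.assert_allclose(z1.bio, z2.bio, atol=1e-9)

    def test_degenerate_sd_rejected(self):
        t = _std_table().assign(bio=[1.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            cohort.standardize_biomarker(t, "bio")


def _wide(rows):
    return pd.DataFrame(rows, columns=["subject_id", "visit_month", "hippocampus", "pnfl", "cdrsb"])


class TestEligibility:
    def test_two_followups_each_modality(self):
        rows = [("s", m, 1.0, None, None) for m in (0, 12, 24)]
        rows += [("s", m, None, 1.0, None) for m in (0, 12, 24)]
        rows += [("s", m, None, None, 1.0) for m in (0, 6, 12)]
        eligible, reasons = cohort.filter_eligibility(_wide(rows))
        assert eligible == {"s"}
        assert reasons == {}

    def test_single_followup_excluded(self):
        rows = [("s", m, 1.0, 1.0, 1.0) for m in (0, 12, 24)]
        rows = [
            (sid, m, h, None if m > 12 else p, c)
            for (sid, m, h, p, c) in rows
        ]
        eligible, reasons = cohort.filter_eligibility(_wide(rows))
        assert eligible == set()
        assert "pnfl: 1 follow-ups" in reasons["s"]

    def test_empty_table(self):
        eligible, reasons = cohort.filter_eligibility(_wide([]))
        assert eligible == set() and reasons == {}


class TestOverlap:
    def test_fully_overlapping_unchanged(self):
        rows = [("s", m, 1.0, 1.0, 1.0) for m in (0.0, 12.0, 24.0)]
        t = _wide(rows)
        out = cohort.intersect_overlapping_visits(t)
        pd.testing.assert_frame_equal(
            out.sort_values("visit_month").reset_index(drop=True), t
        )

    def test_intersection_truncates_to_common_visits(self):
        rows = [("s", m, 1.0, None, None) for m in (0.0, 12.0)]
        rows += [("s", m, None, 1.0, 1.0) for m in (0.0, 12.0, 24.0)]
        out = cohort.intersect_overlapping_visits(_wide(rows))
        assert sorted(out.visit_month) == [0.0, 12.0]
        assert out[["hippocampus", "pnfl", "cdrsb"]].notna().all().all()

    def test_tolerance_matches_offset_visit(self):
        rows = [("s", 0.0, 1.0, 1.0, 1.0), ("s", 12.0, 1.0, 1.0, None),
                ("s", 12.5, None, None, 1.0)]
        out = cohort.intersect_overlapping_visits(
            _wide(rows), nominal_schedule=[0.0, 12.0]
        )
        assert sorted(out.visit_month) == [0.0, 12.0]
        month12 = out[out.visit_month == 12.0].iloc[0]
        assert month12.cdrsb == 1.0 and month12.hippocampus == 1.0

    def test_subset_and_idempotent(self, default_cohort):
        t = default_cohort.table[
            ["subject_id", "visit_month", "hippocampus", "temporal_composite",
             "pnfl", "cdrsb", "pacc"]
        ]
        once = cohort.intersect_overlapping_visits(t)
        assert len(once) <= len(t)
        twice = cohort.intersect_overlapping_visits(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestBuildAssignments:
    def test_recovers_generated_group_labels(self, default_cohort):
        frame = cohort.assignments_frame(
            cohort.build_assignments(default_cohort.table)
        )
        truth = default_cohort.table.groupby("subject_id")["group"].first()
        merged = frame.set_index("subject_id").join(truth.rename("truth"))
        assert (merged.group == merged.truth).mean() >= 0.99

    def test_partition_covers_every_subject(self, default_cohort):
        frame = cohort.assignments_frame(
            cohort.build_assignments(default_cohort.table)
        )
        assert len(frame) == default_cohort.table.subject_id.nunique()
        assert frame.group.isin(
            ["control", "preclinical_ad", "mild_ad", "excluded"]
        ).all()
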