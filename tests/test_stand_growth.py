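"""Stand volume, increment series and culmination age."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mangroveval import (
    GrowthCurveParams,
    StandObservation,
    StandTable,
    generate_stand_trajectory,
    mai,
    pai,
    peak_mai,
    stand_volume,
    summarize_table,
    tree_volume,
)

UNIT_BASAL_D = 100.0 * math.sqrt(4.0 / math.pi)  # diameter of 1 m2 basal area


class TestTreeVolume:
    @pytest.mark.parametrize(
        "d, h, f, expected",
        [
            (5.0, 2.0, 0.85, 0.0033379),     # x2500 stems gives the age-3 stand
            (12.0, 9.0, 0.7, 0.0712514),     # x1390 stems gives the age-20 stand
            (UNIT_BASAL_D, 1.0, 1.0, 1.0),   # unit-basal-area cylinder
        ],
    )
    def test_examples(self, d, h, f, expected):
        assert tree_volume(d, h, f) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize(
        "d, h, f",
        [(-1.0, 2.0, 0.8), (0.0, 2.0, 0.8), (5.0, 0.0, 0.8), (5.0, 2.0, 0.0),
         (5.0, 2.0, 1.5), (5.0, -2.0, 0.8)],
    )
    def test_domain_errors(self, d, h, f):
        with pytest.raises(ValueError):
            tree_volume(d, h, f)


class TestStandVolume:
    @pytest.mark.parametrize(
        "obs, expected",
        [
            (StandObservation(t=3, n=2500, d=5.0, h=2.0, f=0.85), 8.34),
            (StandObservation(t=25, n=780, d=19.0, h=11.5, f=0.66), 167.77),
        ],
    )
    def test_published_rows(self, obs, expected):
        assert stand_volume(obs) == pytest.approx(expected, rel=5e-3)

    def test_empty_stand_has_zero_volume(self):
        assert stand_volume(StandObservation(t=5, n=0, d=8.0, h=4.0, f=0.8)) == 0.0

    def test_volume_oracle_all_printed_cells(self, pre_table, post_table,
                                             pre_refs, post_refs):
        """Recomputed TV agrees with every printed cell except the known
        inconsistent post-thinning age-40 entry."""
        for table, refs in ((pre_table, pre_refs), (post_table, post_refs)):
            for obs in table.rows:
                if table.label == "post-thinning" and obs.t == 40:
                    # printed 229.50 vs formula ~219.5: flagged inconsistency
                    assert stand_volume(obs) == pytest.approx(219.5, rel=5e-3)
                    continue
                assert stand_volume(obs) == pytest.approx(
                    refs.loc[obs.t, "tv_ref"], rel=5e-3
                )


class TestIncrements:
    @pytest.mark.parametrize(
        "v, t, expected",
        [(134.64, 25, 5.39), (167.77, 25, 6.71), (0.0, 7, 0.0)],
    )
    def test_mai(self, v, t, expected):
        assert mai(v, t) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "v_t, v_prev, dt, expected",
        [(98.99, 83.90, 2, 7.55), (153.88, 116.08, 3, 12.60), (50.0, 50.0, 4, 0.0)],
    )
    def test_pai(self, v_t, v_prev, dt, expected):
        # printed cells carry 2 d.p., so agreement is to +/-0.02
        assert pai(v_t, v_prev, dt) == pytest.approx(expected, abs=0.02)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mai(10.0, 0)
        with pytest.raises(ValueError):
            pai(10.0, 5.0, 0)

    def test_pai_may_be_negative_when_volume_declines(self):
        assert pai(90.0, 100.0, 5) == pytest.approx(-2.0)


class TestSummarizeTable:
    def test_structure(self, pre_table):
        rows = summarize_table(pre_table)
        assert len(rows) == len(pre_table.rows)
        assert rows[0].pai is None
        assert all(r.pai is not None for r in rows[1:])
        for r in rows:
            assert r.mai == pytest.approx(r.tv / r.age)

    def test_pai_uses_actual_age_interval(self, pre_table):
        rows = summarize_table(pre_table)
        # ages 3 and 7 are 4 years apart
        assert rows[1].pai == pytest.approx((rows[1].tv - rows[0].tv) / 4.0)

    def test_single_row_table(self):
        t = StandTable(rows=(StandObservation(t=10, n=100, d=8.0, h=5.0, f=0.8),))
        rows = summarize_table(t)
        assert len(rows) == 1 and rows[0].pai is None

    def test_matches_printed_increments_from_printed_volumes(
        self, pre_refs, post_refs
    ):
        """MAI/PAI recomputed from the printed TV column agree with the
        printed increment columns within +/-0.02."""
        for refs in (pre_refs, post_refs):
            ages = list(refs.index)
            for i, age in enumerate(ages):
                tv = refs.loc[age, "tv_ref"]
                assert mai(tv, age) == pytest.approx(refs.loc[age, "mai_ref"], abs=0.02)
                if i > 0:
                    prev = ages[i - 1]
                    assert pai(tv, refs.loc[prev, "tv_ref"], age - prev) == pytest.approx(
                        refs.loc[age, "pai_ref"], abs=0.02
                    )


class TestPeakMai:
    def test_pre_thinning_culmination(self, pre_table):
        age, value = peak_mai(summarize_table(pre_table))
        assert age == 25
        assert value == pytest.approx(5.39, abs=0.01)

    def test_post_thinning_culmination(self, post_table):
        age, value = peak_mai(summarize_table(post_table))
        assert age == 25
        assert value == pytest.approx(6.71, abs=0.01)

    def test_tie_breaks_to_earliest_age(self):
        obs = StandObservation(t=2, n=100, d=8.0, h=5.0, f=0.8)
        v = stand_volume(obs)
        from mangroveval import GrowthRow

        rows = [
            GrowthRow(observation=obs, tv=v, mai=3.0, pai=None),
            GrowthRow(
                observation=StandObservation(t=4, n=100, d=8.0, h=5.0, f=0.8),
                tv=v, mai=3.0, pai=0.0,
            ),
        ]
        assert peak_mai(rows)[0] == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            peak_mai([])


obs_strategy = st.builds(
    StandObservation,
    t=st.integers(min_value=1, max_value=100),
    n=st.integers(min_value=0, max_value=5000),
    d=st.floats(min_value=0.5, max_value=100, allow_nan=False),
    h=st.floats(min_value=0.5, max_value=40, allow_nan=False),
    f=st.floats(min_value=0.05, max_value=1.0, allow_nan=False),
)


class TestProperties:
    @given(obs=obs_strategy)
    def test_mai_reconstruction_identity(self, obs):
        v = stand_volume(obs)
        assert mai(v, obs.t) * obs.t == pytest.approx(v, rel=1e-12, abs=1e-12)

    @given(obs=obs_strategy, scale=st.floats(min_value=1.01, max_value=3.0))
    def test_stand_volume_monotone_in_each_attribute(self, obs, scale):
        if obs.n == 0:
            obs = StandObservation(t=obs.t, n=10, d=obs.d, h=obs.h, f=obs.f)
        base = stand_volume(obs)
        grown_d = StandObservation(t=obs.t, n=obs.n, d=obs.d * scale, h=obs.h, f=obs.f)
        grown_h = StandObservation(t=obs.t, n=obs.n, d=obs.d, h=obs.h * scale, f=obs.f)
        grown_n = StandObservation(t=obs.t, n=obs.n + 1, d=obs.d, h=obs.h, f=obs.f)
        grown_f = StandObservation(t=obs.t, n=obs.n, d=obs.d, h=obs.h,
                                   f=min(1.0, obs.f * scale))
        assert stand_volume(grown_d) > base
        assert stand_volume(grown_h) > base
        assert stand_volume(grown_n) > base
        if grown_f.f > obs.f:
            assert stand_volume(grown_f) > base

    def test_pai_telescoping(self, pre_table):
        """Summing PAI x interval over a table recovers last TV minus first."""
        rows = summarize_table(pre_table)
        ages = [r.age for r in rows]
        acc = rows[0].tv
        for i, r in enumerate(rows[1:], start=1):
            acc += r.pai * (ages[i] - ages[i - 1])
        assert acc == pytest.approx(rows[-1].tv, rel=1e-12)

    def test_culmination_coincides_with_pai_mai_crossing(self):
        """On a unimodal synthetic trajectory measured yearly, PAI first
        drops below MAI on the interval ending at (or just after) the
        MAI culmination age."""
        table = generate_stand_trajectory(GrowthCurveParams(), list(range(3, 41)))
        rows = summarize_table(table)
        mais = [r.mai for r in rows]
        i_peak = mais.index(max(mais))
        assert all(m2 > m1 for m1, m2 in zip(mais[:i_peak], mais[1 : i_peak + 1]))
        assert all(m2 < m1 for m1, m2 in zip(mais[i_peak:], mais[i_peak + 1 :]))
        peak_age = rows[i_peak].age
        first_drop = next(r.age for r in rows if r.pai is not None and r.pai < r.mai)
        assert first_drop in (peak_age, peak_age + 1)


class TestValidation:
    def test_observation_invariants(self):
        with pytest.raises(ValueError):
            StandObservation(t=0, n=10, d=5.0, h=2.0, f=0.8)
        with pytest.raises(ValueError):
            StandObservation(t=3, n=-1, d=5.0, h=2.0, f=0.8)
        with pytest.raises(ValueError):
            StandObservation(t=3, n=10, d=5.0, h=2.0, f=1.2)

    def test_table_requires_increasing_ages(self):
        a = StandObservation(t=5, n=10, d=5.0, h=2.0, f=0.8)
        b = StandObservation(t=5, n=10, d=6.0, h=2.5, f=0.8)
        with pytest.raises(ValueError):
            StandTable(rows=(a, b))
        with pytest.raises(ValueError):
            StandTable(rows=())
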