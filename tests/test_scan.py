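"""Scan statistic: LLR, RR, geometry, enumeration, Monte Carlo, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transgen_scan import (
    AncestorStratum,
    CandidateCylinder,
    ScanConfig,
    bernoulli_llr,
    enumerate_cylinders,
    monte_carlo_pvalue,
    point_in_cylinder,
    relative_risk,
    scan_stratum,
    select_secondary_clusters,
)

from _oracles import (
    brute_force_best,
    enumerate_member_sets_oracle,
    greedy_selection_oracle,
    in_ellipse_oracle,
    llr_oracle,
)
from conftest import make_stratum


# ---------------------------------------------------------------------------
# counts strategy: valid (c, n, C, N) with both inside and outside nonempty
# ---------------------------------------------------------------------------

@st.composite
def count_tuples(draw):
    N = draw(st.integers(2, 400))
    n = draw(st.integers(1, N - 1))
    C = draw(st.integers(0, N))
    c_lo = max(0, C - (N - n))
    c_hi = min(n, C)
    c = draw(st.integers(c_lo, c_hi))
    return c, n, C, N


class TestBernoulliLlr:
    def test_proportional_window_is_zero(self):
        llr, direction = bernoulli_llr(5, 10, 50, 100)
        assert llr == 0.0
        llr, _ = bernoulli_llr(4, 8, 50, 100)
        assert llr == 0.0

    def test_known_high_rate_value(self):
        # frozen from the closed-form oracle evaluated independently
        llr, direction = bernoulli_llr(4, 5, 10, 100)
        assert llr == pytest.approx(7.627174240931277, rel=1e-12)
        assert direction == "high"

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            bernoulli_llr(5, 4, 10, 100)  # c > n
        with pytest.raises(ValueError):
            bernoulli_llr(0, 100, 10, 100)  # n = N
        with pytest.raises(ValueError):
            bernoulli_llr(11, 20, 10, 100)  # c > C

    @settings(max_examples=300, derandomize=True)
    @given(count_tuples())
    def test_matches_closed_form_and_nonnegative(self, cnCN):
        c, n, C, N = cnCN
        llr, direction = bernoulli_llr(c, n, C, N)
        assert llr >= 0.0
        assert llr == pytest.approx(max(llr_oracle(c, n, C, N), 0.0), abs=1e-9)
        if 0 < c < C and llr > 0:
            assert (direction == "high") == (c / n > (C - c) / (N - n))

    @settings(max_examples=200, derandomize=True)
    @given(count_tuples())
    def test_label_swap_symmetry(self, cnCN):
        """Swapping case/control labels (C -> N-C, c -> n-c) preserves the
        LLR and flips the direction when the LLR is positive."""
        c, n, C, N = cnCN
        llr, direction = bernoulli_llr(c, n, C, N)
        llr2, direction2 = bernoulli_llr(n - c, n, N - C, N)
        assert llr == pytest.approx(llr2, abs=1e-9)
        if llr > 1e-9:
            assert direction != direction2

    @settings(max_examples=200, derandomize=True)
    @given(count_tuples())
    def test_monotone_in_inside_cases(self, cnCN):
        """Adding a case inside (same n, C, N) never lowers a high-rate LLR."""
        c, n, C, N = cnCN
        if c + 1 > min(n, C):
            return
        llr1, d1 = bernoulli_llr(c, n, C, N)
        llr2, d2 = bernoulli_llr(c + 1, n, C, N)
        if d1 == "high":
            assert llr2 >= llr1 - 1e-12
            assert d2 == "high"

    def test_zero_iff_exactly_proportional(self):
        llr, _ = bernoulli_llr(10, 40, 50, 200)  # 0.25 both
        assert llr == 0.0
        llr, _ = bernoulli_llr(11, 40, 50, 200)
        assert llr > 0.0


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "c,n,C,N,expected",
        [
            (5, 10, 50, 100, 1.0),
            (10, 20, 50, 200, 2.25),
            (0, 20, 50, 200, 0.0),
        ],
    )
    def test_examples(self, c, n, C, N, expected):
        assert relative_risk(c, n, C, N) == pytest.approx(expected)

    def test_all_cases_inside_flagged_infinite(self):
        assert relative_risk(10, 20, 10, 100) == math.inf

    def test_no_cases_in_stratum_error(self):
        with pytest.raises(ValueError, match="no cases"):
            relative_risk(0, 10, 0, 100)

    @settings(max_examples=200, derandomize=True)
    @given(count_tuples())
    def test_rr_above_one_iff_high(self, cnCN):
        c, n, C, N = cnCN
        if C == 0 or c == 0 or c == C:
            return
        rr = relative_risk(c, n, C, N)
        _, direction = bernoulli_llr(c, n, C, N)
        if direction == "high":
            assert rr > 1
        else:
            assert rr <= 1 + 1e-12


class TestMonteCarloPvalue:
    def test_extremes_and_direct_count(self):
        reps = list(range(1, 1000))  # 999 replicates
        assert monte_carlo_pvalue(1e9, reps) == pytest.approx(0.001)
        assert monte_carlo_pvalue(0.0, reps) == 1.0
        assert monte_carlo_pvalue(5, [1, 2, 3, 4, 5, 6, 7, 8, 9]) == pytest.approx(0.6)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=50),
        st.floats(0, 100),
    )
    def test_bounds(self, reps, obs):
        p = monte_carlo_pvalue(obs, reps)
        R = len(reps)
        assert 1 / (R + 1) <= p <= 1.0


class TestPointInCylinder:
    CYL = CandidateCylinder(
        center=(10.0, 20.0), semi_major=5.0, shape=2.0, angle=0.0,
        year_start=2000, year_end=2002,
    )

    def test_center_inside(self):
        assert point_in_cylinder(10.0, 20.0, 2001, self.CYL)

    def test_beyond_major_axis_outside(self):
        assert not point_in_cylinder(10.0 + 5.05, 20.0, 2001, self.CYL)

    def test_year_outside_interval(self):
        assert not point_in_cylinder(10.0, 20.0, 2003, self.CYL)

    def test_rotated_major_axis_vertical(self):
        cyl = CandidateCylinder(
            center=(0.0, 0.0), semi_major=5.0, shape=2.0, angle=math.pi / 2,
            year_start=2000, year_end=2002,
        )
        assert point_in_cylinder(0.0, 5.0, 2001, cyl)
        assert not point_in_cylinder(5.0, 0.0, 2001, cyl)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.floats(-20, 20), st.floats(-20, 20),
        st.floats(0.5, 10), st.floats(1, 5), st.floats(0, math.pi - 1e-9),
    )
    def test_matches_rotation_matrix_oracle(self, px, py, a, shape, theta):
        cyl = CandidateCylinder(
            center=(1.0, -2.0), semi_major=a, shape=shape, angle=theta,
            year_start=2000, year_end=2000,
        )
        got = point_in_cylinder(px, py, 2000, cyl)
        want = in_ellipse_oracle(px, py, 1.0, -2.0, a, shape, theta)
        # disagreement is only possible within float noise of the boundary
        m = (px - 1.0) ** 2 / a**2 + (py + 2.0) ** 2 / (a / shape) ** 2
        if abs(m - 1.0) > 1e-6:
            assert got == want


class TestEnumerateCylinders:
    def test_three_points_match_bruteforce_member_sets(self):
        stratum = AncestorStratum(
            role="mother", window="birth",
            subject_ids=np.array(["a", "b", "c"], dtype=object),
            x=np.array([0.0, 4.0, 10.0]),
            y=np.array([0.0, 0.0, 3.0]),
            year=np.array([2000, 2001, 2001]),
            is_case=np.array([True, False, False]),
        )
        config = ScanConfig(
            shapes=(1.0,), angles_per_shape=(1,),
            max_spatial_fraction=1.0, max_temporal_fraction=1.0,
        )
        got = set()
        for cyl in enumerate_cylinders(stratum, config):
            spatial = frozenset(
                i for i in range(3)
                if point_in_cylinder(
                    stratum.x[i], stratum.y[i], cyl.year_start, cyl
                )
            )
            got.add((spatial, (cyl.year_start, cyl.year_end)))
        want = enumerate_member_sets_oracle(
            stratum.x, stratum.y, stratum.year, 1.0, 1.0
        )
        assert got == want

    def test_spatial_cap_limits_to_single_subject(self, rng):
        stratum = make_stratum(8, 3, rng)
        config = ScanConfig(
            shapes=(1.0,), angles_per_shape=(1,),
            max_spatial_fraction=0.124,  # floor(.124*8) = 0 -> at least 1
            max_temporal_fraction=1.0,
        )
        for cyl in enumerate_cylinders(stratum, config):
            n_spatial = sum(
                point_in_cylinder(stratum.x[i], stratum.y[i], cyl.year_start, cyl)
                for i in range(stratum.N)
            )
            assert n_spatial >= 1  # windows hold exactly the closest subject(s)

    def test_coincident_points_share_center(self):
        stratum = AncestorStratum(
            role="mother", window="birth",
            subject_ids=np.array(["a", "b", "c"], dtype=object),
            x=np.array([1.0, 1.0, 5.0]),
            y=np.array([2.0, 2.0, 2.0]),
            year=np.array([2000, 2001, 2000]),
            is_case=np.array([True, False, False]),
        )
        config = ScanConfig(
            shapes=(1.0,), angles_per_shape=(1,),
            max_spatial_fraction=1.0, max_temporal_fraction=1.0,
        )
        centers = {cyl.center for cyl in enumerate_cylinders(stratum, config)}
        assert centers == {(1.0, 2.0), (5.0, 2.0)}

    def test_empty_stratum_rejected(self):
        stratum = AncestorStratum(
            role="mother", window="birth",
            subject_ids=np.array([], dtype=object),
            x=np.array([]), y=np.array([]),
            year=np.array([], dtype=int), is_case=np.array([], dtype=bool),
        )
        with pytest.raises(ValueError):
            list(enumerate_cylinders(stratum, ScanConfig()))


class TestScanStratum:
    def test_planted_disc_is_most_likely_cluster(self, rng):
        """9 of 10 cases packed in a tight disc in one year must be found."""
        n = 30
        x = rng.uniform(0, 1000, n)
        y = rng.uniform(0, 1000, n)
        year = rng.integers(2000, 2006, n)
        is_case = np.zeros(n, dtype=bool)
        inside = np.arange(9)
        x[inside] = 500 + rng.uniform(-5, 5, 9)
        y[inside] = 500 + rng.uniform(-5, 5, 9)
        year[inside] = 2002
        is_case[inside] = True
        is_case[20] = True  # the 10th case, far away
        stratum = AncestorStratum(
            role="mother", window="birth",
            subject_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
            x=x, y=y, year=year.astype(int), is_case=is_case,
        )
        config = ScanConfig(shapes=(1.0,), angles_per_shape=(1,), n_replicates=99)
        clusters = scan_stratum(stratum, config, seed=5)
        top = clusters[0]
        assert set(top.member_ids) == {f"s{i}" for i in inside}
        assert top.direction == "high"
        assert top.p_mc == pytest.approx(0.01)

    def test_counts_reproducible_by_membership(self, rng):
        stratum = make_stratum(40, 13, rng)
        config = ScanConfig(
            shapes=(1.0, 2.0), angles_per_shape=(1, 4), n_replicates=19
        )
        for cl in scan_stratum(stratum, config, seed=2):
            inside = [
                i for i in range(stratum.N)
                if point_in_cylinder(
                    stratum.x[i], stratum.y[i], stratum.year[i], cl.cylinder
                )
            ]
            assert len(inside) == cl.n
            assert int(stratum.is_case[inside].sum()) == cl.c
            assert sorted(stratum.subject_ids[inside]) == cl.member_ids

    def test_identical_seed_identical_output(self, rng):
        stratum = make_stratum(35, 11, rng)
        config = ScanConfig(shapes=(1.0,), angles_per_shape=(1,), n_replicates=49)
        a = scan_stratum(stratum, config, seed=7)
        b = scan_stratum(stratum, config, seed=7)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.cylinder == cb.cylinder
            assert (ca.c, ca.n, ca.llr, ca.p_mc) == (cb.c, cb.n, cb.llr, cb.p_mc)
            assert ca.member_ids == cb.member_ids

    def test_degenerate_stratum_rejected(self, rng):
        stratum = make_stratum(10, 0, rng)
        with pytest.raises(ValueError, match="degenerate"):
            scan_stratum(stratum, ScanConfig(n_replicates=9), seed=1)

    def test_null_calibration_small(self, rng):
        """p_mc under label exchangeability: fraction <= 0.05 near nominal."""
        hits = 0
        trials = 220
        for k in range(trials):
            r = np.random.default_rng(1000 + k)
            stratum = make_stratum(30, 10, r, years=(2000, 2009))
            config = ScanConfig(
                shapes=(1.0,), angles_per_shape=(1,), n_replicates=99,
                max_centers=15, n_size_steps=6, time_agg_years=2,
            )
            clusters = scan_stratum(stratum, config, seed=2000 + k)
            p = min((c.p_mc for c in clusters), default=1.0)
            hits += p <= 0.05
        assert 0.02 <= hits / trials <= 0.10


class TestSecondarySelection:
    @staticmethod
    def _cyl(cx, cy, a, shape=1.0, angle=0.0):
        return CandidateCylinder(
            center=(cx, cy), semi_major=a, shape=shape, angle=angle,
            year_start=2000, year_end=2001,
        )

    def test_disjoint_both_reported(self):
        cands = [(self._cyl(0, 0, 10), 5.0, 4), (self._cyl(100, 0, 10), 3.0, 4)]
        assert select_secondary_clusters(cands) == [0, 1]

    def test_nested_only_better_reported(self):
        cands = [(self._cyl(0, 0, 10), 5.0, 4), (self._cyl(1, 0, 3), 3.0, 2)]
        assert select_secondary_clusters(cands) == [0]

    def test_zero_llr_never_reported(self):
        cands = [(self._cyl(0, 0, 10), 0.0, 4)]
        assert select_secondary_clusters(cands) == []

    def test_matches_geometric_oracle_on_random_candidates(self, rng):
        for trial in range(10):
            r = np.random.default_rng(500 + trial)
            cands = []
            for _ in range(10):
                cands.append(
                    (
                        self._cyl(
                            r.uniform(0, 100), r.uniform(0, 100),
                            r.uniform(5, 30), r.choice([1.0, 2.0, 3.0]),
                            r.uniform(0, math.pi * 0.999),
                        ),
                        float(np.round(r.uniform(0, 10), 3)),
                        int(r.integers(1, 20)),
                    )
                )
            assert select_secondary_clusters(cands) == greedy_selection_oracle(cands)
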