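"""Model tests: probability oracle, connectivity, JMLE vs direct ML, fairness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st


from vescasim.errors import ModelError
from vescasim.mfrm import (
    MfrmConfig,
    adjusted_scores,
    category_probabilities,
    check_connectivity,
    expected_score,
    fit_jmle,
)
from vescasim.synthetic_data import OsceDataset, SimulationParams, simulate_dataset


# ---------------------------------------------------------------- probabilities


class TestCategoryProbabilities:
    def test_two_categories_even_odds_at_zero_net_logit(self):
        p = category_probabilities(1.5, 1.0, 0.2, thresholds=[0.3])
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_three_category_closed_form(self):
        # net logit 0, thresholds (-1, +1): probabilities (1, e, 1)/(2 + e)
        p = category_probabilities(0.0, 0.0, 0.0, thresholds=[-1.0, 1.0])
        e = np.e
        np.testing.assert_allclose(p, np.array([1, e, 1]) / (2 + e), atol=1e-12)

    @given(
        st.floats(-8, 8),
        st.floats(-4, 4),
        st.floats(-4, 4),
        st.lists(st.floats(-5, 5), min_size=1, max_size=24),
    )
    def test_normalisation(self, measure, difficulty, severity, thresholds):
        p = category_probabilities(measure, difficulty, severity, thresholds)
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_single_category_rejected(self):
        with pytest.raises(ModelError):
            category_probabilities(0.0, 0.0, 0.0, thresholds=[])


class TestExpectedScore:
    def test_three_category_midpoint(self):
        v = expected_score(0.0, 0.0, 0.0, [-1.0, 1.0], [1, 2, 3])
        assert v == pytest.approx(2.0, abs=1e-12)

    def test_limits_reach_scale_bounds(self):
        values = np.arange(6, 28)
        thr = np.zeros(21)
        assert expected_score(40.0, 0, 0, thr, values) == pytest.approx(27, abs=1e-6)
        assert expected_score(-40.0, 0, 0, thr, values) == pytest.approx(6, abs=1e-6)

    def test_symmetric_thresholds_give_midpoint(self):
        values = np.arange(6, 28)
        thr = np.linspace(-2, 2, 21)
        assert expected_score(0.0, 0, 0, thr, values) == pytest.approx(16.5, abs=1e-9)

    @given(st.floats(-6, 6), st.floats(-6, 6))
    def test_strictly_increasing_in_measure(self, m1, m2):
        if abs(m1 - m2) < 1e-6:  # below float resolution of the expectation
            return
        lo, hi = sorted([m1, m2])
        thr = [-1.0, -0.2, 0.4, 1.1]
        vals = [0, 1, 2, 3, 4]
        assert expected_score(lo, 0, 0, thr, vals) < expected_score(hi, 0, 0, thr, vals)


# ---------------------------------------------------------------- connectivity


class TestConnectivity:
    def test_videos_link_all_cohorts(self, tiny_connected):
        _, _, ds = tiny_connected
        connected, labels = check_connectivity(ds)
        assert connected
        assert len({v for k, v in labels.items() if k[0] == "cohort"}) == 1

    def test_no_videos_give_one_subset_per_cohort(self, tiny_disconnected):
        _, _, ds = tiny_disconnected
        connected, labels = check_connectivity(ds)
        assert not connected
        assert len({v for k, v in labels.items() if k[0] == "cohort"}) == 4

    def test_zero_participation_disconnects(self, rng):
        _, _, ds = simulate_dataset(SimulationParams(participation=0.0), rng)
        connected, labels = check_connectivity(ds)
        assert not connected


# ------------------------------------------------------- JMLE vs direct oracle


def _direct_ml_oracle(records):
    from _oracles import direct_ml_oracle

    return direct_ml_oracle(records)


@pytest.fixture(scope="module")
def tight_config():
    return MfrmConfig(
        max_iterations=3000, convergence_tol=1e-8, separate_video_persons=False
    )


class TestJmleOracleEquivalence:
    def test_matches_direct_likelihood_maximisation(self, tiny_connected, tight_config):
        _, _, ds = tiny_connected
        est = fit_jmle(ds, tight_config)
        assert est.converged
        # the oracle cannot represent extreme-total adjustments; this
        # instance has none, so both optimise the same likelihood
        totals = ds.records.groupby("student_id")["score"].agg(["sum", "count"])
        vals = np.unique(ds.records["score"])
        assert not (totals["sum"] == totals["count"] * vals.max()).any()
        assert not (totals["sum"] == totals["count"] * vals.min()).any()

        b, D, C, F, values = _direct_ml_oracle(ds.records)
        np.testing.assert_allclose(est.student_measures, b, atol=1e-3)
        np.testing.assert_allclose(est.station_difficulties, D, atol=1e-3)
        np.testing.assert_allclose(est.cohort_severities, C, atol=1e-3)
        np.testing.assert_allclose(est.thresholds, F, atol=1e-3)

    def test_constant_video_score_gap_recovers_two_point_severity(
        self, two_cohort_shift, tight_config
    ):
        # two cohorts whose examiners differ in leniency by exactly 2 raw
        # points on identical performances: the fitted severity contrast,
        # back-transformed through the fair average, is ~2 raw points and
        # matches the independent direct-ML oracle
        _, _, ds = two_cohort_shift
        est = fit_jmle(ds, tight_config)
        _, _, C_oracle, _, _ = _direct_ml_oracle(ds.records)
        np.testing.assert_allclose(est.cohort_severities, C_oracle, atol=1e-3)

        mu = est.student_measures.mean()
        gap_raw = expected_score(
            mu - est.cohort_severities[0], 0, 0, est.thresholds, est.category_values
        ) - expected_score(
            mu - est.cohort_severities[1], 0, 0, est.thresholds, est.category_values
        )
        # 24 paired video observations with residual noise: the recovered
        # gap carries sampling error of a few tenths of a point
        assert gap_raw == pytest.approx(2.0, abs=0.6)


# ----------------------------------------------------------------- fit behavior


class TestFitJmle:
    def test_empty_dataset_rejected(self, default_params):
        empty = OsceDataset(
            records=pd.DataFrame(columns=["student_id", "station_id", "examiner_id",
                                          "cohort_id", "is_video", "performance_id",
                                          "score", "residual"]),
            params=default_params,
        )
        with pytest.raises(ModelError):
            fit_jmle(empty)

    def test_gauge_invariance_is_resolved_by_centering(self, tiny_connected):
        # adding a constant to all measures and severities leaves fitted
        # probabilities unchanged; centering must yield station/cohort/
        # threshold means of zero so the reported solution is unique
        _, _, ds = tiny_connected
        est = fit_jmle(ds)
        assert est.station_difficulties.mean() == pytest.approx(0, abs=1e-9)
        assert est.cohort_severities.mean() == pytest.approx(0, abs=1e-9)
        assert est.thresholds.mean() == pytest.approx(0, abs=1e-9)

    def test_disconnected_cohorts_are_anchored_at_zero(self, tiny_disconnected):
        _, _, ds = tiny_disconnected
        est = fit_jmle(ds)
        assert not est.connected
        assert est.cohorts_anchored
        np.testing.assert_array_equal(est.cohort_severities, 0.0)

    def test_extreme_scores_stay_finite(self, rng):
        p = SimulationParams(n_students=6, n_stations=2, n_cohorts=2,
                             scale_min=0, scale_max=3, grand_mean=1.5,
                             student_sd=2.5, residual_sd=0.2, n_videos=2,
                             participation=1.0)
        _, _, ds = simulate_dataset(p, 42)
        # force one student to the maximum everywhere
        recs = ds.records.copy()
        recs.loc[recs["student_id"] == 0, "score"] = 3
        ds2 = OsceDataset(records=recs, params=p)
        est = fit_jmle(ds2)
        assert np.isfinite(est.student_measures).all()

    def test_degenerate_constant_dataset(self, rng):
        p = SimulationParams(student_sd=0, station_sd=0, interaction_sd=0,
                             examiner_sd=0, residual_sd=0)
        _, _, ds = simulate_dataset(p, rng)
        est = fit_jmle(ds)
        adj = adjusted_scores(est)
        assert (adj.table["adjusted_score"] == 19).all()


class TestAdjustedScores:
    def test_identity_configuration_conserves_scores(self):
        # one cohort, no examiner effects, no residual: fair averages come
        # back to each student's rounded true mean within 0.25 raw points
        p = SimulationParams(n_cohorts=1, examiner_sd=0.0, residual_sd=0.0)
        perf, _, ds = simulate_dataset(p, 2024)
        est = fit_jmle(ds)
        adj = adjusted_scores(est).table.set_index("student_id")
        obs = ds.live.groupby("student_id")["score"].mean()
        np.testing.assert_allclose(
            adj["adjusted_score"].to_numpy(), obs.to_numpy(), atol=0.25
        )

    def test_zero_videos_leave_scores_nearly_unadjusted(self):
        # cohorts anchored at zero: adjustment is pure Rasch round-trip noise
        p = SimulationParams(n_videos=0)
        _, _, ds = simulate_dataset(p, 77)
        est = fit_jmle(ds)
        adj = adjusted_scores(est).table.set_index("student_id")
        obs = ds.live.groupby("student_id")["score"].mean()
        mean_adj = np.abs(adj["adjusted_score"].to_numpy() - obs.to_numpy()).mean()
        assert mean_adj < 0.2

    def test_adjusted_strictly_increasing_in_measure(self, tiny_connected):
        _, _, ds = tiny_connected
        est = fit_jmle(ds)
        t = adjusted_scores(est).table.sort_values("measure")
        assert t["adjusted_score"].is_monotonic_increasing

    def test_severer_cohort_student_gets_higher_adjusted_score(self):
        # hand-built two-cohort instance: identical live scores, but cohort 1
        # scores the shared videos 2 points lower; the cohort-1 student must
        # come out ahead after adjustment
        rows = []
        live_scores = {0: [5, 6], 1: [5, 6]}  # student -> per-station scores
        for student, cohort in ((0, 0), (1, 1)):
            for station, score in enumerate(live_scores[student]):
                rows.append((student, station, 10 * cohort + station, cohort,
                             False, student, score, 0.0))
        # shared videos (performances of two extra students) scored by both
        video_truth = {2: [4, 7], 3: [6, 3]}
        for vstudent, scores in video_truth.items():
            for station, truth in enumerate(scores):
                for cohort in (0, 1):
                    score = truth if cohort == 0 else truth - 2
                    rows.append((vstudent, station, 10 * cohort + station, cohort,
                                 True, vstudent, score, 0.0))
        records = pd.DataFrame(
            rows,
            columns=["student_id", "station_id", "examiner_id", "cohort_id",
                     "is_video", "performance_id", "score", "residual"],
        )
        params = SimulationParams(n_students=4, n_stations=2, n_cohorts=2,
                                  scale_min=0, scale_max=9, grand_mean=5.0)
        ds = OsceDataset(records=records, params=params)
        est = fit_jmle(ds, MfrmConfig(max_iterations=500))
        adj = adjusted_scores(est).table.set_index("student_id")
        assert (
            adj.loc[1, "adjusted_score"] > adj.loc[0, "adjusted_score"]
        )

    def test_estimates_frame_covers_all_facets(self, tiny_connected):
        _, _, ds = tiny_connected
        est = fit_jmle(ds)
        frame = est.to_frame()
        assert set(frame["facet"]) == {"student", "station", "cohort", "threshold"}
        assert len(frame[frame.facet == "student"]) == 8
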