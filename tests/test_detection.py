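"""Baseline selection, KDIGO staging, and the alert lifecycle."""

from datetime import timedelta

import pytest
from hypothesis import given, settings, strategies as st

from aki_cds import (
    AlertStatus,
    Analyte,
    BaselineMethod,
    LabResult,
    MedicationOrder,
    Setting,
    SimulationConfig,
    StagingConfig,
    acknowledge_alert,
    compute_baseline,
    detect,
    generate_cohort,
    process_patient,
    stage_aki,
)
from conftest import T0, make_patient, oracle_alerts, oracle_stage

H, C = Setting.HOSPITAL, Setting.COMMUNITY


def _lab(value, hours_before_t0=0.0, setting=C):
    return LabResult("P1", Analyte.CREATININE, T0 - timedelta(hours=hours_before_t0),
                     value, setting=setting)


class TestComputeBaseline:
    def test_short_window_takes_lowest(self, config):
        history = [_lab(110, 6 * 24), _lab(90, 3 * 24)]
        b = compute_baseline(history, T0, config)
        assert b.method is BaselineMethod.SHORT_WINDOW
        assert b.value == 90
        assert b.n_contributing == 2

    def test_short_window_most_recent_variant(self):
        cfg = StagingConfig(baseline_short_method="most_recent")
        history = [_lab(90, 6 * 24), _lab(110, 3 * 24)]
        assert compute_baseline(history, T0, cfg).value == 110

    def test_long_window_median_odd(self, config):
        history = [_lab(90, 300 * 24), _lab(80, 200 * 24), _lab(100, 100 * 24)]
        b = compute_baseline(history, T0, config)
        assert b.method is BaselineMethod.LONG_WINDOW_MEDIAN
        assert b.value == 90

    def test_long_window_median_even_is_midpair_mean(self, config):
        history = [_lab(120, 200 * 24), _lab(100, 50 * 24)]
        b = compute_baseline(history, T0, config)
        assert b.method is BaselineMethod.LONG_WINDOW_MEDIAN
        assert b.value == 110

    def test_no_history_unavailable(self, config):
        b = compute_baseline([], T0, config)
        assert b.method is BaselineMethod.UNAVAILABLE
        assert b.value is None

    def test_short_window_is_half_open(self, config):
        # a result exactly 7 days old falls into the long window
        history = [_lab(100, 7 * 24)]
        b = compute_baseline(history, T0, config)
        assert b.method is BaselineMethod.LONG_WINDOW_MEDIAN

    def test_history_must_precede_index(self, config):
        with pytest.raises(ValueError, match="precede"):
            compute_baseline([_lab(100, -1)], T0, config)


class TestStageAki:
    def _stage(self, index_value, baseline_value, recent=(), config=None):
        config = config or StagingConfig()
        history = [_lab(baseline_value, 2 * 24)] if baseline_value else []
        baseline = compute_baseline(history, T0, config)
        recent_labs = [_lab(v, h) for v, h in recent]
        return stage_aki(_lab(index_value, 0, H), baseline, recent_labs, config)

    @pytest.mark.parametrize(
        "index,baseline,expected",
        [(160, 100, 1), (210, 100, 2), (310, 100, 3), (149, 100, 0), (360, 300, 3)],
    )
    def test_ratio_and_absolute_criteria(self, index, baseline, expected):
        assert self._stage(index, baseline).stage == expected

    def test_absolute_rise_overrides_low_ratio(self):
        a = self._stage(230, 200, recent=[(195, 24)])
        assert a.ratio == pytest.approx(1.15)
        assert a.rise_48h == pytest.approx(35)
        assert a.stage == 1

    def test_absolute_stage3_without_baseline(self):
        a = self._stage(360, None)
        assert a.ratio is None
        assert a.stage == 3

    def test_wrong_analyte_rejected(self, config):
        urea = LabResult("P1", Analyte.UREA, T0, 7.0)
        baseline = compute_baseline([], T0, config)
        with pytest.raises(ValueError, match="creatinine"):
            stage_aki(urea, baseline, [], config)

    def test_exhaustive_grid_matches_oracle(self, config):
        """Staging over a dense (baseline, index) grid agrees with an
        independent flat-scan threshold evaluator."""
        for baseline in range(40, 241, 10):
            for index in range(30, 521, 7):
                for min_recent in (None, max(1, index - 30), max(1, index - 20)):
                    a = self._stage(
                        index, baseline,
                        recent=[(min_recent, 24)] if min_recent else [],
                    )
                    assert a.stage == oracle_stage(
                        index, baseline, min_recent, config
                    ), (baseline, index, min_recent)

    @given(
        baseline=st.floats(30, 400),
        index=st.floats(30, 600),
        bump=st.floats(0, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_index_value(self, baseline, index, bump):
        assert self._stage(index + bump, baseline).stage >= self._stage(index, baseline).stage

    @given(ratio=st.floats(0.2, 6.0))
    @settings(max_examples=200, derandomize=True)
    def test_closed_form_with_absolute_criteria_disabled(self, ratio):
        cfg = StagingConfig(abs_rise_48h=1e9, abs_stage3=1e9)
        baseline = 100.0
        stage = self._stage(baseline * ratio, baseline, config=cfg).stage
        assert stage == sum(ratio >= t for t in (1.5, 2.0, 3.0))


class TestLifecycle:
    def test_progression_then_deescalation(self, config, formulary):
        p = make_patient(creatinine=[
            (T0 - timedelta(days=2), 100, C),
            (T0, 160, H),
            (T0 + timedelta(hours=12), 210, H),
            (T0 + timedelta(hours=24), 160, H),
        ])
        alerts, state = process_patient(p, config, formulary)
        assert [(a.stage, a.episode_index) for a in alerts] == [(1, 1), (2, 1)]
        assert state.in_episode and state.max_alerted_stage == 2

    def test_recovery_opens_second_episode(self, config, formulary):
        p = make_patient(creatinine=[
            (T0 - timedelta(days=2), 100, C),
            (T0, 160, H),
            (T0 + timedelta(hours=12), 105, H),
            (T0 + timedelta(hours=24), 170, H),
        ])
        alerts, state = process_patient(p, config, formulary)
        assert [(a.stage, a.episode_index) for a in alerts] == [(1, 1), (1, 2)]
        assert state.episode_index == 2

    def test_community_results_never_index(self, config, formulary):
        # the elevated value is a community draw: no alert
        p = make_patient(creatinine=[
            (T0 - timedelta(days=2), 100, C),
            (T0, 160, C),
        ])
        alerts, _ = process_patient(p, config, formulary)
        assert alerts == []

    def test_no_creatinine_yields_empty_output(self, config, formulary):
        alerts, state = process_patient(make_patient(), config, formulary)
        assert alerts == [] and state.episode_index == 0

    def test_alert_carries_trigger_time_and_encounter(self, config, formulary):
        p = make_patient(creatinine=[(T0 - timedelta(days=2), 100, C), (T0, 160, H)])
        alerts, _ = process_patient(p, config, formulary)
        assert alerts[0].raised_at == T0
        assert alerts[0].encounter_id == "E-P1"

    def test_streaming_equals_replay_oracle_on_cohort(self, config, formulary):
        cohort, _ = generate_cohort(SimulationConfig(
            n_patients=120, seed=11, aki_incidence=0.4, measurement_noise_cv=0.05,
        ))
        for p in cohort:
            got = [(a.stage, a.episode_index, a.raised_at) for a in detect(p, config, formulary).alerts]
            expected, _ = oracle_alerts(p, config)
            assert got == expected, p.patient_id

    def test_episode_invariants_on_cohort(self, config, formulary):
        cohort, _ = generate_cohort(SimulationConfig(
            n_patients=80, seed=5, aki_incidence=0.5, measurement_noise_cv=0.08,
        ))
        for p in cohort:
            alerts = detect(p, config, formulary).alerts
            seen = set()
            last_ep = 0
            per_episode_stage = {}
            for a in alerts:
                key = (a.episode_index, a.stage)
                assert key not in seen  # at most one alert per (episode, stage)
                seen.add(key)
                assert a.episode_index >= last_ep  # episode index never decreases
                last_ep = a.episode_index
                prev = per_episode_stage.get(a.episode_index, 0)
                assert a.stage > prev  # stages strictly increase within an episode
                per_episode_stage[a.episode_index] = a.stage


class TestAcknowledge:
    def _alert(self, config, formulary):
        p = make_patient(creatinine=[(T0 - timedelta(days=2), 100, C), (T0, 160, H)])
        return detect(p, config, formulary).alerts[0]

    def test_acknowledge_sets_status_and_keeps_history(self, config, formulary):
        alert = self._alert(config, formulary)
        acked = acknowledge_alert(alert, T0 + timedelta(hours=2))
        assert acked.status is AlertStatus.ACKNOWLEDGED
        assert acked.acknowledged_at == T0 + timedelta(hours=2)
        assert acked.alert_id == alert.alert_id  # same alert, never deleted

    def test_double_acknowledge_is_noop(self, config, formulary):
        acked = acknowledge_alert(self._alert(config, formulary), T0 + timedelta(hours=2))
        assert acknowledge_alert(acked, T0 + timedelta(hours=9)) == acked

    def test_acknowledge_before_raise_rejected(self, config, formulary):
        with pytest.raises(ValueError):
            acknowledge_alert(self._alert(config, formulary), T0 - timedelta(hours=1))


def test_staging_config_validation():
    with pytest.raises(ValueError):
        StagingConfig(ratio_stage1=2.5)  # ordering violated
    with pytest.raises(ValueError):
        StagingConfig(abs_rise_48h=-1)
    with pytest.raises(ValueError):
        StagingConfig(baseline_short_method="average")
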