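"""Simulation engine: observers, staircase, ZEST surrogate, cohorts."""

import numpy as np
import pytest

import perimsim as ps
from perimsim.grid import GRID_30_2
from perimsim.normative import Category
from perimsim.sim import (
    PROTOCOLS,
    SimConfig,
    SimPatient,
    fos_probability,
    generate_normative_database,
    generate_vgb_field,
    simulate_cohort,
    simulate_exam,
    staircase_4_2,
    zest,
    _bimodal_prior,
)

from conftest import STUDY_SEED

N = len(GRID_30_2)
MASK = GRID_30_2.analysable_mask
ECC = GRID_30_2.eccentricity
CFG = SimConfig()


class TestFos:
    def test_at_threshold_half(self):
        assert fos_probability(20.0, 20.0, slope=2.0) == pytest.approx(0.5)

    def test_limits(self):
        assert fos_probability(40.0, 0.0, slope=1.0) == pytest.approx(0.0, abs=1e-9)
        assert fos_probability(0.0, 40.0, slope=1.0) == pytest.approx(1.0, abs=1e-9)

    def test_error_rates_compress_range(self):
        hi = fos_probability(0.0, 40.0, 1.0, resp_fp=0.1, resp_fn=0.2)
        lo = fos_probability(40.0, 0.0, 1.0, resp_fp=0.1, resp_fn=0.2)
        assert hi == pytest.approx(0.8, abs=1e-9)
        assert lo == pytest.approx(0.1, abs=1e-9)

    def test_monotone_decreasing_in_stimulus(self):
        ps_ = [fos_probability(s, 20.0, 2.0) for s in np.linspace(0, 40, 41)]
        assert all(a >= b for a, b in zip(ps_, ps_[1:]))

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fos_probability(20.0, 20.0, slope=0.0)


def deterministic_observer(threshold):
    """Ideal observer: sees every stimulus at or below threshold (dB)."""
    return lambda stim: stim <= threshold


def replay_staircase(responses, start, lo=0.0, hi=40.0):
    """Independent re-implementation of the 4-2 rule driven by a fixed
    response list; used as an oracle for `staircase_4_2`."""
    level, step = float(start), 4.0
    reversals, last_seen, prev, edge = 0, None, None, 0
    n = 0
    for seen in responses:
        n += 1
        if seen:
            last_seen = level
        if (level == lo and not seen) or (level == hi and seen):
            edge += 1
            if edge >= 2:
                break
        else:
            edge = 0
        if prev is not None and seen != prev:
            reversals += 1
            if reversals == 1:
                step = 2.0
            else:
                break
        prev = seen
        level = min(max(level + (step if seen else -step), lo), hi)
    return (lo, n, False) if last_seen is None else (last_seen, n, True)


class TestStaircase:
    def test_exact_walk_by_hand(self):
        # threshold 17, start 25: 25 seen? no -> 21 no -> 17 yes (reversal,
        # step 2) -> 19 no (second reversal, stop).  Estimate = 17.
        est, n, seen = staircase_4_2(deterministic_observer(17.0), 25.0)
        assert (est, n, seen) == (17.0, 4, True)

    @pytest.mark.parametrize("threshold", range(0, 41, 4))
    @pytest.mark.parametrize("start", [25.0, 30.0])
    def test_deterministic_bias_bounded(self, threshold, start):
        est, _, seen = staircase_4_2(deterministic_observer(threshold), start)
        assert seen
        assert abs(est - threshold) <= 1.0

    def test_deterministic_mean_bias(self):
        # per-dB-threshold error is 0 or -1 depending on staircase parity
        errs = [
            staircase_4_2(deterministic_observer(t), 30.0)[0] - t
            for t in range(1, 40)
        ]
        assert set(errs) <= {0.0, -1.0}
        assert np.mean(errs) == pytest.approx(-0.488, abs=0.05)

    def test_blind_location_floors_at_zero(self):
        est, _, seen = staircase_4_2(lambda s: False, 25.0)
        assert est == 0.0 and not seen

    def test_ceiling(self):
        est, _, seen = staircase_4_2(lambda s: True, 30.0)
        assert est == 40.0 and seen

    def test_matches_independent_replay_oracle(self):
        rng = np.random.default_rng(STUDY_SEED)
        for _ in range(200):
            resp_seq = rng.random(30) < rng.uniform(0.2, 0.8)
            seq = list(resp_seq)

            def from_seq(seq=seq, it=iter(seq)):
                return lambda s: next(it)

            start = float(rng.integers(0, 41))
            got = staircase_4_2(from_seq(), start)
            assert got == replay_staircase(seq, start)

    def test_bad_start_rejected(self):
        with pytest.raises(ValueError, match="start"):
            staircase_4_2(lambda s: True, 50.0)


class TestZest:
    def test_deterministic_observer_recovers_threshold(self):
        for thr in (15.0, 25.0, 32.0):
            prior = _bimodal_prior(27.0, CFG)
            est, n = zest(deterministic_observer(thr), prior,
                          CFG.zest_sd_stop_standard, CFG.zest_cap_standard, CFG)
            assert abs(est - thr) <= 2.0
            assert 1 <= n <= CFG.zest_cap_standard

    def test_fast_uses_no_more_presentations_than_standard(self):
        rng = np.random.default_rng(STUDY_SEED)
        n_std, n_fast = 0, 0
        for _ in range(100):
            thr = float(rng.uniform(5, 35))
            seq = list(rng.random(12))

            def obs(seq=seq):
                it = iter(seq)
                return lambda s: next(it) < fos_probability(s, thr, 1.5)

            prior = _bimodal_prior(27.0, CFG)
            n_std += zest(obs(), prior, CFG.zest_sd_stop_standard,
                          CFG.zest_cap_standard, CFG)[1]
            n_fast += zest(obs(), prior, CFG.zest_sd_stop_fast,
                           CFG.zest_cap_fast, CFG)[1]
        assert n_fast < n_std

    def test_tight_prior_stops_immediately(self):
        prior = np.zeros(41)
        prior[25] = 1.0  # posterior SD 0 < any tolerance: no presentations
        est, n = zest(deterministic_observer(0.0), prior, 2.0, 6, CFG)
        assert (est, n) == (25.0, 0)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            zest(lambda s: True, np.zeros(41), 2.0, 6, CFG)
        with pytest.raises(ValueError, match="prior"):
            zest(lambda s: True, np.ones(10), 2.0, 6, CFG)


class TestNormativeDatabase:
    def test_deterministic_given_seed(self):
        a = generate_normative_database(n_subjects=60, seed=7)
        b = generate_normative_database(n_subjects=60, seed=7)
        np.testing.assert_array_equal(a.mean_normal, b.mean_normal)
        np.testing.assert_array_equal(a.td_cutoffs[5.0], b.td_cutoffs[5.0])

    def test_mean_declines_with_eccentricity(self, model):
        inner = model.mean_normal[GRID_30_2.zone_mask("inner")].mean()
        outer = model.mean_normal[GRID_30_2.zone_mask("outer")].mean()
        assert inner > outer

    def test_age_slope_positive_decline(self, model):
        assert (model.age_slope[MASK] > 0).all()

    def test_cutoffs_ordered_rarer_is_deeper(self, model):
        for hi, lo in ((5.0, 2.0), (2.0, 1.0), (1.0, 0.5)):
            assert (model.td_cutoffs[lo][MASK] <= model.td_cutoffs[hi][MASK]).all()
            assert (model.pd_cutoffs[lo][MASK] <= model.pd_cutoffs[hi][MASK]).all()

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            generate_normative_database(n_subjects=10)

    def test_noise_free_variant_has_tighter_cutoffs(self):
        meas = generate_normative_database(n_subjects=120, seed=3, measured=True)
        clean = generate_normative_database(n_subjects=120, seed=3, measured=False)
        # estimation error widens the normal limits on average
        assert meas.td_cutoffs[5.0][MASK].mean() < clean.td_cutoffs[5.0][MASK].mean()


class TestVgbField:
    def test_severity_zero_is_normal(self, model):
        p = generate_vgb_field(model, age=40.0, severity=0.0, seed=5)
        assert p.clinical_diagnosis == "normal"
        td = p.true_threshold - CFG.normal_mean(ECC, p.age)
        assert np.abs(td).max() < 8.0  # just population scatter

    def test_loss_grows_with_severity_and_eccentricity(self, model):
        mild = generate_vgb_field(model, 40.0, 0.3, seed=5).true_threshold
        severe = generate_vgb_field(model, 40.0, 0.9, seed=5).true_threshold
        # same seed: identical normal baseline, so the difference is pure loss
        assert ((severe <= mild) | (mild == 0)).all()
        outer, inner = GRID_30_2.zone_mask("outer"), GRID_30_2.zone_mask("inner")
        loss = mild - severe
        assert loss[outer].mean() > loss[inner].mean()
        # central sparing: loss near fixation is a small fraction of outer loss
        central = MASK & (ECC < 10.0)
        assert loss[central].mean() < 0.25 * loss[outer].mean()

    def test_nasal_predominance_of_loss_profile(self):
        loss = CFG.vgb_loss(1.0)
        nasal = GRID_30_2.x < 0
        # compare mirror pairs so eccentricity is matched exactly
        mirror = GRID_30_2.mirror_index()
        for i in np.flatnonzero(nasal):
            assert loss[i] == pytest.approx(CFG.nasal_weight * loss[mirror[i]])

    def test_bad_severity_rejected(self, model):
        with pytest.raises(ValueError, match="severity"):
            generate_vgb_field(model, 40.0, 1.5, seed=0)


class TestSimulateExam:
    def test_duration_identity_and_catch_trials(self, model):
        pat = generate_vgb_field(model, 40.0, 0.0, seed=2)
        vf, res = simulate_exam(pat, "full_threshold", model,
                                np.random.default_rng(2))
        assert res.total_presentations == (
            int(res.presentations.sum()) + 3 * CFG.catch_trials_per_exam
        )
        assert vf.duration_s == res.total_presentations * CFG.per_presentation_time_s
        for pct in (vf.catch_trials.fp_pct, vf.catch_trials.fn_pct,
                    vf.catch_trials.fixation_loss_pct):
            assert 0.0 <= pct <= 100.0

    def test_blind_spot_locations_untested(self, model):
        pat = generate_vgb_field(model, 40.0, 0.0, seed=2)
        vf, res = simulate_exam(pat, "sita_fast", model, np.random.default_rng(2))
        assert np.isnan(vf.sensitivities[~MASK]).all()
        assert (res.presentations[~MASK] == 0).all()
        assert (res.presentations[MASK] >= 1).all()

    def test_unknown_algorithm_rejected(self, model):
        pat = generate_vgb_field(model, 40.0, 0.0, seed=2)
        with pytest.raises(ValueError, match="algorithm"):
            simulate_exam(pat, "tendency_oriented", model, np.random.default_rng(0))


class TestCohort:
    def test_bookkeeping(self, cohort):
        assert len(cohort.patients) == 16
        assert len(cohort.fields) == len(cohort.results) == 16 * 2 * 3
        diseased = [p for p in cohort.patients if p.clinical_diagnosis == "vgb_loss"]
        assert len(diseased) == 6
        assert all(0.3 <= p.severity <= 1.0 for p in diseased)
        # round-robin protocols: four patients on each
        from collections import Counter

        counts = Counter(p.protocol for p in cohort.patients)
        assert counts == {k: 4 for k in PROTOCOLS}

    def test_each_patient_has_all_six_exams(self, cohort):
        from collections import Counter

        c = Counter((f.patient_id, f.algorithm, f.visit) for f in cohort.fields)
        assert set(c.values()) == {1}
        assert len(c) == 96

    def test_deterministic(self, cohort, model):
        again = simulate_cohort(n=16, prevalence=6 / 16, seed=STUDY_SEED, model=model)
        for a, b in zip(cohort.fields, again.fields):
            np.testing.assert_array_equal(a.sensitivities, b.sensitivities)
            assert a.duration_s == b.duration_s

    def test_different_seed_differs(self, cohort, model):
        other = simulate_cohort(n=16, prevalence=6 / 16, seed=STUDY_SEED + 1,
                                model=model)
        assert not np.array_equal(
            other.fields[0].sensitivities, cohort.fields[0].sensitivities,
            equal_nan=True,
        )

    def test_too_small_rejected(self, model):
        with pytest.raises(ValueError, match="at least 4"):
            simulate_cohort(n=2, seed=0, model=model)


class TestRecovery:
    def test_full_threshold_recovers_truth_with_small_bias(self, cohort):
        errs = []
        truth = {p.patient_id: p.true_threshold for p in cohort.patients}
        for f in cohort.fields_for("full_threshold", visit=3):
            errs.append((f.sensitivities - truth[f.patient_id])[MASK])
        errs = np.concatenate(errs)
        assert abs(errs.mean()) <= 1.0
        assert errs.std() < 5.0
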