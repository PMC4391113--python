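"""Synthetic perimetry engine.

Generates everything the analysis pipeline consumes, with no external
data: a simulated normative database, ground-truth visual fields with the
vigabatrin loss pattern (concentric peripheral constriction, nasal
predominance, relative central sparing), probabilistic observers defined
by frequency-of-seeing (FOS) curves, and three thresholding strategies:

* a 4-2 dB **staircase** (Full Threshold): step 4 dB until the first
  response reversal, then 2 dB until the second; the estimate is the last
  seen stimulus level;
* a **ZEST-style Bayesian surrogate** for SITA Standard and SITA Fast: a
  bimodal (normal + abnormal) prior over thresholds updated after every
  presentation, stimulus placed at the posterior mean, stopping when the
  posterior SD falls below a mode-specific tolerance.  The estimate is the
  posterior mean, i.e. the 50%-seen point.  The two modes differ only in
  stopping tolerance and presentation cap: Fast stops earlier, trading
  precision for speed.  This surrogate is *not* the proprietary SITA
  machinery; it reproduces its two structural properties — shorter exams
  and slightly higher threshold estimates than the staircase — which is
  what the downstream comparisons exercise.

All randomness flows from one explicit root seed through named
``numpy.random.SeedSequence`` sub-streams; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Callable

import numpy as np
from scipy.special import ndtr

from .field import ALGORITHMS, CatchTrials, VisualField
from .grid import GRID_30_2
from .normative import GH_RANK, NormativeModel, PCTS

__all__ = [
    "SimConfig",
    "SimPatient",
    "TestResult",
    "PROTOCOLS",
    "fos_probability",
    "staircase_4_2",
    "run_staircase_4_2",
    "zest",
    "run_zest_surrogate",
    "generate_normative_database",
    "generate_vgb_field",
    "simulate_exam",
    "simulate_cohort",
    "Cohort",
]

#: Test-order protocols: each uses all three algorithms once across two
#: sessions separated by a rest, balancing fatigue across strategies.
PROTOCOLS = {
    "A": (("full_threshold",), ("sita_standard", "sita_fast")),
    "B": (("full_threshold",), ("sita_fast", "sita_standard")),
    "C": (("sita_standard", "sita_fast"), ("full_threshold",)),
    "D": (("sita_fast", "sita_standard"), ("full_threshold",)),
}

_ANALYSABLE = GRID_30_2.analysable_mask
_ECC = GRID_30_2.eccentricity


@dataclass(frozen=True)
class SimConfig:
    """Tunable parameters of the synthetic cohort, with units.

    Hill-of-vision and variability parameters describe the simulated
    normal population; the loss profile describes the vigabatrin pattern;
    observer and strategy parameters drive the response model and the
    thresholding algorithms.
    """

    # normal hill of vision
    hill_peak_db: float = 34.0          # sensitivity near fixation at ref age
    hill_ecc_slope: float = 0.28        # dB lost per degree of eccentricity
    age_slope_base: float = 0.55        # dB per decade at fixation
    age_slope_ecc: float = 0.010        # extra dB/decade per degree
    ref_age: float = 45.0
    subject_sd_db: float = 1.0          # between-subject general-height SD
    local_sd_base: float = 0.6          # between-subject per-location SD ...
    local_sd_ecc: float = 0.05          # ... growing with eccentricity (dB/deg)

    # vigabatrin loss profile: smooth sigmoid in eccentricity
    vgb_max_loss_db: float = 20.0
    vgb_onset_ecc: float = 19.0         # sigmoid midpoint (deg)
    vgb_width_ecc: float = 4.0          # sigmoid width (deg)
    nasal_weight: float = 1.5           # multiplier on the nasal (x < 0) half

    # observer (frequency-of-seeing) model
    fos_slope_base: float = 1.2         # psychometric SD (dB) at fixation
    fos_slope_ecc: float = 0.05         # relative growth per degree
    fos_slope_loss: float = 0.04        # relative growth per dB of loss
    resp_fp: float = 0.03               # press-without-seeing probability
    resp_fn: float = 0.03               # miss-despite-seeing probability

    # test-retest perturbation of true thresholds between visits
    retest_sd_base: float = 0.8         # dB at fixation
    retest_sd_ecc: float = 0.06         # relative growth per degree

    # strategy parameters
    zest_prior_normal_weight: float = 0.75
    zest_prior_normal_sd: float = 3.5   # dB, normal prior mode
    zest_prior_abnormal_mean: float = 4.0
    zest_prior_abnormal_sd: float = 8.0
    zest_likelihood_slope: float = 1.5  # dB
    zest_likelihood_lapse: float = 0.03
    zest_sd_stop_standard: float = 2.0  # posterior-SD stop tolerance (dB)
    zest_sd_stop_fast: float = 3.0
    zest_cap_standard: int = 6          # presentation cap per location
    zest_cap_fast: int = 5

    per_presentation_time_s: float = 2.0
    catch_trials_per_exam: int = 15
    fixation_loss_p: float = 0.04

    def fos_slope_at(self, ecc: np.ndarray, loss: np.ndarray) -> np.ndarray:
        """Effective psychometric slope: flatter FOS curves in the damaged
        periphery, the main driver of eccentricity-graded test-retest noise."""
        return self.fos_slope_base * (
            1.0 + self.fos_slope_ecc * ecc + self.fos_slope_loss * np.maximum(loss, 0)
        )

    def retest_sd_at(self, ecc: np.ndarray) -> np.ndarray:
        return self.retest_sd_base * (1.0 + self.retest_sd_ecc * ecc)

    def normal_mean(self, ecc: np.ndarray, age: float) -> np.ndarray:
        slope = self.age_slope_base + self.age_slope_ecc * ecc
        return (
            self.hill_peak_db
            - self.hill_ecc_slope * ecc
            - slope * (age - self.ref_age) / 10.0
        )

    def vgb_loss(self, severity: float, nasal_weight: float | None = None) -> np.ndarray:
        """Per-location dB loss of the vigabatrin pattern at a given severity."""
        if not 0.0 <= severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        nw = self.nasal_weight if nasal_weight is None else nasal_weight
        shape = 1.0 / (1.0 + np.exp(-(_ECC - self.vgb_onset_ecc) / self.vgb_width_ecc))
        side = np.where(GRID_30_2.x < 0, nw, 1.0)
        return self.vgb_max_loss_db * severity * shape * side


@dataclass(frozen=True)
class SimPatient:
    """Ground truth of one simulated observer."""

    patient_id: str
    age: float
    true_threshold: np.ndarray          # dB per grid location, [0, 40]
    severity: float                      # 0 = normal, 1 = maximal VGB loss
    clinical_diagnosis: str              # "vgb_loss" or "normal"
    resp_fp: float = 0.03
    resp_fn: float = 0.03
    protocol: str = "A"

    def __post_init__(self):
        t = np.asarray(self.true_threshold, dtype=float)
        if ((t < 0) | (t > 40)).any():
            raise ValueError("true thresholds must lie in [0, 40] dB")
        if not (0 <= self.resp_fp < 0.5 and 0 <= self.resp_fn < 0.5):
            raise ValueError("response error rates must lie in [0, 0.5)")
        object.__setattr__(self, "true_threshold", t)


@dataclass(frozen=True)
class TestResult:
    """Bookkeeping of one simulated exam."""

    estimates: np.ndarray
    presentations: np.ndarray
    total_presentations: int
    duration_s: float
    not_seen: np.ndarray                 # flags: never saw any stimulus


def fos_probability(
    stim: float, threshold: float, slope: float, resp_fp: float = 0.0,
    resp_fn: float = 0.0,
) -> float:
    """Probability the observer reports seeing a stimulus.

    ``stim`` and ``threshold`` are in dB of attenuation (larger = dimmer);
    the underlying psychometric function is a cumulative Gaussian in dB
    whose 50% point is the threshold, compressed by the response error
    rates: ``p = fp + (1 - fp - fn) * Phi((threshold - stim) / slope)``.
    """
    if slope <= 0:
        raise ValueError("FOS slope must be positive")
    return float(resp_fp + (1.0 - resp_fp - resp_fn) * ndtr((threshold - stim) / slope))


# ---------------------------------------------------------------------------
# 4-2 staircase (Full Threshold)
# ---------------------------------------------------------------------------

def staircase_4_2(
    respond: Callable[[float], bool],
    start: float,
    lo: float = 0.0,
    hi: float = 40.0,
    max_presentations: int = 30,
) -> tuple[float, int, bool]:
    """Run a 4-2 dB staircase against an arbitrary observer.

    Presents at ``start``; after "seen" the stimulus is dimmed (dB
    increased) by the current step, after "not seen" brightened.  The step
    is 4 dB until the first response reversal, then 2 dB; the run stops at
    the second reversal.  Returns ``(estimate, n_presentations, seen_any)``
    where the estimate is the last seen stimulus level, or ``lo`` with
    ``seen_any=False`` if nothing was ever seen.

    Edge policy: levels clamp to [lo, hi]; a second consecutive "not seen"
    at the floor terminates with estimate ``lo`` ("<0" in clinical
    output), and symmetrically two "seen" at the ceiling give ``hi``.
    """
    if not lo <= start <= hi:
        raise ValueError(f"start {start} outside [{lo}, {hi}]")
    level = float(start)
    step = 4.0
    reversals = 0
    last_seen: float | None = None
    prev_resp: bool | None = None
    n = 0
    at_edge_count = 0
    while n < max_presentations:
        seen = bool(respond(level))
        n += 1
        if seen:
            last_seen = level
        # edge termination: stuck at floor/ceiling with a confirming response
        if (level == lo and not seen) or (level == hi and seen):
            at_edge_count += 1
            if at_edge_count >= 2:
                break
        else:
            at_edge_count = 0
        if prev_resp is not None and seen != prev_resp:
            reversals += 1
            if reversals == 1:
                step = 2.0
            else:
                break
        prev_resp = seen
        level = min(max(level + (step if seen else -step), lo), hi)
    if last_seen is None:
        return lo, n, False
    return last_seen, n, True


# ---------------------------------------------------------------------------
# ZEST-style Bayesian surrogate (SITA Standard / Fast)
# ---------------------------------------------------------------------------

_DOMAIN = np.arange(0.0, 41.0)  # candidate thresholds, 1 dB steps


def _bimodal_prior(
    normal_mean: float, cfg: SimConfig
) -> np.ndarray:
    """Discrete bimodal prior: a normal-behaviour mode centred on the
    age-expected sensitivity plus a broad low-sensitivity abnormal mode."""
    wn = cfg.zest_prior_normal_weight
    pn = np.exp(-0.5 * ((_DOMAIN - normal_mean) / cfg.zest_prior_normal_sd) ** 2)
    pa = np.exp(
        -0.5 * ((_DOMAIN - cfg.zest_prior_abnormal_mean) / cfg.zest_prior_abnormal_sd) ** 2
    )
    prior = wn * pn / pn.sum() + (1.0 - wn) * pa / pa.sum()
    return prior / prior.sum()


def zest(
    respond: Callable[[float], bool],
    prior: np.ndarray,
    sd_stop: float,
    cap: int,
    cfg: SimConfig,
) -> tuple[float, int]:
    """Bayesian threshold estimation on the 0-40 dB domain.

    Each presentation is placed at the current posterior mean; the
    posterior is updated with a cumulative-Gaussian seen/not-seen
    likelihood; the run stops when the posterior SD drops below
    ``sd_stop`` or after ``cap`` presentations.  Returns the posterior
    mean (the 50%-seen point) and the presentation count.
    """
    post = np.asarray(prior, dtype=float)
    if post.shape != _DOMAIN.shape or post.sum() <= 0 or (post < 0).any():
        raise ValueError("prior must be a nonnegative distribution over 0..40 dB")
    post = post / post.sum()
    lapse = cfg.zest_likelihood_lapse
    slope = cfg.zest_likelihood_slope
    n = 0

    def _mean_sd(p):
        m = float(np.sum(_DOMAIN * p))
        v = float(np.sum((_DOMAIN - m) ** 2 * p))
        return m, np.sqrt(v)

    mean, sd = _mean_sd(post)
    while sd >= sd_stop and n < cap:
        stim = float(np.clip(np.round(mean), 0, 40))
        seen = bool(respond(stim))
        n += 1
        p_seen = lapse + (1 - 2 * lapse) * ndtr((_DOMAIN - stim) / slope)
        post = post * (p_seen if seen else (1.0 - p_seen))
        total = post.sum()
        if total <= 0:
            raise RuntimeError("posterior vanished; degenerate prior/likelihood")
        post = post / total
        mean, sd = _mean_sd(post)
    return float(np.clip(mean, 0, 40)), n


def _respond_fos(
    threshold: float, slope: float, resp_fp: float, resp_fn: float, rng: np.random.Generator
) -> Callable[[float], bool]:
    def respond(stim: float) -> bool:
        p = fos_probability(stim, threshold, slope, resp_fp, resp_fn)
        return bool(rng.random() < p)

    return respond


def run_staircase_4_2(
    patient: SimPatient,
    loc_index: int,
    start: float,
    rng: np.random.Generator,
    cfg: SimConfig | None = None,
    threshold: float | None = None,
) -> tuple[float, int, bool]:
    """Full Threshold estimation at one grid location for a stochastic
    observer; returns (estimate dB, presentations, seen_any)."""
    cfg = cfg or SimConfig()
    thr = patient.true_threshold[loc_index] if threshold is None else threshold
    loss = cfg.normal_mean(_ECC[loc_index], patient.age) - thr
    slope = float(cfg.fos_slope_at(_ECC[loc_index], np.asarray(loss)))
    respond = _respond_fos(thr, slope, patient.resp_fp, patient.resp_fn, rng)
    return staircase_4_2(respond, start)


def run_zest_surrogate(
    patient: SimPatient,
    loc_index: int,
    mode: str,
    model: NormativeModel,
    rng: np.random.Generator,
    cfg: SimConfig | None = None,
    threshold: float | None = None,
) -> tuple[float, int]:
    """SITA-surrogate estimation at one grid location (mode: standard/fast)."""
    cfg = cfg or SimConfig()
    if mode not in ("standard", "fast"):
        raise ValueError(f"mode must be 'standard' or 'fast', got {mode!r}")
    thr = patient.true_threshold[loc_index] if threshold is None else threshold
    loss = cfg.normal_mean(_ECC[loc_index], patient.age) - thr
    slope = float(cfg.fos_slope_at(_ECC[loc_index], np.asarray(loss)))
    respond = _respond_fos(thr, slope, patient.resp_fp, patient.resp_fn, rng)
    prior = _bimodal_prior(float(model.expected(patient.age)[loc_index]), cfg)
    if mode == "standard":
        return zest(respond, prior, cfg.zest_sd_stop_standard, cfg.zest_cap_standard, cfg)
    return zest(respond, prior, cfg.zest_sd_stop_fast, cfg.zest_cap_fast, cfg)


# ---------------------------------------------------------------------------
# Normative database
# ---------------------------------------------------------------------------

def _measure_normal_field(
    truth: np.ndarray, age: float, rng: np.random.Generator, cfg: SimConfig
) -> np.ndarray:
    """Measure a normal subject's true field with the 4-2 staircase.

    Used when building the normative database so that the deviation
    cutoffs absorb threshold-estimation error, exactly as clinical
    normative databases (built from measured exams) do.
    """
    slopes = cfg.fos_slope_at(_ECC, np.zeros_like(_ECC))
    expected = cfg.normal_mean(_ECC, age)
    out = np.empty(len(truth))
    for i, thr in enumerate(truth):
        respond = _respond_fos(float(thr), float(slopes[i]), cfg.resp_fp, cfg.resp_fn, rng)
        start = float(np.clip(np.round(expected[i]), 0, 40))
        out[i], _, _ = staircase_4_2(respond, start)
    return out


def generate_normative_database(
    n_subjects: int = 300,
    age_range: tuple[float, float] = (18.0, 80.0),
    seed: int = 0,
    cfg: SimConfig | None = None,
    measured: bool = True,
) -> NormativeModel:
    """Simulate a cohort of normal observers and fit a normative model.

    Each subject's true field is the age-dependent hill of vision plus a
    subject-level general-height offset and independent per-location
    deviations whose SD grows with eccentricity.  By default each true
    field is then *measured* with the 4-2 staircase and a stochastic
    observer, so the model describes what a perimeter reports for normal
    eyes, estimation error included — probability maps computed against it
    are calibrated for measured exams, the same reason clinical normative
    databases are built from measured fields (``measured=False`` fits the
    noise-free population instead).  Per location, sensitivity is
    regressed on age to give the reference-age mean and the decade slope;
    the regression residuals supply the SD and the empirical 5/2/1/0.5%
    total-deviation cutoffs, and pattern-deviation cutoffs are derived
    after removing each subject's general height.
    """
    if n_subjects < 50:
        raise ValueError("need at least 50 subjects for stable percentile cutoffs")
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_loc = len(GRID_30_2)

    ages = rng.uniform(age_range[0], age_range[1], size=n_subjects)
    offsets = rng.normal(0.0, cfg.subject_sd_db, size=n_subjects)
    local_sd = cfg.local_sd_base + cfg.local_sd_ecc * _ECC
    noise = rng.normal(0.0, 1.0, size=(n_subjects, n_loc)) * local_sd
    fields = (
        np.array([cfg.normal_mean(_ECC, a) for a in ages])
        + offsets[:, None]
        + noise
    )
    if measured:
        fields = np.clip(fields, 0.0, 40.0)
        fields = np.array(
            [
                _measure_normal_field(fields[k], ages[k], rng, cfg)
                for k in range(n_subjects)
            ]
        )

    # per-location linear fit: sensitivity ~ (age - ref)/10
    x = (ages - cfg.ref_age) / 10.0
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, fields, rcond=None)
    mean_normal = coef[0]
    age_slope = -coef[1]  # positive = decline with age

    fitted = design @ coef
    resid = fields - fitted
    sd_normal = resid.std(axis=0, ddof=2)

    td_cutoffs = {p: np.percentile(resid, p, axis=0) for p in PCTS}

    # pattern deviation of each simulated subject
    analys = resid[:, _ANALYSABLE]
    gh = np.sort(analys, axis=1)[:, -GH_RANK]
    pd_vals = resid - gh[:, None]
    pd_cutoffs = {p: np.percentile(pd_vals, p, axis=0) for p in PCTS}

    return NormativeModel(
        ref_age=cfg.ref_age,
        mean_normal=mean_normal,
        age_slope=age_slope,
        sd_normal=sd_normal,
        td_cutoffs=td_cutoffs,
        pd_cutoffs=pd_cutoffs,
        age_range=age_range,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Patients and cohorts
# ---------------------------------------------------------------------------

def generate_vgb_field(
    model: NormativeModel,
    age: float,
    severity: float,
    nasal_weight: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    cfg: SimConfig | None = None,
    patient_id: str = "sim",
) -> SimPatient:
    """Sample a ground-truth field with the vigabatrin loss pattern.

    At severity 0 this is a draw from the normal population; increasing
    severity subtracts a loss profile that is near zero inside ~17 degrees
    (central sparing), rises steeply through the middle zone and saturates
    in the far periphery, amplified on the nasal half.  Thresholds floor
    at 0 dB.

    Ground truth is sampled from the population generator (``cfg``), the
    same process the normative database subjects come from; the fitted
    ``model`` is accepted so the patient's age can be checked against its
    calibration range, but its estimated means are never used as truth.
    """
    cfg = cfg or SimConfig()
    lo, hi = model.age_range
    age = float(min(max(age, lo), hi))
    rng = np.random.default_rng(seed)
    local_sd = cfg.local_sd_base + cfg.local_sd_ecc * _ECC
    normal = (
        cfg.normal_mean(_ECC, age)
        + rng.normal(0.0, cfg.subject_sd_db)
        + rng.normal(0.0, 1.0, size=len(GRID_30_2)) * local_sd
    )
    truth = np.clip(normal - cfg.vgb_loss(severity, nasal_weight), 0.0, 40.0)
    return SimPatient(
        patient_id=patient_id,
        age=age,
        true_threshold=truth,
        severity=severity,
        clinical_diagnosis="vgb_loss" if severity > 0 else "normal",
        resp_fp=cfg.resp_fp,
        resp_fn=cfg.resp_fn,
    )


def simulate_exam(
    patient: SimPatient,
    algorithm: str,
    model: NormativeModel,
    rng: np.random.Generator,
    cfg: SimConfig | None = None,
    visit: int = 3,
    thresholds: np.ndarray | None = None,
) -> tuple[VisualField, TestResult]:
    """Run one full exam: the chosen strategy at all 74 analysable points.

    Start values (staircase) and prior centres (ZEST) are seeded from the
    age-expected normal sensitivities.  Exam duration is presentation
    count (stimuli plus catch trials) times the per-presentation time;
    catch-trial rates are simulated from the patient's response error
    probabilities.
    """
    cfg = cfg or SimConfig()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    thr = patient.true_threshold if thresholds is None else np.asarray(thresholds)
    # Staircase starts must follow the same policy as the exams the
    # normative cutoffs were calibrated from (see _measure_normal_field):
    # 4-2 estimates live on a lattice anchored at the start value, so a
    # different start offset shifts the discrete estimate distribution
    # relative to the per-location percentile cutoffs and miscalibrates
    # the probability maps.
    start_expected = cfg.normal_mean(_ECC, patient.age)

    estimates = np.full(len(GRID_30_2), np.nan)
    presentations = np.zeros(len(GRID_30_2), dtype=int)
    not_seen = np.zeros(len(GRID_30_2), dtype=bool)
    for i in np.flatnonzero(_ANALYSABLE):
        if algorithm == "full_threshold":
            start = float(np.clip(np.round(start_expected[i]), 0, 40))
            est, n, seen_any = run_staircase_4_2(
                patient, i, start, rng, cfg, threshold=float(thr[i])
            )
            not_seen[i] = not seen_any
        else:
            mode = "standard" if algorithm == "sita_standard" else "fast"
            est, n = run_zest_surrogate(
                patient, i, mode, model, rng, cfg, threshold=float(thr[i])
            )
        estimates[i] = est
        presentations[i] = n

    # catch trials: false-positive (blank) and false-negative (suprathreshold)
    n_catch = cfg.catch_trials_per_exam
    fp_hits = int(rng.binomial(n_catch, patient.resp_fp))
    fn_hits = int(rng.binomial(n_catch, patient.resp_fn))
    fl_hits = int(rng.binomial(n_catch, cfg.fixation_loss_p))
    total = int(presentations.sum()) + 3 * n_catch
    duration = total * cfg.per_presentation_time_s

    vf = VisualField(
        patient_id=patient.patient_id,
        algorithm=algorithm,
        visit=visit,
        eye="right",
        sensitivities=estimates,
        duration_s=duration,
        catch_trials=CatchTrials(
            fp_pct=100.0 * fp_hits / n_catch,
            fn_pct=100.0 * fn_hits / n_catch,
            fixation_loss_pct=100.0 * fl_hits / n_catch,
        ),
        age=patient.age,
    )
    result = TestResult(
        estimates=estimates,
        presentations=presentations,
        total_presentations=total,
        duration_s=duration,
        not_seen=not_seen,
    )
    return vf, result


@dataclass(frozen=True)
class Cohort:
    """A simulated study cohort: patients plus all their exams."""

    patients: tuple[SimPatient, ...]
    fields: tuple[VisualField, ...]
    results: tuple[TestResult, ...]
    seed: int
    config: SimConfig = dc_field(default_factory=SimConfig)

    def fields_for(self, algorithm: str | None = None, visit: int | None = None):
        out = self.fields
        if algorithm is not None:
            out = tuple(f for f in out if f.algorithm == algorithm)
        if visit is not None:
            out = tuple(f for f in out if f.visit == visit)
        return out


def simulate_cohort(
    n: int = 16,
    prevalence: float = 6 / 16,
    seed: int = 0,
    model: NormativeModel | None = None,
    cfg: SimConfig | None = None,
    mean_age: float = 39.3,
    sd_age: float = 14.5,
) -> Cohort:
    """Simulate a full study cohort: n patients x 2 visits x 3 algorithms.

    A fraction ``prevalence`` of patients carry vigabatrin-pattern loss
    with severities drawn uniformly from [0.3, 1]; the rest are normal.
    Test-order protocols A-D are assigned round-robin after a seeded
    shuffle.  Visits 2 and 3 use independently perturbed true thresholds
    (zero-mean jitter growing with eccentricity) and independent response
    noise.  Fully determined by ``seed``.
    """
    if n < 4:
        raise ValueError("cohort needs at least 4 patients (one per protocol)")
    cfg = cfg or SimConfig()
    root = np.random.SeedSequence(seed)
    ss_model, ss_patients, ss_assign = root.spawn(3)
    if model is None:
        model = generate_normative_database(seed=seed, cfg=cfg)

    assign_rng = np.random.default_rng(ss_assign)
    order = assign_rng.permutation(n)
    protocols = [None] * n
    labels = sorted(PROTOCOLS)
    for slot, patient_idx in enumerate(order):
        protocols[patient_idx] = labels[slot % 4]

    n_diseased = int(round(n * prevalence))
    diseased = set(assign_rng.permutation(n)[:n_diseased].tolist())

    lo, hi = model.age_range
    patients = []
    fields: list[VisualField] = []
    results: list[TestResult] = []
    for i, ss_p in enumerate(ss_patients.spawn(n)):
        ss_truth, ss_sev, ss_v2, ss_v3 = ss_p.spawn(4)
        prng = np.random.default_rng(ss_sev)
        age = float(np.clip(prng.normal(mean_age, sd_age), lo, hi))
        severity = float(prng.uniform(0.3, 1.0)) if i in diseased else 0.0
        patient = replace(
            generate_vgb_field(
                model, age, severity, seed=ss_truth, cfg=cfg,
                patient_id=f"P{i + 1:02d}",
            ),
            protocol=protocols[i],
        )
        patients.append(patient)

        for visit, ss_v in ((2, ss_v2), (3, ss_v3)):
            vrng = np.random.default_rng(ss_v)
            jitter = vrng.normal(0.0, 1.0, len(GRID_30_2)) * cfg.retest_sd_at(_ECC)
            thr = np.clip(patient.true_threshold + jitter, 0.0, 40.0)
            first, second = PROTOCOLS[patient.protocol]
            for alg in (*first, *second):
                vf, res = simulate_exam(
                    patient, alg, model, vrng, cfg, visit=visit, thresholds=thr
                )
                fields.append(vf)
                results.append(res)

    return Cohort(
        patients=tuple(patients),
        fields=tuple(fields),
        results=tuple(results),
        seed=seed,
        config=cfg,
    )
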