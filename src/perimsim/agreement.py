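"""Agreement statistics for comparing perimetric threshold strategies.

Implements the comparison battery used to judge whether two threshold
algorithms map the same field loss:

* pointwise **RMSE** between two exams of the same eye, whole-field or
  restricted to an eccentricity zone, with group summaries and 95% CIs;
* **dissimilarity percentage** — the share of locations whose
  defective/normal status differs between two probability maps
  (defect-area agreement);
* **depth aggregate** — the sum of per-location significance levels
  (0..4), a scalar measure of defect depth;
* a **reliability filter** on catch-trial rates;
* **severity classification** from a configurable, ordered rule table on
  counts of deeply abnormal locations per zone;
* **diagnostic false-positive / false-negative rates** of a strategy
  against a gold-standard classification;
* **cohort summaries** of global indices and exam durations.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .field import VisualField
from .grid import GRID_30_2, Zone
from .normative import Category, ProbabilityMap

__all__ = [
    "SEVERITY_ORDER",
    "DEFAULT_SEVERITY_RULES",
    "DiagnosticRates",
    "rmse",
    "rmse_group_summary",
    "dissimilarity_percent",
    "depth_aggregate",
    "reliability_filter",
    "classify_severity",
    "validate_severity_rules",
    "diagnostic_rates",
    "cohort_summary",
]

SEVERITY_ORDER = ("Nil", "Mild", "Moderate", "Severe")

#: Ordered severity rule table (first match wins; no match = Nil).
#: A "defective" location is one at or beyond the defect level
#: (default p < 1%).  This table is a documented stand-in for the
#: published clinical criteria, which are not reproduced here; it is plain
#: data so the true criteria can be dropped in from a config file.
DEFAULT_SEVERITY_RULES: list[dict] = [
    {"label": "Severe", "zones_involved": ["outer", "middle", "inner"]},
    {"label": "Severe", "min_total": 20},
    {"label": "Moderate", "min_by_zone": {"outer": 2, "middle": 2}},
    {"label": "Mild", "min_total": 2},
]

_RULE_KEYS = {"label", "min_total", "min_by_zone", "zones_involved"}


def _zone_selector(zone: str | Zone) -> np.ndarray:
    if zone in ("whole", None):
        return GRID_30_2.analysable_mask
    z = Zone(zone)
    if z is Zone.EXCLUDED:
        raise ValueError("cannot compute metrics over the excluded zone")
    return GRID_30_2.zone_mask(z)


def rmse(field_a: VisualField, field_b: VisualField, zone: str = "whole") -> float:
    """Root mean square error (dB) between two exams over a zone.

    Both fields must be in right-eye format; the blind-spot-adjacent pair
    never contributes.
    """
    for f in (field_a, field_b):
        if f.eye != "right":
            raise ValueError("RMSE requires right-eye format; mirror first")
    sel = _zone_selector(zone)
    if not sel.any():
        raise ValueError(f"zone {zone!r} selects no locations")
    d = field_a.sensitivities[sel] - field_b.sensitivities[sel]
    return float(np.sqrt(np.mean(d**2)))


def rmse_group_summary(
    fields: Iterable[VisualField],
    algorithm: str,
    zone: str = "whole",
    ci: str = "normal",
) -> dict:
    """Test-retest RMSE of one algorithm across visits 2 and 3, summarised.

    Computes each patient's RMSE between their visit-2 and visit-3 exams
    with ``algorithm``, then the group mean and a 95% confidence interval
    (``ci='normal'``: mean +/- 1.96 SD/sqrt(n); ``ci='t'``: Student-t
    quantile instead of 1.96).
    """
    by_patient: dict[str, dict[int, VisualField]] = defaultdict(dict)
    for f in fields:
        if f.algorithm == algorithm:
            by_patient[f.patient_id][f.visit] = f
    per_patient = {
        pid: rmse(v[2], v[3], zone)
        for pid, v in sorted(by_patient.items())
        if 2 in v and 3 in v
    }
    vals = np.array(list(per_patient.values()))
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 patients with both visits")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if ci == "normal":
        q = 1.959963984540054
    elif ci == "t":
        from scipy import stats

        q = float(stats.t.ppf(0.975, n - 1))
    else:
        raise ValueError(f"unknown CI method {ci!r}")
    half = q * sd / np.sqrt(n)
    return {
        "algorithm": algorithm,
        "zone": zone,
        "n": n,
        "mean": mean,
        "sd": sd,
        "ci95": (mean - half, mean + half),
        "ci_method": ci,
        "per_patient": per_patient,
    }


def dissimilarity_percent(
    map_a: ProbabilityMap,
    map_b: ProbabilityMap,
    defect_level: Category = Category.P5,
) -> float:
    """Percentage of locations with non-overlapping defect status.

    A location is *defective* when its category is at or beyond
    ``defect_level`` (default: any significant deviation, p <= 5%).  The
    result is the count of locations defective in exactly one of the two
    maps, as a percentage of the 74 analysable locations.
    """
    if map_a.basis != map_b.basis:
        raise ValueError(
            f"probability-map bases differ: {map_a.basis!r} vs {map_b.basis!r}"
        )
    a = map_a.analysable >= int(defect_level)
    b = map_b.analysable >= int(defect_level)
    return float(100.0 * np.sum(a != b) / len(a))


def depth_aggregate(pmap: ProbabilityMap) -> int:
    """Sum of significance levels over the field (NS=0 ... p<0.5% = 4).

    A scalar depth score: 0 for an entirely normal map, 296 (4 x 74) at
    the deepest possible loss.
    """
    return int(pmap.analysable.sum())


def reliability_filter(
    fp_pct: float, fn_pct: float, fixation_loss_pct: float
) -> tuple[bool, list[str]]:
    """Apply the exam reliability criteria; returns (passed, reasons).

    Criteria: false positives strictly below 33%, false negatives at most
    33%, fixation losses at most 20%.  The fixation-loss bound is taken as
    inclusive.
    """
    rates = {"fp": fp_pct, "fn": fn_pct, "fixation_loss": fixation_loss_pct}
    for name, r in rates.items():
        if r < 0:
            raise ValueError(f"negative {name} rate: {r}")
    reasons = []
    if not fp_pct < 33:
        reasons.append(f"false positives {fp_pct}% (must be < 33%)")
    if not fn_pct <= 33:
        reasons.append(f"false negatives {fn_pct}% (must be <= 33%)")
    if not fixation_loss_pct <= 20:
        reasons.append(f"fixation losses {fixation_loss_pct}% (must be <= 20%)")
    return (not reasons, reasons)


def validate_severity_rules(rules: Sequence[Mapping]) -> None:
    """Check a severity rule table; raises ValueError on malformed rules."""
    if not rules:
        raise ValueError("empty severity rule table")
    for i, rule in enumerate(rules):
        keys = set(rule)
        if "label" not in keys:
            raise ValueError(f"rule {i} has no label")
        if rule["label"] not in SEVERITY_ORDER:
            raise ValueError(f"rule {i}: unknown label {rule['label']!r}")
        unknown = keys - _RULE_KEYS
        if unknown:
            raise ValueError(f"rule {i}: unknown keys {sorted(unknown)}")
        if keys == {"label"}:
            raise ValueError(f"rule {i} has no condition")


def classify_severity(
    pmap: ProbabilityMap,
    rules: Sequence[Mapping] | None = None,
    defect_level: Category = Category.P1,
) -> str:
    """Classify defect severity from counts of deeply abnormal locations.

    A location counts as defective when its probability category is at or
    beyond ``defect_level`` (default p < 1%, i.e. the p < 1% and p < 0.5%
    levels).  The ordered rule table is scanned top-down; the first rule
    whose conditions all hold gives the label, and a map matching no rule
    is Nil.  Rule conditions:

    ``min_total``      — at least this many defective locations in all;
    ``min_by_zone``    — at least the given count in each named zone;
    ``zones_involved`` — at least one defective location in each named zone.
    """
    if rules is None:
        rules = DEFAULT_SEVERITY_RULES
    validate_severity_rules(rules)
    defect = pmap.categories >= int(defect_level)
    defect &= GRID_30_2.analysable_mask
    by_zone = {
        z: int(np.sum(defect & GRID_30_2.zone_mask(z)))
        for z in ("inner", "middle", "outer")
    }
    total = int(defect.sum())
    for rule in rules:
        ok = True
        if "min_total" in rule and total < rule["min_total"]:
            ok = False
        if ok and "min_by_zone" in rule:
            ok = all(by_zone[z] >= k for z, k in rule["min_by_zone"].items())
        if ok and "zones_involved" in rule:
            ok = all(by_zone[z] >= 1 for z in rule["zones_involved"])
        if ok:
            return rule["label"]
    return "Nil"


@dataclass(frozen=True)
class DiagnosticRates:
    """FP/FN rates of a strategy's classification against a gold standard.

    ``fp_rate``: proportion of gold-normal patients called diseased;
    ``fn_rate``: proportion of gold-diseased patients called normal.
    A rate with an empty denominator is ``None`` (undefined), never 0.
    """

    fp_rate: float | None
    fn_rate: float | None
    n_gold_negative: int
    n_gold_positive: int


def diagnostic_rates(
    pred: Mapping[str, str], gold: Mapping[str, str]
) -> DiagnosticRates:
    """Score predicted severity labels against gold-standard labels.

    A patient is *diseased* when their label is anything but Nil.  Both
    mappings must cover the same patients.
    """
    if set(pred) != set(gold):
        raise ValueError("prediction and gold standard cover different patients")
    gold_pos = [p for p in gold if gold[p] != "Nil"]
    gold_neg = [p for p in gold if gold[p] == "Nil"]
    fp = sum(1 for p in gold_neg if pred[p] != "Nil")
    fn = sum(1 for p in gold_pos if pred[p] == "Nil")
    return DiagnosticRates(
        fp_rate=fp / len(gold_neg) if gold_neg else None,
        fn_rate=fn / len(gold_pos) if gold_pos else None,
        n_gold_negative=len(gold_neg),
        n_gold_positive=len(gold_pos),
    )


def cohort_summary(exams: pd.DataFrame) -> dict:
    """Group summary of global indices and durations, per algorithm.

    ``exams`` is tidy, one row per exam, with columns ``patient_id``,
    ``algorithm``, ``visit``, ``MS``, ``MD``, ``PSD``, ``duration_s``.

    Returns per-algorithm, per-visit means and SDs of the indices, the
    across-visit mean exam duration in minutes (1 dp), the visit-3 MS
    difference of each SITA strategy relative to Full Threshold (2 dp) and
    the MD pooled over the three algorithms at visit 3 (2 dp).  A group of
    one exam reports SD 0 with an ``sd_undefined`` flag.
    """
    required = {"patient_id", "algorithm", "visit", "MS", "MD", "PSD", "duration_s"}
    missing = required - set(exams.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    def _mean_sd(s: pd.Series) -> dict:
        if len(s) < 2:
            return {"mean": float(s.mean()), "sd": 0.0, "sd_undefined": True}
        return {"mean": float(s.mean()), "sd": float(s.std(ddof=1))}

    indices: dict = {}
    for (alg, visit), g in exams.groupby(["algorithm", "visit"]):
        indices.setdefault(alg, {})[int(visit)] = {
            k: _mean_sd(g[k]) for k in ("MS", "MD", "PSD", "duration_s")
        }

    duration_min = {
        alg: round(float(g["duration_s"].mean()) / 60.0, 1)
        for alg, g in exams.groupby("algorithm")
    }

    v3 = exams[exams["visit"] == 3]
    ms_v3 = v3.groupby("algorithm")["MS"].mean()
    ms_delta = {}
    if "full_threshold" in ms_v3.index:
        for alg in ms_v3.index:
            if alg != "full_threshold":
                ms_delta[alg] = round(float(ms_v3[alg] - ms_v3["full_threshold"]), 2)

    md_v3 = v3.groupby("algorithm")["MD"].mean()
    pooled_md_v3 = round(float(md_v3.mean()), 2) if len(md_v3) else None

    return {
        "indices": indices,
        "duration_min": duration_min,
        "ms_delta_visit3_vs_full_threshold": ms_delta,
        "pooled_md_visit3": pooled_md_v3,
    }
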