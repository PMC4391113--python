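"""End-to-end analysis flows over a cohort of exams.

These functions mirror how the study data were analysed: every exam is
normalised to right-eye format with the blind-spot pair excluded, reduced
to deviation and probability maps against a normative model, and then the
cohort is compared across strategies (test-retest RMSE by zone,
defect-area dissimilarity, defect-depth aggregates, severity labels and
diagnostic rates against the Full Threshold gold standard).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import agreement
from .field import ALGORITHMS, VisualField, exclude_blind_spot, mirror_left_to_right
from .normative import (
    Category,
    NormativeModel,
    ProbabilityMap,
    general_height,
    global_indices,
    pattern_deviation,
    probability_map,
    total_deviation,
)

__all__ = ["prepare_field", "analyze_field", "analyze_cohort", "compare_cohort"]


def prepare_field(field: VisualField) -> VisualField:
    """Normalise an exam for analysis: right-eye format, blind spot out."""
    if field.eye == "left":
        field = mirror_left_to_right(field)
    return exclude_blind_spot(field)


def analyze_field(field: VisualField, model: NormativeModel, age: float | None = None):
    """Full single-field analysis; returns a dict of maps and indices."""
    field = prepare_field(field)
    if age is None:
        age = field.age
    if age is None:
        raise ValueError("patient age is required for normative analysis")
    td = total_deviation(field, model, age)
    gh = general_height(td)
    pd_map = pattern_deviation(td, gh)
    return {
        "field": field,
        "td": td,
        "gh": gh,
        "pd": pd_map,
        "td_prob": probability_map(td, model, "total_deviation"),
        "pd_prob": probability_map(pd_map, model, "pattern_deviation"),
        "indices": global_indices(field, model, age),
    }


def analyze_cohort(
    fields: Iterable[VisualField], model: NormativeModel
) -> tuple[pd.DataFrame, dict]:
    """Analyse every exam; returns (per-exam index table, per-exam maps).

    The table has one row per exam (patient_id, algorithm, visit, MS, MD,
    PSD, duration_s, plus TD/PD depth aggregates); the map dict is keyed
    by (patient_id, algorithm, visit).
    """
    rows = []
    maps: dict[tuple, dict] = {}
    for f in fields:
        res = analyze_field(f, model)
        key = (f.patient_id, f.algorithm, f.visit)
        maps[key] = res
        idx = res["indices"]
        rows.append(
            {
                "patient_id": f.patient_id,
                "algorithm": f.algorithm,
                "visit": f.visit,
                "MS": idx.MS,
                "MD": idx.MD,
                "PSD": idx.PSD,
                "duration_s": f.duration_s,
                "td_aggregate": agreement.depth_aggregate(res["td_prob"]),
                "pd_aggregate": agreement.depth_aggregate(res["pd_prob"]),
            }
        )
    return pd.DataFrame(rows), maps


def compare_cohort(
    fields: Sequence[VisualField],
    model: NormativeModel,
    gold: str = "full_threshold",
    rules: Sequence[Mapping] | None = None,
    defect_level: Category = Category.P1,
    basis: str = "total_deviation",
    dissimilarity_level: Category = Category.P5,
) -> dict:
    """The study's comparison battery over an analysed cohort.

    Severity is classified from the visit-3 probability maps of each
    algorithm (``basis`` selects total or pattern deviation) and the SITA
    surrogates are scored against the ``gold`` algorithm's labels.
    """
    fields = [prepare_field(f) for f in fields]
    table, maps = analyze_cohort(fields, model)
    prob_key = "td_prob" if basis == "total_deviation" else "pd_prob"

    patients = sorted({f.patient_id for f in fields})
    algorithms = [a for a in ALGORITHMS if any(f.algorithm == a for f in fields)]

    # test-retest RMSE per algorithm and zone
    rmse_summary = {
        alg: {
            zone: agreement.rmse_group_summary(fields, alg, zone)
            for zone in ("whole", "outer", "middle", "inner")
        }
        for alg in algorithms
    }

    def _pmap(pid, alg, visit) -> ProbabilityMap:
        return maps[(pid, alg, visit)][prob_key]

    # defect-area dissimilarity: between algorithms at visit 3,
    # and within each algorithm between visits 2 and 3
    between = {}
    for i, a in enumerate(algorithms):
        for b in algorithms[i + 1:]:
            vals = [
                agreement.dissimilarity_percent(
                    _pmap(p, a, 3), _pmap(p, b, 3), dissimilarity_level
                )
                for p in patients
            ]
            s = pd.Series(vals)
            between[f"{a}-{b}"] = {"mean": float(s.mean()), "sd": float(s.std(ddof=1))}
    within = {}
    for a in algorithms:
        vals = [
            agreement.dissimilarity_percent(
                _pmap(p, a, 2), _pmap(p, a, 3), dissimilarity_level
            )
            for p in patients
        ]
        s = pd.Series(vals)
        within[a] = {"mean": float(s.mean()), "sd": float(s.std(ddof=1))}

    # severity and diagnostic rates at the final visit
    labels = {
        alg: {
            p: agreement.classify_severity(_pmap(p, alg, 3), rules, defect_level)
            for p in patients
        }
        for alg in algorithms
    }
    rates = {
        alg: agreement.diagnostic_rates(labels[alg], labels[gold])
        for alg in algorithms
        if alg != gold
    }

    return {
        "table": table,
        "maps": maps,
        "summary": agreement.cohort_summary(table),
        "rmse": rmse_summary,
        "dissimilarity_between_v3": between,
        "dissimilarity_within": within,
        "severity_labels": labels,
        "diagnostic_rates": rates,
        "basis": basis,
    }
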