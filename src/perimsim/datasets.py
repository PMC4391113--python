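"""Bundled reference data from a published 16-patient vigabatrin cohort.

Two small tables accompany the package so the worked examples and the
diagnostic-rate calculations can run without transcription:

* per-patient defect severity classifications under each of the three
  threshold strategies (Full Threshold is the gold standard);
* group means and SDs of the global indices (MS, MD, PSD) and exam
  durations per strategy and visit.

These are observed clinical results, not simulator output.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_severity_labels",
    "reference_severity_by_algorithm",
    "reference_group_indices",
    "reference_group_exam_rows",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("perimsim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def reference_severity_labels() -> pd.DataFrame:
    """Severity labels (Nil/Mild/Moderate/Severe) per patient x algorithm."""
    return _read("severity_labels.csv")


def reference_severity_by_algorithm(algorithm: str) -> dict[str, str]:
    """Severity labels of one algorithm as a patient -> label mapping."""
    df = reference_severity_labels()
    if algorithm not in df.columns:
        raise KeyError(f"no labels for algorithm {algorithm!r}")
    return dict(zip(df["patient"].astype(str), df[algorithm]))


def reference_group_indices() -> pd.DataFrame:
    """Tidy group means/SDs: algorithm, visit, index, mean, sd."""
    return _read("group_indices.csv")


def reference_group_exam_rows() -> pd.DataFrame:
    """The group means reshaped as one exam-like row per algorithm x visit.

    Feeding group means through :func:`perimsim.agreement.cohort_summary`
    reproduces the published headline numbers (mean durations in minutes,
    visit-3 MS deltas, pooled visit-3 MD) because those are linear in the
    group means.
    """
    df = reference_group_indices()
    wide = df.pivot_table(
        index=["algorithm", "visit"], columns="index", values="mean"
    ).reset_index()
    wide.columns.name = None
    wide["patient_id"] = "group_mean"
    return wide[["patient_id", "algorithm", "visit", "MS", "MD", "PSD", "duration_s"]]
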