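"""Exact arithmetic on the bundled reference tables.

The package ships two small reference tables describing a 16-patient
strategy-comparison study: per-patient severity labels under each
algorithm, and group-level index summaries (MS, MD, PSD, duration) per
algorithm and visit. The agreement functions reproduce that study's
headline numbers exactly - a useful exact check that the arithmetic
(rate denominators, pooling, rounding) is right.

Run: python examples/04_reference_tables.py
"""

import perimsim as ps
from perimsim.datasets import (
    reference_group_exam_rows,
    reference_severity_by_algorithm,
    reference_severity_labels,
)

labels = reference_severity_labels()
print(labels.to_string(index=False))

gold = reference_severity_by_algorithm("full_threshold")
prevalence = sum(1 for v in gold.values() if v != "Nil") / len(gold)
print(f"\ndefect prevalence under Full Threshold: {100 * prevalence:.0f}%")

for alg in ("sita_standard", "sita_fast"):
    r = ps.diagnostic_rates(reference_severity_by_algorithm(alg), gold)
    print(
        f"{alg:15s}: FP {100 * r.fp_rate:.0f}% ({r.n_gold_negative} gold-normal), "
        f"FN {100 * r.fn_rate:.0f}% ({r.n_gold_positive} gold-diseased)"
    )

s = ps.cohort_summary(reference_group_exam_rows())
print("\nmean exam duration (min):", s["duration_min"])
print("visit-3 MS gain over Full Threshold (dB):",
      s["ms_delta_visit3_vs_full_threshold"])
print("pooled visit-3 MD across algorithms (dB):", s["pooled_md_visit3"])
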