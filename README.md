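# perimsim

Simulation and agreement analysis of automated perimetry thresholding
strategies on the 30-2 visual field grid.

## The problem

Automated static perimetry estimates light-sensitivity thresholds (in dB)
at a fixed grid of retinal locations. The classic Full Threshold strategy
(a 4-2 dB staircase at every point) is accurate but slow — around 15
minutes per eye — which matters for patients who tire easily and for
screening programmes that test often. Faster Bayesian strategies (SITA
Standard, SITA Fast) cut exam time by half to two-thirds, but they are not
interchangeable with Full Threshold: they return slightly higher
sensitivities and their errors are distributed differently across the
field. Whether that trade-off is acceptable depends on the disease being
monitored. For drug-induced peripheral field loss — the motivating case is
vigabatrin-attributed constriction, which starts nasally and peripherally
and spares the centre — the periphery is exactly where the strategies
disagree most, so the question "would the fast test have caught this
defect?" needs a quantitative answer.

`perimsim` provides the pieces needed to study that question end to end,
with no external data:

* **Grid geometry** — the 76-point 30-2 pattern, blind-spot exclusion, and
  the inner / middle / outer eccentricity zones used for all zonal
  statistics (`perimsim.grid`).
* **Normative analysis** — a Statpac-style single-field analysis: total
  deviation, general height, pattern deviation, empirical probability maps
  (p < 5/2/1/0.5%), global indices (MS, MD, PSD) and grey-scale rendering
  (`perimsim.normative`, `perimsim.render`).
* **Agreement metrics** — zonal RMSE between exams, probability-map
  dissimilarity, defect-depth aggregates, reliability filtering, a
  rule-based severity classification, false-positive / false-negative
  diagnostic rates against a gold standard, and cohort-level summaries
  (`perimsim.agreement`).
* **Simulation** — a simulated normative database, ground-truth fields with
  the vigabatrin loss pattern, frequency-of-seeing observers, the 4-2
  staircase, a ZEST-style surrogate for the two SITA strategies, and full
  multi-visit cohort simulation, all driven by one explicit seed
  (`perimsim.sim`).
* **Files and CLI** — a plain CSV exam format with JSON sidecars, cohort
  manifests, config files, and a `perimsim` command with `simulate`,
  `analyze`, `compare` and `report` subcommands (`perimsim.io`,
  `perimsim.cli`).

The package also bundles two small reference tables (per-patient severity
labels and group index summaries from a 16-patient three-strategy study)
whose headline numbers the agreement functions reproduce exactly; they
serve as fixed, human-checkable test vectors.

## Quick start

```python
import numpy as np
import perimsim as ps
from perimsim import pipeline

model = ps.generate_normative_database(n_subjects=300, seed=11)
patient = ps.generate_vgb_field(model, age=36.0, severity=0.8, seed=11)
field, result = ps.simulate_exam(
    patient, "full_threshold", model, np.random.default_rng(11)
)

res = pipeline.analyze_field(field, model)
gi = res["indices"]
print(f"MS {gi.MS:.2f}  MD {gi.MD:.2f}  PSD {gi.PSD:.2f}")
print("severity:", ps.classify_severity(res["td_prob"]))
```

prints

```
MS 18.95  MD -8.03  PSD 6.69
severity: Severe
```

A whole study in three lines:

```python
cohort = ps.simulate_cohort(n=16, prevalence=6/16, seed=1, model=model)
res = pipeline.compare_cohort(list(cohort.fields), model)
print(res["summary"]["duration_min"])
```

The scripts in `examples/` walk through each capability with commentary:
grid geometry, single-field analysis, a full strategy-comparison study,
the bundled reference tables, and the file formats / CLI.

From the shell:

```sh
perimsim simulate --seed 7 --out study/
perimsim analyze  --in study/
perimsim compare  --in study/        # RMSE, dissimilarity, FP/FN rates
perimsim report   --in study/ --out study/report/
```

## Testing and reproduction

```sh
python -m pytest            # full suite, a few seconds
```

`scripts/acceptance.py` recomputes the headline quantities from scratch —
grid geometry, the exact reference-table arithmetic, and the statistical
properties of a freshly simulated study (threshold-recovery bias,
duration and sensitivity orderings across strategies, zonal test-retest
RMSE, false-flag calibration on simulated normals):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each emitted quantity carries its sample size. The geometry and
reference-table entries are seed-independent; the simulation entries are
deterministic given `--seed`.

## Layout

```
src/perimsim/       library (grid, field, normative, agreement, sim, io, cli, pipeline)
src/perimsim/data/  bundled reference tables (CSV)
examples/           narrative example scripts
scripts/            acceptance.py
tests/              pytest suite (unit + acceptance)
docs/methods.md     model description, parameters, design rationale
```
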