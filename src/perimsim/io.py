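"""File formats: field CSV + sidecar metadata, cohorts, configs, rules.

A field file is a CSV with one row per tested location::

    patient_id,algorithm,visit,eye,x_deg,y_deg,sensitivity_db

accompanied by a sidecar JSON (same stem, ``.json``) carrying exam
metadata (duration_s, fp_pct, fn_pct, fl_pct, age).  Left-eye fields are
stored exactly as recorded and converted to right-eye format only when
they enter analysis.  Sensitivities are written with two decimals, so a
canonical file round-trips byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .agreement import validate_severity_rules
from .field import ALGORITHMS, CatchTrials, VisualField
from .grid import GRID_30_2, BLIND_SPOT_ADJACENT
from .sim import Cohort, SimConfig

__all__ = [
    "FieldParseError",
    "read_field",
    "write_field",
    "write_cohort",
    "read_cohort_fields",
    "load_severity_rules",
    "RunConfig",
]

_HEADER = "patient_id,algorithm,visit,eye,x_deg,y_deg,sensitivity_db"


class FieldParseError(ValueError):
    """A field file failed validation; the message names the offending line."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_field(field: VisualField, path) -> Path:
    """Write one exam as CSV + sidecar JSON; returns the CSV path."""
    path = Path(path)
    lines = [_HEADER]
    for i, p in enumerate(GRID_30_2):
        s = field.sensitivities[i]
        if not np.isfinite(s):
            continue  # excluded location without a measurement
        lines.append(
            f"{field.patient_id},{field.algorithm},{field.visit},{field.eye},"
            f"{p.x:g},{p.y:g},{s:.2f}"
        )
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "duration_s": field.duration_s,
        "fp_pct": field.catch_trials.fp_pct,
        "fn_pct": field.catch_trials.fn_pct,
        "fl_pct": field.catch_trials.fixation_loss_pct,
        "age": field.age,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_field(path) -> VisualField:
    """Read one exam; raises :class:`FieldParseError` with line numbers."""
    path = Path(path)
    text = path.read_text().splitlines()
    if not text or text[0].strip() != _HEADER:
        raise FieldParseError(
            f"{path}:1: expected header {_HEADER!r}, got {text[0]!r}"
            if text
            else f"{path}: empty file"
        )
    sens = np.full(len(GRID_30_2), np.nan)
    meta: dict = {}
    seen_coords = set()
    for ln, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise FieldParseError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
        pid, alg, visit, eye, xs, ys, ss = parts
        if alg not in ALGORITHMS:
            raise FieldParseError(f"{path}:{ln}: unknown algorithm {alg!r}")
        try:
            x, y, s = float(xs), float(ys), float(ss)
            visit_i = int(visit)
        except ValueError as e:
            raise FieldParseError(f"{path}:{ln}: {e}") from None
        if not 0.0 <= s <= 40.0:
            raise FieldParseError(f"{path}:{ln}: sensitivity {s} outside [0, 40] dB")
        try:
            idx = GRID_30_2.index_of(x, y)
        except KeyError:
            raise FieldParseError(
                f"{path}:{ln}: ({x:g}, {y:g}) is not a 30-2 location"
            ) from None
        if (x, y) in seen_coords:
            raise FieldParseError(f"{path}:{ln}: duplicate location ({x:g}, {y:g})")
        seen_coords.add((x, y))
        sens[idx] = s
        meta.setdefault("patient_id", pid)
        meta.setdefault("algorithm", alg)
        meta.setdefault("visit", visit_i)
        meta.setdefault("eye", eye)

    missing = [
        (p.x, p.y)
        for p in GRID_30_2
        if p.analysable and (p.x, p.y) not in seen_coords
    ]
    if missing:
        raise FieldParseError(
            f"{path}: missing {len(missing)} location(s), first missing "
            f"coordinate ({missing[0][0]:g}, {missing[0][1]:g})"
        )

    side = _sidecar(path)
    extra = json.loads(side.read_text()) if side.exists() else {}
    return VisualField(
        patient_id=meta["patient_id"],
        algorithm=meta["algorithm"],
        visit=meta["visit"],
        eye=meta["eye"],
        sensitivities=sens,
        duration_s=extra.get("duration_s", 0.0),
        catch_trials=CatchTrials(
            fp_pct=extra.get("fp_pct", 0.0),
            fn_pct=extra.get("fn_pct", 0.0),
            fixation_loss_pct=extra.get("fl_pct", 0.0),
        ),
        age=extra.get("age"),
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a simulated cohort: a manifest JSON plus one CSV per exam."""
    out = Path(out_dir)
    (out / "fields").mkdir(parents=True, exist_ok=True)
    for f in cohort.fields:
        write_field(f, out / "fields" / f"{f.patient_id}_{f.algorithm}_v{f.visit}.csv")
    manifest = {
        "seed": cohort.seed,
        "config": dataclasses.asdict(cohort.config),
        "patients": [
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "severity": p.severity,
                "clinical_diagnosis": p.clinical_diagnosis,
                "protocol": p.protocol,
            }
            for p in cohort.patients
        ],
        "fields": [
            f"fields/{f.patient_id}_{f.algorithm}_v{f.visit}.csv"
            for f in cohort.fields
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return out


def read_cohort_fields(cohort_dir) -> list[VisualField]:
    """Load every exam listed in a cohort directory's manifest."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    return [read_field(cohort_dir / rel) for rel in manifest["fields"]]


def load_severity_rules(path) -> list[dict]:
    """Load an ordered severity rule table from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    rules = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    validate_severity_rules(rules)
    return rules


@dataclasses.dataclass
class RunConfig:
    """End-to-end run configuration; echoed into each output directory."""

    seed: int = 0
    n_patients: int = 16
    prevalence: float = 6 / 16
    n_normative_subjects: int = 300
    defect_level: int = 3  # probability category defining "defective" (p < 1%)
    severity_rules: list | None = None
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        doc = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        ) or {}
        sim = SimConfig(**doc.pop("sim", {}))
        if doc.get("severity_rules"):
            validate_severity_rules(doc["severity_rules"])
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **doc)

    def to_file(self, path) -> None:
        doc = dataclasses.asdict(self)
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(doc, indent=1) + "\n")
        else:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
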