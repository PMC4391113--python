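"""Statpac-style normative analysis of a single visual field.

Given an age-corrected normative model, a measured field is reduced to:

* a **total deviation** (TD) map — measured minus age-expected sensitivity
  at each location;
* the **general height** (GH) — a high percentile of the TD distribution,
  capturing any uniform depression (media opacity, miosis);
* a **pattern deviation** (PD) map — TD minus GH, isolating localised loss;
* **probability maps** — per-location significance categories (p < 5, 2, 1,
  0.5 %) against empirical normative percentile cutoffs;
* **global indices** — MS (mean sensitivity), MD (mean deviation) and PSD
  (pattern standard deviation).

MD is the variance-weighted mean of TD (weights 1/sd^2 per location) and
PSD the square root of the equally weighted variance of TD about MD; with
constant per-location SD both reduce to their plain unweighted forms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .field import VisualField
from .grid import GRID_30_2

__all__ = [
    "PCTS",
    "Category",
    "NormativeModel",
    "ProbabilityMap",
    "GlobalIndices",
    "total_deviation",
    "general_height",
    "pattern_deviation",
    "probability_map",
    "weighted_md_psd",
    "global_indices",
]

#: Tail probabilities of the per-location cutoffs, rarest last.
PCTS = (5.0, 2.0, 1.0, 0.5)

#: Rank (1-based, from the top) of the TD value taken as general height:
#: the 11th highest of 74 sits at the 85th percentile.
GH_RANK = 11


class Category(IntEnum):
    """Probability-map category; higher = rarer deviation."""

    NS = 0   # not significant
    P5 = 1   # p < 5 %
    P2 = 2   # p < 2 %
    P1 = 3   # p < 1 %
    P05 = 4  # p < 0.5 %


@dataclass(frozen=True)
class NormativeModel:
    """Age-corrected normal sensitivities and deviation cutoffs.

    All per-location arrays are aligned to the canonical grid order
    (length 76; blind-spot-adjacent entries are present but unused).

    ``age_slope`` is the sensitivity decline in dB per decade (positive =
    loss with age); ``td_cutoffs`` / ``pd_cutoffs`` map tail percentages
    (5, 2, 1, 0.5) to per-location deviation cutoffs in dB (negative, and
    strictly more negative for rarer tails).
    """

    ref_age: float
    mean_normal: np.ndarray
    age_slope: np.ndarray
    sd_normal: np.ndarray
    td_cutoffs: dict[float, np.ndarray]
    pd_cutoffs: dict[float, np.ndarray]
    age_range: tuple[float, float] = (18.0, 80.0)
    seed: int | None = None
    version: str = "1"

    def expected(self, age: float) -> np.ndarray:
        """Age-expected normal sensitivity per location (dB)."""
        lo, hi = self.age_range
        if age < lo or age > hi:
            import warnings

            warnings.warn(
                f"age {age} outside normative calibration range {self.age_range}; "
                "clamping",
                stacklevel=2,
            )
            age = min(max(age, lo), hi)
        return self.mean_normal - self.age_slope * (age - self.ref_age) / 10.0

    def cutoffs(self, basis: str) -> dict[float, np.ndarray]:
        if basis == "total_deviation":
            return self.td_cutoffs
        if basis == "pattern_deviation":
            return self.pd_cutoffs
        raise ValueError(f"unknown basis {basis!r}")

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "version": self.version,
            "seed": self.seed,
            "ref_age": self.ref_age,
            "age_range": list(self.age_range),
            "mean_normal": self.mean_normal.tolist(),
            "age_slope": self.age_slope.tolist(),
            "sd_normal": self.sd_normal.tolist(),
            "td_cutoffs": {str(p): c.tolist() for p, c in self.td_cutoffs.items()},
            "pd_cutoffs": {str(p): c.tolist() for p, c in self.pd_cutoffs.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormativeModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            ref_age=doc["ref_age"],
            mean_normal=np.asarray(doc["mean_normal"]),
            age_slope=np.asarray(doc["age_slope"]),
            sd_normal=np.asarray(doc["sd_normal"]),
            td_cutoffs={float(p): np.asarray(c) for p, c in doc["td_cutoffs"].items()},
            pd_cutoffs={float(p): np.asarray(c) for p, c in doc["pd_cutoffs"].items()},
            age_range=tuple(doc["age_range"]),
            seed=doc["seed"],
            version=doc["version"],
        )


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-location significance categories of a deviation map.

    ``categories`` is aligned to the grid (length 76, dtype int); excluded
    locations carry -1 and are never counted by downstream metrics.
    """

    categories: np.ndarray
    basis: str

    def __post_init__(self):
        c = np.asarray(self.categories, dtype=int)
        mask = GRID_30_2.analysable_mask
        if c.shape != (len(GRID_30_2),):
            raise ValueError("category array must cover the full grid")
        if ((c[mask] < 0) | (c[mask] > 4)).any():
            raise ValueError("categories must be in 0..4 at analysable locations")
        object.__setattr__(self, "categories", c)

    @property
    def analysable(self) -> np.ndarray:
        return self.categories[GRID_30_2.analysable_mask]


@dataclass(frozen=True)
class GlobalIndices:
    MS: float
    MD: float
    PSD: float


def total_deviation(field: VisualField, model: NormativeModel, age: float) -> np.ndarray:
    """TD map: measured sensitivity minus age-expected normal (dB).

    Negative values are loss.  Returned aligned to the grid with NaN at the
    excluded blind-spot pair.
    """
    td = field.sensitivities - model.expected(age)
    out = np.where(GRID_30_2.analysable_mask, td, np.nan)
    return out


def general_height(td_map: np.ndarray) -> float:
    """General height: the 11th-highest analysable TD value (85th percentile).

    A fixed rank rather than an interpolated percentile keeps GH exactly
    reproducible and equal to one of the observed deviations.
    """
    vals = np.sort(td_map[np.isfinite(td_map)])[::-1]
    if len(vals) < GH_RANK:
        raise ValueError(f"need at least {GH_RANK} TD values, got {len(vals)}")
    return float(vals[GH_RANK - 1])


def pattern_deviation(td_map: np.ndarray, gh: float) -> np.ndarray:
    """PD map: TD minus general height (uniform depression removed)."""
    return td_map - gh


def probability_map(
    dev_map: np.ndarray, model: NormativeModel, basis: str
) -> ProbabilityMap:
    """Categorise each deviation against the normative percentile cutoffs.

    A deviation is assigned the rarest tail whose cutoff it does not
    exceed; equality with a cutoff takes the rarer category (inclusive
    boundary).  Locations at or above the 5 % cutoff are NS.
    """
    cutoffs = model.cutoffs(basis)
    cats = np.zeros(len(GRID_30_2), dtype=int)
    for pct, cat in zip(PCTS, (Category.P5, Category.P2, Category.P1, Category.P05)):
        cats = np.where(dev_map <= cutoffs[pct], int(cat), cats)
    cats[~GRID_30_2.analysable_mask] = -1
    return ProbabilityMap(categories=cats, basis=basis)


def weighted_md_psd(td: np.ndarray, sd: np.ndarray) -> tuple[float, float]:
    """MD and PSD of a TD vector with inverse-variance weights 1/sd^2.

    With constant ``sd`` this reduces to the plain mean and the population
    standard deviation of ``td``.
    """
    td = np.asarray(td, dtype=float)
    w = 1.0 / np.asarray(sd, dtype=float) ** 2
    w = w / w.sum()
    md = float(np.sum(w * td))
    psd = float(np.sqrt(np.sum(w * (td - md) ** 2)))
    return md, psd


def global_indices(
    field: VisualField, model: NormativeModel, age: float
) -> GlobalIndices:
    """MS, MD and PSD of one exam.

    MS is the plain mean sensitivity.  MD weights each location's TD by the
    inverse normative variance, down-weighting the noisy periphery; PSD is
    the weighted SD of TD about MD with the same weights.
    """
    mask = GRID_30_2.analysable_mask
    td = total_deviation(field, model, age)[mask]
    md, psd = weighted_md_psd(td, model.sd_normal[mask])
    return GlobalIndices(MS=field.mean_sensitivity, MD=md, PSD=psd)
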