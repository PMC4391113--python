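"""The visual-field exam record and its geometric transforms.

A :class:`VisualField` holds one exam: per-location differential light
sensitivities in dB (0-40; 0 means the brightest stimulus was not seen),
aligned to the canonical 30-2 grid order, plus the exam metadata needed by
the reliability filter and the duration summaries.

Left-eye exams are stored as recorded and converted to right-eye format
(x negated) only on entry to analysis, so a file round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .grid import GRID_30_2, BLIND_SPOT_ADJACENT

__all__ = [
    "ALGORITHMS",
    "CatchTrials",
    "VisualField",
    "mirror_left_to_right",
    "exclude_blind_spot",
]

ALGORITHMS = ("full_threshold", "sita_standard", "sita_fast")

_BLIND_SPOT_IDX = tuple(
    GRID_30_2.index_of(x, y) for (x, y) in sorted(BLIND_SPOT_ADJACENT)
)


@dataclass(frozen=True)
class CatchTrials:
    """Reliability indices of one exam, in percent."""

    fp_pct: float = 0.0
    fn_pct: float = 0.0
    fixation_loss_pct: float = 0.0


@dataclass(frozen=True)
class VisualField:
    """One perimetric exam on the 30-2 grid.

    ``sensitivities`` has one entry per grid location in canonical order
    (length 76); the two blind-spot-adjacent entries may be NaN, every
    other entry must lie in [0, 40] dB.
    """

    patient_id: str
    algorithm: str
    visit: int
    eye: str
    sensitivities: np.ndarray
    duration_s: float = 0.0
    catch_trials: CatchTrials = dc_field(default_factory=CatchTrials)
    age: float | None = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")
        s = np.asarray(self.sensitivities, dtype=float)
        if s.shape != (len(GRID_30_2),):
            raise ValueError(
                f"expected {len(GRID_30_2)} sensitivities, got shape {s.shape}"
            )
        finite = np.isfinite(s)
        nan_ok = np.zeros(len(s), dtype=bool)
        nan_ok[list(_BLIND_SPOT_IDX)] = True
        if not finite[~nan_ok].all():
            raise ValueError("NaN sensitivity at a non-excluded location")
        if ((s[finite] < 0) | (s[finite] > 40)).any():
            raise ValueError("sensitivities must lie in [0, 40] dB")
        object.__setattr__(self, "sensitivities", s)

    @property
    def analysable(self) -> np.ndarray:
        """Sensitivities at the 74 analysable locations, in grid order."""
        return self.sensitivities[GRID_30_2.analysable_mask]

    @property
    def mean_sensitivity(self) -> float:
        """Unweighted mean sensitivity (MS, dB) over analysable locations."""
        return float(np.mean(self.analysable))


def mirror_left_to_right(f: VisualField, *, force: bool = False) -> VisualField:
    """Convert a left-eye exam to right-eye format by negating x.

    Sensitivities are carried unchanged; only their grid positions move.
    Applying this to a field already in right-eye format is refused (a
    double mirror would silently corrupt the nasal/temporal labelling)
    unless ``force`` is given, which exists for testing the involution.
    """
    if f.eye != "left" and not force:
        raise ValueError("field is already in right-eye format; refusing to mirror")
    idx = GRID_30_2.mirror_index()
    return replace(
        f,
        sensitivities=f.sensitivities[idx],
        eye="right" if f.eye == "left" else "left",
    )


def exclude_blind_spot(obj):
    """Mark the blind-spot-adjacent pair as excluded; idempotent.

    For a :class:`VisualField` the two entries are set to NaN so that no
    downstream metric can consume them; for a :class:`~perimsim.grid.StimulusGrid`
    the grid is returned unchanged because exclusion is built into its zone
    labels.  Either way the result has 74 analysable locations.
    """
    from .grid import StimulusGrid

    if isinstance(obj, StimulusGrid):
        return obj
    if isinstance(obj, VisualField):
        s = obj.sensitivities.copy()
        s[list(_BLIND_SPOT_IDX)] = np.nan
        return replace(obj, sensitivities=s)
    raise TypeError(f"cannot exclude blind spot from {type(obj).__name__}")
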