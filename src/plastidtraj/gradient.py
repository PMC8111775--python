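"""Leaf positional gradient, cell age mapping and cell-division correction.

The first wheat leaf is sampled as an ordered series of segments from the
shoot apex (sample 1) to the mature blade (sample 15).  Because cells are
displaced from the basal meristem by the growth of the cells below them,
position along the leaf is a proxy for cell age ("developmental time").
This module maps segment midpoints to cell ages through a monotone lookup,
and converts flow-cytometric S-phase fractions into the per-transition
correction factors that undo the dilution of per-cell organelle counts by
cell division (one division halves the average count per cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, RangeError

__all__ = [
    "AgeModel",
    "default_age_model",
    "default_sample_frame",
    "position_to_age",
    "correction_factor",
    "correction_factors_from_profile",
    "cumulative_correction",
    "doubling_time",
    "validate_cell_cycle_profile",
]

#: Fractions of S-phase nuclei below this are indistinguishable from
#: instrument background and are treated as zero (no ongoing division).
DEFAULT_S_FLOOR = 0.01

# Position (mm from the leaf base) -> cell age (days since leaving the
# meristem).  Knots follow the saturating displacement kinetics of a
# steadily elongating monocot leaf: early segments are traversed quickly
# while the cell is being pushed by the expansion zone below it.
_DEFAULT_KNOTS_MM = np.array(
    [0.0, 2.5, 7.5, 12.5, 17.5, 22.5, 27.5, 32.5, 37.5, 45.0, 60.0, 75.0, 90.0, 105.0, 170.0]
)
_DEFAULT_KNOTS_DAYS = np.array(
    [0.0, 0.5, 0.83, 1.2, 1.45, 1.65, 1.85, 2.05, 2.25, 2.5, 2.8, 3.05, 3.35, 3.7, 5.0]
)


@dataclass(frozen=True)
class AgeModel:
    """Monotone position→age lookup plus elongation-rate rescaling.

    Parameters
    ----------
    positions_mm, ages_days:
        Knots of the lookup table.  Positions must be strictly increasing
        and ages non-decreasing.
    elongation_rates:
        Measured leaf elongation rates (mm/day) on consecutive days of
        sampling; the default (44, 43, 42) reflects steady elongation of
        the first leaf around the day of harvest.
    reference_rate:
        Elongation rate underlying the lookup table.  Ages are rescaled by
        ``reference_rate / mean(elongation_rates)``; when the two agree
        (the default) the correction is the identity.
    """

    positions_mm: np.ndarray
    ages_days: np.ndarray
    elongation_rates: tuple[float, ...] = (44.0, 43.0, 42.0)
    reference_rate: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        ages = np.asarray(self.ages_days, dtype=float)
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "ages_days", ages)
        if pos.ndim != 1 or pos.size < 2:
            raise ArgumentError("AgeModel lookup needs at least two knots")
        if not np.all(np.diff(pos) > 0):
            raise ArgumentError("AgeModel positions must be strictly increasing")
        if not np.all(np.diff(ages) >= 0):
            raise ArgumentError("AgeModel ages must be non-decreasing")
        if any(r <= 0 for r in self.elongation_rates):
            raise ArgumentError("AgeModel elongation rates must be positive")
        if self.reference_rate is not None and self.reference_rate <= 0:
            raise ArgumentError("AgeModel reference_rate must be positive")

    @property
    def observed_rate(self) -> float:
        return float(np.mean(self.elongation_rates))

    @property
    def time_correction(self) -> float:
        """Multiplicative age correction: reference rate ÷ observed rate."""
        ref = self.reference_rate if self.reference_rate is not None else self.observed_rate
        return ref / self.observed_rate


def default_age_model(**kwargs) -> AgeModel:
    """The packaged position→age relation (saturating monotone curve)."""
    return AgeModel(_DEFAULT_KNOTS_MM.copy(), _DEFAULT_KNOTS_DAYS.copy(), **kwargs)


def position_to_age(midpoint_mm: float, age_model: AgeModel) -> float:
    """Cell age (days) at a segment midpoint.

    Monotone interpolation of the lookup, then the elongation-rate
    rescaling applied as a multiplicative time correction.
    """
    pos = age_model.positions_mm
    if not (pos[0] <= midpoint_mm <= pos[-1]):
        raise RangeError(
            f"midpoint {midpoint_mm} mm outside lookup domain [{pos[0]}, {pos[-1]}]"
        )
    age = float(np.interp(midpoint_mm, pos, age_model.ages_days))
    return age * age_model.time_correction


def default_sample_frame(
    age_model: AgeModel | None = None, mature_age_days: float = 8.0
) -> pd.DataFrame:
    """The ordered 15-sample design of the leaf developmental gradient.

    Sample 1 is the shoot apex (meristem plus leaf primordia, position 0).
    Samples 2–9 are consecutive 5-mm segments from the leaf base; samples
    10–14 are discontinuous 10-mm segments further up the blade.  Sample 15
    is the mature blade of an older leaf and carries no position; its age
    is a configurable label that never enters rate calculations.
    """
    model = age_model if age_model is not None else default_age_model()
    rows = []
    rows.append((1, 0.0, 0.3, 0.0))
    for i in range(8):  # samples 2..9
        rows.append((2 + i, 5.0 * i, 5.0 * (i + 1), 5.0 * i + 2.5))
    starts = [40.0, 55.0, 70.0, 85.0, 100.0]
    for j, s in enumerate(starts):  # samples 10..14
        rows.append((10 + j, s, s + 10.0, s + 5.0))
    frame = pd.DataFrame(rows, columns=["sample_id", "start_mm", "end_mm", "midpoint_mm"])
    frame["age_days"] = [position_to_age(m, model) for m in frame["midpoint_mm"]]
    mature = pd.DataFrame(
        {
            "sample_id": [15],
            "start_mm": [np.nan],
            "end_mm": [np.nan],
            "midpoint_mm": [np.nan],
            "age_days": [mature_age_days],
        }
    )
    frame = pd.concat([frame, mature], ignore_index=True)
    frame["under_coleoptile"] = frame["sample_id"] <= 8
    frame["continuous"] = frame["sample_id"] <= 9
    frame["mature"] = frame["sample_id"] == 15
    return frame


def _floored(f_s: float, floor: float) -> float:
    if f_s < 0:
        raise ArgumentError(f"S-phase fraction must be non-negative, got {f_s}")
    return 0.0 if f_s < floor else f_s


def correction_factor(
    f_s_i: float, f_s_reference: float, floor: float = DEFAULT_S_FLOOR
) -> float:
    """Cell-division correction factor for one sample transition.

    ``C = 1 + min(1, f_S / f_S_ref)``, clipped to [1, 2]: at full cycling
    (relative S fraction 1, the meristem→base transition) every cell
    divides once and the factor is exactly 2; with no cells in S phase the
    factor is 1 and counts pass through uncorrected.  At most one division
    per transition is assumed.
    """
    if f_s_reference <= 0:
        raise ArgumentError(f"f_S_reference must be positive, got {f_s_reference}")
    f = _floored(f_s_i, floor)
    return float(np.clip(1.0 + min(1.0, f / f_s_reference), 1.0, 2.0))


def correction_factors_from_profile(
    profile: pd.DataFrame, floor: float = DEFAULT_S_FLOOR
) -> pd.Series:
    """Per-transition correction factors from a cell-cycle profile.

    The factor for transition i→i+1 uses the upstream sample's S fraction
    relative to sample 1 (the fully cycling meristem reference).  Returns a
    series indexed by the upstream sample id.
    """
    validate_cell_cycle_profile(profile)
    prof = profile.sort_values("sample_id")
    ref = float(prof["f_S"].iloc[0])
    if ref < floor or ref <= 0:
        raise ArgumentError("reference sample has no measurable S-phase fraction")
    upstream = prof.iloc[:-1]
    factors = [correction_factor(f, ref, floor=floor) for f in upstream["f_S"]]
    return pd.Series(factors, index=upstream["sample_id"].to_numpy(), name="C")


def cumulative_correction(
    factors: Sequence[float] | pd.Series,
    from_sample: int | None = None,
    to_sample: int | None = None,
) -> float:
    """Product of per-transition correction factors over a sample range.

    ``factors[i]`` is the factor for the transition leaving sample ``i+1``
    (1-based).  ``from_sample``/``to_sample`` select the transitions from
    ``from_sample`` up to (but not including) ``to_sample``.
    """
    values = np.asarray(factors, dtype=float)
    if from_sample is not None or to_sample is not None:
        lo = 1 if from_sample is None else from_sample
        hi = values.size + 1 if to_sample is None else to_sample
        if lo >= hi:
            raise ArgumentError(f"empty transition range {lo}→{hi}")
        values = values[lo - 1 : hi - 1]
    if values.size == 0:
        raise ArgumentError("empty sequence of correction factors")
    if np.any(values < 1.0):
        raise ArgumentError("correction factors must all be ≥ 1")
    return float(np.prod(values))


def doubling_time(
    f_s_i: float,
    f_s_reference: float,
    full_cycle_hours: float = 12.0,
    floor: float = DEFAULT_S_FLOOR,
) -> float:
    """Cell doubling time (hours) implied by the relative S-phase fraction.

    Scales the fastest recorded full cell-cycle duration by the inverse of
    the S fraction relative to the fully cycling reference; returns
    ``inf`` when no cells are in S phase.
    """
    if full_cycle_hours <= 0:
        raise ArgumentError(f"full_cycle_hours must be positive, got {full_cycle_hours}")
    if f_s_reference <= 0:
        raise ArgumentError(f"f_S_reference must be positive, got {f_s_reference}")
    f = _floored(f_s_i, floor)
    if f == 0.0:
        return math.inf
    return full_cycle_hours / (f / f_s_reference)


def validate_cell_cycle_profile(profile: pd.DataFrame) -> None:
    """Check fraction and count invariants of a cell-cycle table."""
    required = {"sample_id", "f_G1", "f_S", "f_G2", "n_nuclei"}
    missing = required - set(profile.columns)
    if missing:
        raise ArgumentError(f"cell-cycle profile missing columns: {sorted(missing)}")
    fracs = profile[["f_G1", "f_S", "f_G2"]].to_numpy(dtype=float)
    if np.any(fracs < 0) or np.any(fracs > 1):
        raise ArgumentError("cell-cycle fractions must lie in [0, 1]")
    if np.any(fracs.sum(axis=1) > 1.0 + 1e-9):
        raise ArgumentError("G1+S+G2 fractions exceed 1")
    if np.any(profile["n_nuclei"].to_numpy() < 1):
        raise ArgumentError("n_nuclei must be ≥ 1")
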