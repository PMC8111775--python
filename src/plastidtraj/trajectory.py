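"""Per-sample organelle statistics and division-corrected build-up rates.

Chloroplast biogenesis along the leaf proceeds in two phases: an early
"plastid" phase of rapid organelle proliferation and establishment of the
genetic machinery, and a later "chloroplast" phase of photosynthetic
build-up.  Because proliferating cells halve their per-cell organelle
counts at every division, raw counts understate organelle multiplication;
all rates here are corrected with the cell-division factors derived from
flow cytometry (see :mod:`plastidtraj.gradient`).

Rates are expressed as log2 fold per day on the cell-age axis, so one
"round" of organelle division literally doubles the corrected count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, PlastidTrajError
from .gradient import (
    DEFAULT_S_FLOOR,
    correction_factors_from_profile,
    cumulative_correction,
)

__all__ = [
    "reference_trajectory",
    "summarize_cells",
    "division_rate",
    "cumulative_division_rounds",
    "growth_rate",
    "chloroplast_index",
    "detect_phases",
    "PhaseSplit",
    "compute_trajectory",
]

_MEASURES = ["cell_area", "plastid_count", "mean_plastid_area"]


def reference_trajectory() -> pd.DataFrame:
    """The packaged two-point reference trajectory: per-cell plastid count
    at the basal sample and at the count peak, with the cumulative
    cell-division correction over the interval."""
    from importlib.resources import files

    path = files("plastidtraj").joinpath("data/reference_trajectory.tsv")
    with path.open() as handle:
        return pd.read_csv(handle, sep="\t")


def summarize_cells(
    cells: pd.DataFrame,
    expected_samples: Sequence[int] | None = None,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-sample summary of the per-cell microscopy table.

    Cells are pooled across replicates.  For each of cell plan area,
    plastid count and mean individual plastid plan area the median,
    quartiles and full range are reported; the per-sample mean plastid
    count ``N``, mean individual plastid area ``a`` and their product, the
    total plastid plan area per cell ``A = N × a``, feed the rate and
    chloroplast-index calculations.
    """
    required = {"sample_id", *_MEASURES}
    missing = required - set(cells.columns)
    if missing:
        raise ArgumentError(f"cell table missing columns: {sorted(missing)}")
    present = set(cells["sample_id"].unique())
    if expected_samples is not None:
        for s in expected_samples:
            if s not in present:
                raise PlastidTrajError(f"sample {s} has no cells")
    rows = []
    for sample_id, grp in cells.groupby("sample_id", sort=True):
        if len(grp) < min_cells:
            raise PlastidTrajError(
                f"sample {sample_id} has only {len(grp)} cells (minimum {min_cells})"
            )
        row: dict = {"sample_id": sample_id, "n_cells": len(grp)}
        for col in _MEASURES:
            v = grp[col].to_numpy(dtype=float)
            if col != "plastid_count" and np.any(v <= 0):
                raise ArgumentError(f"non-positive {col} in sample {sample_id}")
            row[f"{col}_median"] = float(np.median(v))
            row[f"{col}_q1"] = float(np.percentile(v, 25))
            row[f"{col}_q3"] = float(np.percentile(v, 75))
            row[f"{col}_min"] = float(v.min())
            row[f"{col}_max"] = float(v.max())
        n_mean = float(grp["plastid_count"].mean())
        a_mean = float(grp["mean_plastid_area"].mean())
        row["N"] = n_mean
        row["a"] = a_mean
        row["A"] = n_mean * a_mean
        row["chloroplast_index"] = chloroplast_index(
            n_mean, a_mean, float(grp["cell_area"].mean())
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def _rate(x_i: float, x_next: float, c_i: float, age_i: float, age_next: float, what: str) -> float:
    if x_i <= 0 or x_next <= 0:
        raise ArgumentError(f"{what} values must be positive ({x_i}, {x_next})")
    if age_next <= age_i:
        raise ArgumentError(f"ages must be increasing ({age_i} → {age_next})")
    if c_i < 1.0:
        raise ArgumentError(f"correction factor must be ≥ 1, got {c_i}")
    return float(np.log2(x_next * c_i / x_i) / (age_next - age_i))


def division_rate(
    n_i: float, n_next: float, c_i: float, age_i: float, age_next: float
) -> float:
    """Plastid division rate in rounds per day for one sample transition.

    ``r = log2(N_{i+1} C_i / N_i) / Δage``: the cell-division factor C
    restores counts diluted by cytokinesis, so r counts actual organelle
    fission events.  The late small decline in plastid number appears as a
    negative rate and is never clipped.
    """
    return _rate(n_i, n_next, c_i, age_i, age_next, "plastid counts")


def cumulative_division_rounds(
    n_first: float, n_last: float, cumulative_c: float
) -> float:
    """Total corrected organelle division rounds over a sample range.

    ``log2(N_last × C_cumulative / N_first)`` where the cumulative factor
    is the product of per-transition cell-division corrections.
    """
    if n_first <= 0 or n_last <= 0:
        raise ArgumentError(f"plastid counts must be positive ({n_first}, {n_last})")
    if cumulative_c < 1.0:
        raise ArgumentError(f"cumulative correction must be ≥ 1, got {cumulative_c}")
    return float(np.log2(n_last * cumulative_c / n_first))


def growth_rate(
    a_i: float, a_next: float, c_i: float, age_i: float, age_next: float
) -> float:
    """Chloroplast compartment growth rate (log2 fold of total plastid
    area per cell, per day), corrected for cell division like
    :func:`division_rate`."""
    return _rate(a_i, a_next, c_i, age_i, age_next, "total plastid areas")


def chloroplast_index(n_i: float, a_i: float, cell_area_i: float) -> float:
    """Fraction of the cell plan area occupied by the plastid compartment:
    total plastid area (count × mean individual area) over cell area."""
    if n_i <= 0 or a_i <= 0:
        raise ArgumentError(f"plastid count and area must be positive ({n_i}, {a_i})")
    if cell_area_i <= 0:
        raise ArgumentError(f"cell area must be positive, got {cell_area_i}")
    return float(n_i * a_i / cell_area_i)


def _smooth3(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        out[i] = x[max(0, i - 1) : i + 2].mean()
    return out


def _local_maxima(s: np.ndarray) -> list[int]:
    idx = []
    n = s.size
    for i in range(n):
        left = s[i - 1] if i > 0 else -np.inf
        right = s[i + 1] if i < n - 1 else -np.inf
        if s[i] >= left and s[i] >= right and (s[i] > left or s[i] > right):
            idx.append(i)
    return idx


@dataclass(frozen=True)
class PhaseSplit:
    """Partition of a growth-rate series into the two build-up phases."""

    plastid: tuple[int, ...]
    transition: int
    chloroplast: tuple[int, ...]


def detect_phases(rates: Sequence[float], smooth: bool = True) -> PhaseSplit:
    """Locate the trough separating the plastid and chloroplast phases.

    The transition is the interior local minimum of the (optionally
    3-point smoothed) growth-rate series that separates its two largest
    local maxima; indices before it are labelled plastid phase and indices
    after it chloroplast phase.  Ties resolve to the earliest index.  A
    monotone series has no interior minimum and raises an error.
    """
    x = np.asarray(rates, dtype=float)
    if x.size < 5:
        raise ArgumentError(f"growth-rate series too short ({x.size} < 5)")
    s = _smooth3(x) if smooth else x.copy()
    maxima = _local_maxima(s)
    if len(maxima) < 2:
        raise PlastidTrajError("no biphasic structure in growth-rate series")
    # two largest local maxima, earliest first on ties
    order = sorted(maxima, key=lambda i: (-s[i], i))
    p1, p2 = sorted(order[:2])
    if p2 - p1 < 2:
        raise PlastidTrajError("no biphasic structure in growth-rate series")
    interior = s[p1 + 1 : p2]
    t = p1 + 1 + int(np.argmin(interior))  # argmin returns earliest tie
    return PhaseSplit(
        plastid=tuple(range(0, t)),
        transition=t,
        chloroplast=tuple(range(t + 1, x.size)),
    )


def compute_trajectory(
    cells: pd.DataFrame,
    cell_cycle: pd.DataFrame,
    sample_frame: pd.DataFrame,
    s_floor: float = DEFAULT_S_FLOOR,
    smooth: bool = True,
) -> dict:
    """Full trajectory reconstruction from the three input tables.

    Returns a dict with the per-sample summary (including phase labels),
    the per-transition rate table, the detected transition sample, and the
    cumulative corrected division rounds over the plastid phase.  The
    mature sample (no position, non-adjacent sampling) is summarized but
    excluded from all rate calculations.
    """
    summary = summarize_cells(cells, expected_samples=sorted(cell_cycle["sample_id"]))
    ages = sample_frame.set_index("sample_id")["age_days"]
    factors = correction_factors_from_profile(cell_cycle, floor=s_floor)

    mature_ids = set(
        sample_frame.loc[sample_frame.get("mature", False) == True, "sample_id"]  # noqa: E712
    )
    rate_samples = [s for s in summary.index if s not in mature_ids and s in ages.index]
    rows = []
    for s_i, s_next in zip(rate_samples[:-1], rate_samples[1:]):
        if s_next != s_i + 1 or s_i not in factors.index:
            continue
        c = float(factors.loc[s_i])
        rows.append(
            {
                "from_sample": s_i,
                "to_sample": s_next,
                "C": c,
                "dt_days": float(ages[s_next] - ages[s_i]),
                "division_rate": division_rate(
                    summary.loc[s_i, "N"], summary.loc[s_next, "N"], c, ages[s_i], ages[s_next]
                ),
                "growth_rate": growth_rate(
                    summary.loc[s_i, "A"], summary.loc[s_next, "A"], c, ages[s_i], ages[s_next]
                ),
            }
        )
    transitions = pd.DataFrame(rows)
    split = detect_phases(transitions["growth_rate"].to_numpy(), smooth=smooth)
    transition_sample = int(transitions.iloc[split.transition]["from_sample"])

    def label(sample_id: int) -> str:
        if sample_id < transition_sample:
            return "plastid"
        if sample_id == transition_sample:
            return "transition"
        return "chloroplast"

    summary = summary.copy()
    summary["phase"] = [label(s) for s in summary.index]

    plastid_rows = transitions[transitions["from_sample"] < transition_sample]
    cum_c = cumulative_correction(plastid_rows["C"].to_list())
    first, last = plastid_rows.iloc[0]["from_sample"], plastid_rows.iloc[-1]["to_sample"]
    rounds = cumulative_division_rounds(
        summary.loc[first, "N"], summary.loc[last, "N"], cum_c
    )
    return {
        "summary": summary,
        "transitions": transitions,
        "transition_sample": transition_sample,
        "phase_split": split,
        "plastid_phase_division_rounds": rounds,
        "plastid_phase_cumulative_C": cum_c,
    }
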