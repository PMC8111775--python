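"""Absolute qPCR quantitation: plastid genome and ribosome build-up.

Plastid genome copy number is expressed per haploid nuclear genome as the
ratio of the mean of three plastid amplicons — rbcL (large single-copy
region), ndhD (small single-copy region) and rps7, which lies in the
inverted repeat and therefore occurs twice per genome and is halved — to
the mean of two nuclear single-copy amplicons (TaKO1, TaKS):

    cpDNA/gDNA = [(rbcL + ndhD + rps7/2) / 3] / [(TaKO1 + TaKS) / 2]

Plastid ribosome build-up is the ratio of 16S (plastid) to 18S (cytosolic)
rRNA quantities; the same contract serves qPCR quantities and
electropherogram peak areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, FitError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "absolute_quantity",
    "cpdna_per_haploid_genome",
    "rrna_ratio",
    "aggregate_replicates",
    "quantify_samples",
    "cpdna_ratio_by_sample",
    "rrna_ratio_by_sample",
    "PLASTID_AMPLICONS",
    "NUCLEAR_AMPLICONS",
]

PLASTID_AMPLICONS = ("rbcL", "ndhD", "rps7")
NUCLEAR_AMPLICONS = ("TaKO1", "TaKS")


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares calibration line Cq ~ log10(concentration)."""

    amplicon: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, ``10^(−1/slope) − 1``
        (1.0 for a perfect doubling, slope −3.3219)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    concentrations: Sequence[float], cqs: Sequence[float], amplicon: str = ""
) -> StandardCurve:
    """Fit a standard curve from a dilution series of known concentrations."""
    conc = np.asarray(concentrations, dtype=float)
    cq = np.asarray(cqs, dtype=float)
    if conc.size != cq.size:
        raise ArgumentError("concentrations and Cq values differ in length")
    if np.any(conc <= 0):
        raise ArgumentError("standard concentrations must be positive")
    if np.unique(conc).size < 3:
        raise FitError(
            f"standard curve for {amplicon or 'amplicon'} needs ≥ 3 distinct "
            f"concentrations, got {np.unique(conc).size}"
        )
    res = stats.linregress(np.log10(conc), cq)
    if res.slope >= 0:
        raise FitError(f"standard curve for {amplicon or 'amplicon'} has non-negative slope")
    return StandardCurve(
        amplicon=amplicon,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def absolute_quantity(cq: float, curve: StandardCurve, dilution_factor: float = 1.0) -> float:
    """Concentration (pg/μl of undiluted extract) from a Cq value:
    ``10^((Cq − intercept)/slope) × dilution_factor``."""
    if dilution_factor < 1.0:
        raise ArgumentError(f"dilution factor must be ≥ 1, got {dilution_factor}")
    return float(10.0 ** ((cq - curve.intercept) / curve.slope) * dilution_factor)


def cpdna_per_haploid_genome(
    rbcl: float, ndhd: float, rps7: float, tako1: float, taks: float
) -> float:
    """Plastid genome copies per haploid nuclear genome.

    rps7 is halved because the inverted repeat carries two copies per
    plastid genome.  The ratio is invariant under a common rescaling of
    all five copy-equivalent quantities.
    """
    for name, v in (("rbcL", rbcl), ("ndhD", ndhd), ("rps7", rps7)):
        if v < 0:
            raise ArgumentError(f"plastid quantity {name} must be ≥ 0, got {v}")
    if tako1 <= 0 or taks <= 0:
        raise ArgumentError("nuclear quantities must be positive")
    plastid_mean = (rbcl + ndhd + rps7 / 2.0) / 3.0
    nuclear_mean = (tako1 + taks) / 2.0
    return float(plastid_mean / nuclear_mean)


def rrna_ratio(q16s: float, q18s: float) -> float:
    """Plastid ribosome build-up: 16S over 18S rRNA quantity."""
    if q18s <= 0:
        raise ArgumentError(f"18S quantity must be positive, got {q18s}")
    if q16s < 0:
        raise ArgumentError(f"16S quantity must be ≥ 0, got {q16s}")
    return float(q16s / q18s)


def aggregate_replicates(
    replicates: Mapping[object, Sequence[float]] | Sequence[Sequence[float]],
) -> tuple[float, float, int]:
    """Mean ± standard error across biological replicates.

    Technical replicates within each biological replicate are averaged
    first; the SEM is computed between biological replicate means (sample
    sd / √n).  With a single biological replicate the SEM is undefined
    and returned as NaN.
    """
    if isinstance(replicates, Mapping):
        groups = [np.asarray(v, dtype=float) for _, v in sorted(replicates.items(), key=str)]
    else:
        groups = [np.asarray(v, dtype=float) for v in replicates]
    if len(groups) == 0 or any(g.size == 0 for g in groups):
        raise ArgumentError("each biological replicate needs at least one measurement")
    bio_means = np.array([g.mean() for g in groups])
    mean = float(bio_means.mean())
    if bio_means.size == 1:
        return mean, math.nan, 1
    sem = float(bio_means.std(ddof=1) / math.sqrt(bio_means.size))
    return mean, sem, int(bio_means.size)


def quantify_samples(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Absolute quantities for every unknown in a qPCR table.

    Standards (``role == 'standard'``) are fitted per amplicon; unknowns
    have their technical-replicate Cq values averaged first (standard
    practice: average Cq, not concentration), then interpolated through
    the curve and scaled by the dilution factor.  Returns one row per
    (sample, amplicon, biological replicate) with the recovered quantity
    in pg/μl of undiluted extract.
    """
    required = {"amplicon", "role", "cq"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ArgumentError(f"qPCR table missing columns: {sorted(missing)}")
    curves: dict[str, StandardCurve] = {}
    std = qpcr[qpcr["role"] == "standard"]
    for amp, grp in std.groupby("amplicon"):
        curves[amp] = fit_standard_curve(grp["concentration"], grp["cq"], amplicon=amp)
    unknowns = qpcr[qpcr["role"] == "unknown"]
    rows = []
    group_cols = ["sample_id", "amplicon", "biological_replicate"]
    for (sample, amp, bio), grp in unknowns.groupby(group_cols):
        if amp not in curves:
            raise FitError(f"no standard curve for amplicon {amp}")
        mean_cq = float(grp["cq"].mean())
        dilution = float(grp["dilution_factor"].iloc[0])
        rows.append(
            {
                "sample_id": sample,
                "amplicon": amp,
                "biological_replicate": bio,
                "mean_cq": mean_cq,
                "quantity": absolute_quantity(mean_cq, curves[amp], dilution),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["curves"] = curves
    return out


def cpdna_ratio_by_sample(quantities: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cpDNA/gDNA ratio with SEM across biological replicates.

    ``quantities`` is the output of :func:`quantify_samples`; the ratio is
    computed within each biological replicate, then aggregated.
    """
    rows = []
    for sample, grp in quantities.groupby("sample_id"):
        per_bio: dict = {}
        for bio, sub in grp.groupby("biological_replicate"):
            q = sub.set_index("amplicon")["quantity"]
            if not set(PLASTID_AMPLICONS + NUCLEAR_AMPLICONS) <= set(q.index):
                raise ArgumentError(
                    f"sample {sample} replicate {bio} is missing amplicons"
                )
            per_bio[bio] = [
                cpdna_per_haploid_genome(
                    q["rbcL"], q["ndhD"], q["rps7"], q["TaKO1"], q["TaKS"]
                )
            ]
        mean, sem, n = aggregate_replicates(per_bio)
        rows.append(
            {"sample_id": int(sample), "cpdna_per_genome": mean, "sem": sem, "n_bio": n}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def rrna_ratio_by_sample(rrna: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 16S/18S ratio with SEM across independent preparations."""
    rows = []
    for sample, grp in rrna.groupby("sample_id"):
        ratios = {
            rep: [rrna_ratio(row["q16S"], row["q18S"])]
            for rep, row in grp.set_index("replicate").iterrows()
        }
        mean, sem, n = aggregate_replicates(ratios)
        rows.append({"sample_id": sample, "rrna_ratio": mean, "sem": sem, "n_preps": n})
    return pd.DataFrame(rows).set_index("sample_id")
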