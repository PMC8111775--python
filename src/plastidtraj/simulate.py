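"""Synthetic leaf-gradient experiment with planted ground truth.

Every input stream of the pipeline is generated jointly and consistently:
an ordered 15-sample design; per-cell microscopy records whose plastid
counts follow a planted schedule of cumulative organelle division rounds
(diluted by the planted cell-division schedule); flow-cytometry cell-cycle
fractions declining from a fully cycling meristem; qPCR standards and
unknowns drawn from planted plastid-genome copy ratios through realistic
amplification efficiencies; 16S/18S rRNA quantities; and a count matrix
in which dynamically expressed genes follow module-specific Gaussian
bumps on the cell-age axis with negative-binomial replicate noise, plus
planted regulator→target dependencies.

The generator's defaults are the study conditions: 15 samples, 3
replicates, 48 cells per sample, ≥10,000 nuclei per cytometry run, an
S-phase fraction of 0.30 at the meristem, 12 expression modules, 4.5
total organelle division rounds, and qPCR standards spanning four orders
of magnitude (25 → 0.0025 pg/μl).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import make_column
from .gradient import (
    DEFAULT_S_FLOOR,
    correction_factor,
    default_sample_frame,
)
from .trajectory import detect_phases

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ExperimentData",
    "generate_experiment",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

_AMPLICON_INTERCEPTS = {"rbcL": 21.5, "ndhD": 21.9, "rps7": 21.2, "TaKO1": 23.6, "TaKS": 23.9}
_REGULATOR_PEAKS = {
    "REG01": 4, "REG02": 11, "REG03": 8, "REG04": 2, "REG05": 5,
    "REG06": 7, "REG07": 9, "REG08": 13, "REG09": 15, "REG10": 6,
}
_NEGATIVE_REGULATORS = ("REG09", "REG10")
_MODULE_CLASSES = [
    "cell_cycle", "hormone", "cytosolic_ribosome", "mitochondrion",
    "cell_wall", "protein_import", "plastid_ribosome", "tetrapyrrole",
    "photosystem", "carbon_fixation", "photorespiration", "senescence",
]
_PLASTID_CLASSES = {
    "protein_import", "plastid_ribosome", "tetrapyrrole",
    "photosystem", "carbon_fixation", "photorespiration",
}

# substream offsets: adding a table never perturbs the others
_STREAMS = {"cells": 1, "cycle": 2, "qpcr": 3, "rrna": 4, "expr": 5, "lib": 6, "annot": 7}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_samples: int = 15
    n_replicates: int = 3
    n_genes: int = 600
    n_modules: int = 12
    module_peak_samples: tuple[int, ...] | None = None
    nb_dispersion: float = 50.0
    n_cells_per_sample: int = 48
    s_phase_start: float = 0.30
    organelle_rounds_total: float = 4.5
    biphasic_params: tuple[float, float, float] = (3.0, 8.0, 11.0)
    qpcr_efficiencies: dict = field(
        default_factory=lambda: {a: 0.95 for a in _AMPLICON_INTERCEPTS}
    )
    standard_range: tuple[float, float] = (25.0, 0.0025)
    planted_edges: tuple[tuple[str, str, float], ...] | None = None
    dynamic_fraction: float = 0.6
    microscopy_cv: float = 0.15
    cq_noise_sd: float = 0.15
    module_width_days: float = 0.35
    mature_age_days: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples != 15:
            raise ConfigurationError("n_samples: the sampling design is fixed at 15")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be ≥ 1")
        if self.n_genes < self.n_modules:
            raise ConfigurationError("n_genes must be ≥ n_modules")
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be ≥ 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not (0.0 <= self.s_phase_start <= 1.0):
            raise ConfigurationError("s_phase_start must lie in [0, 1]")
        if self.n_cells_per_sample < 5:
            raise ConfigurationError("n_cells_per_sample must be ≥ 5")
        peaks = self.peak_samples
        if any(not (1 <= p <= self.n_samples) for p in peaks):
            raise ConfigurationError("module_peak_samples must lie within [1, n_samples]")
        if len(peaks) != self.n_modules:
            raise ConfigurationError("module_peak_samples must list one peak per module")
        hi, lo = self.standard_range
        if not (hi > lo > 0):
            raise ConfigurationError("standard_range must satisfy max > min > 0")
        if self.dynamic_fraction <= 0 or self.dynamic_fraction > 1:
            raise ConfigurationError("dynamic_fraction must lie in (0, 1]")
        if self.microscopy_cv < 0:
            raise ConfigurationError("microscopy_cv must be ≥ 0")

    @property
    def peak_samples(self) -> tuple[int, ...]:
        if self.module_peak_samples is not None:
            return tuple(self.module_peak_samples)
        # staggered peaks covering the full gradient, early-weighted
        defaults = (1, 2, 3, 4, 5, 6, 7, 8, 9, 11, 13, 15)
        if self.n_modules == 12:
            return defaults
        return tuple(
            int(round(p)) for p in np.linspace(1, self.n_samples, self.n_modules)
        )

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["module_peak_samples"] = list(self.peak_samples)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Planted quantities every downstream stage is tested against."""

    gene_modules: dict
    dynamic_genes: list
    flat_genes: list
    regulators: list
    edges: list
    s_fractions: list
    cell_division_rounds: list  # cumulative log2 doublings per sample
    organelle_rounds: list  # cumulative organelle division rounds per sample
    organelle_rounds_total: float
    plastid_counts: list
    plastid_areas: list
    cell_areas: list
    total_plastid_area: list
    growth_rates: list  # true corrected log2 area fold per day, per transition
    phase_boundary_transition: int  # upstream sample id of the trough transition
    phase_boundary_sample: int
    cpdna_ratio: list
    rrna_ratio: list
    module_peak_samples: dict
    seed: int
    config_hash: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        payload = dict(payload)
        payload["gene_modules"] = dict(payload["gene_modules"])
        payload["module_peak_samples"] = {
            int(k): int(v) for k, v in payload["module_peak_samples"].items()
        }
        payload["edges"] = [tuple(e) for e in payload["edges"]]
        return cls(**payload)


@dataclass
class ExperimentData:
    """All generated input tables plus the ground truth."""

    samples: pd.DataFrame
    cells: pd.DataFrame
    cell_cycle: pd.DataFrame
    qpcr: pd.DataFrame
    rrna: pd.DataFrame
    counts: pd.DataFrame
    annotations: pd.DataFrame
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# planted trajectories


def _s_fraction_profile(config: SimConfig) -> np.ndarray:
    rel = np.array(
        [1.0, 0.9, 0.267, 0.03, 0.012, 0.008, 0.006, 0.004,
         0.003, 0.003, 0.002, 0.002, 0.002, 0.002]
    )
    return config.s_phase_start * rel


def _division_rounds(f_s: np.ndarray, s_ref: float) -> np.ndarray:
    """Cumulative log2 cell doublings per sample from the planted S fractions."""
    d = [0.0]
    for f in f_s[:-1]:
        c = correction_factor(f, s_ref, floor=DEFAULT_S_FLOOR) if s_ref > 0 else 1.0
        d.append(d[-1] + math.log2(c))
    return np.array(d)


def _organelle_rounds(ages: np.ndarray, config: SimConfig) -> np.ndarray:
    """Cumulative organelle division rounds: logistic rise saturating at the
    configured total by the plastid/chloroplast transition, then a small
    planted decline (the late reduction of plastid numbers)."""
    total = config.organelle_rounds_total
    trough = int(round(config.biphasic_params[1]))
    s = _logistic((ages - 0.7) / 0.25)
    sat_idx = min(trough - 2, len(ages) - 1)  # saturate two samples before the trough
    raw = (s - s[0]) / (s[sat_idx] - s[0])
    rounds = total * np.clip(raw, 0.0, 1.0)
    for i in range(len(ages)):
        sample = i + 1
        if sample > trough:
            rounds[i] = total - 0.03 * (sample - trough)
    return rounds


def _area_profiles(ages: np.ndarray, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Mean individual plastid area and mean cell plan area (μm²) per sample.

    The individual plastid area rises through the proliferation phase,
    plateaus before greening and undergoes a second rapid enlargement; the
    cell area saturates early with a small late second bout of expansion.
    """
    trough = int(round(config.biphasic_params[1]))
    trough_age = ages[trough - 1]
    c1, c2 = trough_age - 1.05, trough_age + 1.25
    plastid = 3.0 + 6.5 * _logistic((ages - c1) / 0.28) + 25.0 * _logistic((ages - c2) / 0.22)
    cell = 200.0 + 2100.0 * _logistic((ages - 1.1) / 0.4) + 450.0 * _logistic((ages - 3.3) / 0.3)
    return plastid, cell


# ---------------------------------------------------------------------------
# per-table generators


def _make_cell_cycle(config: SimConfig, f_s_true: np.ndarray) -> pd.DataFrame:
    rng = _rng(config.seed, "cycle")
    rows = []
    g2_rel = np.array(
        [1.0, 0.95, 0.5, 0.25, 0.15, 0.1, 0.08, 0.06, 0.05, 0.05, 0.04, 0.04, 0.04, 0.04]
    )
    for i, f in enumerate(f_s_true):
        n = int(rng.integers(10000, 16000))
        s_count = rng.binomial(n, f)
        g2_count = rng.binomial(n, 0.14 * g2_rel[i] + 0.02)
        background = rng.binomial(n, 0.02)
        g1_count = n - s_count - g2_count - background
        rows.append(
            {
                "sample_id": i + 1,
                "f_G1": g1_count / n,
                "f_S": s_count / n,
                "f_G2": g2_count / n,
                "n_nuclei": n,
            }
        )
    return pd.DataFrame(rows)


def _make_cells(
    config: SimConfig, n_true: np.ndarray, a_true: np.ndarray, c_true: np.ndarray
) -> pd.DataFrame:
    rng = _rng(config.seed, "cells")
    cv = config.microscopy_cv
    rows = []
    for i in range(config.n_samples):
        for cell in range(config.n_cells_per_sample):
            lam = n_true[i] * math.exp(rng.normal(0.0, cv) - cv**2 / 2)
            count = max(1, int(rng.poisson(lam)))
            area_mult = math.exp(rng.normal(0.0, 0.8 * cv) - (0.8 * cv) ** 2 / 2)
            cell_mult = math.exp(rng.normal(0.0, 1.6 * cv) - (1.6 * cv) ** 2 / 2)
            rows.append(
                {
                    "sample_id": i + 1,
                    "replicate": cell % config.n_replicates + 1,
                    "cell_id": f"S{i + 1:02d}C{cell + 1:03d}",
                    "cell_area": c_true[i] * cell_mult,
                    "plastid_count": count,
                    "mean_plastid_area": a_true[i] * area_mult,
                }
            )
    return pd.DataFrame(rows)


def _make_qpcr(config: SimConfig, ratio_true: np.ndarray) -> pd.DataFrame:
    rng = _rng(config.seed, "qpcr")
    hi, lo = config.standard_range
    ladder = []
    c = hi
    while c >= lo * 0.999:
        ladder.append(c)
        c /= 10.0
    rows = []
    intercepts = {
        amp: base + rng.uniform(-0.3, 0.3) for amp, base in _AMPLICON_INTERCEPTS.items()
    }
    slopes = {
        amp: -1.0 / math.log10(1.0 + config.qpcr_efficiencies.get(amp, 0.95))
        for amp in _AMPLICON_INTERCEPTS
    }
    for amp in _AMPLICON_INTERCEPTS:
        for conc in ladder:
            for tech in (1, 2):
                cq = intercepts[amp] + slopes[amp] * math.log10(conc)
                rows.append(
                    {
                        "amplicon": amp,
                        "role": "standard",
                        "concentration": conc,
                        "sample_id": np.nan,
                        "biological_replicate": np.nan,
                        "technical_replicate": tech,
                        "dilution_factor": 1.0,
                        "cq": cq + rng.normal(0.0, config.cq_noise_sd),
                    }
                )
    q_nuc_sample = 1.5 * np.exp(rng.normal(0.0, 0.15, size=config.n_samples))
    for i in range(config.n_samples):
        for bio in (1, 2, 3):
            bio_mult = math.exp(rng.normal(0.0, 0.05))
            q_nuc = q_nuc_sample[i] * bio_mult
            quantities = {
                "TaKO1": (q_nuc, 10.0),
                "TaKS": (q_nuc, 10.0),
                "rbcL": (ratio_true[i] * q_nuc, 100.0),
                "ndhD": (ratio_true[i] * q_nuc, 100.0),
                "rps7": (2.0 * ratio_true[i] * q_nuc, 100.0),
            }
            for amp, (quantity, dilution) in quantities.items():
                diluted = quantity / dilution
                for tech in (1, 2):
                    cq = intercepts[amp] + slopes[amp] * math.log10(diluted)
                    rows.append(
                        {
                            "amplicon": amp,
                            "role": "unknown",
                            "concentration": np.nan,
                            "sample_id": i + 1,
                            "biological_replicate": bio,
                            "technical_replicate": tech,
                            "dilution_factor": dilution,
                            "cq": cq + rng.normal(0.0, config.cq_noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


def _make_rrna(config: SimConfig, rrna_true: np.ndarray) -> pd.DataFrame:
    rng = _rng(config.seed, "rrna")
    rows = []
    for i in range(config.n_samples):
        for prep in range(1, 5):
            q18 = 120.0 * math.exp(rng.normal(0.0, 0.15))
            q16 = rrna_true[i] * q18 * math.exp(rng.normal(0.0, 0.08))
            rows.append({"sample_id": i + 1, "replicate": prep, "q16S": q16, "q18S": q18})
    return pd.DataFrame(rows)


def _gene_names(config: SimConfig) -> tuple[list[str], list[str]]:
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    regulators = list(_REGULATOR_PEAKS)
    return genes, regulators


def _default_edges(
    config: SimConfig, module_of_peak: dict, dynamic: list[str], gene_module: dict
) -> list[tuple[str, str, float]]:
    """Two active regulators, six plastid-phase and six chloroplast-phase
    targets, unit effect size (regulator amplitude ≈ 1 profile sd)."""
    edges = []
    for reg in ("REG01", "REG02"):
        peak = _REGULATOR_PEAKS[reg]
        module = module_of_peak.get(peak)
        members = [g for g in dynamic if gene_module[g] == module]
        for target in members[:6]:
            edges.append((reg, target, 1.0))
    return edges


def _make_expression(
    config: SimConfig, ages: np.ndarray
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rng = _rng(config.seed, "expr")
    lib_rng = _rng(config.seed, "lib")
    genes, regulators = _gene_names(config)
    peaks = config.peak_samples
    module_of_peak = {p: m + 1 for m, p in enumerate(peaks)}

    n_dynamic = int(round(config.dynamic_fraction * config.n_genes))
    dynamic = genes[:n_dynamic]
    flat = genes[n_dynamic:]
    gene_module = {g: (i % config.n_modules) + 1 for i, g in enumerate(dynamic)}

    if config.planted_edges is not None:
        edges = [tuple(e) for e in config.planted_edges]
    else:
        edges = _default_edges(config, module_of_peak, dynamic, gene_module)
    edge_targets = {t: (r, eff) for r, t, eff in edges}

    module_amp = {m + 1: rng.uniform(0.85, 1.2) for m in range(config.n_modules)}
    reg_shapes: dict[str, np.ndarray] = {}
    profiles = {}

    def bump(center_age: float, sigma: float) -> np.ndarray:
        return np.exp(-((ages - center_age) ** 2) / (2.0 * sigma**2))

    for reg in regulators:
        center = ages[_REGULATOR_PEAKS[reg] - 1]
        sigma = config.module_width_days * rng.uniform(0.9, 1.15)
        shape = bump(center, sigma)
        reg_shapes[reg] = shape
        base = 12.0 * math.exp(rng.normal(0.0, 0.2))
        fold = rng.uniform(4.0, 6.0)
        profiles[reg] = base * (1.0 + (fold - 1.0) * shape)

    for g in dynamic:
        base = math.exp(rng.normal(math.log(10.0), 0.4))
        fold = max(2.8, math.exp(rng.normal(math.log(4.0), 0.3)))
        module = gene_module[g]
        if g in edge_targets:
            reg, effect = edge_targets[g]
            shape = reg_shapes[reg]
            amp = base * (fold - 1.0) * effect
        else:
            center = ages[peaks[module - 1] - 1]
            sigma = config.module_width_days * rng.uniform(0.85, 1.25)
            shape = bump(center, sigma)
            amp = base * (fold - 1.0) * module_amp[module]
        profiles[g] = base + amp * shape

    for g in flat:
        level = math.exp(rng.normal(math.log(50.0), 0.5))
        profiles[g] = np.full(config.n_samples, level)

    all_genes = list(profiles)
    mean_rpm = np.vstack([profiles[g] for g in all_genes])
    background = 1e6 - mean_rpm.sum(axis=0)
    if np.any(background <= 0):
        raise ConfigurationError(
            "n_genes: planted expression exceeds the library; reduce n_genes"
        )

    k = config.nb_dispersion
    columns, data = [], []
    for s in range(1, config.n_samples + 1):
        for r in range(1, config.n_replicates + 1):
            lib = 1e6 * math.exp(lib_rng.normal(0.0, 0.2))
            mu = mean_rpm[:, s - 1] * lib / 1e6
            if k > 1e8:
                counts = rng.poisson(mu)
            else:
                counts = rng.negative_binomial(k, k / (k + mu))
            mu_bg = background[s - 1] * lib / 1e6
            counts = np.append(counts, rng.poisson(mu_bg))
            columns.append(make_column(s, r))
            data.append(counts)
    counts_df = pd.DataFrame(
        np.column_stack(data), index=all_genes + ["BACKGROUND"], columns=columns
    )
    counts_df.index.name = "gene"

    ann_rng = _rng(config.seed, "annot")
    class_rows = []
    for g in all_genes + ["BACKGROUND"]:
        if g == "BACKGROUND":
            cls, plastid = "background", False
        elif g in regulators:
            cls, plastid = "transcription_factor", False
        elif g in edge_targets:
            cls = _MODULE_CLASSES[(gene_module[g] - 1) % len(_MODULE_CLASSES)]
            plastid = True
        elif g in gene_module:
            module = gene_module[g]
            if ann_rng.uniform() < 0.7:
                cls = _MODULE_CLASSES[(module - 1) % len(_MODULE_CLASSES)]
            else:
                cls = _MODULE_CLASSES[int(ann_rng.integers(len(_MODULE_CLASSES)))]
            plastid = cls in _PLASTID_CLASSES or ann_rng.uniform() < 0.1
        else:
            cls = "housekeeping"
            plastid = ann_rng.uniform() < 0.05
        class_rows.append(
            {
                "gene": g,
                "functional_class": cls,
                "plastid_localized": bool(plastid),
                "is_regulator": g in regulators,
                "regulator_sign": (
                    ("negative" if g in _NEGATIVE_REGULATORS else "positive")
                    if g in regulators
                    else ""
                ),
            }
        )
    annotations = pd.DataFrame(class_rows)

    truth = {
        "gene_modules": gene_module,
        "dynamic_genes": dynamic,
        "flat_genes": flat,
        "regulators": regulators,
        "edges": edges,
        "module_peak_samples": {m + 1: peaks[m] for m in range(config.n_modules)},
    }
    return counts_df, annotations, truth


# ---------------------------------------------------------------------------
# top level


def generate_experiment(config: SimConfig | None = None) -> ExperimentData:
    """Generate all input tables plus ground truth for one experiment."""
    config = config or SimConfig()
    config.validate()

    samples = default_sample_frame(mature_age_days=config.mature_age_days)
    ages = samples["age_days"].to_numpy()

    f_s_true = _s_fraction_profile(config)
    division_rounds = _division_rounds(f_s_true, f_s_true[0] if f_s_true[0] > 0 else 1.0)
    division_rounds = np.append(division_rounds, division_rounds[-1])  # mature sample
    organelle_rounds = _organelle_rounds(ages, config)
    n_true = 12.0 * 2.0 ** (organelle_rounds - division_rounds)
    a_true, c_true = _area_profiles(ages, config)
    area_total = n_true * a_true

    # true corrected growth-rate series over the adjacent samples 1..14
    factors = [
        correction_factor(f, f_s_true[0], floor=DEFAULT_S_FLOOR) for f in f_s_true[:-1]
    ]
    g_true = [
        math.log2(area_total[i + 1] * factors[i] / area_total[i]) / (ages[i + 1] - ages[i])
        for i in range(len(f_s_true) - 1)
    ]
    split = detect_phases(g_true, smooth=True)
    boundary_transition = split.transition + 1  # 1-based upstream sample id

    cell_cycle = _make_cell_cycle(config, f_s_true)
    cells = _make_cells(config, n_true, a_true, c_true)

    ratio_true = 4.0 + 150.0 * _logistic((ages - 1.6) / 0.45)
    ratio_true[-1] *= 0.5  # final loss of ~50% of cpDNA in the mature blade
    qpcr = _make_qpcr(config, ratio_true)

    rrna_true = 0.004 + 0.30 * _logistic((ages - 1.6) / 0.4)
    rrna = _make_rrna(config, rrna_true)

    counts, annotations, expr_truth = _make_expression(config, ages)

    truth = GroundTruth(
        s_fractions=list(f_s_true),
        cell_division_rounds=list(division_rounds),
        organelle_rounds=list(organelle_rounds),
        organelle_rounds_total=config.organelle_rounds_total,
        plastid_counts=list(n_true),
        plastid_areas=list(a_true),
        cell_areas=list(c_true),
        total_plastid_area=list(area_total),
        growth_rates=list(g_true),
        phase_boundary_transition=int(boundary_transition),
        phase_boundary_sample=int(boundary_transition),
        cpdna_ratio=list(ratio_true),
        rrna_ratio=list(rrna_true),
        seed=config.seed,
        config_hash=config.hash(),
        **expr_truth,
    )
    return ExperimentData(
        samples=samples,
        cells=cells,
        cell_cycle=cell_cycle,
        qpcr=qpcr,
        rrna=rrna,
        counts=counts,
        annotations=annotations,
        ground_truth=truth,
    )


_TABLES = ["samples", "cells", "cell_cycle", "qpcr", "rrna", "counts", "annotations"]


def write_fixture_bundle(data: ExperimentData, directory: str | Path) -> dict:
    """Write one TSV per table plus JSON ground truth and manifest.

    Floats are serialized with a fixed format so a fixed seed yields a
    byte-identical bundle.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in _TABLES:
        table: pd.DataFrame = getattr(data, name)
        path = directory / f"{name}.tsv"
        table.to_csv(
            path, sep="\t", index=(name == "counts"), float_format="%.10g",
            lineterminator="\n",
        )
        files[name] = path.name
    gt_path = directory / "ground_truth.json"
    gt_path.write_text(json.dumps(data.ground_truth.to_dict(), sort_keys=True, indent=1))
    manifest = {
        "seed": data.ground_truth.seed,
        "config_hash": data.ground_truth.config_hash,
        "tables": files,
        "ground_truth": gt_path.name,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def read_fixture_bundle(directory: str | Path) -> ExperimentData:
    """Read a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    tables = {}
    for name, filename in manifest["tables"].items():
        index_col = 0 if name == "counts" else None
        tables[name] = pd.read_csv(directory / filename, sep="\t", index_col=index_col)
    truth = GroundTruth.from_dict(
        json.loads((directory / manifest["ground_truth"]).read_text())
    )
    return ExperimentData(ground_truth=truth, **tables)
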