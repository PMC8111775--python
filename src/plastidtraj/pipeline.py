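"""End-to-end runs: stage orchestration, report, and output bundle.

A run reads a fixture bundle (or generates one in memory), executes the
requested stages in dependency order and writes one TSV per result table
plus a JSON report validated against the packaged schema.  Reruns with
the same configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
from pydantic import BaseModel

from . import __version__
from .errors import ArgumentError, DependencyError, PlastidTrajError
from .expression import (
    cluster_modules,
    dyg_filter,
    enrich,
    expressed_filter,
    pca_map,
    rpm_normalize,
    sample_means,
    zscore,
)
from .gradient import DEFAULT_S_FLOOR
from .network import assemble_targets, rank_regulators, summarize_by_phase
from .qpcr import cpdna_ratio_by_sample, quantify_samples, rrna_ratio_by_sample
from .simulate import ExperimentData, SimConfig, generate_experiment, read_fixture_bundle
from .trajectory import compute_trajectory

log = logging.getLogger("plastidtraj")

_ALL_STAGES = ("trajectory", "copynumber", "expression", "network")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either ``bundle_dir`` points at a fixture bundle on disk or the run
    generates one in memory from ``SimConfig(seed=seed)``.  All numeric
    conventions are surfaced here rather than hard-coded.
    """

    out_dir: str | Path = "plastidtraj_run"
    bundle_dir: str | Path | None = None
    stages: tuple[str, ...] = _ALL_STAGES
    seed: int = 0
    s_floor: float = DEFAULT_S_FLOOR
    soft_power: float = 14.0
    n_modules: int = 12
    n_trees: int = 1000
    smooth_rates: bool = True
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ArgumentError(f"unknown run-config keys: {sorted(unknown)}")
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "bundle_dir", "overwrite"):
            payload.pop(key)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class Report(BaseModel):
    """Schema of the combined run report."""

    package_version: str
    seed: int
    run_config_hash: str
    data_config_hash: str
    stages: List[str]
    transition_sample: Optional[int] = None
    cumulative_division_rounds: Optional[float] = None
    phase_labels: Optional[Dict[int, str]] = None
    cpdna_ratio: Optional[Dict[int, float]] = None
    rrna_ratio: Optional[Dict[int, float]] = None
    n_expressed: Optional[int] = None
    n_dyg: Optional[int] = None
    n_modules: Optional[int] = None
    module_peak_samples: Optional[Dict[int, int]] = None
    pca_variance_pct: Optional[List[float]] = None
    n_targets: Optional[int] = None
    top_regulator_by_phase: Optional[Dict[str, str]] = None


def _round(value: float, digits: int = 10) -> float:
    return round(float(value), digits)


def run_pipeline(config: RunConfig, data: ExperimentData | None = None) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns the validated report as a plain dict.  Existing outputs are
    never overwritten silently: a populated output directory requires
    ``overwrite=True``.
    """
    stages = list(config.stages)
    for s in stages:
        if s not in _ALL_STAGES:
            raise ArgumentError(f"unknown stage {s!r}")
    if "network" in stages and "expression" not in stages:
        raise DependencyError("network stage requires the expression stage")
    if "network" in stages and "trajectory" not in stages:
        raise DependencyError("network stage requires the trajectory stage")

    out = Path(config.out_dir)
    report_path = out / "report.json"
    if report_path.exists() and not config.overwrite:
        raise PlastidTrajError(f"output {report_path} exists; pass overwrite to replace")
    out.mkdir(parents=True, exist_ok=True)

    if data is None:
        if config.bundle_dir is not None:
            data = read_fixture_bundle(config.bundle_dir)
        else:
            data = generate_experiment(SimConfig(seed=config.seed))

    payload: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "run_config_hash": config.hash(),
        "data_config_hash": data.ground_truth.config_hash,
        "stages": stages,
    }

    def _write(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=index, float_format="%.10g")

    trajectory_result = None
    if "trajectory" in stages:
        t0 = time.perf_counter()
        trajectory_result = compute_trajectory(
            data.cells, data.cell_cycle, data.samples,
            s_floor=config.s_floor, smooth=config.smooth_rates,
        )
        _write("trajectory_summary", trajectory_result["summary"])
        _write("trajectory_transitions", trajectory_result["transitions"], index=False)
        payload["transition_sample"] = int(trajectory_result["transition_sample"])
        payload["cumulative_division_rounds"] = _round(
            trajectory_result["plastid_phase_division_rounds"]
        )
        payload["phase_labels"] = {
            int(s): p for s, p in trajectory_result["summary"]["phase"].items()
        }
        log.info("trajectory stage done in %.2fs", time.perf_counter() - t0)

    if "copynumber" in stages:
        t0 = time.perf_counter()
        quantities = quantify_samples(data.qpcr)
        cpdna = cpdna_ratio_by_sample(quantities)
        rrna = rrna_ratio_by_sample(data.rrna)
        _write("qpcr_quantities", quantities, index=False)
        _write("cpdna_ratio", cpdna)
        _write("rrna_ratio", rrna)
        payload["cpdna_ratio"] = {
            int(s): _round(v) for s, v in cpdna["cpdna_per_genome"].items()
        }
        payload["rrna_ratio"] = {int(s): _round(v) for s, v in rrna["rrna_ratio"].items()}
        log.info("copynumber stage done in %.2fs", time.perf_counter() - t0)

    modules = None
    dyg_genes: list = []
    rpm = None
    if "expression" in stages:
        t0 = time.perf_counter()
        rpm = rpm_normalize(data.counts)
        background = data.annotations.loc[
            data.annotations["functional_class"] == "background", "gene"
        ]
        rpm = rpm.drop(index=[g for g in background if g in rpm.index])
        expressed = expressed_filter(rpm)
        stats = dyg_filter(rpm.loc[expressed])
        dyg_genes = list(stats.index)
        z = zscore(sample_means(rpm.loc[dyg_genes]))
        modules = cluster_modules(z, soft_power=config.soft_power, n_modules=config.n_modules)
        pca = pca_map(rpm.loc[expressed])
        classes = data.annotations.set_index("gene")["functional_class"]
        enr_rows = []
        universe = dyg_genes
        for m in sorted(modules.peaks):
            members = modules.genes_in(m)
            for cls in sorted(classes.loc[universe].unique()):
                cls_genes = [g for g in universe if classes.loc[g] == cls]
                res = enrich(members, cls_genes, universe)
                enr_rows.append(
                    {
                        "module": m,
                        "functional_class": cls,
                        "overlap": res.overlap,
                        "expected": res.expected,
                        "neg_log10_p_over": res.neg_log10_over,
                        "neg_log10_p_under": res.neg_log10_under,
                    }
                )
        _write("dyg_stats", stats)
        module_table = modules.modules.to_frame()
        module_table["peak_sample"] = [modules.peaks[m] for m in modules.modules]
        _write("modules", module_table)
        _write("enrichment", pd.DataFrame(enr_rows), index=False)
        _write("pca_scores", pca.scores)
        _write("pca_loadings", pca.loadings)
        payload["n_expressed"] = int(len(expressed))
        payload["n_dyg"] = int(len(dyg_genes))
        payload["n_modules"] = int(len(modules.peaks))
        payload["module_peak_samples"] = {int(m): int(p) for m, p in modules.peaks.items()}
        payload["pca_variance_pct"] = [_round(v, 6) for v in pca.variance_pct[:5]]
        log.info("expression stage done in %.2fs", time.perf_counter() - t0)

    if "network" in stages:
        t0 = time.perf_counter()
        assert modules is not None and trajectory_result is not None and rpm is not None
        flags = data.annotations.set_index("gene")["plastid_localized"]
        regulators = sorted(data.annotations.loc[data.annotations["is_regulator"], "gene"])
        targets = assemble_targets(dyg_genes, flags, regulators)
        zrep = zscore(rpm.loc[sorted(set(targets) | set(regulators))])
        ranking = rank_regulators(
            zrep, targets, regulators, n_trees=config.n_trees, seed=config.seed
        )
        ts = payload["transition_sample"]
        module_phases = {
            m: ("plastid" if p < ts else "transition" if p == ts else "chloroplast")
            for m, p in modules.peaks.items()
        }
        phase_summary = summarize_by_phase(ranking, modules.modules, module_phases)
        _write("network_weights", ranking.weights)
        _write("network_ranks", ranking.ranks)
        _write("network_phase_summary", phase_summary)
        payload["n_targets"] = int(len(targets))
        payload["top_regulator_by_phase"] = {
            str(phase): str(row.idxmax()) for phase, row in phase_summary.iterrows()
        }
        log.info("network stage done in %.2fs", time.perf_counter() - t0)

    report = Report(**payload)
    report_json = json.dumps(report.model_dump(), sort_keys=True, indent=1)
    report_path.write_text(report_json)
    (out / "report_schema.json").write_text(
        json.dumps(Report.model_json_schema(), sort_keys=True, indent=1)
    )
    manifest = {
        "report_sha256": hashlib.sha256(report_json.encode()).hexdigest(),
        "package_version": __version__,
        "seed": config.seed,
        "run_config_hash": config.hash(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return report.model_dump()
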