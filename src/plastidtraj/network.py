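"""Tree-ensemble ranking of candidate regulators of chloroplast genes.

For every target gene (a dynamically expressed gene encoding a
plastid-localized protein) an ensemble of regression trees predicts the
target's expression profile from the profiles of the candidate
regulators; the total impurity reduction credited to each regulator,
normalized to sum to one per target, is its importance weight.  This is
the random-forest network-ranking scheme popularized for gene regulatory
network inference, applied with a fixed small panel of regulators rather
than genome-wide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ArgumentError, PlastidTrajError

__all__ = ["assemble_targets", "rank_regulators", "RankingMatrix", "summarize_by_phase"]


def assemble_targets(dyg_genes, plastid_flags, regulators) -> list:
    """Targets = dynamically expressed genes flagged plastid-localized,
    with the regulators themselves excluded."""
    if plastid_flags is None or len(plastid_flags) == 0:
        raise ArgumentError("no plastid-localization flags provided")
    flags = pd.Series(plastid_flags)
    flagged = set(flags.index[flags.astype(bool)])
    targets = sorted((set(dyg_genes) & flagged) - set(regulators))
    if not targets:
        raise PlastidTrajError("no targets: empty intersection of DYGs and plastid flags")
    return targets


@dataclass(frozen=True)
class RankingMatrix:
    """Importance weights (targets × regulators) with per-target ranks.

    ``no_signal`` flags targets whose profile was constant — their weight
    row is all zero (absolute lack of predicted regulatory association).
    ``ranks`` holds 1 = strongest per target among nonzero weights; zero
    weights are unranked (NaN).
    """

    weights: pd.DataFrame
    ranks: pd.DataFrame
    no_signal: pd.Series


def _target_seed(seed: int, target: str) -> int:
    digest = hashlib.sha256(f"{seed}:{target}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rank_regulators(
    expression: pd.DataFrame,
    targets,
    regulators,
    n_trees: int = 1000,
    max_features: str | float = "sqrt",
    seed: int = 0,
) -> RankingMatrix:
    """Random-forest importance of each regulator for each target.

    ``expression`` holds genes in rows and observations (replicate
    samples, ideally Z-scored) in columns.  A regulator that is also the
    current target is excluded from its own predictor set.  Results are
    deterministic under a fixed seed: each target's forest is seeded from
    a stable hash of (seed, target), so regulator column order and target
    order do not affect the weights.
    """
    regulators = list(regulators)
    if len(regulators) < 2:
        raise ArgumentError("need at least 2 candidate regulators")
    if expression.shape[1] < 5:
        raise ArgumentError("need at least 5 observations per gene")
    missing = [g for g in list(targets) + regulators if g not in expression.index]
    if missing:
        raise ArgumentError(f"genes absent from expression matrix: {missing[:5]}")
    weights = pd.DataFrame(0.0, index=list(targets), columns=regulators)
    no_signal = pd.Series(False, index=list(targets), name="no_signal")
    for target in targets:
        y = expression.loc[target].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            no_signal.loc[target] = True
            continue
        # canonical predictor order: the fit does not depend on the
        # caller's regulator column order
        preds = sorted(str(r) for r in regulators if r != target)
        X = expression.loc[preds].to_numpy(dtype=float).T
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=_target_seed(seed, str(target)),
            n_jobs=1,
        )
        forest.fit(X, y)
        imp = forest.feature_importances_
        total = imp.sum()
        if total <= 0:
            no_signal.loc[target] = True
            continue
        weights.loc[target, preds] = imp / total
    ranks = weights.where(weights > 0).rank(axis=1, ascending=False, method="first")
    return RankingMatrix(weights=weights, ranks=ranks, no_signal=no_signal)


def summarize_by_phase(
    ranking: RankingMatrix, gene_modules: pd.Series, module_phases: dict
) -> pd.DataFrame:
    """Mean normalized importance of each regulator per build-up phase.

    Each target is mapped to a phase through its co-expression module;
    a target without a module label, or a module without a phase, is an
    error rather than being silently dropped.
    """
    modules = pd.Series(gene_modules)
    phases = []
    for target in ranking.weights.index:
        if target not in modules.index:
            raise ArgumentError(f"target {target!r} has no module assignment")
        module = modules.loc[target]
        if module not in module_phases:
            raise ArgumentError(f"module {module!r} has no phase label")
        phases.append(module_phases[module])
    grouped = ranking.weights.groupby(pd.Series(phases, index=ranking.weights.index))
    return grouped.mean()
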