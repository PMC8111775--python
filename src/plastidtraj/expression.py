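"""Transcriptome map of the leaf gradient.

Counts are normalized to reads per million (RPM).  Genes expressed at
RPM ≥ 1 in all replicates of at least one sample form the expressed set;
dynamically expressed genes (DYGs) additionally satisfy, on the
replicate-averaged sample profile, max RPM ≥ 5, fold change
(max/min) ≥ 2 and coefficient of variation ≥ 0.2.  Z-scored DYG profiles
are clustered into co-expression modules with a weighted correlation
network (soft-thresholded adjacency, topological overlap, average-linkage
tree cut), and modules are numbered by the timing of their expression
peak along the gradient.  Functional-class enrichment of modules uses the
hypergeometric test in both directions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.decomposition import PCA

from .errors import ArgumentError, PlastidTrajError

__all__ = [
    "rpm_normalize",
    "expressed_filter",
    "dyg_filter",
    "zscore",
    "sample_means",
    "pca_map",
    "PCAMap",
    "cluster_modules",
    "ModuleAssignment",
    "enrich",
    "EnrichmentResult",
    "peak_sample",
    "column_layout",
    "make_column",
]

_COLUMN_RE = re.compile(r"^S(\d+)R(\d+)$")


def make_column(sample: int, replicate: int) -> str:
    """Canonical replicate column name, e.g. sample 3 rep 1 → ``S03R1``."""
    return f"S{sample:02d}R{replicate}"


def column_layout(matrix: pd.DataFrame) -> tuple[list[int], list[int]]:
    """Samples and replicates encoded in ``S{sample}R{rep}`` column names."""
    samples, reps = set(), set()
    for col in matrix.columns:
        m = _COLUMN_RE.match(str(col))
        if not m:
            raise ArgumentError(f"column {col!r} does not match S<sample>R<replicate>")
        samples.add(int(m.group(1)))
        reps.add(int(m.group(2)))
    return sorted(samples), sorted(reps)


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization: count / replicate library × 10⁶."""
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ArgumentError("counts must be non-negative")
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ArgumentError(f"replicate {counts.columns[zero[0]]!r} has a zero library")
    return counts.astype(float) / totals * 1e6


def expressed_filter(rpm: pd.DataFrame) -> pd.Index:
    """Genes with RPM ≥ 1 in all replicates of at least one sample."""
    samples, reps = column_layout(rpm)
    keep = np.zeros(len(rpm), dtype=bool)
    for s in samples:
        cols = [make_column(s, r) for r in reps if make_column(s, r) in rpm.columns]
        keep |= (rpm[cols].to_numpy() >= 1.0).all(axis=1)
    return rpm.index[keep]


def sample_means(rpm: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged RPM per sample (genes × samples)."""
    samples, reps = column_layout(rpm)
    out = {}
    for s in samples:
        cols = [make_column(s, r) for r in reps if make_column(s, r) in rpm.columns]
        out[s] = rpm[cols].mean(axis=1)
    return pd.DataFrame(out)


def dyg_filter(
    rpm: pd.DataFrame,
    min_max_rpm: float = 5.0,
    min_fold: float = 2.0,
    min_cv: float = 0.2,
) -> pd.DataFrame:
    """Dynamically expressed genes on the replicate-averaged profile.

    A gene is kept iff max RPM ≥ 5 and max/min ≥ 2 and CV ≥ 0.2, where the
    CV uses the sample (n−1) standard deviation over the per-sample means.
    A minimum of zero makes the fold change infinite — a gene switched
    fully on or off is maximally dynamic and passes the fold criterion.
    Returns the per-gene statistics table restricted to passing genes.
    """
    means = sample_means(rpm)
    mx = means.max(axis=1)
    mn = means.min(axis=1)
    with np.errstate(divide="ignore"):
        fold = np.where(mn > 0, mx / mn, np.inf)
    mean = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    cv = np.where(mean > 0, sd / mean, 0.0)
    stats = pd.DataFrame(
        {"max_rpm": mx, "min_rpm": mn, "fold_change": fold, "cv": cv}, index=rpm.index
    )
    keep = (stats["max_rpm"] >= min_max_rpm) & (stats["fold_change"] >= min_fold) & (
        stats["cv"] >= min_cv
    )
    return stats[keep]


def zscore(profile, ddof: int = 1):
    """Standardize a profile (or the rows of a genes × samples frame).

    Sample-sd convention (ddof=1); a zero-variance profile is an error —
    it cannot occur for a gene that passed the dynamic filter.
    """
    if isinstance(profile, pd.DataFrame):
        mean = profile.mean(axis=1)
        sd = profile.std(axis=1, ddof=ddof)
        if (sd <= 0).any():
            bad = profile.index[(sd <= 0)][0]
            raise ArgumentError(f"zero-variance profile for {bad!r}")
        return profile.sub(mean, axis=0).div(sd, axis=0)
    x = np.asarray(profile, dtype=float)
    sd = x.std(ddof=ddof)
    if sd <= 0:
        raise ArgumentError("zero-variance profile")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class PCAMap:
    """PCA of replicate expression profiles.

    ``scores`` has one row per replicate column; ``loadings`` one row per
    gene; ``variance_pct`` is the percentage of total variance per
    component; ``top``/``bottom`` hold the 5% of genes with the most
    positive / most negative loading on each component.
    """

    scores: pd.DataFrame
    variance_pct: np.ndarray
    loadings: pd.DataFrame
    top: dict = field(default_factory=dict)
    bottom: dict = field(default_factory=dict)


def pca_map(
    rpm: pd.DataFrame,
    n_components: int | None = None,
    load_fraction: float = 0.05,
    standardize: bool = True,
) -> PCAMap:
    """Principal components of the gene-standardized replicate matrix.

    Observations are the replicate columns (so biological replicates of a
    sample should plot as near-coincident points); variables are genes.
    For each component the top and bottom ``load_fraction`` of genes by
    loading (``ceil`` of the fraction) are returned for enrichment use.
    """
    if rpm.shape[1] < 3:
        raise ArgumentError("PCA needs at least 3 replicate observations")
    X = rpm.to_numpy(dtype=float).T  # observations × genes
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ArgumentError("constant gene rows cannot be standardized for PCA")
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    k = n_components or min(10, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    total_var = X.var(axis=0, ddof=1).sum()
    variance_pct = pca.explained_variance_ / total_var * 100.0
    comps = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(pca.components_.T, index=rpm.index, columns=comps)
    n_load = math.ceil(load_fraction * rpm.shape[0])
    top, bottom = {}, {}
    for c in comps:
        order = loadings[c].sort_values()
        bottom[c] = list(order.index[:n_load])
        top[c] = list(order.index[-n_load:][::-1])
    return PCAMap(
        scores=pd.DataFrame(scores, index=rpm.columns, columns=comps),
        variance_pct=variance_pct,
        loadings=loadings,
        top=top,
        bottom=bottom,
    )


@dataclass(frozen=True)
class ModuleAssignment:
    """Partition of genes into co-expression modules ordered by peak."""

    modules: pd.Series  # gene -> module id (1..k)
    peaks: dict  # module id -> peak sample

    def genes_in(self, module: int) -> list:
        return list(self.modules.index[self.modules == module])


def _topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=0)
    k_min = np.minimum.outer(k, k)
    tom = (l + a) / (k_min + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def cluster_modules(
    zmat: pd.DataFrame,
    soft_power: float = 14.0,
    n_modules: int = 12,
) -> ModuleAssignment:
    """Weighted-correlation-network clustering of Z-scored profiles.

    Unsigned adjacency ``|r|^soft_power`` → topological overlap
    dissimilarity → average-linkage hierarchical clustering, with the tree
    cut at a fixed number of modules.  Modules are relabelled 1..k in
    order of the peak sample of their mean profile (earliest peak first).
    """
    if len(zmat) < 2:
        raise ArgumentError("module clustering needs at least 2 genes")
    if soft_power < 1:
        raise ArgumentError(f"soft power must be ≥ 1, got {soft_power}")
    values = zmat.to_numpy(dtype=float)
    if np.any(values.std(axis=1) <= 0):
        bad = zmat.index[values.std(axis=1) <= 0][0]
        raise ArgumentError(f"constant profile for {bad!r}; run the dynamic filter first")
    corr = np.corrcoef(values)
    adjacency = np.abs(corr) ** soft_power
    diss = 1.0 - _topological_overlap(adjacency)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=n_modules, criterion="maxclust")

    # relabel by peak timing of the module mean profile
    order_keys = []
    for label in np.unique(raw):
        mean_profile = zmat.iloc[raw == label].mean(axis=0)
        order_keys.append((peak_sample(mean_profile), label))
    relabel = {old: new + 1 for new, (_, old) in enumerate(sorted(order_keys))}
    modules = pd.Series([relabel[r] for r in raw], index=zmat.index, name="module")
    peaks = {
        relabel[label]: peak_sample(zmat.iloc[raw == label].mean(axis=0))
        for label in np.unique(raw)
    }
    return ModuleAssignment(modules=modules, peaks=peaks)


@dataclass(frozen=True)
class EnrichmentResult:
    p_over: float
    p_under: float
    overlap: int
    expected: float

    @property
    def neg_log10_over(self) -> float:
        return -math.log10(max(self.p_over, 1e-300))

    @property
    def neg_log10_under(self) -> float:
        return -math.log10(max(self.p_under, 1e-300))


def enrich(module_genes, class_genes, universe) -> EnrichmentResult:
    """Hypergeometric over/under-representation of a class in a module.

    ``p_over`` is the upper-tail probability of an overlap at least as
    large as observed; ``p_under`` the lower tail.  Both are raw
    probabilities (report as −log10 for display).
    """
    uni = set(universe)
    if not uni:
        raise ArgumentError("empty universe")
    mod = set(module_genes)
    cls = set(class_genes)
    if not mod <= uni or not cls <= uni:
        raise ArgumentError("module and class gene sets must lie within the universe")
    M, K, n = len(uni), len(cls), len(mod)
    k = len(mod & cls)
    expected = n * K / M
    p_over = float(hypergeom.sf(k - 1, M, K, n))
    p_under = float(hypergeom.cdf(k, M, K, n))
    return EnrichmentResult(p_over=p_over, p_under=p_under, overlap=k, expected=expected)


def peak_sample(profile: pd.Series):
    """Sample label at which a profile peaks (earliest label on ties)."""
    if len(profile) < 1:
        raise ArgumentError("empty profile")
    values = np.asarray(profile, dtype=float)
    return profile.index[int(np.argmax(values))]
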