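"""Normalization, expression filters, PCA, module clustering, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from plastidtraj.errors import ArgumentError
from plastidtraj.expression import (
    cluster_modules,
    dyg_filter,
    enrich,
    expressed_filter,
    make_column,
    pca_map,
    peak_sample,
    rpm_normalize,
    sample_means,
    zscore,
)
from plastidtraj.simulate import SimConfig, generate_experiment


def _matrix(profiles: dict, n_samples=15, n_reps=3):
    cols = [make_column(s, r) for s in range(1, n_samples + 1) for r in range(1, n_reps + 1)]
    rows = {}
    for gene, profile in profiles.items():
        rows[gene] = np.repeat(np.asarray(profile, dtype=float), n_reps)
    return pd.DataFrame(rows, index=cols).T


class TestRPMNormalize:
    def test_single_gene_library(self):
        counts = pd.DataFrame({"S01R1": [7]}, index=["g1"])
        assert rpm_normalize(counts).iloc[0, 0] == 1e6

    def test_proportions(self):
        counts = pd.DataFrame({"S01R1": [1, 3]}, index=["g1", "g2"])
        rpm = rpm_normalize(counts)
        assert list(rpm["S01R1"]) == [250000.0, 750000.0]

    def test_zero_library_names_replicate(self):
        counts = pd.DataFrame({"S01R1": [1], "S01R2": [0]}, index=["g1"])
        with pytest.raises(ArgumentError, match="S01R2"):
            rpm_normalize(counts)


class TestExpressedFilter:
    def test_boundary_inclusive(self):
        rpm = _matrix({"g1": [0.0] * 15})
        rpm.loc["g1", [make_column(3, r) for r in (1, 2, 3)]] = 1.0
        assert list(expressed_filter(rpm)) == ["g1"]

    def test_one_failing_replicate_drops_gene(self):
        rpm = _matrix({"g1": [5.0] * 15})
        for s in range(1, 16):
            rpm.loc["g1", make_column(s, 3)] = 0.5
        assert len(expressed_filter(rpm)) == 0

    def test_all_zero_dropped(self):
        rpm = _matrix({"g1": [0.0] * 15})
        assert len(expressed_filter(rpm)) == 0

    def test_idempotent(self, rpm):
        kept = expressed_filter(rpm)
        assert list(expressed_filter(rpm.loc[kept])) == list(kept)


class TestDYGFilter:
    def test_flat_profile_dropped(self):
        stats = dyg_filter(_matrix({"g1": [10.0] * 15}))
        assert len(stats) == 0

    def test_low_maximum_dropped_regardless_of_shape(self):
        profile = np.linspace(0.1, 4.9, 15)
        assert len(dyg_filter(_matrix({"g1": profile}))) == 0

    def test_passing_profile(self):
        profile = np.array([4.0] * 13 + [8.0, 10.0])
        stats = dyg_filter(_matrix({"g1": profile}))
        assert list(stats.index) == ["g1"]
        assert stats.loc["g1", "fold_change"] == pytest.approx(2.5)

    def test_zero_minimum_gives_infinite_fold(self):
        profile = np.array([0.0] * 13 + [8.0, 10.0])
        stats = dyg_filter(_matrix({"g1": profile}))
        assert math.isinf(stats.loc["g1", "fold_change"])
        assert list(stats.index) == ["g1"]

    def test_idempotent_and_order_independent(self, rpm):
        first = dyg_filter(rpm)
        again = dyg_filter(rpm.loc[first.index])
        assert list(again.index) == list(first.index)
        shuffled = dyg_filter(rpm.sample(frac=1.0, random_state=0))
        assert set(shuffled.index) == set(first.index)

    def test_planted_dynamic_genes_recovered(self, experiment, rpm):
        stats = dyg_filter(rpm)
        truth = experiment.ground_truth
        dynamic = set(truth.dynamic_genes)
        flat = set(truth.flat_genes)
        got = set(stats.index)
        assert len(got & dynamic) / len(dynamic) >= 0.95
        assert len(got & flat) / len(flat) <= 0.05


class TestZScore:
    def test_two_point_profile_sample_sd_convention(self):
        z = zscore([0.0, 2.0])
        assert z == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_mean_zero_unit_sd(self, rpm):
        z = zscore(sample_means(rpm.head(20)))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert zscore(3.0 * x + 7.0) == pytest.approx(zscore(x))

    def test_constant_profile_rejected(self):
        with pytest.raises(ArgumentError):
            zscore([3.0, 3.0, 3.0])


class TestPCAMap:
    def test_five_percent_load_factor_lists(self):
        rng = np.random.default_rng(0)
        cols = [make_column(s, r) for s in range(1, 6) for r in (1, 2, 3)]
        rpm = pd.DataFrame(
            rng.gamma(2.0, 10.0, size=(1000, len(cols))),
            index=[f"g{i}" for i in range(1000)],
            columns=cols,
        )
        result = pca_map(rpm, n_components=3)
        assert all(len(result.top[c]) == 50 for c in result.top)
        assert all(len(result.bottom[c]) == 50 for c in result.bottom)

    def test_variance_percentages_non_increasing_and_bounded(self, rpm):
        result = pca_map(rpm.head(200))
        assert np.all(np.diff(result.variance_pct) <= 1e-9)
        assert result.variance_pct.sum() <= 100.0 + 1e-6

    def test_duplicated_replicate_scores_coincide(self):
        rng = np.random.default_rng(1)
        cols = [make_column(s, r) for s in range(1, 6) for r in (1, 2)]
        rpm = pd.DataFrame(
            rng.gamma(2.0, 10.0, size=(100, len(cols))),
            index=[f"g{i}" for i in range(100)],
            columns=cols,
        )
        rpm["S06R1"] = rpm["S05R2"]
        rpm["S06R2"] = rpm["S05R2"]
        result = pca_map(rpm, n_components=3)
        gap = result.scores.loc["S06R1"] - result.scores.loc["S06R2"]
        assert np.linalg.norm(gap) < 1e-9

    def test_module_structure_dominates_when_noise_is_small(self):
        # strong planted amplitudes, near-Poisson noise: the first three
        # components carry the bulk of the structured variance
        data = generate_experiment(
            SimConfig(seed=3, dynamic_fraction=0.95, nb_dispersion=1e9)
        )
        rpm = rpm_normalize(data.counts).drop(index="BACKGROUND")
        result = pca_map(rpm.loc[expressed_filter(rpm)])
        assert result.variance_pct[:3].sum() >= 60.0


class TestClusterModules:
    def test_two_anticorrelated_blocks_perfectly_partitioned(self):
        # opposing-peak bumps (negatively correlated blocks); the soft
        # threshold crushes the between-block correlation to zero
        x = np.arange(15.0)
        early = 10.0 * np.exp(-((x - 1.0) ** 2) / 8.0) + 2.0
        late = 10.0 * np.exp(-((x - 13.0) ** 2) / 8.0) + 2.0
        profiles = {f"up{i}": early * (1 + 0.02 * i) for i in range(6)}
        profiles |= {f"dn{i}": late * (1 + 0.02 * i) for i in range(6)}
        z = zscore(sample_means(_matrix(profiles)))
        assignment = cluster_modules(z, soft_power=14, n_modules=2)
        up_modules = {assignment.modules[f"up{i}"] for i in range(6)}
        dn_modules = {assignment.modules[f"dn{i}"] for i in range(6)}
        assert len(up_modules) == 1 and len(dn_modules) == 1
        assert up_modules != dn_modules

    def test_identical_profiles_form_single_cluster(self):
        profile = np.sin(np.linspace(0.0, 3.0, 15)) * 5 + 10
        profiles = {f"g{i}": profile * (1 + 0.001 * i) for i in range(8)}
        z = zscore(sample_means(_matrix(profiles)))
        assignment = cluster_modules(z, n_modules=1)
        assert set(assignment.modules) == {1}

    def test_constant_row_rejected(self):
        z = pd.DataFrame([[0.0] * 15], index=["g1"], columns=range(1, 16))
        with pytest.raises(ArgumentError):
            cluster_modules(pd.concat([z, z.rename(index={"g1": "g2"})]))

    def test_modules_ordered_by_peak_timing(self, experiment, rpm):
        stats = dyg_filter(rpm)
        z = zscore(sample_means(rpm.loc[stats.index]))
        assignment = cluster_modules(z, soft_power=14, n_modules=12)
        peaks = [assignment.peaks[m] for m in sorted(assignment.peaks)]
        assert peaks == sorted(peaks)

    def test_planted_modules_recovered(self, experiment, rpm):
        from sklearn.metrics import adjusted_rand_score

        truth = experiment.ground_truth
        stats = dyg_filter(rpm)
        dygs = [g for g in stats.index if g in truth.gene_modules]
        z = zscore(sample_means(rpm.loc[dygs]))
        assignment = cluster_modules(z, soft_power=14, n_modules=12)
        ari = adjusted_rand_score(
            [truth.gene_modules[g] for g in dygs],
            assignment.modules.loc[dygs].to_numpy(),
        )
        assert ari >= 0.8


class TestEnrich:
    def test_forced_overlap_has_probability_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = enrich(universe, universe, universe)
        assert res.p_over == pytest.approx(1.0)

    def test_exact_combinatorics(self):
        universe = [f"g{i}" for i in range(20)]
        module = universe[:5]
        res = enrich(module, module, universe)
        assert res.p_over == pytest.approx(1.0 / math.comb(20, 5), rel=1e-9)

    def test_depletion_directionality(self):
        universe = [f"g{i}" for i in range(40)]
        module = universe[:20]
        cls = universe[20:40]  # zero overlap, expected overlap 10
        res = enrich(module, cls, universe)
        assert res.p_under < 1e-5
        assert res.p_over == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ArgumentError):
            enrich([], [], [])


class TestPeakSample:
    def test_monotone_profile_peaks_at_last_sample(self):
        profile = pd.Series(np.arange(15.0), index=range(1, 16))
        assert peak_sample(profile) == 15

    def test_tie_resolves_to_earliest(self):
        values = np.zeros(15)
        values[3] = values[8] = 5.0
        assert peak_sample(pd.Series(values, index=range(1, 16))) == 4

    def test_planted_bumps_peak_at_configured_samples(self):
        # near-noiseless generation: every module mean must peak exactly
        # at its configured sample, and the profile must be unimodal
        data = generate_experiment(SimConfig(seed=5, nb_dispersion=1e9))
        rpm = rpm_normalize(data.counts).drop(index="BACKGROUND")
        means = sample_means(rpm)
        truth = data.ground_truth
        planted_targets = {t for _, t, _ in truth.edges}
        for module, peak in truth.module_peak_samples.items():
            members = [
                g
                for g, m in truth.gene_modules.items()
                if m == module and g not in planted_targets
            ]
            profile = means.loc[members].mean(axis=0)
            assert peak_sample(profile) == peak
            # unimodal in sample index up to residual Poisson jitter
            values = profile.to_numpy()
            diffs = np.diff(values)
            diffs[np.abs(diffs) < 0.05 * np.ptp(values)] = 0.0
            signs = np.sign(diffs)
            signs = signs[signs != 0]
            flips = int(np.sum(np.diff(signs) != 0))
            assert flips <= 1
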