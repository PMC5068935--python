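"""Forward simulator: meiosis, phenotype model, cohorts, pooling, arrays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germxqtl import (
    CohortSpec,
    EnvironmentSpec,
    QTLEffect,
    assign_germination_times,
    combine_pools,
    default_cohorts,
    default_map,
    estimate_allele_freq,
    haldane_recombination,
    no_salt_environment,
    pool_allele_frequency,
    salt_environment,
    select_cohorts,
    simulate_f2_population,
    simulate_f3_population,
    simulate_hybridization,
)
from germxqtl.simulate import PoolObservation


class TestHaldane:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 0.0), (50.0, 0.5 * (1 - np.exp(-1.0)))],
    )
    def test_closed_form(self, d, expected):
        assert haldane_recombination(d) == pytest.approx(expected, abs=1e-12)

    def test_independence_limit(self):
        assert haldane_recombination(10_000) > 0.4999

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_recombination(-1.0)

    @given(st.floats(min_value=0, max_value=1e4))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_range_and_monotonicity(self, d):
        r = haldane_recombination(d)
        assert 0.0 <= r <= 0.5
        if d < 1000:  # beyond that 1 - exp(-2d/100) rounds to 1 in float64
            assert r < 0.5
        assert haldane_recombination(d + 1.0) >= r


class TestF3Population:
    def test_empty_population(self, small_map):
        assert simulate_f3_population(small_map, 0, 1).shape == (0, small_map.n_snps)

    def test_mendelian_expectations(self, small_map):
        # freq 0.5 and (after one selfing) heterozygosity 0.25, within 4
        # binomial standard errors of the Mendelian expectation
        n = 2000
        pop = simulate_f3_population(small_map, n, 7)
        freq = pop.mean() / 2
        het = (pop == 1).mean()
        se_freq = np.sqrt(0.5 * 0.5 / (2 * n))
        se_het = np.sqrt(0.25 * 0.75 / n)
        assert abs(freq - 0.5) < 4 * se_freq
        assert abs(het - 0.25) < 4 * se_het

    def test_f2_heterozygosity_is_half(self, small_map):
        pop = simulate_f2_population(small_map, 2000, 3)
        assert abs((pop == 1).mean() - 0.5) < 4 * np.sqrt(0.5 * 0.5 / 2000)

    def test_linkage_decay(self, small_map):
        # dosage correlation decays with map distance; unlinked chromosomes
        # are uncorrelated
        pop = simulate_f3_population(small_map, 1500, 11).astype(float)
        sl = small_map.chrom_slices()["Chr1"]
        base = pop[:, sl.start]

        def corr(j):
            return np.corrcoef(base, pop[:, sl.start + j])[0, 1]

        near, mid, far = corr(2), corr(30), corr(90)
        assert near > mid > far
        other = pop[:, small_map.chrom_slices()["Chr2"].start + 50]
        assert abs(np.corrcoef(base, other)[0, 1]) < 0.1

    def test_determinism(self, small_map):
        a = simulate_f3_population(small_map, 50, 123)
        b = simulate_f3_population(small_map, 50, 123)
        assert np.array_equal(a, b)


class TestGerminationTimes:
    def test_zero_noise_no_qtl_is_baseline(self, small_map):
        env = EnvironmentSpec("e", 40.0, 0.0, 1e9)
        pop = simulate_f3_population(small_map, 10, 1)
        t = assign_germination_times(pop, [], env, small_map, 1)
        assert np.allclose(t, 40.0)

    def test_additive_effect_on_homozygotes(self, small_map):
        env = EnvironmentSpec("salt", 300.0, 0.0, 1e9)
        qtl = QTLEffect("Chr1", 5_000_000, {"salt": -12.0})
        col = np.full((1, small_map.n_snps), 2, dtype=np.int8)
        bs = np.zeros((1, small_map.n_snps), dtype=np.int8)
        t_col = assign_germination_times(col, [qtl], env, small_map, 1)
        t_bs = assign_germination_times(bs, [qtl], env, small_map, 1)
        assert t_col[0] == pytest.approx(288.0)
        assert t_bs[0] == pytest.approx(312.0)

    def test_cryptic_construction(self, small_map):
        # effect map {no_salt: 0, salt: -12}: parents identical without salt,
        # 24 h apart with salt
        qtl = QTLEffect("Chr1", 5_000_000, {"salt": -12.0})
        col = np.full((1, small_map.n_snps), 2, dtype=np.int8)
        bs = np.zeros((1, small_map.n_snps), dtype=np.int8)
        for env_name, expected_gap in (("no_salt", 0.0), ("salt", 24.0)):
            env = EnvironmentSpec(env_name, 100.0, 0.0, 1e9)
            gap = abs(
                assign_germination_times(bs, [qtl], env, small_map, 1)[0]
                - assign_germination_times(col, [qtl], env, small_map, 1)[0]
            )
            assert gap == pytest.approx(expected_gap)

    def test_censoring(self, small_map):
        env = EnvironmentSpec("e", 100.0, 0.0, 50.0)
        pop = simulate_f3_population(small_map, 5, 1)
        t = assign_germination_times(pop, [], env, small_map, 1)
        assert np.all(np.isnan(t))

    def test_qtl_outside_map_rejected(self, small_map):
        env = EnvironmentSpec("e", 100.0, 0.0, 1e9)
        qtl = QTLEffect("Chr9", 1, {"e": 1.0})
        pop = simulate_f3_population(small_map, 2, 1)
        with pytest.raises(ValueError):
            assign_germination_times(pop, [qtl], env, small_map, 1)


class TestCohorts:
    def test_published_percentiles(self):
        # 100 seeds, 23 germinants, bounds (0-.05, .05-.20, .20-.23)
        times = np.full(100, np.nan)
        times[:23] = np.arange(23, dtype=float)
        cohorts = select_cohorts(times, default_cohorts())
        assert [len(cohorts[k]) for k in ("early", "medium", "late")] == [5, 15, 3]

    def test_tie_break_by_id(self):
        times = np.zeros(100)
        times[23:] = np.nan
        cohorts = select_cohorts(times, default_cohorts())
        assert list(cohorts["early"]) == [0, 1, 2, 3, 4]
        assert list(cohorts["late"]) == [20, 21, 22]

    def test_single_full_cohort(self):
        times = np.arange(10, dtype=float)
        spec = CohortSpec(bounds={"all": (0.0, 1.0)})
        assert len(select_cohorts(times, spec)["all"]) == 10

    def test_all_censored_warns_empty(self):
        with pytest.warns(UserWarning):
            cohorts = select_cohorts(np.full(5, np.nan), default_cohorts())
        assert all(len(v) == 0 for v in cohorts.values())

    def test_overlapping_bounds_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(bounds={"a": (0.0, 0.3), "b": (0.2, 0.5)})

    def test_truncation_sign_flip(self, small_map):
        # one speed-reducing Col-0 allele + censoring at the 23rd percentile:
        # early cohort depleted of Col-0, late cohort enriched (mean over 20
        # simulation replicates)
        qtl = QTLEffect("Chr1", 5_000_000, {"salt_250mM": +12.0})
        env = salt_environment()
        idx = small_map.snp_index("Chr1", 5_000_000)
        early, late = [], []
        rng = np.random.default_rng(42)
        for _ in range(20):
            pop = simulate_f3_population(small_map, 2000, rng)
            t = assign_germination_times(pop, [qtl], env, small_map, rng)
            cohorts = select_cohorts(t, default_cohorts())
            early.append(pool_allele_frequency(pop[cohorts["early"]])[idx])
            late.append(pool_allele_frequency(pop[cohorts["late"]])[idx])
        assert np.mean(early) < 0.5 < np.mean(late)

    def test_null_environment_no_deviation(self, small_map):
        # salt-only QTL leaves no-salt cohorts unbiased (within 4 SE)
        qtl = QTLEffect("Chr1", 5_000_000, {"salt_250mM": -12.0})
        env = no_salt_environment()
        idx = small_map.snp_index("Chr1", 5_000_000)
        rng = np.random.default_rng(5)
        devs = []
        for _ in range(5):
            pop = simulate_f3_population(small_map, 2000, rng)
            t = assign_germination_times(pop, [qtl], env, small_map, rng)
            ids = select_cohorts(t, default_cohorts())["early"]
            devs.append(pool_allele_frequency(pop[ids])[idx] - 0.5)
        se = np.sqrt(0.5 * 0.5 / (2 * 100) / 5)
        assert abs(np.mean(devs)) < 4 * se


class TestPooling:
    def test_pool_frequency_examples(self):
        assert pool_allele_frequency(np.full((3, 4), 2)).tolist() == [1.0] * 4
        assert pool_allele_frequency(np.ones((5, 2))).tolist() == [0.5, 0.5]
        assert pool_allele_frequency(np.array([[0], [1], [2], [2]]))[0] == 0.625

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_allele_frequency(np.empty((0, 3)))

    def test_combine_weighted_mean(self):
        a = PoolObservation("a", 5000, freq=np.full(3, 0.6))
        b = PoolObservation("b", 15000, freq=np.full(3, 0.5))
        combined = combine_pools([a, b])
        assert np.allclose(combined.freq, 0.525)
        assert combined.n_individuals == 20000

    def test_combine_identity_and_equal(self):
        a = PoolObservation("a", 10, freq=np.full(4, 0.5))
        assert np.allclose(combine_pools([a]).freq, a.freq)
        b = PoolObservation("b", 99, freq=np.full(4, 0.5))
        assert np.allclose(combine_pools([a, b]).freq, 0.5)

    def test_combine_mismatched_panels_rejected(self):
        a = PoolObservation("a", 10, freq=np.full(4, 0.5))
        b = PoolObservation("b", 10, freq=np.full(5, 0.5))
        with pytest.raises(ValueError):
            combine_pools([a, b])


class TestHybridization:
    def test_noise_free_round_trip(self):
        f = np.array([0.7, 0.25, 0.5])
        obs = simulate_hybridization(f, 1.0, 1.0, 0.0, 1, 1)
        ref = simulate_hybridization(np.full(3, 0.5), 1.0, 1.0, 0.0, 1, 2)
        est = estimate_allele_freq(obs, ref)
        assert np.allclose(np.sort(est["freq"]), np.sort(f))

    def test_probe_affinity_cancels(self):
        f = np.array([0.7, 0.3])
        a_col, a_bs = np.array([3.0, 0.2]), np.array([0.5, 4.0])
        obs = simulate_hybridization(f, a_col, a_bs, 0.0, 1, 1)
        ref = simulate_hybridization(np.full(2, 0.5), a_col, a_bs, 0.0, 1, 2)
        assert np.allclose(np.sort(estimate_allele_freq(obs, ref)["freq"]), np.sort(f))

    def test_dye_gains_cancel(self):
        f = np.array([0.8, 0.4])
        kw = dict(dye_gains=(2.0, 0.5))
        obs = simulate_hybridization(f, 1.0, 1.0, 0.0, 1, 1, **kw)
        ref = simulate_hybridization(np.full(2, 0.5), 1.0, 1.0, 0.0, 1, 2, **kw)
        assert np.allclose(np.sort(estimate_allele_freq(obs, ref)["freq"]), np.sort(f))

    def test_dye_swap_pairing_present(self):
        obs = simulate_hybridization(np.array([0.5]), 1.0, 1.0, 0.1, 3, 1)
        per_rep = obs.intensities.groupby("replicate")["dye"].apply(set)
        assert all(d == {"forward", "swapped"} for d in per_rep)

    def test_determinism(self):
        f = np.array([0.6, 0.4])
        a = simulate_hybridization(f, 1.0, 1.0, 0.1, 2, 42)
        b = simulate_hybridization(f, 1.0, 1.0, 0.1, 2, 42)
        assert a.intensities.equals(b.intensities)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_hybridization(np.array([1.2]), 1.0, 1.0, 0.0, 1, 1)
        with pytest.raises(ValueError):
            simulate_hybridization(np.array([0.5]), 1.0, 1.0, -0.1, 1, 1)
        with pytest.raises(ValueError):
            simulate_hybridization(np.array([0.5]), 1.0, 1.0, 0.0, 0, 1)
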