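"""Hardy-Weinberg genotype simulation and GRS construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gbrpower import (
    InvalidConfigurationError,
    SNPPanel,
    compute_grs,
    draw_panel,
    load_panel,
    sample_genotypes,
    save_panel,
)


class TestSNPPanel:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidConfigurationError):
            SNPPanel(freqs=[0.0], beta_main=[0.0], beta_int=[0.1])
        with pytest.raises(InvalidConfigurationError):
            SNPPanel(freqs=[1.0], beta_main=[0.0], beta_int=[0.1])
        with pytest.raises(InvalidConfigurationError):
            SNPPanel(freqs=[0.2, 0.3], beta_main=[0.0], beta_int=[0.1, 0.2])
        with pytest.raises(InvalidConfigurationError):
            SNPPanel(freqs=[0.2], beta_main=[0.0], beta_int=[np.inf])

    def test_grs_moments_closed_form(self):
        panel = SNPPanel(freqs=[0.1, 0.4], beta_main=[0, 0], beta_int=[0, 0])
        assert panel.grs_mean == pytest.approx(2 * 0.1 + 2 * 0.4)
        assert panel.grs_var == pytest.approx(2 * 0.1 * 0.9 + 2 * 0.4 * 0.6)


class TestDrawPanel:
    def test_frequencies_within_range(self, rng):
        panel = draw_panel(20, (0.2, 0.5), (0.15, 0.30), rng=rng)
        assert panel.k == 20
        assert np.all((panel.freqs >= 0.2) & (panel.freqs <= 0.5))

    def test_protective_interactions_map_to_hr_below_one(self, rng):
        panel = draw_panel(50, (0.2, 0.5), (0.05, 0.15),
                           direction="protective", rng=rng)
        hrs = np.exp(panel.beta_int)
        assert np.all(hrs >= np.exp(-0.15) - 1e-12)
        assert np.all(hrs <= np.exp(-0.05) + 1e-12)

    def test_degenerate_point_interval(self, rng):
        panel = draw_panel(5, (0.3, 0.3), (0.1, 0.1), rng=rng)
        assert np.allclose(panel.freqs, 0.3)
        assert np.allclose(panel.beta_int, -0.1)

    def test_marginal_effects_default_zero_and_overridable(self, rng):
        assert np.all(draw_panel(3, (0.2, 0.5), (0.1, 0.2), rng=rng).beta_main == 0)
        panel = draw_panel(3, (0.2, 0.5), (0.1, 0.2), rng=rng, beta_main=0.05)
        assert np.allclose(panel.beta_main, 0.05)

    @pytest.mark.parametrize("maf_range,effect_range", [
        ((0.5, 0.2), (0.1, 0.2)),   # inverted MAF interval
        ((0.2, 0.5), (0.3, 0.1)),   # inverted effect interval
        ((0.0, 0.2), (0.1, 0.2)),   # MAF lower bound not in (0, 1)
    ])
    def test_invalid_intervals_rejected(self, rng, maf_range, effect_range):
        with pytest.raises(InvalidConfigurationError):
            draw_panel(5, maf_range, effect_range, rng=rng)


class TestSampleGenotypes:
    def test_hwe_proportions_chi_square(self, rng):
        """Genotype counts at p=0.3 match (q^2, 2pq, p^2) at n=1e5."""
        n, p = 100_000, 0.3
        g = sample_genotypes([p], n, rng)[:, 0]
        observed = np.bincount(g, minlength=3)
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert stats.chi2.sf(chi2, df=2) > 0.001

    def test_rare_allele_limit_is_all_zero(self, rng):
        g = sample_genotypes([1e-12], 1000, rng)
        assert np.all(g == 0)

    def test_dpp_mean_allele_count(self, rng):
        g = sample_genotypes([0.44], 31_000, rng)
        se = np.sqrt(2 * 0.44 * 0.56 / 31_000)
        assert np.mean(g) == pytest.approx(0.88, abs=3 * se)

    def test_invalid_frequency_rejected(self, rng):
        with pytest.raises(InvalidConfigurationError):
            sample_genotypes([1.2], 10, rng)
        with pytest.raises(InvalidConfigurationError):
            sample_genotypes([0.3], 0, rng)

    @given(st.integers(1, 30), st.integers(1, 50),
           st.floats(0.01, 0.99), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_entries_are_allele_counts(self, n, k, p, seed):
        rng = np.random.default_rng(seed)
        g = sample_genotypes(np.full(k, p), n, rng)
        assert g.shape == (n, k)
        assert set(np.unique(g)) <= {0, 1, 2}
        assert np.array_equal(compute_grs(g), g.sum(axis=1))


class TestComputeGrs:
    def test_direct_sum(self):
        assert compute_grs(np.array([[0, 1, 2]]))[0] == 3

    def test_range_bounded_by_two_k(self, rng):
        g = sample_genotypes(np.full(20, 0.45), 10_000, rng)
        grs = compute_grs(g)
        assert grs.min() >= 0 and grs.max() <= 40

    def test_moments_match_binomial_oracle(self, rng):
        """20 SNPs at p=0.5: GRS mean 20, variance 10 = sum 2p(1-p)."""
        n = 1_000_000
        grs = compute_grs(sample_genotypes(np.full(20, 0.5), n, rng))
        se_mean = np.sqrt(10 / n)
        assert np.mean(grs) == pytest.approx(20.0, abs=3 * se_mean)
        # SE of a binomial-sum variance estimate, via its fourth moment
        se_var = np.sqrt(2 * 10**2 / (n - 1)) * 1.5
        assert np.var(grs) == pytest.approx(10.0, abs=3 * se_var)

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            compute_grs(np.empty((0, 0)))

    def test_grs_approximately_normal_for_common_snps(self, rng):
        """k=20, MAF 0.2-0.5: simulated GRS has negligible skew at n=1e5."""
        panel = draw_panel(20, (0.2, 0.5), (0.1, 0.2), rng=rng)
        grs = compute_grs(sample_genotypes(panel.freqs, 100_000, rng))
        assert abs(stats.skew(grs)) < 0.1


class TestPanelIO:
    def test_tsv_round_trip(self, tmp_path, grs20_panel):
        path = tmp_path / "panel.tsv"
        save_panel(grs20_panel, path)
        loaded = load_panel(path)
        assert np.allclose(loaded.freqs, grs20_panel.freqs)
        assert np.allclose(loaded.beta_int, grs20_panel.beta_int)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp_id\teaf\n rs1\t0.3\n")
        with pytest.raises(InvalidConfigurationError):
            load_panel(path)
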