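import numpy as np
import pytest
from scipy import stats

from admixscan.simdata import (
    RejectionBudgetExceeded,
    SweepSimConfig,
    TractSimConfig,
    simulate_pair,
    simulate_panel,
    simulate_tracts,
    tract_lengths,
)


class TestSweepSimConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_diploids=1),
            dict(s=-0.1),
            dict(s=1.5),
            dict(freq_condition=1.2),
            dict(sel_pos_bp=2_000_000),
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SweepSimConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SweepSimConfig(seed=7, s=0.02, mu=3e-8)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SweepSimConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestSimulatePanel:
    def test_zero_mutation_rate_gives_empty_panel(self):
        panel, sites, sel = simulate_panel(
            SweepSimConfig(mu=0.0, Ne=50, n_diploids=5, seq_len_bp=10_000, seed=1)
        )
        assert panel.n_sites == 0 and len(sites) == 0 and sel is None

    def test_bit_reproducible_given_seed(self):
        cfg = SweepSimConfig(Ne=100, n_diploids=10, seq_len_bp=200_000, seed=9)
        p1, s1, _ = simulate_panel(cfg)
        p2, s2, _ = simulate_panel(cfg)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert np.array_equal(p1.positions_bp, p2.positions_bp)

    def test_backends_disagree_only_statistically(self):
        # same config, different backends: both neutral equilibrium panels
        cfg = SweepSimConfig(Ne=100, n_diploids=20, seq_len_bp=500_000, seed=3)
        ph, _, _ = simulate_panel(cfg, backend="hybrid")
        pw, _, _ = simulate_panel(cfg, backend="wf")
        a, b = ph.n_sites, pw.n_sites
        assert a > 0 and b > 0 and 0.3 < a / b < 3.0

    def test_segregating_sites_match_watterson_forward_wf(self):
        """Forward-WF neutral panels match the Watterson prediction
        theta_W * a_{n-1} within 3 SD of the mean over seeds."""
        Ne, n_dip, L, mu = 100, 50, 1_000_000, 1e-8
        n = 2 * n_dip
        theta = 4 * Ne * mu * L
        a1 = np.sum(1.0 / np.arange(1, n))
        a2 = np.sum(1.0 / np.arange(1, n) ** 2)
        expected = theta * a1
        var_one = theta * a1 + theta**2 * a2
        n_seeds = 12
        counts = [
            simulate_panel(
                SweepSimConfig(Ne=Ne, n_diploids=n_dip, seq_len_bp=L, mu=mu, seed=s),
                backend="wf",
            )[0].n_sites
            for s in range(n_seeds)
        ]
        sd_mean = np.sqrt(var_one / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * sd_mean

    def test_singleton_fraction_matches_neutral_sfs(self):
        """Unfolded SFS: the proportion of singletons is ~1/a_{n-1}."""
        cfg = lambda s: SweepSimConfig(
            Ne=200, n_diploids=25, seq_len_bp=1_000_000, mu=1e-7, seed=s
        )
        fracs = []
        for s in range(8):
            panel, sites, _ = simulate_panel(cfg(s))
            fracs.append(sites["is_singleton"].mean())
        n = 50
        expected = 1.0 / np.sum(1.0 / np.arange(1, n))
        assert abs(np.mean(fracs) - expected) < 3 * np.std(fracs) / np.sqrt(len(fracs))

    def test_sweep_panel_meets_frequency_condition(self):
        cfg = SweepSimConfig(
            Ne=200, n_diploids=20, seq_len_bp=500_000, sel_pos_bp=250_000,
            s=0.05, freq_condition=0.8, mu=5e-8, seed=11,
        )
        panel, sites, sel = simulate_panel(cfg)
        assert sel is not None
        assert panel.haplotypes[:, sel].mean() >= 0.8
        assert sites["position_bp"].iloc[sel] == 250_000

    def test_rejection_budget_failure_names_budget(self):
        cfg = SweepSimConfig(
            Ne=100, n_diploids=10, seq_len_bp=100_000, sel_pos_bp=50_000,
            s=0.001, freq_condition=0.99, max_tries=2, sweep_duration=5, seed=1,
        )
        with pytest.raises(RejectionBudgetExceeded, match="budget of 2 tries"):
            simulate_panel(cfg)


class TestSimulatePair:
    def test_pair_shares_coordinates_and_daf(self):
        cfg = SweepSimConfig(
            Ne=200, n_diploids=20, seq_len_bp=500_000, sel_pos_bp=250_000,
            s=0.05, mu=5e-8, seed=4,
        )
        pA, pB, sitesA, sel = simulate_pair(cfg)
        assert np.array_equal(pA.positions_bp, pB.positions_bp)
        assert pA.haplotypes[:, sel].mean() >= cfg.freq_condition
        assert pB.haplotypes[:, sel].mean() < 0.5  # outgroup untouched by the sweep

    def test_msprime_backend_neutral_pair(self):
        cfg = SweepSimConfig(Ne=200, n_diploids=20, seq_len_bp=500_000, mu=1e-7, seed=5)
        pA, pB, sitesA, sel = simulate_pair(cfg, backend="msprime")
        assert sel is None
        assert np.array_equal(pA.positions_bp, pB.positions_bp)
        assert pA.n_sites > 50

    def test_msprime_backend_rejects_selection(self):
        with pytest.raises(ValueError, match="neutral-only"):
            simulate_pair(SweepSimConfig(s=0.05), backend="msprime")


class TestTractSim:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TractSimConfig(K=2, m=(0.5, 0.4))

    def test_delta_bound_enforced(self):
        with pytest.raises(ValueError, match="delta"):
            TractSimConfig(K=2, m=(0.9, 0.1), delta=0.95, sel_locus_cM=50.0)

    def test_single_ancestry_is_constant(self):
        cfg = TractSimConfig(n_haplotypes=5, K=1, m=(1.0,), g=10, seed=0)
        am = simulate_tracts(cfg, np.linspace(0, 100, 50))
        assert (am.codes == 0).all()

    def test_interior_tract_lengths_are_exponential(self):
        """KS test against Exp(mean 100/g) does not reject at alpha=0.01."""
        cfg = TractSimConfig(n_haplotypes=10, g=10, seed=2)
        lengths = tract_lengths(cfg, min_tracts=10_000)
        assert lengths.size >= 10_000
        stat = stats.kstest(lengths, "expon", args=(0, 100.0 / cfg.g))
        assert stat.pvalue > 0.01
        assert abs(lengths.mean() - 10.0) / 10.0 < 0.05

    def test_stationary_proportion_close_to_m(self):
        cfg = TractSimConfig(n_haplotypes=300, K=2, m=(0.9, 0.1), g=30, seed=3)
        am = simulate_tracts(cfg, np.linspace(0, 100, 200))
        assert abs((am.codes == 1).mean() - 0.1) < 0.02

    def test_selection_boost_raises_locus_marginal(self):
        cfg = TractSimConfig(
            n_haplotypes=400, K=2, m=(0.9, 0.1), g=30, seed=4,
            sel_locus_cM=50.0, sel_ancestry=1, delta=0.3,
        )
        grid = np.linspace(0, 100, 201)
        am = simulate_tracts(cfg, grid)
        p = (am.codes == 1).mean(axis=0)
        at_locus = p[100]
        far = p[np.abs(grid - 50) > 30].mean()
        assert at_locus > 0.3  # target 0.4, binomial noise ~0.025
        assert far < 0.15

    def test_window_boost_mode_attenuated_but_present(self):
        cfg = TractSimConfig(
            n_haplotypes=400, K=2, m=(0.9, 0.1), g=30, seed=5,
            sel_locus_cM=50.0, sel_ancestry=1, delta=0.3,
            sel_halfwidth_cM=15.0, boost_mode="window",
        )
        grid = np.linspace(0, 100, 201)
        p = (simulate_tracts(cfg, grid).codes == 1).mean(axis=0)
        assert p[100] > 0.15  # boosted above baseline, below the full target
        assert p[np.abs(grid - 50) > 30].mean() < 0.15

    def test_deterministic_given_seed(self):
        cfg = TractSimConfig(n_haplotypes=20, g=15, seed=8)
        grid = np.linspace(0, 100, 77)
        a = simulate_tracts(cfg, grid)
        b = simulate_tracts(cfg, grid)
        assert np.array_equal(a.codes, b.codes)
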