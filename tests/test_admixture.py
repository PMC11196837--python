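"""Maximum-likelihood admixture: likelihood oracle, optimizer, recovery."""

import math

import numpy as np
import pytest
import sympy

from beeadmix import (
    ColonyObservation,
    LineagePanel,
    SimulationConfig,
    estimate_admixture,
    estimate_batch,
    grid_oracle,
    mixture_freq,
    neg_log_likelihood,
    simulate_colony,
    simulate_dataset,
    simulate_panel,
)
from beeadmix.admixture import FREQ_CLAMP, _simplex_lattice, binomial_log_prob


def exact_nll(counts, n, probs):
    """Arbitrary-precision term-by-term negative log-likelihood oracle."""
    total = sympy.Integer(0)
    for r, p in zip(counts, probs):
        pr = sympy.Rational(p)  # exact binary expansion of the float
        term = sympy.binomial(n, int(r)) * pr ** int(r) * (1 - pr) ** (n - int(r))
        total += sympy.log(term)
    return float((-total).evalf(30))


class TestMixtureFreq:
    def test_simplex_vertex(self):
        panel = LineagePanel(["s1"], np.array([[0.8], [0.2], [0.5]]))
        assert mixture_freq(panel, (1, 0, 0), 0) == pytest.approx(0.8)

    def test_midpoint(self):
        panel = LineagePanel(["s1"], np.array([[0.8], [0.2], [0.5]]))
        assert mixture_freq(panel, (0.5, 0.5, 0), 0) == pytest.approx(0.5)

    def test_weighted(self):
        panel = LineagePanel(["s1"], np.array([[0.9], [0.1], [0.5]]))
        assert mixture_freq(panel, (0.6, 0.2, 0.2), 0) == pytest.approx(0.66)

    def test_clamped_away_from_zero_and_one(self):
        panel = LineagePanel(["s1", "s2"], np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]))
        p = mixture_freq(panel, (1, 0, 0))
        assert p[0] == FREQ_CLAMP and p[1] == 1 - FREQ_CLAMP


class TestBinomialLogProb:
    def test_all_failures(self):
        assert binomial_log_prob(0, 40, 0.5) == pytest.approx(40 * math.log(0.5))

    def test_symmetry_at_half(self):
        assert binomial_log_prob(40, 40, 0.5) == pytest.approx(binomial_log_prob(0, 40, 0.5))

    def test_central_term_exact_integer_coefficient(self):
        # C(40, 20) computed by Python's big-integer comb, independent of gammaln
        expected = math.log(math.comb(40, 20)) + 40 * math.log(0.5)
        assert binomial_log_prob(20, 40, 0.5) == pytest.approx(expected, abs=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binomial_log_prob(41, 40, 0.5)


class TestNegLogLikelihood:
    def test_flat_panel_same_value_everywhere(self, flat_panel):
        obs = ColonyObservation("c1", counts=[10, 20, 30], n_alleles=40)
        values = {
            neg_log_likelihood(obs, flat_panel, w)
            for w in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1 / 3, 1 / 3, 1 / 3), (0.2, 0.5, 0.3)]
        }
        assert max(values) - min(values) < 1e-12

    def test_single_snp_reduces_to_one_term(self):
        panel = LineagePanel(["s1"], np.array([[1.0], [0.0], [0.0]]))
        obs = ColonyObservation("c1", counts=[20], n_alleles=40)
        got = neg_log_likelihood(obs, panel, (0.5, 0.25, 0.25))
        assert got == pytest.approx(-binomial_log_prob(20, 40, 0.5), abs=1e-12)

    def test_missing_snps_contribute_nothing(self, small_panel):
        full = ColonyObservation("c1", counts=[30, 5, 5], n_alleles=40)
        masked = ColonyObservation(
            "c1", counts=[30, 99999 % 41, 5], n_alleles=40, missing=[False, True, False]
        )
        w = (0.7, 0.1, 0.2)
        sub_panel = LineagePanel(["s1", "s3"], small_panel.freqs[:, [0, 2]])
        sub = ColonyObservation("c1", counts=[30, 5], n_alleles=40)
        assert neg_log_likelihood(masked, small_panel, w) == pytest.approx(
            neg_log_likelihood(sub, sub_panel, w)
        )
        assert neg_log_likelihood(full, small_panel, w) != pytest.approx(
            neg_log_likelihood(masked, small_panel, w)
        )

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_arbitrary_precision_oracle(self, trial, rng):
        L = 5
        freqs = rng.random((3, L))
        panel = LineagePanel([f"s{j}" for j in range(L)], freqs)
        counts = rng.integers(0, 41, size=L)
        obs = ColonyObservation(f"c{trial}", counts=counts, n_alleles=40)
        w = rng.dirichlet([1, 1, 1])
        p = np.clip(w @ freqs, FREQ_CLAMP, 1 - FREQ_CLAMP)
        expected = exact_nll(counts, 40, p)
        got = neg_log_likelihood(obs, panel, w)
        assert abs(got - expected) / max(1.0, abs(expected)) < 1e-9


class TestGridOracle:
    def test_lattice_count_step_half(self):
        assert len(_simplex_lattice(0.5)) == 6

    def test_flat_panel_tie_break(self, flat_panel):
        obs = ColonyObservation("c1", counts=[10, 20, 30], n_alleles=40)
        (a, m, c), _ = grid_oracle(obs, flat_panel, step=0.1)
        assert (a, m, c) == (0.0, 0.0, 1.0)

    def test_step_bounds(self, flat_panel):
        obs = ColonyObservation("c1", counts=[10, 20, 30], n_alleles=40)
        with pytest.raises(ValueError):
            grid_oracle(obs, flat_panel, step=0.2)

    def test_optimizer_agrees_within_one_step(self, rng):
        cfg = SimulationConfig(seed=31, n_snps=20, panel_mode="beta")
        panel = simulate_panel(cfg)
        for k in range(10):
            truth = rng.dirichlet([1, 1, 1])
            obs, _ = simulate_colony(panel, truth, cfg, rng, colony_id=f"c{k}")
            est = estimate_admixture(obs, panel, seed=k)
            (a, m, c), grid_nll = grid_oracle(obs, panel, step=0.01)
            assert est.neg_log_likelihood <= grid_nll + 1e-6
            assert max(abs(est.A - a), abs(est.M - m), abs(est.C - c)) <= 0.011


class TestEstimateAdmixture:
    def test_vertex_recovery(self, rng):
        cfg = SimulationConfig(seed=17, n_snps=94)
        panel = simulate_panel(cfg)
        obs, _ = simulate_colony(panel, (1.0, 0.0, 0.0), cfg, rng)
        est = estimate_admixture(obs, panel, seed=0)
        assert est.A >= 0.99
        assert est.converged

    def test_estimate_on_simplex(self, rng):
        cfg = SimulationConfig(seed=18, n_snps=10, panel_mode="beta")
        panel = simulate_panel(cfg)
        obs, _ = simulate_colony(panel, (0.3, 0.3, 0.4), cfg, rng)
        est = estimate_admixture(obs, panel)
        assert est.A + est.M + est.C == pytest.approx(1.0, abs=1e-6)
        assert 0 <= min(est.A, est.M, est.C)

    def test_flat_likelihood_flag(self, flat_panel):
        obs = ColonyObservation("c1", counts=[10, 20, 30], n_alleles=40)
        est = estimate_admixture(obs, flat_panel)
        assert est.flat_likelihood_flag

    def test_informative_panel_not_flagged(self, rng):
        cfg = SimulationConfig(seed=19, n_snps=94)
        panel = simulate_panel(cfg)
        obs, _ = simulate_colony(panel, (0.6, 0.2, 0.2), cfg, rng)
        assert not estimate_admixture(obs, panel).flat_likelihood_flag

    def test_permutation_equivariance(self, rng):
        """Relabeling the panel's lineages permutes the estimate identically."""
        cfg = SimulationConfig(seed=23, n_snps=94)
        panel = simulate_panel(cfg)
        obs, _ = simulate_colony(panel, (0.6, 0.2, 0.2), cfg, rng)
        est = estimate_admixture(obs, panel, seed=1)
        permuted = panel.permute_lineages(["C", "A", "M"])
        est_p = estimate_admixture(obs, permuted, seed=1)
        np.testing.assert_allclose(
            [est_p.A, est_p.M, est_p.C], [est.C, est.A, est.M], atol=1e-4
        )

    def test_error_shrinks_with_panel_size(self):
        """Consistency: median |A-hat - A| decreases from L=10 to L=94 to L=500
        on matched seeds (idealized simulation, diagnostic panel)."""
        errors = {}
        truth = (0.6, 0.2, 0.2)
        for L in (10, 94, 500):
            cfg = SimulationConfig(seed=29, n_snps=L)
            panel = simulate_panel(cfg)
            rng = np.random.default_rng(29)
            errs = []
            for k in range(40):
                obs, _ = simulate_colony(panel, truth, cfg, rng, colony_id=f"c{k}")
                est = estimate_admixture(obs, panel, seed=k)
                errs.append(abs(est.A - truth[0]))
            errors[L] = float(np.median(errs))
        assert errors[94] <= errors[10]
        assert errors[500] <= errors[94]


class TestEstimateBatch:
    def test_all_converged(self, sim_dataset):
        panel, colonies, _ = sim_dataset
        table = estimate_batch(colonies, panel, seed=0)
        assert len(table) == 10
        assert table["converged"].all()
        assert (table["error"] == "").all()

    def test_batch_mean_is_arithmetic_mean(self, sim_dataset):
        panel, colonies, _ = sim_dataset
        table = estimate_batch(colonies, panel, seed=0)
        singles = [estimate_admixture(c, panel, seed=i).A for i, c in enumerate(colonies)]
        assert table["A"].mean() == pytest.approx(float(np.mean(singles)))

    def test_failures_recorded_batch_continues(self, sim_dataset):
        panel, colonies, _ = sim_dataset
        broken = ColonyObservation("broken", counts=[1, 2], n_alleles=40)  # wrong width
        table = estimate_batch([colonies[0], broken, colonies[1]], panel, seed=0)
        assert len(table) == 3
        row = table[table["colony_id"] == "broken"].iloc[0]
        assert not row["converged"] and row["error"] != ""
        assert table[table["colony_id"] != "broken"]["converged"].all()

    def test_rank_order_recovery(self):
        """With per-colony truths spread over the simplex, estimated A ranks
        colonies in nearly the same order as true A."""
        from scipy.stats import spearmanr

        cfg = SimulationConfig(seed=37, n_colonies=40, admixture_concentration=3.0)
        panel, colonies, truths = simulate_dataset(cfg)
        table = estimate_batch(colonies, panel, seed=0)
        rho = spearmanr(table["A"], [t.true_admixture[0] for t in truths]).statistic
        assert rho > 0.9
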