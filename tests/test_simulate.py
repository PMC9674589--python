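"""Synthetic-data generators: trajectories, genealogies, haplotypes, fixtures."""

import numpy as np
import pytest

import treesel as ts
from treesel.demography import Demography, SimParams
from treesel.simulate import SimulationError, make_locus_fixture

from conftest import flat_trajectory


class TestTrajectory:
    def test_neutral_mean_is_martingale(self, const_dem):
        """Under neutrality the mean frequency stays at its initial value."""
        rng = np.random.default_rng(0)
        finals = [
            ts.simulate_trajectory(
                0.0, const_dem, 0.3, 50, seed=int(rng.integers(2**31))
            ).freqs_forward[50]
            for _ in range(3000)
        ]
        assert np.mean(finals) == pytest.approx(0.30, abs=0.01)

    def test_deterministic_step_matches_additive_selection(self, const_dem):
        tr = ts.simulate_trajectory(0.02, const_dem, 0.5, 1, deterministic=True)
        assert tr.freqs_forward[1] == pytest.approx(0.505, abs=1e-12)

    def test_fixation_probability_matches_exact_wf_matrix(self):
        """MC fixation fraction vs exact transition-matrix absorption (2N=20)."""
        two_n, s = 20, 0.05
        dem = Demography.constant(two_n / 2)
        # exact oracle: u(i) = sum_j P(i->j) u(j), u(0)=0, u(2N)=1
        i = np.arange(two_n + 1)
        x = i / two_n
        psel = np.clip(x + s * x * (1 - x), 0, 1)
        from scipy.stats import binom

        P = binom.pmf(np.arange(two_n + 1)[None, :], two_n, psel[:, None])
        A = np.eye(two_n - 1) - P[1:-1, 1:-1]
        b = P[1:-1, -1]
        u = np.linalg.solve(A, b)
        p_fix = u[0]  # from one copy
        rng = np.random.default_rng(1)
        n_rep = 20000
        fixed = 0
        for r in range(n_rep):
            tr = ts.simulate_trajectory(
                s, dem, 1 / two_n, 400, seed=int(rng.integers(2**31))
            )
            fixed += tr.freqs_forward[-1] == 1.0
        se = np.sqrt(p_fix * (1 - p_fix) / n_rep)
        assert fixed / n_rep == pytest.approx(p_fix, abs=4 * se)

    def test_absorbing_boundaries(self, const_dem):
        tr = ts.simulate_trajectory(0.1, const_dem, 0.0, 20, seed=0)
        assert np.all(tr.freqs == 0.0)

    def test_invalid_inputs_raise(self, const_dem):
        with pytest.raises(ValueError):
            ts.simulate_trajectory(0.0, const_dem, 1.5, 10)
        with pytest.raises(ValueError):
            ts.simulate_trajectory(0.0, const_dem, 0.5, 0)


class TestBackwardNeutral:
    def test_paths_end_at_origin_and_start_at_present(self, const_dem):
        x0 = np.array([0.2, 0.5, 0.8])
        trajs = ts.backward_neutral_trajectories(x0, const_dem, seed=4)
        for tr, x in zip(trajs, x0):
            assert tr.present_freq == x
            assert tr.freqs[-1] == 0.0
            assert tr.origin_generation == len(tr.freqs) - 1

    def test_mean_decays_on_2N_timescale(self, const_dem):
        """The conditioned backward walk loses frequency at rate ~x/(2N)."""
        trajs = ts.backward_neutral_trajectories(
            np.full(400, 0.5), const_dem, seed=9
        )
        at = []
        for tr in trajs:
            if len(tr.freqs) > 1000:
                at.append(tr.freqs[1000])
            else:
                at.append(0.0)
        expected = 0.5 * np.exp(-1000 / 2000.0)
        assert np.mean(at) == pytest.approx(expected, rel=0.2)


class TestGenealogy:
    def test_single_derived_lineage_never_coalesces_before_origin(self, const_dem):
        tr = flat_trajectory(0.3, 500, const_dem)
        tree = ts.sample_genealogy(tr, 10, 1, seed=3)
        assert tree.n_derived == 1
        assert tree.t_child == 0.0
        assert len(tree.class_schedule().derived_times) == 0

    def test_pairwise_coalescence_time_matches_2N(self):
        """Single class, constant 2N=1000 haploids: E[T2] = 1000 generations."""
        dem = Demography.constant(500)
        tr = flat_trajectory(1.0, 10, dem, absorbed=False)
        rng = np.random.default_rng(2)
        times = [
            ts.sample_genealogy(tr, 2, 2, seed=int(rng.integers(2**31))).tmrca
            for _ in range(400)
        ]
        se = 1000 / np.sqrt(400)
        assert np.mean(times) == pytest.approx(1000, abs=4 * se)

    def test_fixed_frequency_tmrca_matches_standard_coalescent(self):
        """x = 1: mean TMRCA matches 2*2N*(1 - 1/n) haploid generations."""
        dem = Demography.constant(500)
        n = 8
        tr = flat_trajectory(1.0, 10, dem, absorbed=False)
        rng = np.random.default_rng(5)
        times = [
            ts.sample_genealogy(tr, n, n, seed=int(rng.integers(2**31))).tmrca
            for _ in range(400)
        ]
        expect = 2 * 1000 * (1 - 1 / n)
        assert np.mean(times) == pytest.approx(expect, rel=0.1)

    def test_tree_structure_invariants(self, const_dem, rng):
        """Ultrametric tips, positive class sizes, derived TMRCA <= origin."""
        for _ in range(20):
            x0 = rng.uniform(0.1, 0.9)
            tr = ts.backward_neutral_trajectories(
                np.array([x0]), const_dem, seed=int(rng.integers(2**31))
            )[0]
            d = int(rng.integers(2, 15))
            tree = ts.sample_genealogy(tr, 20, d, seed=int(rng.integers(2**31)))
            assert tree.n_derived == d
            assert np.all(tree.time[: tree.n_leaves] == 0.0)
            sched = tree.class_schedule()
            assert sched.t_child <= tr.origin_generation + 1e-9
            assert np.isfinite(tree.tmrca)
            has_parent = np.flatnonzero(tree.parent >= 0)
            assert np.all(
                tree.time[tree.parent[has_parent]] >= tree.time[has_parent] - 1e-9
            )

    def test_unreachable_origin_raises(self, const_dem):
        tr = flat_trajectory(0.5, 100, const_dem, absorbed=False)
        with pytest.raises(SimulationError):
            ts.sample_genealogy(tr, 10, 4, seed=0)


class TestForwardHaplotypes:
    def test_zero_mutation_rate_gives_no_sites(self):
        dem = Demography.constant(30)
        params = SimParams(
            mutation_rate=0.0, recombination_rate=1e-8, sequence_length=1e4,
            n_samples=20,
        )
        haps, truth = ts.simulate_haplotypes(params, dem, seed=0, burn_in=120)
        assert haps.n_sites == 0
        assert truth is None

    def test_no_recombination_satisfies_four_gamete_rule(self):
        """Without recombination any two sites show at most 3 gamete types."""
        dem = Demography.constant(50)
        params = SimParams(
            mutation_rate=2e-7, recombination_rate=0.0, sequence_length=5e4,
            n_samples=30,
        )
        haps, _ = ts.simulate_haplotypes(params, dem, seed=2, burn_in=600)
        m = haps.matrix
        assert haps.n_sites >= 2
        for i in range(haps.n_sites):
            for j in range(i + 1, haps.n_sites):
                gametes = {(a, b) for a, b in zip(m[:, i], m[:, j])}
                assert len(gametes) <= 3

    def test_pairwise_diversity_matches_theta(self):
        """Neutral equilibrium: mean pairwise diversity ~ 4*N*mu per site.

        Per-replicate variance of pi is large (few, correlated sites), so the
        check uses 12 independent populations and a ~4-sigma band.
        """
        dem = Demography.constant(50)
        params = SimParams(
            mutation_rate=1e-6, recombination_rate=0.0, sequence_length=1e4,
            n_samples=40,
        )
        pis = []
        for seed in range(12):
            haps, _ = ts.simulate_haplotypes(params, dem, seed=seed)
            p = haps.matrix.mean(axis=0)
            n = haps.n_haplotypes
            pis.append(np.sum(2 * p * (1 - p) * n / (n - 1)))
        expected = 4 * 50 * 1e-6 * 1e4  # = 2.0
        assert np.mean(pis) == pytest.approx(expected, abs=1.4)

    def test_selected_site_truth_is_consistent(self):
        """Final derived frequency equals the trajectory endpoint; the
        carriers of the selected allele form a clade on the returned tree."""
        dem = Demography.constant(100)
        params = SimParams(
            mutation_rate=1e-7, recombination_rate=1e-8, sequence_length=5e4,
            n_samples=40,
        )
        haps, truth = ts.simulate_haplotypes(
            params, dem, selected_site=(2.5e4, 0.08, 70), seed=3,
            final_freq_range=(0.2, 0.95), max_retries=80, burn_in=800,
        )
        traj = truth["trajectory"]
        pop_freq = traj.present_freq
        assert 0.2 <= pop_freq <= 0.95
        col = haps.matrix[:, truth["selected_index"]]
        assert np.array_equal(col, truth["selected_column"])
        tree = truth["tree"]
        if tree is not None:
            carriers = {f"hap{i}" for i in np.flatnonzero(col)}
            assert tree.derived_leaves == carriers

    def test_population_size_limit_enforced(self):
        with pytest.raises(ValueError, match="limited to N"):
            ts.simulate_haplotypes(SimParams(), Demography.constant(5000), seed=0)


class TestCoalescentHaplotypes:
    def test_msprime_panel_shape_and_polarization(self, const_dem):
        params = SimParams(n_samples=40, sequence_length=1e5, recombination_rate=1e-8)
        haps = ts.coalescent_haplotypes(params, const_dem, seed=7)
        assert haps.n_haplotypes == 40
        assert haps.n_sites > 10
        assert np.all(np.diff(haps.positions) > 0)
        assert set(np.unique(haps.matrix)) <= {0, 1}


class TestLocusFixtures:
    @pytest.mark.parametrize("scenario", ["A", "B", "C", "D"])
    def test_fixture_realizes_requested_scenario(self, scenario):
        haps, table, truth = make_locus_fixture(scenario, seed=42)
        assert truth["scenario"] == scenario
        top = table.loc[table["pics"].idxmax()]
        if scenario == "A":
            # planted selected SNP carries the top PICS score
            assert top["snp_id"] == "rs_target"
        elif scenario == "D":
            assert not top["testable"]
            assert "derived count" in top["reason"]
        else:
            from treesel.ld import r_squared

            r2 = r_squared(haps.column("rs_top"), haps.column("rs_target"))
            if scenario == "B":
                assert r2 < 0.6
            else:
                assert r2 >= 0.6

    def test_fixture_risk_hitchhiker_phasing(self):
        """Scenario B risk sub-class: the risk allele rides the selected
        haplotype but stays below the strong-LD band."""
        haps, table, truth = make_locus_fixture("B", seed=11, subscenario="risk")
        assert truth["subscenario"] == 3
        t = haps.column("rs_target")
        p = haps.column("rs_top")
        # majority phase of the top SNP's derived (risk) allele with the target
        assert p[t == 1].mean() > 0.5

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            make_locus_fixture("E", seed=0)
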