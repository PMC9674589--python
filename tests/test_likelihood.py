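"""Selection likelihood: transition moments, filter oracles, fits, medians."""

import numpy as np
import pytest
from scipy.stats import binom, norm

import treesel as ts
from treesel.demography import Demography
from treesel.likelihood import (
    SelectionModel,
    TrajectoryModel,
    _aug_matrix,
    _coal_hazard,
    _split_dt,
    _tree_loglik_multi,
    allele_age,
    default_s_grid,
    fit_selection,
    replicate_median,
    tree_loglik,
    wf_transition,
)
from treesel.trees import LocalTree

from conftest import flat_trajectory


class TestWfTransition:
    def test_moments_examples(self):
        mean, var = wf_transition(0.5, 0.02, 1000, 1)
        assert mean == pytest.approx(0.505)
        assert var == pytest.approx(0.25 / 2000)
        mean0, var0 = wf_transition(0.0, 0.3, 1000)
        assert (mean0, var0) == (0.0, 0.0)

    def test_one_step_gaussian_close_to_exact_binomial(self):
        """TV distance between the moment-matched Gaussian and the exact
        Wright-Fisher binomial (2N=20, x=0.3) is small."""
        mean, var = wf_transition(0.3, 0.0, 10, 1)
        lat = np.arange(21) / 20
        edges = np.concatenate([[-1], (lat[:-1] + lat[1:]) / 2, [2]])
        pn = np.diff(norm.cdf(edges, loc=mean, scale=np.sqrt(var)))
        pb = binom.pmf(np.arange(21), 20, 0.3)
        tv = 0.5 * np.abs(pn - pb).sum()
        assert tv < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wf_transition(1.2, 0.0, 100)
        with pytest.raises(ValueError):
            wf_transition(0.5, 0.0, 1)


def _three_leaf_tree(t_coal=200.0, t_root=600.0):
    """Two derived leaves coalescing at t_coal, one ancestral leaf, root."""
    parent = np.array([3, 3, 4, 4, -1])
    time = np.array([0.0, 0.0, 0.0, t_coal, t_root])
    return LocalTree(parent, time, ("a", "b", "c"), 3)


class TestTreeLoglik:
    def test_closed_form_exponential_density(self):
        """Two derived lineages at clamped x=0.5 with 2N=1000 haploids and a
        coalescence at t=200: loglik = ln(1/500) - 200/500 exactly."""
        tree = _three_leaf_tree()
        model = TrajectoryModel(
            demography=Demography.constant(500), fixed_freq=0.5, anchor="none"
        )
        assert tree_loglik(tree, model) == pytest.approx(
            np.log(1 / 500) - 200 / 500, abs=1e-9
        )

    def test_empty_window_gives_zero_logLR(self, const_dem):
        """window (0,0): selection never acts, so all s give the same value."""
        tree = _three_leaf_tree()
        lls = _tree_loglik_multi(
            tree,
            TrajectoryModel(demography=const_dem, window=(0.0, 0.0)),
            np.array([-0.05, 0.0, 0.05]),
        )
        assert np.allclose(lls, lls[0], atol=1e-9)

    def test_monomorphic_tree_rejected(self, const_dem):
        parent = np.array([2, 2, -1])
        tree = LocalTree(parent, np.array([0.0, 0.0, 50.0]), ("a", "b"), 2)
        with pytest.raises(ValueError, match="monomorphic"):
            tree_loglik(tree, TrajectoryModel(demography=const_dem))

    def test_likelihood_invariant_under_leaf_relabeling(self, const_dem):
        tr = flat_trajectory(0.4, 400, const_dem)
        tree = ts.sample_genealogy(tr, 12, 5, seed=8)
        relabeled = LocalTree(
            tree.parent, tree.time,
            tuple(f"z{i}" for i in range(tree.n_leaves)), tree.mutation_node,
        )
        m = TrajectoryModel(demography=const_dem)
        assert tree_loglik(tree, m) == pytest.approx(tree_loglik(relabeled, m))

    @pytest.mark.parametrize(
        "fixture_id,n,d,ev_d,ev_a,t_parent,t_root",
        [
            ("two-derived", 3, 2, [4.0], [], 10, 14),
            ("singleton", 3, 1, [], [5.0], 9, 9),
            ("mixed", 4, 2, [3.0], [5.0], 8, 12),
        ],
    )
    def test_hmm_matches_monte_carlo_path_integration(
        self, fixture_id, n, d, ev_d, ev_a, t_parent, t_root
    ):
        """The filter's marginal likelihood equals Monte-Carlo averaging of
        emission weights over sampled latent frequency paths."""
        tree = _build_tree(n, d, ev_d, ev_a, t_parent, t_root)
        dem = Demography.constant(50)
        model = TrajectoryModel(demography=dem, n_bins=5, grid_lo=0.01)
        for s in (0.0, 0.1):
            ll = _tree_loglik_multi(tree, model, np.array([s]))[0]
            mc, mc_se = _mc_loglik(tree, model, s, n_paths=200_000, seed=77)
            assert ll == pytest.approx(mc, abs=max(3 * mc_se, 0.02))

    def test_logLR_nonnegative_property(self, const_dem, rng):
        """With 0 in the grid, the MLE dominates the null: logLR >= 0."""
        for _ in range(10):
            x0 = rng.uniform(0.15, 0.85)
            tr = ts.backward_neutral_trajectories(
                np.array([x0]), const_dem, seed=int(rng.integers(2**31))
            )[0]
            tree = ts.sample_genealogy(tr, 16, int(rng.integers(2, 14)),
                                       seed=int(rng.integers(2**31)))
            fit = SelectionModel(tree, const_dem).fit()
            assert fit.logLR >= 0.0

    def test_filter_state_normalizes(self, const_dem):
        """Scaled filtering keeps a proper distribution at every slice: the
        total likelihood is finite and reproducible."""
        tr = flat_trajectory(0.4, 300, const_dem)
        tree = ts.sample_genealogy(tr, 10, 4, seed=1)
        m = TrajectoryModel(demography=const_dem)
        v1, v2 = tree_loglik(tree, m), tree_loglik(tree, m)
        assert np.isfinite(v1) and v1 == v2


def _build_tree(n, d, ev_d, ev_a, t_parent, t_root):
    """Caterpillar tree with prescribed class-event times."""
    parent = [-1] * n
    time = [0.0] * n
    nxt = n

    def chain(leaves, evs):
        nonlocal nxt
        cur = leaves[0]
        for i, t in enumerate(evs):
            parent.append(-1)
            time.append(t)
            parent[cur] = nxt
            parent[leaves[i + 1]] = nxt
            cur = nxt
            nxt += 1
        return cur

    dnode = chain(list(range(d)), ev_d)
    anode = chain(list(range(d, n)), ev_a)
    parent.append(-1)
    time.append(float(t_parent))
    parent[dnode] = nxt
    parent[anode] = nxt
    root = nxt
    nxt += 1
    if t_root > t_parent:  # optional stub above (keeps t_parent < t_root)
        pass
    return LocalTree(
        np.array(parent), np.array(time),
        tuple(f"h{i}" for i in range(n)), dnode,
    )


def _mc_loglik(tree, model, s, n_paths, seed):
    """Monte-Carlo path integration over the same latent chain: sample
    frequency paths chunk by chunk from the transition matrices and average
    the emission weights (an independent estimate of the filter's sum)."""
    rng = np.random.default_rng(seed)
    edges, centers = model.grid()
    nb = len(centers)
    sched = tree.class_schedule()
    n, d = tree.n_leaves, tree.n_derived
    dem = model.demography
    t_child = int(round(sched.t_child))
    t_parent = int(round(sched.t_parent))
    if t_parent <= t_child:
        t_parent = t_child + 1
    ev_d = [max(1, int(round(t))) for t in sched.derived_times]
    ev_a = [max(1, int(round(t))) for t in sched.ancestral_times if t <= t_parent]
    bps = sorted(set(ev_d) | set(ev_a) | {t_parent} | {t_child} - {0})
    w0 = binom.pmf(d, n, centers)
    Z0 = w0.sum()
    state = rng.choice(nb, size=n_paths, p=w0 / Z0)
    logw = np.full(n_paths, np.log(Z0))
    at_origin = np.zeros(n_paths, dtype=bool)
    kd, ka = d, n - d
    t = 0
    for b in bps:
        if b > t_parent:
            break
        for dt in _split_dt(b - t):
            N = dem.size_at(t + 0.5)
            two_n = 2.0 * N
            aug = _aug_matrix(s, N, dt, edges, centers)
            cum = np.cumsum(aug, axis=1)
            u = rng.random(n_paths)
            nxt = (u[:, None] > cum[state]).sum(axis=1)
            newly = (~at_origin) & (nxt == nb)
            if t < t_child:
                logw[newly] = -np.inf  # absorption before the mutation branch
            at_origin |= nxt == nb
            state = np.minimum(nxt, nb - 1)
            h_d = _coal_hazard(kd, two_n * centers)[state]
            h_a = _coal_hazard(ka, two_n * (1 - centers))[state]
            h_a0 = _coal_hazard(ka, np.array([two_n]))[0]
            interior = ~at_origin
            logw[interior] += -(h_d[interior] + h_a[interior]) * dt
            logw[at_origin] += -h_a0 * dt if kd <= 1 else -np.inf
            is_event = t + dt == b
            if is_event:
                for _ in range(ev_d.count(b)):
                    hk = _coal_hazard(kd, two_n * centers)[state]
                    with np.errstate(divide="ignore"):
                        logw[interior] += np.log(hk[interior])
                    logw[at_origin] = -np.inf
                    kd -= 1
                for _ in range(ev_a.count(b)):
                    hk = _coal_hazard(ka, two_n * (1 - centers))[state]
                    with np.errstate(divide="ignore"):
                        logw[interior] += np.log(hk[interior])
                        logw[at_origin] += np.log(h_a0)
                    ka -= 1
            t += dt
    logw[~at_origin] = -np.inf  # condition on origin within the branch
    w = np.exp(logw - logw.max())
    mean = w.mean()
    se = w.std(ddof=1) / np.sqrt(n_paths)
    ll = np.log(mean) + logw.max()
    return ll, se / mean  # delta-method se on the log scale


class TestFitSelection:
    def test_sweep_recovery_single_tree(self):
        """An ongoing s=0.05 sweep leaves a detectable positive signal."""
        dem = Demography.constant(1000)
        traj = ts.conditioned_sweep_trajectory(0.05, dem, 0.6, seed=100)
        d = int(round(traj.present_freq * 30))
        tree = ts.sample_genealogy(traj, 30, d, seed=200)
        fit = SelectionModel(tree, dem).fit()
        assert fit.s_hat > 0
        assert fit.logLR > 2
        lo, hi = fit.support_interval()
        assert lo <= fit.s_hat <= hi
        assert "logLR" in fit.summary()

    def test_trivial_grid_gives_zero_logLR(self, const_dem):
        tr = flat_trajectory(0.4, 300, const_dem)
        tree = ts.sample_genealogy(tr, 10, 4, seed=5)
        fit = fit_selection(tree, const_dem, s_grid=np.array([0.0]))
        assert fit.logLR == 0.0
        assert fit.s_hat == 0.0

    def test_model_validation(self, const_dem):
        tr = flat_trajectory(0.4, 300, const_dem)
        tree = ts.sample_genealogy(tr, 10, 4, seed=5)
        with pytest.raises(ValueError, match="contain 0"):
            SelectionModel(tree, const_dem, s_grid=np.array([0.01]))
        with pytest.raises(ValueError, match="at least one"):
            SelectionModel([], const_dem)

    def test_default_s_grid_is_symmetric_with_zero(self):
        g = default_s_grid()
        assert 0.0 in g
        assert np.allclose(np.sort(-g), np.sort(g))


class TestReplicateMedian:
    class _Fit:
        def __init__(self, logLR, s=0.01):
            self.logLR = logLR
            self.s_hat = s
            self.allele_age_generations = 100.0
            self.derived_freq = 0.4

    @pytest.mark.parametrize(
        "values,expect_runs,expect_median",
        [
            ([1.0, 1.5], 2, 1.25),
            ([1.0, 3.5, 2.0], 3, 2.0),
            ([2.2, 2.2], 2, 2.2),
        ],
    )
    def test_two_or_three_run_rule(self, values, expect_runs, expect_median):
        calls = []

        def run(i):
            calls.append(i)
            return self._Fit(values[i])

        res = replicate_median(run, snp_id="rs1")
        assert len(calls) == expect_runs
        assert res.logLR_median == pytest.approx(expect_median)
        assert res.logLR_replicates == values[:expect_runs]
        assert res.meta["n_runs"] == expect_runs

    def test_median_invariant_enforced(self):
        from treesel.likelihood import SelectionResult

        with pytest.raises(ValueError, match="median"):
            SelectionResult("x", 0.0, [1.0, 2.0], 5.0, 0.0, 0.0, 0.5)


class TestAlleleAge:
    def test_midpoint_of_mutation_branch(self):
        tree = _three_leaf_tree(t_coal=100.0, t_root=300.0)
        assert allele_age(tree) == pytest.approx(200.0)

    def test_tip_branch_and_year_conversion(self):
        parent = np.array([3, 3, 4, 4, -1])
        time = np.array([0.0, 0.0, 0.0, 100.0, 400.0])
        tree = LocalTree(parent, time, ("a", "b", "c"), 0)  # mutation on leaf 0
        age = allele_age(tree)
        assert age == pytest.approx(50.0)
        dem = Demography.constant(1000)  # generation time 28 years
        assert dem.generations_to_years(age) == pytest.approx(1400.0)

    def test_age_monotone_in_branch_height(self):
        younger = _three_leaf_tree(t_coal=50.0, t_root=300.0)
        older = _three_leaf_tree(t_coal=150.0, t_root=300.0)
        assert allele_age(older) > allele_age(younger)
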