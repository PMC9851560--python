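import numpy as np
import pytest

from emasym import gvar, synthetic
from emasym.gvar import (
    LaggedDesign,
    build_lagged,
    concat_designs,
    fit_gvar,
    lambda_grid,
    partial_correlations,
    pooled_networks,
    select_ebic,
)

from conftest import make_cohort, make_series


def _design_from_var(b, innov_cov, n, seed=0):
    """Simulate x_t = B x_{t-1} + e_t and wrap as a LaggedDesign."""
    rng = np.random.default_rng(seed)
    k = b.shape[0]
    x = np.zeros(k)
    xs, ys = [], []
    for _ in range(n + 50):
        nxt = b @ x + rng.multivariate_normal(np.zeros(k), innov_cov)
        xs.append(x)
        ys.append(nxt)
        x = nxt
    xs, ys = np.array(xs[50:]), np.array(ys[50:])
    return LaggedDesign(
        x=xs, y=ys, variables=tuple(f"v{i}" for i in range(k)),
        participant_ids=np.repeat("p", len(xs)),
    )


class TestBuildLagged:
    def test_full_day_gives_four_pairs(self):
        s = make_series("P1", {"fatigue": [10, 30, 20, 40, 50]})
        d = build_lagged(s, ("fatigue", "pain"))
        assert d.n_pairs == 4

    def test_missing_slot_breaks_pairs(self):
        slots = [(0, 1), (0, 2), (0, 4), (0, 5)]  # slot 3 missing
        s = make_series("P1", {"fatigue": [10, 30, 20, 40]}, slots=slots)
        d = build_lagged(s, ("fatigue", "pain"))
        assert d.n_pairs == 2  # (1->2) and (4->5) only

    def test_day_boundary_never_paired(self):
        slots = [(0, 5), (1, 1)]  # evening then next morning
        s = make_series("P1", {"fatigue": [10, 90]}, slots=slots)
        assert build_lagged(s, ("fatigue", "pain")).n_pairs == 0

    def test_fourteen_complete_days_give_56_pairs(self):
        rng = np.random.default_rng(0)
        s = make_series("P1", {"fatigue": rng.integers(0, 100, 70)})
        assert build_lagged(s, ("fatigue", "pain")).n_pairs == 56

    def test_values_standardized_within_person(self):
        rng = np.random.default_rng(1)
        s = make_series("P1", {"fatigue": rng.integers(0, 100, 70)})
        d = build_lagged(s, ("fatigue",))
        # standardization is over all 70 completed entries; with every slot
        # completed, predictors are the slot-1..4 entries of each day
        raw = s.values("fatigue")
        z = (raw - raw.mean()) / raw.std(ddof=1)
        expected_x = z[np.arange(70) % 5 != 4]
        expected_y = z[np.arange(70) % 5 != 0]
        assert d.x[:, 0] == pytest.approx(expected_x, abs=1e-12)
        assert d.y[:, 0] == pytest.approx(expected_y, abs=1e-12)

    def test_zero_variance_symptom_dropped(self):
        rng = np.random.default_rng(2)
        s = make_series(
            "P1", {"fatigue": rng.integers(0, 100, 20), "taste": [0] * 20}
        )
        d = build_lagged(s, ("fatigue", "taste"))
        assert d.variables == ("fatigue",)
        assert d.dropped == ("taste",)

    def test_low_data_flagged(self):
        s = make_series("P1", {"fatigue": [10, 20, 30]})
        assert build_lagged(s, ("fatigue",)).low_data


class TestFitGvar:
    def test_full_shrinkage_empties_both_networks(self):
        d = _design_from_var(np.eye(3) * 0.4, np.eye(3), 300)
        lb, lk = lambda_grid(d)
        m = fit_gvar(d, lb[0] * 1.01, lk[0] * 1.01)
        assert np.all(m.beta == 0)
        assert np.all(m.pcc == 0)
        assert m.temporal_edges == set()

    def test_partial_correlation_hand_example(self):
        kappa = np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert partial_correlations(kappa)[0, 1] == pytest.approx(0.5)
        assert partial_correlations(kappa)[0, 0] == 0.0

    def test_consistency_on_large_sample(self):
        b = np.array([[0.4, 0.2, 0.0], [0.0, 0.3, 0.0], [0.0, 0.0, 0.25]])
        kappa_true = np.array(
            [[1.0, -0.3, 0.0], [-0.3, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        d = _design_from_var(b, np.linalg.inv(kappa_true), 5000, seed=4)
        m = fit_gvar(d, 1e-4, 1e-4)
        assert np.abs(m.beta - b).max() < 0.05
        assert np.abs(m.pcc - partial_correlations(kappa_true)).max() < 0.05

    def test_oracle_equivalence_at_zero_penalty(self):
        d = _design_from_var(np.array([[0.5, 0.2], [-0.1, 0.3]]), np.eye(2), 400)
        m = fit_gvar(d, 0.0, 0.0)
        b_ls = np.linalg.solve(d.x.T @ d.x, d.x.T @ d.y).T
        assert np.abs(m.beta - b_ls).max() < 1e-6

    def test_pcc_symmetric_and_bounded_across_fits(self):
        d = _design_from_var(np.eye(4) * 0.3, np.eye(4), 200, seed=5)
        lb, lk = lambda_grid(d, 5)
        for l1 in lb[::2]:
            for l2 in lk[::2]:
                m = fit_gvar(d, l1, l2)
                assert np.allclose(m.pcc, m.pcc.T)
                assert np.all(np.abs(m.pcc) <= 1 + 1e-9)

    def test_monotone_sparsity_along_beta_path(self):
        d = _design_from_var(
            np.array([[0.5, 0.3, 0.0], [0.0, 0.4, 0.2], [0.0, 0.0, 0.3]]),
            np.eye(3),
            400,
            seed=6,
        )
        lb, _ = lambda_grid(d, 12)
        sizes = []
        for lam in lb:  # decreasing penalties
            m = fit_gvar(d, lam, 0.0, kappa_fixed=np.eye(3))
            sizes.append(int(np.sum(m.beta != 0)))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_rejects_undersized_design(self):
        d = _design_from_var(np.eye(3) * 0.2, np.eye(3), 2)
        with pytest.raises(ValueError):
            fit_gvar(d, 0.1, 0.1)


class TestSelectEbic:
    def test_single_point_grid_returns_that_fit(self):
        d = _design_from_var(np.eye(2) * 0.4, np.eye(2), 200, seed=7)
        m = select_ebic(d, lambda_betas=[0.1], lambda_kappas=[0.05])
        assert (m.lambda_beta, m.lambda_kappa) == (0.1, 0.05)

    def test_matches_bruteforce_grid_minimum(self):
        d = _design_from_var(
            np.array([[0.5, 0.0], [0.3, 0.4]]), np.eye(2), 400, seed=8
        )
        lbs, lks = [0.02, 0.1, 0.5], [0.01, 0.05, 0.25]
        best = select_ebic(d, lambda_betas=lbs, lambda_kappas=lks)
        scores = {
            (lb, lk): fit_gvar(d, lb, lk).ebic for lb in lbs for lk in lks
        }
        assert best.ebic == pytest.approx(min(scores.values()), rel=1e-3)

    def test_pure_noise_selects_empty_model(self):
        rng = np.random.default_rng(9)
        d = LaggedDesign(
            x=rng.normal(size=(300, 3)),
            y=rng.normal(size=(300, 3)),
            variables=("a", "b", "c"),
            participant_ids=np.repeat("p", 300),
        )
        m = select_ebic(d, n_lambda=10)
        assert np.all(m.beta == 0)
        assert np.all(m.pcc == 0)


class TestPooledNetworks:
    def test_null_cohort_gives_empty_temporal_network(self):
        empties = 0
        for seed in range(10):
            spec = synthetic.independence_spec(n_participants=12, seed=seed)
            cohort, _ = synthetic.generate_ema(spec)
            nets = pooled_networks(
                cohort, pooled_n_lambda=10, fit_individuals=False
            )
            if np.all(nets.temporal == 0):
                empties += 1
        assert empties >= 9

    def test_strong_contemporaneous_edge_recovered_with_sign(self):
        spec = synthetic.recovery_spec(n_participants=40, seed=11)
        cohort, truth = synthetic.generate_ema(spec)
        nets = pooled_networks(cohort, pooled_n_lambda=10, fit_individuals=False)
        i, j = 0, 1  # overall-fatigue true partial correlation 0.4
        assert truth.pcc[i, j] == pytest.approx(0.4)
        assert nets.contemporaneous[i, j] > 0

    def test_between_network_shows_constructed_dependence(self):
        rng = np.random.default_rng(12)
        cov = np.eye(8) * 100.0
        cov[0, 1] = cov[1, 0] = 85.0  # overall-fatigue person means coupled
        spec = synthetic.CohortSpec(
            n_participants=60,
            between_cov=cov,
            mean_vector=np.full(8, 50.0),
            seed=13,
        )
        cohort, _ = synthetic.generate_ema(spec)
        nets = pooled_networks(cohort, pooled_n_lambda=8, fit_individuals=False)
        assert nets.between[0, 1] > 0.2
        assert np.allclose(nets.between, nets.between.T)

    def test_autocorrelation_profile_counts(self, default_cohort):
        cohort, _ = default_cohort
        sub = make_cohort(list(cohort)[:4])
        nets = pooled_networks(
            sub, pooled_n_lambda=6, individual_n_lambda=6
        )
        prof = gvar.autocorrelation_profile(nets)
        assert len(prof) == len(nets.individual)
        assert prof["n_autocorrelations"].between(0, 8).all()
        for _, row in prof.iterrows():
            m = nets.individual[row["participant_id"]]
            assert row["n_autocorrelations"] == int(
                np.sum(np.abs(np.diag(m.beta)) > 0)
            )

    def test_edge_list_round_trips_pooled_edges(self, default_cohort):
        cohort, _ = default_cohort
        nets = pooled_networks(cohort, pooled_n_lambda=8, fit_individuals=False)
        el = nets.edge_list()
        n_contemp = int(
            np.sum(np.abs(nets.contemporaneous[np.triu_indices(8, 1)]) > 0)
        )
        assert len(el[(el.network_type == "contemporaneous") & (el.participant_id == "pooled")]) == n_contemp
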