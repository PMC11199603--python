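import numpy as np
import pytest

from genefold.tasep import (TasepParams, TasepState, burst_derived,
                            density_profile, simulate, solve_meanfield, step,
                            transcription_observables,
                            uniform_profile_params)


def exact_stationary_n3(params: TasepParams) -> np.ndarray:
    """Stationary distribution of the exact 8-state Markov chain of one MCS.

    The composite step is bind, unbind, then two elongation attempts each
    picking site 1 or 2 uniformly; enumerated as 8x8 stochastic matrices and
    composed, the stationary law follows by linear algebra -- fully
    independent of the simulation code.
    """
    pa, pb, pg, pg0, _, _ = params.probabilities()

    def unpack(k):
        return (k >> 2) & 1, (k >> 1) & 1, k & 1

    def pack(s):
        return (s[0] << 2) | (s[1] << 1) | s[2]

    P_bind = np.zeros((8, 8))
    P_unbind = np.zeros((8, 8))
    P_hop = [np.zeros((8, 8)), np.zeros((8, 8))]
    for k in range(8):
        s = list(unpack(k))
        if s[0] == 0:
            s2 = s.copy()
            s2[0] = 1
            P_bind[k, pack(s2)] += pa
            P_bind[k, k] += 1 - pa
        else:
            P_bind[k, k] = 1.0
        if s[2] == 1:
            s2 = s.copy()
            s2[2] = 0
            P_unbind[k, pack(s2)] += pb
            P_unbind[k, k] += 1 - pb
        else:
            P_unbind[k, k] = 1.0
        for i, p in ((0, pg0), (1, pg)):
            if s[i] == 1 and s[i + 1] == 0:
                s2 = s.copy()
                s2[i], s2[i + 1] = 0, 1
                P_hop[i][k, pack(s2)] += p
                P_hop[i][k, k] += 1 - p
            else:
                P_hop[i][k, k] = 1.0
    P_elong = 0.5 * (P_hop[0] + P_hop[1])
    P = P_bind @ P_unbind @ P_elong @ P_elong
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return pi / pi.sum()


class TestStep:
    def test_alpha_zero_stays_empty(self):
        params = TasepParams(n=5, alpha=0.0, beta=1.0, gamma=1.0, dt=0.05)
        state = TasepState.empty(5)
        rng = np.random.default_rng(0)
        for t in range(500):
            step(state, params, rng, now=t)
        assert state.s.sum() == 0

    def test_gamma_zero_freezes_midgene_pol(self):
        params = TasepParams(n=5, alpha=0.0, beta=0.0, gamma=0.0, dt=0.05)
        state = TasepState.empty(5)
        state.s[2] = 1
        rng = np.random.default_rng(0)
        for t in range(500):
            step(state, params, rng, now=t)
        assert list(state.s) == [0, 0, 1, 0, 0]

    def test_exclusion_never_violated(self):
        params = TasepParams(n=8, alpha=1.5, beta=0.3, gamma=1.0, dt=0.05)
        state = TasepState.empty(8)
        rng = np.random.default_rng(1)
        for t in range(2000):
            step(state, params, rng, now=t)
            assert set(np.unique(state.s)) <= {0, 1}
            occupied = np.flatnonzero(state.s)
            # tags exist exactly on occupied sites
            assert (state.tags[occupied] >= 0).all()
            assert (state.tags[state.s == 0] == -1).all()


class TestStationaryDistribution:
    def test_three_site_chain_matches_exact_master_equation(self):
        """Empirical state frequencies of the simulated 3-site chain agree
        with the exact stationary law of the enumerated Markov chain."""
        params = TasepParams(n=3, alpha=1.0, beta=0.8, gamma=1.2, gamma0=0.6,
                             dt=0.05)
        pi = exact_stationary_n3(params)
        traj = simulate(params, steps=2_200_000, burn_in=200_000, seed=7,
                        record_every=1)
        idx = traj.s_series.astype(int) @ np.array([4, 2, 1])
        freq = np.bincount(idx, minlength=8) / len(idx)
        assert np.abs(freq - pi).max() < 0.01


class TestMeanField:
    def test_equal_boundaries_constant(self):
        x, rho = solve_meanfield(50, 0.215, 0.215)
        assert np.allclose(rho, 0.215)

    def test_solution_satisfies_ode(self):
        n = 50
        x, rho = solve_meanfield(n, 0.3, 0.1)
        # residual of (2n)^-1 rho'' + (2 rho - 1) rho' on the interior
        h = x[1] - x[0]
        d1 = np.gradient(rho, h)
        d2 = np.gradient(d1, h)
        res = d2 / (2 * n) + (2 * rho - 1) * d1
        assert np.abs(res[5:-5]).max() < 2e-2 * max(1.0, np.abs(d1).max())

    def test_boundaries_hit(self):
        x, rho = solve_meanfield(50, 0.3, 0.1)
        assert rho[0] == pytest.approx(0.3, abs=1e-6)
        assert rho[-1] == pytest.approx(0.1, abs=1e-6)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            solve_meanfield(50, -0.1, 0.5)


class TestBursting:
    def test_koff_zero_never_switches_off(self):
        params = TasepParams(n=4, alpha=0.5, beta=0.5, gamma=1.0, k_on=1.0,
                             k_off=0.0, dt=0.05)
        traj = simulate(params, steps=50_000, burn_in=0, seed=3,
                        record_every=10)
        assert traj.promoter_series.all()

    def test_symmetric_rates_half_time_on(self):
        params = TasepParams(n=4, alpha=0.0, beta=0.5, gamma=1.0, k_on=1.0,
                             k_off=1.0, dt=0.05)
        traj = simulate(params, steps=400_000, burn_in=10_000, seed=4,
                        record_every=1)
        frac_on = traj.promoter_series.mean()
        assert frac_on == pytest.approx(0.5, abs=0.02)

    def test_switching_rates_recovered(self):
        """Empirical on->off and off->on rates recover k within a few
        percent over 4e5 steps."""
        k = 0.5
        dt = 0.05
        params = TasepParams(n=4, alpha=0.0, beta=0.5, gamma=1.0, k_on=k,
                             k_off=k, dt=dt)
        traj = simulate(params, steps=400_000, burn_in=0, seed=5,
                        record_every=1)
        p = traj.promoter_series.astype(int)
        on_steps = (p[:-1] == 1).sum()
        off_steps = (p[:-1] == 0).sum()
        k_off_hat = ((p[:-1] == 1) & (p[1:] == 0)).sum() / (on_steps * dt)
        k_on_hat = ((p[:-1] == 0) & (p[1:] == 1)).sum() / (off_steps * dt)
        assert k_off_hat == pytest.approx(k, rel=0.1)
        assert k_on_hat == pytest.approx(k, rel=0.1)

    def test_derived_quantities_symmetric_case(self):
        params = TasepParams(n=4, alpha=2.0, beta=0.5, gamma=1.0, k_on=0.3,
                             k_off=0.3, dt=0.01)
        d = burst_derived(params)
        assert d.alpha_eff == pytest.approx(1.0)        # alpha/2
        assert d.burst_frequency == pytest.approx(0.15)  # k/2
        assert d.train_size == pytest.approx(2.0 / 0.3)  # alpha/k

    def test_derived_limits(self):
        inf_case = burst_derived(TasepParams(n=4, alpha=1.0, beta=0.5,
                                             gamma=1.0, k_on=0.5, k_off=0.0,
                                             dt=0.05))
        assert inf_case.train_size_infinite
        zero_case = burst_derived(TasepParams(n=4, alpha=0.0, beta=0.5,
                                              gamma=1.0, k_on=0.5, k_off=0.5,
                                              dt=0.05))
        assert zero_case.train_size == 0.0

    def test_no_bursting_alpha_eff_is_alpha(self):
        d = burst_derived(TasepParams(n=4, alpha=0.7, beta=0.5, gamma=1.0,
                                      dt=0.05))
        assert d.alpha_eff == 0.7


class TestObservables:
    def test_single_pol_transit_time(self):
        """An unobstructed Pol II crosses in 1/gamma0 + (n-2)/gamma + 1/beta
        minutes in expectation (equal to (n-1)/gamma + 1/beta at
        gamma0 = gamma)."""
        params = TasepParams(n=10, alpha=0.02, beta=0.5, gamma=1.0, dt=0.1)
        traj = simulate(params, steps=1_500_000, burn_in=10_000, seed=6)
        obs = transcription_observables(traj)
        assert obs["n_unloadings"] > 200
        expected = (params.n - 1) / params.gamma + 1.0 / params.beta
        se = expected / np.sqrt(obs["n_unloadings"])
        assert obs["mean_transit_min"] == pytest.approx(expected,
                                                        abs=4 * se + 0.2)
        assert obs["effective_elongation_rate"] == pytest.approx(1.0, abs=0.1)

    def test_low_density_rate_approaches_alpha(self):
        params = TasepParams(n=10, alpha=0.02, beta=0.5, gamma=1.0, dt=0.1)
        traj = simulate(params, steps=1_500_000, burn_in=10_000, seed=8)
        obs = transcription_observables(traj)
        assert obs["transcription_rate"] == pytest.approx(params.alpha,
                                                          rel=0.15)

    def test_current_non_monotone_with_maximum_near_half(self):
        """Unloading current follows gamma*rho*(1-rho): non-monotone in
        density, maximal near rho = 0.5."""
        rates = {}
        for dens in (0.139, 0.516, 0.8):
            p = uniform_profile_params(dens, gamma=1.0, n=30, dt=0.05)
            traj = simulate(p, steps=400_000, burn_in=40_000, seed=9)
            obs = transcription_observables(traj)
            rates[dens] = obs["transcription_rate"]
            oracle = dens * (1 - dens) * p.gamma
            assert rates[dens] == pytest.approx(oracle, rel=0.2)
        assert rates[0.516] > rates[0.139]
        assert rates[0.516] > rates[0.8]

    def test_no_transits_flagged(self):
        params = TasepParams(n=10, alpha=0.0, beta=0.5, gamma=1.0, dt=0.1)
        traj = simulate(params, steps=5_000, burn_in=0, seed=1)
        obs = transcription_observables(traj)
        assert not obs["elongation_defined"]

    def test_density_profile_se_flags_short_runs(self):
        p = uniform_profile_params(0.5, gamma=1.0, n=20, dt=0.05)
        short = simulate(p, steps=2_000, burn_in=1_000, seed=2, record_every=100)
        _, _, flagged = density_profile(short)
        assert flagged


class TestParams:
    def test_rate_dt_cap_enforced(self):
        with pytest.raises(ValueError, match="rate"):
            TasepParams(n=5, alpha=3.0, beta=0.5, gamma=1.0, dt=0.05)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            TasepParams(n=5, alpha=-1.0, beta=0.5, gamma=1.0, dt=0.01)

    def test_uniform_profile_construction(self):
        p = uniform_profile_params(0.215, gamma=1.0, n=50, dt=0.05)
        assert p.alpha == pytest.approx(0.215)
        assert p.beta == pytest.approx(0.785)
        assert p.gamma0 == p.gamma
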