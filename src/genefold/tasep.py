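"""Stochastic 1D model of Pol II traffic along a gene (TASEP).

A gene of ``n`` monomers carries a binary occupancy ``s_i`` (Pol II bound or
not).  Per Monte Carlo step (MCS): one attempt to load a Pol II at the TSS
with rate ``alpha`` (if the promoter is on and site 1 is empty), one attempt
to unload at the TTS with rate ``beta``, and ``n-1`` elongation attempts,
each picking a random site in [1, n-1] and hopping its Pol II forward if the
next site is free -- the first hop (initiation) uses ``gamma0``, interior
hops ``gamma``.  Pol IIs exclude each other and never bypass.  An optional
two-state promoter (rates ``k_on``/``k_off``) produces transcriptional
bursts; every loaded Pol II is tagged with its burst episode so trains can be
counted.

Rates are per minute; each attempt succeeds with probability ``rate * dt``
where ``dt`` is the MCS duration (default 3 ms, the lattice-time calibration
used for the coupled polymer model).  ``rate * dt`` is capped at 0.1 to
bound time-discretization bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_bvp

__all__ = [
    "DT_DEFAULT_MIN",
    "TasepParams",
    "TasepState",
    "TasepTrajectory",
    "BurstDerived",
    "step",
    "simulate",
    "density_profile",
    "solve_meanfield",
    "burst_derived",
    "transcription_observables",
    "uniform_profile_params",
]

#: default MCS duration in minutes (3 ms)
DT_DEFAULT_MIN = 0.003 / 60.0
#: per-attempt probability cap keeping discretization bias small
MAX_RATE_DT = 0.1


@dataclass
class TasepParams:
    """Rates (per minute) and geometry of the Pol II traffic model.

    ``gamma`` converts to an elongation speed of ``gamma * monomer_bp`` bp/min
    (2 kb monomers give the biological ~2 kb/min at gamma=1).  ``gamma0`` is
    the initiation (first-hop) rate, defaulting to ``gamma``.  Bursting is
    enabled by setting both ``k_on`` and ``k_off``.
    """

    n: int
    alpha: float
    beta: float
    gamma: float
    gamma0: float | None = None
    k_on: float | None = None
    k_off: float | None = None
    dt: float = DT_DEFAULT_MIN

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("gene must have n >= 2 monomers")
        if self.gamma0 is None:
            self.gamma0 = self.gamma
        rates = [self.alpha, self.beta, self.gamma, self.gamma0]
        if self.bursting:
            rates += [self.k_on, self.k_off]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        for r in rates:
            if r * self.dt > MAX_RATE_DT + 1e-12:
                raise ValueError(
                    f"rate*dt = {r * self.dt:.3g} exceeds {MAX_RATE_DT}; "
                    "reduce dt or the rate"
                )

    @property
    def bursting(self) -> bool:
        return self.k_on is not None and self.k_off is not None

    def probabilities(self) -> tuple[float, float, float, float, float, float]:
        """Per-attempt probabilities (pa, pb, pg, pg0, pon, poff)."""
        pon = (self.k_on or 0.0) * self.dt
        poff = (self.k_off or 0.0) * self.dt
        return (self.alpha * self.dt, self.beta * self.dt,
                self.gamma * self.dt, self.gamma0 * self.dt, pon, poff)


def uniform_profile_params(density: float, gamma: float = 1.0, n: int = 50,
                           dt: float = DT_DEFAULT_MIN, **kwargs) -> TasepParams:
    """Parameters producing a flat steady-state occupancy at the given density.

    Uses gamma0 = gamma and beta = gamma - alpha with alpha = density * gamma,
    the matched-boundary regime where the stationary profile is uniform at
    rho = alpha/gamma.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    alpha = density * gamma
    return TasepParams(n=n, alpha=alpha, beta=gamma - alpha, gamma=gamma,
                       gamma0=gamma, dt=dt, **kwargs)


@dataclass
class TasepState:
    """Occupancy vector, promoter state and per-Pol II tags."""

    s: np.ndarray
    promoter_on: bool = True
    episode: int = 0
    tags: np.ndarray = field(default=None)  # type: ignore[assignment]
    load_steps: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def empty(cls, n: int) -> "TasepState":
        return cls(s=np.zeros(n, dtype=np.uint8), promoter_on=True, episode=0,
                   tags=np.full(n, -1, dtype=np.int64),
                   load_steps=np.full(n, -1, dtype=np.int64))

    def train_count(self) -> int:
        """Number of distinct burst episodes currently elongating."""
        present = self.tags[self.s.astype(bool)]
        return len(np.unique(present)) if present.size else 0


def step(state: TasepState, params: TasepParams, rng: np.random.Generator,
         now: int = 0) -> TasepState:
    """One MCS, in place: bind, unbind, n-1 elongation attempts, promoter switch."""
    pa, pb, pg, pg0, pon, poff = params.probabilities()
    s, n = state.s, params.n
    if state.promoter_on and s[0] == 0 and rng.random() < pa:
        s[0] = 1
        state.tags[0] = state.episode
        state.load_steps[0] = now
    if s[n - 1] == 1 and rng.random() < pb:
        s[n - 1] = 0
        state.tags[n - 1] = -1
        state.load_steps[n - 1] = -1
    for _ in range(n - 1):
        i = int(rng.integers(0, n - 1))
        p = pg0 if i == 0 else pg
        if s[i] == 1 and s[i + 1] == 0 and rng.random() < p:
            s[i], s[i + 1] = 0, 1
            state.tags[i + 1] = state.tags[i]
            state.load_steps[i + 1] = state.load_steps[i]
            state.tags[i] = -1
            state.load_steps[i] = -1
    if params.bursting:
        if state.promoter_on:
            if rng.random() < poff:
                state.promoter_on = False
        elif rng.random() < pon:
            state.promoter_on = True
            state.episode += 1
    return state


@njit(cache=True)
def _run_kernel(n, pa, pb, pg, pg0, pon, poff, bursting, steps, burn,
                record_every, seed, max_events):  # pragma: no cover - jitted
    np.random.seed(seed)
    s = np.zeros(n, dtype=np.uint8)
    tags = np.full(n, -1, dtype=np.int64)
    loads = np.full(n, -1, dtype=np.int64)
    mean_s = np.zeros(n)
    n_frames = (steps - burn) // record_every if record_every > 0 else 0
    s_series = np.zeros((n_frames, n), dtype=np.uint8)
    prom_series = np.zeros(n_frames, dtype=np.uint8)
    train_series = np.zeros(n_frames, dtype=np.int32)
    events = np.zeros((max_events, 3), dtype=np.int64)
    n_events = 0
    promoter_on = True
    episode = 0
    frame = 0
    n_avg = 0
    for t in range(steps):
        if promoter_on and s[0] == 0 and np.random.random() < pa:
            s[0] = 1
            tags[0] = episode
            loads[0] = t
        if s[n - 1] == 1 and np.random.random() < pb:
            if t >= burn and n_events < max_events:
                events[n_events, 0] = loads[n - 1]
                events[n_events, 1] = t
                events[n_events, 2] = tags[n - 1]
                n_events += 1
            s[n - 1] = 0
            tags[n - 1] = -1
            loads[n - 1] = -1
        for _ in range(n - 1):
            i = np.random.randint(0, n - 1)
            p = pg0 if i == 0 else pg
            if s[i] == 1 and s[i + 1] == 0 and np.random.random() < p:
                s[i] = 0
                s[i + 1] = 1
                tags[i + 1] = tags[i]
                loads[i + 1] = loads[i]
                tags[i] = -1
                loads[i] = -1
        if bursting:
            if promoter_on:
                if np.random.random() < poff:
                    promoter_on = False
            else:
                if np.random.random() < pon:
                    promoter_on = True
                    episode += 1
        if t >= burn:
            mean_s += s
            n_avg += 1
            if record_every > 0 and (t - burn) % record_every == 0 and frame < n_frames:
                s_series[frame] = s
                prom_series[frame] = 1 if promoter_on else 0
                # count distinct episode tags among occupied sites
                cnt = 0
                for i in range(n):
                    if s[i] == 1:
                        fresh = True
                        for j in range(i):
                            if s[j] == 1 and tags[j] == tags[i]:
                                fresh = False
                                break
                        if fresh:
                            cnt += 1
                train_series[frame] = cnt
                frame += 1
    if n_avg > 0:
        mean_s /= n_avg
    return mean_s, s_series, prom_series, train_series, events, n_events


@dataclass
class TasepTrajectory:
    """Thinned occupancy trajectory plus time-averaged density and events."""

    params: TasepParams
    steps: int
    burn_in: int
    record_every: int
    mean_density: np.ndarray
    s_series: np.ndarray
    promoter_series: np.ndarray
    train_series: np.ndarray
    events: np.ndarray  # (n_events, 3): load step, unload step, episode tag

    @property
    def duration_min(self) -> float:
        return (self.steps - self.burn_in) * self.params.dt


def simulate(params: TasepParams, steps: int, burn_in: int = 0, seed: int = 0,
             record_every: int = 0) -> TasepTrajectory:
    """Run the TASEP for ``steps`` MCS, averaging occupancy after ``burn_in``.

    ``record_every > 0`` additionally stores a thinned occupancy series with
    promoter state and train counts at that cadence.
    """
    pa, pb, pg, pg0, pon, poff = params.probabilities()
    max_events = int(steps * min(pb, MAX_RATE_DT) * 1.2) + 1024
    out = _run_kernel(params.n, pa, pb, pg, pg0, pon, poff, params.bursting,
                      steps, burn_in, record_every, seed, max_events)
    mean_s, s_series, prom, trains, events, n_events = out
    return TasepTrajectory(params=params, steps=steps, burn_in=burn_in,
                           record_every=record_every, mean_density=mean_s,
                           s_series=s_series, promoter_series=prom,
                           train_series=trains, events=events[:n_events])


def density_profile(traj: TasepTrajectory, se_warn: float = 0.05):
    """Time-averaged occupancy with a naive standard-error estimate.

    The SE is computed from the thinned series (if recorded); a trajectory
    too short for the requested precision is flagged.
    """
    mean = traj.mean_density
    if traj.s_series.shape[0] > 1:
        se = traj.s_series.std(axis=0, ddof=1) / np.sqrt(traj.s_series.shape[0])
    else:
        se = np.full_like(mean, np.nan)
    flagged = bool(np.nanmax(se) > se_warn) if np.isfinite(se).any() else True
    return mean, se, flagged


def solve_meanfield(n: int, rho0: float, rho1: float,
                    mesh: int = 401, tol: float = 1e-10):
    """Steady-state mean-field density: (2n)^-1 rho'' + (2 rho - 1) rho' = 0.

    Two-point boundary-value problem with rho(0)=rho0 and rho(1)=rho1 solved
    numerically; equal boundary values return the exact constant solution.
    Returns ``(x, rho)``; raises ``RuntimeError`` with the residual when the
    solver fails to converge.
    """
    for r in (rho0, rho1):
        if not 0.0 <= r <= 1.0:
            raise ValueError("boundary densities must lie in [0, 1]")
    x = np.linspace(0.0, 1.0, mesh)
    if abs(rho0 - rho1) < 1e-14:
        return x, np.full(mesh, rho0)

    def odes(x, y):
        return np.vstack([y[1], -2.0 * n * (2.0 * y[0] - 1.0) * y[1]])

    def bc(ya, yb):
        return np.array([ya[0] - rho0, yb[0] - rho1])

    guess = np.vstack([rho0 + (rho1 - rho0) * x, np.full(mesh, rho1 - rho0)])
    sol = solve_bvp(odes, bc, x, guess, tol=tol, max_nodes=200_000)
    if not sol.success:
        raise RuntimeError(
            f"mean-field BVP did not converge (residual {sol.rms_residuals.max():.3g})"
        )
    rho = sol.sol(x)[0]
    return x, rho


@dataclass
class BurstDerived:
    """Closed-form observables of the two-state (telegraph) promoter."""

    alpha_eff: float
    burst_frequency: float
    train_size: float
    train_size_infinite: bool = False


def burst_derived(params: TasepParams) -> BurstDerived:
    """Effective loading rate, burst frequency and mean train size.

    alpha_eff = alpha k_on / (k_on + k_off); burst frequency =
    k_on k_off / (k_on + k_off) (bursts per minute); train size =
    alpha / k_off (mean Pol IIs loaded per burst, infinite when k_off -> 0).
    """
    if not params.bursting:
        return BurstDerived(alpha_eff=params.alpha, burst_frequency=0.0,
                            train_size=float("inf") if params.alpha > 0 else 0.0,
                            train_size_infinite=params.alpha > 0)
    kon, koff = params.k_on, params.k_off
    ktot = kon + koff
    alpha_eff = params.alpha * kon / ktot if ktot > 0 else params.alpha
    freq = kon * koff / ktot if ktot > 0 else 0.0
    if params.alpha == 0:
        return BurstDerived(alpha_eff=alpha_eff, burst_frequency=freq,
                            train_size=0.0)
    if koff == 0:
        return BurstDerived(alpha_eff=alpha_eff, burst_frequency=freq,
                            train_size=float("inf"), train_size_infinite=True)
    return BurstDerived(alpha_eff=alpha_eff, burst_frequency=freq,
                        train_size=params.alpha / koff)


def transcription_observables(traj: TasepTrajectory) -> dict:
    """Transcription rate, effective elongation rate and train statistics.

    The transcription rate is the number of Pol II unloadings from the TTS
    per minute.  The effective elongation rate is the inverse of the mean
    time a Pol II needs to traverse the gene, normalized by the unobstructed
    expectation 1/gamma0 + (n-2)/gamma + 1/beta so a free Pol II scores ~1.
    """
    p = traj.params
    n_unload = traj.events.shape[0]
    rate = n_unload / traj.duration_min if traj.duration_min > 0 else float("nan")
    out = {
        "transcription_rate": rate,
        "n_unloadings": n_unload,
        "train_series": traj.train_series,
    }
    if n_unload == 0:
        out["effective_elongation_rate"] = float("nan")
        out["elongation_defined"] = False
        return out
    transit_min = (traj.events[:, 1] - traj.events[:, 0]).astype(float) * p.dt
    free_transit = 1.0 / p.gamma0 + (p.n - 2) / p.gamma + 1.0 / p.beta
    out["mean_transit_min"] = float(transit_min.mean())
    out["effective_elongation_rate"] = float(free_transit / transit_min.mean())
    out["elongation_defined"] = True
    return out
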