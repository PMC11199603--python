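"""Pol II occupancy profiles of the transcription traffic model.

Simulates the TASEP on a 50-monomer gene in the matched-boundary regime
(gamma0 = gamma, beta = gamma - alpha) where the stationary profile is
uniform at rho = alpha/gamma, and compares the stochastic profile with the
mean-field boundary-value solution.  Also prints the closed-form bursting
observables for a two-state promoter.
"""

import numpy as np

from genefold.tasep import (TasepParams, burst_derived, simulate,
                            solve_meanfield, transcription_observables,
                            uniform_profile_params)

for density in (0.215, 0.516, 0.8):
    params = uniform_profile_params(density, gamma=1.0, n=50, dt=0.05)
    traj = simulate(params, steps=500_000, burn_in=50_000, seed=1)
    interior = traj.mean_density[10:40]
    obs = transcription_observables(traj)
    print(f"rho target {density:.3f}: simulated interior occupancy "
          f"{interior.mean():.3f}, transcription rate "
          f"{obs['transcription_rate']:.3f}/min "
          f"(current oracle {density * (1 - density):.3f})")

x, rho = solve_meanfield(50, rho0=0.3, rho1=0.1)
print(f"\nmean-field profile with rho(0)=0.3, rho(1)=0.1: "
      f"bulk {rho[len(rho) // 2]:.3f}, boundary layer at the exit")

burst = burst_derived(TasepParams(n=50, alpha=1.0, beta=0.5, gamma=1.0,
                                  k_on=0.02, k_off=0.02, dt=0.05))
print(f"bursting at k=0.02/min: alpha_eff={burst.alpha_eff:.2f}/min, "
      f"burst frequency={burst.burst_frequency:.3f}/min, "
      f"train size={burst.train_size:.0f} Pol IIs")
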