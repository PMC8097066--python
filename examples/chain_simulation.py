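"""Simulate chain hydrolysis for the 10-CB and 100-CB scenarios.

The state vector omega_i holds the mass fraction of each molecular-mass
class; one discrete step advances it by the transition matrix.  The 10-CB
run uses a 100 s step and a glucose-terminal ladder; the 100-CB run uses a
10 s step, a glucose-then-HMF ladder and the published process conditions
(T = 483 K vs 453 K, 4% vs 1% acid).
"""

import numpy as np

from cellhydro import RunConfig, config_from_dict, run_simulation

# --- 10 cellobiose units, Gauss scission, reference conditions ----------
cfg = RunConfig()  # the defaults are exactly this scenario
ladder, P, traj = run_simulation(cfg)
print("10-CB chain, Gauss scission, dt = 100 s")
print("  step  omega_0  omega_5  omega_10(glucose)")
for n in (0, 1, 2, 5, 10, 20, 50):
    w = traj.states[n]
    print(f"  {n:>4}  {w[0]:.4f}   {w[5]:.4f}   {w[10]:.4f}")
print("-> the intact chain empties within a couple of steps; glucose")
print("   absorbs essentially all mass after ~10 steps (1000 s).")

# --- 100 cellobiose units at the published hot/acid conditions ----------
cfg200 = config_from_dict({"n_units": 100, "n_steps": 200})
ladder, P, traj = run_simulation(cfg200)
c = traj.concentrations
print("\n100-CB chain, Gauss scission, dt = 10 s, c_C0 = 100 g/L")
print("  time (s)  chains (g/L)  glucose (g/L)  HMF (g/L)")
for n in (0, 5, 10, 20, 40, 80, 200):
    chains = c[n, :99].sum()
    print(f"  {traj.times[n]:>8.0f}  {chains:>12.2f}  {c[n, 99]:>13.2f}  {c[n, 100]:>9.2f}")
print("-> heavy chains disappear quickly; glucose passes through a")
print("   transient maximum before degrading to HMF, the absorbing class.")
assert np.allclose(traj.states.sum(axis=1), 1.0, atol=1e-9)
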