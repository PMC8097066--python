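# cellhydro

Markov-chain and first-order kinetic models of acid cellulose hydrolysis.

Dilute-acid hydrolysis chops cellulose chains into ever shorter fragments
until only glucose — and, at harsher conditions, its degradation product
hydroxymethylfurfural (HMF) — remains.  Classical treatments compress this
into one or two pseudo-homogeneous first-order reactions; `cellhydro`
instead resolves the full fragment population as an absorbing Markov chain
over molecular-mass classes, with the scission position governed by a
probability distribution.  It is aimed at reaction-engineering and
biorefinery modellers who want fragment-resolved hydrolysis kinetics with
a handful of interpretable parameters, plus the classical scheme alongside
for comparison.

## The model

A chain of `n` cellobiose units (342 g/mol each; a bond condenses out
18 g/mol of water) is discretized into molecular-mass classes
`i = 0 .. N`: class 0 is the intact chain (e.g. 3258 g/mol for 10 units),
each following class is one unit lighter (324 g/mol spacing), and the
terminal class — glucose, or HMF fed from a glucose class — is absorbing.

During a time step `Δτ`, a chain in class `i` cleaves and jumps to a
lighter class `j > i` with probability

    P_ji = f(j − i),        p_i = Σ_j P_ji,      P_ii = 1 − p_i,

where `f` is a Gauss density (mid-chain scission, endo-type attack)

    f_GS(x) = exp(−(x − μ)² / 2σ²) / (σ √2π),
    μ(x) = (N + 1 − x)/2,   σ²(x) = ((N + 1 − x)² − 1)/12,

or a Weibull density (chain-end scission, exo-type attack)

    f_W(x) = (β/λ)(x/λ)^{β−1} exp(−(x/λ)^β),
    λ(x) = 1.4 + μ(x)/N,    β(x) = 0.95 + σ²(x)/N.

The state vector of class mass fractions `ω` evolves as
`ω(τ_{n+1}) = P ω(τ_n)` (or through the equivalent continuous-time mass
balance, integrated with fixed-step RK4).  Transition frequencies
`α_ji = P_ji/Δτ` can be re-proportioned by destination molar mass and are
modulated by acid concentration and temperature:

    g(c_a) = (c_a/c_a,ref)^n,    h(T) = exp[(E_A/R)(1/T − 1/T_ref)],

with a separate activation energy for the glucose → HMF step.  The
deterministic reference is the consecutive first-order scheme
`C →k1→ G →k2→ HMF` with its closed-form solutions and
Arrhenius/acid-order rate constants; agreement between the two models is
quantified by RMSE and by CV = RMSE / mean of the reference trajectory.

## Worked example

```python
from cellhydro import RunConfig, run_simulation

ladder, P, traj = run_simulation(RunConfig())   # 10-CB chain, Gauss, dt = 100 s
for n in (0, 1, 2, 5, 10):
    w = traj.states[n]
    print(f"step {n:>2}: omega_0 = {w[0]:.4f}  omega_10 = {w[10]:.4f}")
```

prints

```
step  0: omega_0 = 1.0000  omega_10 = 0.0000
step  1: omega_0 = 0.1123  omega_10 = 0.0056
step  2: omega_0 = 0.0126  omega_10 = 0.0554
step  5: omega_0 = 0.0000  omega_10 = 0.7020
step 10: omega_0 = 0.0000  omega_10 = 0.9975
```

— the intact 3258 g/mol chain (class 0) survives one 100 s step with
probability 0.11 and is essentially gone after two; glucose (class 10,
the absorbing terminal class) holds 70 % of the mass after 500 s and
virtually all of it after 1000 s.  The scripts in `examples/` walk through
the mass ladder, matrix assembly and modulation, both simulation
scenarios, and the deterministic comparison; a thin CLI exposes the same
pipelines (`cellhydro matrix|simulate|deterministic|compare|fixtures`).

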