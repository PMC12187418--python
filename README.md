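# spinloop

Intrinsic-utility analysis of the 2D Ising model read as a
perception–action loop.

Why do self-organizing collectives — flocks, swarms, neural tissue — so
often sit near a critical point?  One family of explanations says agents
optimize an *intrinsic* utility, and the candidates disagree about where
the optimum lies.  `spinloop` puts four of them side by side on the same
canonical system, the square-lattice Ising model at β = 1 with coupling J
as the control knob, where every site is an agent: it senses the alignment
of its four neighbours (m = Σ σᵢσⱼ ∈ {−4,−2,0,2,4}), acts by flipping its
spin or not, and lives in a world summarized by the lattice magnetization.

The four utilities, all computable from equilibrium event samples:

- **Predictive information** I(S_{t+1}; S_t) — mutual information between
  the sensory state before and after one action (bits); favours *weak*
  coupling.
- **Empowerment** Ē = Σ_s p(s)·C(s), the capacity of the action channel
  p(s_{t+1}|a_t): C = 1 bit for s ≠ 0 (noiseless binary channel), 0 for
  s = 0; favours *strong* coupling.
- **Negative variational free energy** −F̄ = −Σ_a p(a)·H(S_{t+1}|W_{t+1},a)
  (bits, ≤ 0), the intrinsic active-inference term; favours *strong*
  coupling.
- **Thermodynamic efficiency**
  η(J) = (−dS/dJ) / ∫_J^{J*} I(J′) dJ′ — entropy reduction per unit of
  generalized work, with S the Kikuchi configuration entropy
  (S₄ − 2S₂ + S₁ per site) and I the Fisher information
  β²·Var(M)/L² of the Boltzmann family; favours the *critical* region,
  and its large-lattice asymptote η = [ln(1+√2)/2]·|J − Jc|⁻¹ diverges at
  Jc = ln(1+√2)/2 ≈ 0.4407.

The package provides the Monte-Carlo simulator (Glauber/Metropolis, numba
kernel), plug-in estimators for all four measures, an exact enumeration
oracle for L ≤ 4 that the estimators are tested against, the closed-form
critical results, and sweep/finite-size orchestration with a CLI.  It is
aimed at researchers studying criticality and intrinsic motivation in
collective systems who want a reproducible, tested reference
implementation.

## Worked example

A small sweep (L = 16, Glauber, 3 replicates of 2×10⁵ events — a couple of
seconds; defaults are 10 × 2×10⁶):

```python
from spinloop.sweep import SweepConfig, run_sweep

cfg = SweepConfig(J_grid=(0.1, 0.3, 0.45, 0.7, 1.0), L=16,
                  rules=("glauber",), n_steps=200_000,
                  replicates=3, base_seed=42)
res = run_sweep(cfg)
print(res.aggregated.round(4).to_string(index=False))
```

which prints (abridged):

```
        measure    rule  L     J    mean  n  stderr
    empowerment glauber 16  0.10  0.6368  3  0.0013
    empowerment glauber 16  1.00  1.0000  3  0.0000
        entropy glauber 16  0.10  0.6831  3  0.0002
        entropy glauber 16  1.00  0.0013  3  0.0001
         fisher glauber 16  0.45  7.6776  3  1.0778
         fisher glauber 16  1.00  0.0258  3  0.0015
neg_free_energy glauber 16  0.10 -2.0057  3  0.0013
neg_free_energy glauber 16  1.00 -0.0179  3  0.0003
             pi glauber 16  0.10  1.4251  3  0.0002
             pi glauber 16  1.00  0.0175  3  0.0003
```

Reading it: at weak coupling (J = 0.1) a site's future is rich and
guessable from its past (PI ≈ 1.43 bits) but its actions barely register
in the world (empowerment 0.64 bits) and its local view explains little of
the global state (−F̄ ≈ −2 bits).  At strong coupling (J = 1) the lattice
is ordered: actions are fully perceivable (1 bit), surprise is nearly zero,
and sensory diversity — hence PI — is gone.  The Fisher information peaks
near the critical coupling (J = 0.45, close to Jc ≈ 0.4407), where the
entropy falls fastest; `res.efficiency_curve("glauber", 16)` combines the
entropy and Fisher columns into η(J).  The closed forms are one call away:

```python
>>> import spinloop as sl
>>> sl.onsager_critical_coupling().Jc
0.44068679350977147
>>> sl.ising_efficiency_asymptote(0.5)   # [ln(1+√2)/2] / |0.5 - Jc|
7.429805949557826
```

The same machinery is exposed on the command line:

```bash
spinloop simulate -L 16 -J 0.45 --rule glauber --steps 200000 --out runs/demo
spinloop sweep --j-grid 0.05:1.0:0.05 --replicates 10 --out runs/sweep
spinloop finite-size --lengths 8,16,32 --j-grid 0.40:0.60:0.025 --out runs/fs
spinloop analytic --j-grid 0.42,0.46,0.5
spinloop oracle-check -L 3 --j-grid 0.0,0.3 --events 100000
```

See `docs/methods.md` for estimator details (symmetrization and bias
correction of the Kikuchi entropy, magnetization binning, the work
integral to the zero-response point J* = 10) and for why the choice of
entropy convention shapes the ordered-phase tail of the efficiency curve.

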