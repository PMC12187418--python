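# Methods

## Model and perception–action reading

The system is the zero-field square-lattice Ising model with periodic
boundaries, Hamiltonian

    H(σ) = −J · M(σ),        M(σ) = Σ_{⟨ij⟩} σ(i) σ(j),

where the link sum M counts each nearest-neighbour bond once and the
inverse temperature is fixed at β = 1, so the coupling J is the only
control parameter.  Each site is read as an agent in a perception–action
loop: its *sensory state* is the neighbour-alignment category
m = Σ_{j∈ν(i)} σ(i)σ(j) ∈ {−4, −2, 0, 2, 4} (the site energy is −J·m), its
*action* is flip (a = −1) or no-flip (a = +1), and the *world state* is the
lattice magnetization w.  Storing m rather than the energy −J·m keeps the
sensory alphabet non-degenerate at J = 0, where every energy collapses to
zero but the alignment statistics remain informative; the two carry the
same information for any J ≠ 0.

Dynamics are single-site Glauber or Metropolis updates: one uniformly
random site per time step (an update attempt is the time unit — not a
sweep), flip probability 0.5·[1 − tanh(0.5·β·dE)] or min(1, e^{−β·dE})
with dE = 2·J·m.  Both satisfy detailed balance with respect to the
Boltzmann law, which the test suite checks exactly on enumerated
configurations.  One event record stores (a, σ, m, w) immediately before
and after the action; post-action fields are derived from the pre-action
ones (σ′ = a·σ, m′ = a·m, w′ = w − (1−a)·σ/L²), so the record-level
invariants hold by construction.

## Sampling protocol (the data generator)

`simulate` discards a burn-in, records n_steps events, and stores a full
lattice snapshot every snapshot_interval steps.  Defaults (the package's
desk-scale study conditions): L = 16, burn-in 200·L² steps (200 sweeps),
n_steps = 2×10⁶, snapshot interval L² (one sweep), 10 replicates per
condition; a paper-scale profile (L = 50, 2×10⁷ steps, 100 replicates) is a
configuration away for users with hours of compute.  All randomness in a
run comes from one numpy Generator: the initial condition (if random) is
drawn first, then the site-index stream, then the uniform stream, so a run
is a pure function of its spec.  Replicate seeds derive from a base seed
via `SeedSequence([base, L, rule, round(J·10⁶), replicate])`, making
replicates independent, individually reproducible, and order-free to
aggregate.  The inner update loop is numba-compiled; a desk-scale replicate
takes well under a second.

Initial condition: uniform random spins below the critical coupling,
all-up above it (the `auto` policy).  Deep in the ordered phase a random
start must coarsen through long-lived domain-wall (stripe) states; starting
aligned removes that transient, and equilibrium statistics do not depend on
the starting sector.

## The four intrinsic utilities

**Predictive information** is the plug-in mutual information between the
pre- and post-action sensory categories of one event,
I(m′; m) = H(m′) − H(m′|m), reported in bits together with its
diversity/unpredictability decomposition.  Pairs are within-event; the
25-cell alphabet and ≥10⁶ samples make plug-in bias negligible at
production scale.  A Miller–Madow flag exists for matched-small-n
comparisons against the oracle.

**Empowerment** is the capacity of the one-step action channel
p(m′ | a) averaged over sensory contexts.  For m ≠ 0 the channel is a
noiseless binary permutation (flip → −m, no-flip → m): capacity 1 bit,
achieved by the uniform action law.  For m = 0 both actions give the same
output: capacity 0.  Hence the average empowerment is 1 − p̂(m = 0) bits.
The closed-form capacities are cross-checked by Blahut–Arimoto iteration on
the explicitly constructed channels.

**Negative variational free energy** keeps only the intrinsic
(entropy) term of the active-inference objective:
−F̄ = −Σ_a p̂(a) · H(m′ | w′, a) in bits, always ≤ 0, measuring how well a
site's local sensory outcome is pinned down by the global world state and
its own action.  The magnetization must be discretized: exact levels
(ssum/L²) for L ≤ 8, otherwise 21 equal-width bins on [−1, 1]; the choice
is a recorded run parameter, not a hidden constant.

**Thermodynamic efficiency** is the ratio of the entropy-reduction rate to
the generalized-work rate,

    η(J) = (−dS/dJ) / ∫_J^{J*} I(J′) dJ′ ,

with both ingredients per site and in nats (ratios on the k_B = 1 scale).
The configuration entropy uses the Kikuchi (cluster-variation) combination
S = S4 − 2·S2 + S1 over 2×2-plaquette, nearest-pair (horizontal and
vertical pooled) and single-site marginals, one plaquette, two pairs, and
one site anchored per lattice position; that normalization yields exactly
ln 2 per site for independent uniform spins and 0 for a frozen lattice.
The Fisher information of the equilibrium family with respect to J uses
the exponential-family identity I(J) = β²·Var(M)/L² evaluated on
snapshots — exact for a Boltzmann family, cheap, and cross-checked in the
suite against the curvature of the KL divergence computed by enumeration.
The work integral runs to the zero-response point J* = 10 (configurable)
by the trapezoid rule; sweeps measure Fisher information on a sparse
high-J extension grid so the integral is covered beyond the main grid,
where the lattice is essentially frozen and the integrand is
exponentially small.  dS/dJ uses central differences (one-sided at the
ends; optional width-3 moving-average smoothing, off by default and
recorded when used).  Points where the work integral falls below 10⁻¹²
are flagged undefined rather than dropped.

### Estimator details worth knowing

*Symmetrization.*  The zero-field equilibrium law is invariant under a
global spin flip, but a finite run divides its time unevenly between the
two magnetization sectors.  The Kikuchi combination is sensitive to that
split at the order of the excitation density: under the symmetric law the
single-site marginal saturates at exactly (½, ½) while the cluster terms
do not, so a sector-pure run overstates S by roughly the single-site
excitation entropy (measured ≈ +7×10⁻³ nats at L = 4, J = 0.8 with 5×10⁴
events — persisting until runs are much longer than the sector-switching
time).  The estimator therefore pools every snapshot with its global flip
by default, which matches the functional the exact oracle evaluates and
reduces variance; `symmetrize=False` restores the raw count.

*Split-half bias correction.*  Plug-in entropies are biased downward by
O(1/n).  Exactly at J = 0 the Kikuchi estimate sits at its maximum ln 2,
where the estimator's first-order fluctuation cancels (count deviations
sum to zero) and the remaining error is pure bias of the same magnitude
as its spread — no amount of replicate averaging makes a plain z-test
sensible there.  `bias_correction="split"` applies the split-half
jackknife 2·S(n) − mean(S(n/2)), removing the O(1/n) term at a modest
variance cost; it is used for small-sample oracle comparisons and off by
default at production sizes.

## Exact enumeration oracle

For L ≤ 4 the full Boltzmann distribution over 2^{L²} configurations is
enumerated (bit-indexed row-major).  From it the package computes the exact
single-flip transition matrix (L ≤ 3; stationarity on the Boltzmann law
holds to <10⁻¹⁰ total variation), the exact joint law of one
perception–action event (configuration ~ Boltzmann, site ~ uniform,
action ~ flip probability), and exact values of all measures: PI,
empowerment, −F̄ from the event law; true per-site entropy from the
configuration probabilities; the exact Kikuchi value from exact marginals
(kept separate from the true entropy — Kikuchi is an approximation, and
the right comparator for the simulation estimator is the same functional,
not the true entropy; on L = 4 lattices the two differ by < 0.05 nats);
and Fisher information β²·Var(M)/L².  Sampling estimators are tested to
agree with the oracle within three replicate standard errors across both
dynamics and J ∈ {0, 0.2, 0.4, 0.8}, at 12 replicates of 5×10⁵ events
(the Kikuchi check adds a 22/n-nat floor, the iid plug-in bias scale, for
the degenerate uniform point described above).

## Closed forms

The critical coupling solves sinh(2βJc) = 1: Jc = ln(1+√2)/(2β) ≈ 0.4407
at β = 1.  Near criticality the efficiency of the square-lattice model
follows η(J) = [ln(1+√2)/2]·|J − Jc|⁻¹, and the mean-field (Curie–Weiss)
model diverges with the same |θ − θc|⁻¹ exponent with branch prefactors
−θc/(2k_B) below and 1/k_B above the critical temperature.  These are
encoded, not re-derived; the extracted source rendered the square-lattice
prefactor ambiguously and ln(1+√2)/2 is the unique constant consistent
with Jc at β = 1 (it *is* Jc numerically).

## What the sweeps show — and why the entropy convention matters

At desk scale the sweep reproduces the expected qualitative picture:
predictive information is large at weak coupling (≈1.4–1.8 bits), is
maximal at the smallest grid J under Metropolis while Glauber peaks nearer
the critical region, and collapses below 0.1 bits by J = 1; empowerment
rises monotonically from 0.625 bits (the binomial weight of m ≠ 0 at
J = 0) toward 1 bit; negative free energy rises monotonically toward 0;
the Kikuchi entropy decreases monotonically from ≈ ln 2; the efficiency
rises to a peak just above the critical coupling (J = 0.50 at L = 16)
and decays on both sides.

The shape of the efficiency tail deserves an honest accounting, because
it depends on which entropy the numerator differentiates.  For this
Boltzmann family an exact identity holds for the *true* configuration
entropy: −dS/dJ = J·I(J) (verified to machine precision against
enumeration).  The true entropy's ordered-phase tail is carried by dilute
single-spin excitations, S ≈ (1 + 8J)·e^{−8J} per site with
I ≈ 64·e^{−8J}, so with that numerator η → 8J — the efficiency would
*grow* linearly through the upper end of the sweep, and on small lattices
(where the near-critical peak height grows only logarithmically with L
through the specific-heat maximum) the growth would dominate the curve.
The cluster-variation entropy of the *symmetric* equilibrium law behaves
differently: its single-site term is pinned at exactly ln 2 for every J
(the symmetric single-site marginal is always (½, ½)), so the
spin-flip-symmetric global bit cancels in S₄ − 2·S₂ + S₁ and the tail is
≈ 4·ln 2·e^{−8J}, giving a *bounded* tail η → 4·ln 2 ≈ 2.77 that the
critical peak clearly exceeds.  The package estimates exactly this
symmetric-law functional (that is what the symmetrized estimator is
consistent for, what the enumeration oracle evaluates, and what pooling
records across many random-initialized replicates produces naturally,
since individual ordered-phase runs never change sector): under this
convention the desk-scale efficiency peaks in the near-critical window
and the whole curve has the expected published shape.  The identity
−dS/dJ = J·I is asserted in the suite only through J ≤ 0.6, where the
cluster entropy tracks the true entropy; the deliberate tail departure is
a property of the convention, not an estimator defect.

The finite-size analysis asks where within the critical neighbourhood the
peak sits: on a J ∈ [0.40, 0.60] window (step 0.025, 8 replicates) the
peak location is non-increasing in L and approaches Jc from above (L = 32
peaks at 0.450, within one grid step of Jc), the finite-size displacement
expected of the pseudo-critical point.  The measured log–log slope of η
against |J − Jc| above the peak is still far from the asymptotic −1 at
these sizes, so the inverse-distance law is asserted only where it is
exact (the closed forms), not on scaled-down simulations.

## Numerical choices and degenerate inputs

- Entropies in bits for the information measures (matching their usual
  reporting), nats internally for configuration entropy and Fisher
  information; the efficiency ratio is basis-invariant.
- 0·log 0 ≡ 0 throughout; conditional entropies average over observed
  conditioning cells weighted by their empirical mass.
- Mutual information is clamped at 0 against floating-point cancellation;
  single-cell tables return 0.
- Ties in the efficiency argmax break toward smaller J (recorded
  behaviour, exercised in tests).
- Degenerate efficiency denominators (work integral below 10⁻¹²) yield
  NaN with a `defined` mask; an all-undefined curve raises.
- Enumeration refuses L > 4; the transition matrix L > 3; Fisher
  estimation needs ≥ 2 snapshots; derivatives need ≥ 3 grid points.

## What the generator does not emulate

The simulator produces exact equilibrium samples of the model itself, so
oracle agreement validates the estimators, not any claim about real
collective systems: there is no external field, no noise in sensing or
action, no heterogeneity across agents, and no out-of-equilibrium drive.
Passing tests show the measures are computed correctly at the stated
sample sizes; finite-size and finite-sampling artifacts (pseudo-critical
shift, plug-in bias, the ordered-phase η background) are characterized
above rather than removed.

## Known limitations

- One-step, context-free empowerment only; no n-step channels, no policy
  optimization, and no full active-inference belief updating — only the
  intrinsic term of the free energy.
- Kikuchi is an uncontrolled approximation of the true configuration
  entropy (exact only on trees); on enumerable lattices the discrepancy is
  bounded in the suite, on large lattices it is unquantified.
- Fisher information from snapshot variance ignores snapshot
  autocorrelation in its per-replicate error bar; uncertainties are
  therefore always taken across independent replicates.
- The efficiency peak location inherits one-sided-difference bias at grid
  boundaries; windows should bracket the region of interest.
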