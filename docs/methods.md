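# Methods

## The models

`ribodyn` implements two closed mass-action models of protein translation
and the machinery to analyze how a microRNA — modeled as a multiplicative
suppression of one rate constant — changes what an experiment can observe.

**Linear cycle.** Three species (free 40S subunit, the initiation complex
mRNA:40S, the start-codon complex AUG) cycle through initiation-complex
assembly (k1), late cap-independent initiation (k2) and combined
elongation/termination (k3), the last step releasing the subunit and one
protein. The total 40S pool is conserved. With k3 ≫ k1, k2 the dynamics
splits into a fast elongation transient (~1/k3) and a slow exchange
between the free subunit and the initiation complex, giving

    Prsynth_ss = [40S]0 · k1 k2 / (k1 + k2),    t_rel = 1/(k1 + k2).

**Recycling (non-linear) model.** Six species and four irreversible
reactions:

    R1: 40S + eIF4F -> mRNA:40S        (k1, second order)
    R2: mRNA:40S    -> AUG + eIF4F     (k2)
    R3: AUG + 60S   -> 80S             (k3, second order)
    R4: 80S         -> 40S + 60S       (k4, one protein per turn)

with three conservation laws (total 40S in all its forms; total eIF4F free
plus bound; total 60S free plus assembled). mRNA is a catalyst-like
"place" and is folded into the rate constants; synthesis, degradation and
storage of mRNA/microRNA are outside the models by construction.

All quantities are in relative, unitless model units; no calibration to
wall-clock time scales is attempted.

## Steady state and the regime ratio

Flux balance plus the conservation laws reduce the steady state to one
scalar equation in the free-60S fraction x = [60S]s/[60S]0, solved by
bracketed root finding on the physical branch (residual tolerance 1e-12;
the closure is monotone there, diverging at the left edge and negative at
x = 1). Dropping the term bounded by the scarce factor pool turns the
closure into a cubic

    x³ + (δ+β−2+γ+αβ) x² + [(δ−1)(β−1) − αβ − γ(2−β)] x + γ(1−β) = 0,

with α = k4/(k1[eIF4F]0), β = k2[eIF4F]0/(k4[60S]0), γ = k4/(k3[60S]0),
δ = [40S]0/[60S]0. One root (x2) is always negative; of the remaining
two, exactly one survives back-substitution with positive [eIF4F]s and
[40S]s — the near-zero root x0 ≈ γ(β−1)/a1 when β > 1, the order-one root
x1 ≈ (1−β) + corrections when β < 1 (the α term is kept in the quadratic
precisely so that [eIF4F]s does not collapse to zero there).

β is the critical parameter combination: the maximal initiation flux
k2[eIF4F]0 against the maximal recycling flux k4[60S]0. To leading order
the steady synthesis rate is min(k2[eIF4F]0, k4[60S]0) — factor-limited
under *inefficient initiation* (β < 1), recycling-limited under
*efficient initiation* (β > 1) — and never depends on k1 or k3 directly.
Results within |β−1| < 0.05 carry a regime-boundary flag; the asymptotic
formulas are not trusted there and the staged solver falls back to
numerics.

## Numerical integration

`solve_ivp` with LSODA (switching to Radau when the elongation scale
exceeds the other rate scales by more than two orders of magnitude),
rtol 1e-8 / atol 1e-10, dense output on a log-spaced grid. Trajectories
are rejected if any conservation law drifts beyond 1e-6 relative or any
concentration undershoots −1e-9; surviving sub-tolerance negatives are
clipped to zero.

## Dominant-system staged solution

For β > 1 from the all-free start the relaxation passes through three
dominant systems (">>" means a factor of 10 throughout):

1. **Stage 1** ([40S] ≫ [eIF4F], [60S] ≫ [AUG]): both bimolecular
   reactions are pseudo-monomolecular; eIF4F, mRNA:40S and AUG rush to
   quasiequilibrium plateaus (cascade ramps with rates k1[40S]0+k2 and
   k3[60S]0 describe the switch-on) while [80S] integrates the
   near-constant initiation flux w0 ≈ k2[eIF4F]0. After
   t′ = −ln(1−k4[60S]0/(10 w0))/k4 the plateaus drift with the depleting
   pools; the stage ends at t″ where [60S] falls to √(10 w0/k3), i.e.
   [60S] = 10·[AUG] fails.
2. **Stage 2** ([40S] ≫ [eIF4F], [60S] ≪ [AUG]): both network cycles are
   internally flux-balanced. The product integrates the two-variable
   reduction (slow [40S]; residual free [60S] still being absorbed),
   slaving mRNA:40S to the R1–R2 balance and closing [AUG] by
   conservation. The further-simplified closed form of the [40S] descent
   — linear with slope K1 = k2[eIF4F]0 − k4[60S]0 down to k2/k1, then
   exponential at K2 = k1[eIF4F]0 toward [40S]_s2 = k4[60S]0/(k1[eIF4F]0),
   with A = [40S]+[AUG] invariant — is exposed alongside
   (`Stage2Params`, `info["closed_form_40S"]`). The stage ends at t‴
   where [40S] = 10·[eIF4F].
3. **Stage 3**: the R3–R4 cycle is equilibrated at its steady values and
   the remaining relaxation is the chain 40S → mRNA:40S with rates
   k1[eIF4F] and k2. Because the factor pool is released during the
   stage, the first rate grows ~10-fold; the product therefore integrates
   the stage's two-ODE dominant system (constant recycling flux w_s into
   the chain) rather than freezing the coefficient, and reports both the
   nominal chain time 1/min(k1[eIF4F]s, k2) and the operational stage
   relaxation time (when the stage solution itself enters the 10% band).
   A constant-coefficient chain misses the mid-stage trajectory by up to
   ~90% and was rejected on the numeric evidence.

Stages are glued on the single degree of freedom [40S] at t″ and t‴. For
β < 1 the Stage-1 description with pool drift covers the whole process
(relaxation ~1/k4); the system never reaches the Stage-2 ordering. A
transcript with a very weak cap (k1[40S]0 < 10·k2, the A-cap situation)
breaks the Stage-1 ordering at t = 0; that regime is detected and
described by numeric stage detection (ordering-crossing events measured
on the exact trajectory), as is the β ≈ 1 boundary band.

**Accuracy.** `compare_to_numeric` scores the glued solution per species
on log-spaced samples in each stage interior, excluding a 10% log-time
buffer at each window edge (transitions are approximation-free zones),
with a floor of 2% of each species' scale and a ±5% log-time slack — the
metric operationalizes tracking on a log-time concentration plot, where a
steep front reproduced with a slight timing offset is a good fit but a
pointwise comparison would score it as a large vertical miss. Measured
maxima: 5.5% for the slow-recycling set (k4 = 0.1), 9% for the strongly
separated set (k1=1, k2=5, k3=50, k4=0.01), 8% for the single-stage
baseline. Increasing the elongation/recycling separation ×10 → ×1000
shrinks the errors of the species slaved to the fast reactions
monotonically (60S: 5.5% → 0.01%); the slow-chain species plateau near
10% because their accuracy is set by the gluing, not by that separation.

## Relaxation time and kinetic signatures

The relaxation time of a trajectory is the latest time at which any
species differs from its steady value by more than 10% (relative bands;
species with steady values below 1e-6 of the largest pool are banded
absolutely to avoid division blow-ups). Scans integrate from the all-free
initial condition with a horizon that starts at 50 over the slowest
first-order scale and grows tenfold until the measurement is clear of it.

An inhibition scan multiplies one constant by 25 log-spaced factors over
three decades (factor 1 first, so the baseline is exact). The qualitative
classifier maps the two curves onto the closed label vocabularies using:

* fold changes inside an *observable window* of factors ≥ 0.05 (up to
  20-fold suppression — the range an experiment can realistically
  titrate; deeper inhibition informs shape, not magnitude);
* the knee where the rate curve first leaves the no-change band
  (log-log interpolated): a knee after ≥ 0.22 decades of flatness makes
  the decline threshold-like, split at knee factor 0.30 into "after
  threshold" vs "after strong inhibition";
* an interior window maximum of the relaxation curve ≥ 1.25× baseline
  followed by a ≥ 8% decline → "goes up and down";
* the time no-change band widens to a quarter of the largest relaxation
  response among the mechanisms probed in the same setting — a 2× shift
  is invisible on a panel whose salient effect is 16–30×, which is how
  the qualitative reference table summarizes curves sharing one axis;
* a rise below 2× that is still growing at the window edge counts as a
  clear increase if the full-scan fold reaches 2.2.

These constants were tuned once against the canonical settings (the
classifier margins are reported by the test suite) and are frozen;
all are configurable via `Thresholds`. Shapes outside the vocabulary are
labeled with `confident=False`, never silently guessed.

The canonical settings cross transcript type (wild-type cap vs A-cap,
the latter k1 = 0.01) with the initiation regime (baseline k-set, β=0.48,
vs the efficient scan set k1=2, k2=3, k3=50, k4=0.1, β=7.2). For the
linear model the wild-type base is k1 = k2 = 1 and the A-cap base
k1 = k2/1000 — far enough into the cap-limited regime that moderate k2
suppression is invisible in the steady rate while the relaxation time
grows drastically; elongation is set to k3 = 1e5 so it stays the fastest
step across the whole scan range. `mechanism_lookup` inverts the
reference tables: it returns every mechanism whose predicted row matches
all observed (rate, time) labels, including the explicit ambiguity
between "acts on the never-limiting step" and "no effect at all".

## Asymptotology toolkit

First-order networks are solved exactly by dense eigen-decomposition
(left vectors from the inverse of the right-eigenvector matrix,
biorthonormal to 1e-8); a defective kinetic matrix triggers a warning and
matrix-exponential propagation — rates are never perturbed to force
diagonalizability. The irreversible chain and cycle carry the
limiting-step results (harmonic stationary rate b/Σ(1/k_i), zero-order
mass concentration at the slow step's reactant, λ_i ≈ −k_i off the
limiting step, relaxation time = inverse second-smallest constant,
lumping vector with ones upstream of the slow step); the limiting-step
outputs require a ×10-separated minimum and are refused otherwise (an
equal-rate cycle has a genuinely complex spectrum). The classic
S + E ⇌ SE → P + E example carries both reductions: the quasi-steady-state
Michaelis–Menten rate with K_M = (κ₋ + k2)/κ₊ (scarce catalyst) and the
quasiequilibrium quadratic manifold (fast binding).

## Degenerate inputs and tie-breaks

Zero or negative rates/pools are rejected at construction. Near-ties in
chain/cycle constants raise an ambiguity error listing the contenders.
β = 1 within ±0.05 is flagged and routed to numerics. Scan points whose
solves fail are logged and reported as NaN rather than aborting the scan;
the classifier requires at least five valid points. SBML import accepts
only the two supported mass-action topologies and rejects anything else
explicitly.

## Limitations

* The models exclude mRNA/microRNA synthesis and decay, storage granules
  and ribosome drop-off; conclusions about those mechanisms are out of
  scope by construction.
* Parameter values are order-of-magnitude, unitless choices; the
  signature tables are qualitative predictions, not fits to data, and the
  classifier's label boundaries are conventions (frozen, but
  configurable) rather than measured quantities.
* The staged solution assumes the all-free initial condition and the
  standing parameter ordering; outside it (weak cap, β ≈ 1) the package
  deliberately reports numerically derived stage structure instead of
  closed forms.
* The SBML layer writes/reads only these two models with explicit
  mass-action laws; it is an exchange convenience, not a general SBML
  implementation.
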