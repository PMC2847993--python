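# ribodyn

Kinetic modeling of microRNA action on protein translation: mass-action
models of the translation machinery, their dominant-system asymptotic
analysis, and the *kinetic signatures* that let time-resolved
measurements discriminate which translation step a microRNA inhibits.

## The problem

A microRNA that represses a target mRNA can act at several steps of
translation — initiation-complex assembly, start-codon recognition,
ribosome assembly, elongation — and experiments monitoring only the
steady-state protein synthesis rate often cannot tell these mechanisms
apart: an inhibited step that is not rate-limiting leaves the steady rate
untouched. `ribodyn` implements the kinetic analysis showing that
*dynamical* observables, above all the relaxation time (the time to
approach the steady state after restarting translation), break this
degeneracy.

Two mass-action models are provided:

* a **linear cycle** `40S → mRNA:40S → AUG → 40S` (rates k1, k2, k3) with
  conserved 40S pool, whose closed-form analysis gives
  `Prsynth_ss = [40S]0·k1k2/(k1+k2)` and `t_rel = 1/(k1+k2)` when
  elongation is fast — the relaxation time of a catalytic cycle is set by
  the **second slowest** constant, so a suppressed step can be invisible
  in the rate yet dominate the relaxation;
* a **non-linear recycling model** (six species: 40S, 60S, eIF4F,
  mRNA:40S, AUG, 80S; four irreversible reactions) whose behavior is
  organized by the regime ratio

      β = k2·[eIF4F]0 / (k4·[60S]0),

  the maximal initiation flux over the maximal ribosome-recycling flux.
  β < 1 is *inefficient initiation* (the factor pool limits the rate,
  steady rate ≈ k2[eIF4F]0, single-stage relaxation ~1/k4); β > 1 is
  *efficient initiation* (recycling limits the rate, ≈ k4[60S]0, and the
  relaxation passes through three successive dominant systems with
  transition times t′, t″, t‴).

On top sit the steady-state solver (exact flux balance plus the
asymptotic cubic in the free-60S fraction), the staged (glued)
approximate solutions, the relaxation-time measurement (latest time any
species is outside a 10% band around its steady value), inhibition scans
over k1–k4 in four experimental settings (wild-type vs A-cap transcript ×
inefficient vs efficient initiation), a qualitative classifier producing
the signature tables, their inverse lookup (observed signature →
candidate mechanisms), the exact eigen-solver / limiting-step toolkit for
first-order networks, and SBML Level 3 export/import.

## Worked example

```python
from ribodyn import (NonlinearParams, beta, steady_state_exact,
                     glue, measure_relaxation_time)

p = NonlinearParams(k1=2, k2=2, k3=5, k4=1)          # baseline set
print(beta(p))                                        # 0.48  -> inefficient
ss = steady_state_exact(p)
print(round(ss.x, 4), round(ss.prsynth, 3), ss.regime)
# 0.5258 11.855 inefficient

q = p.replace(k4=0.1)                                 # slow recycling
print(beta(q))                                        # 4.8   -> efficient
sol = glue(q)                                         # three-stage solution
print(sol.route, [round(t, 2) for t in
      (sol.transitions.t_prime, sol.transitions.t_dprime,
       sol.transitions.t_tprime)])
# three_stage [0.21, 1.86, 9.13]
tau, _ = measure_relaxation_time(q)
print(round(tau, 1))                                  # 12.2
```

Reading: at the baseline parameters β = 0.48 < 1, so initiation is
inefficient — about half the 60S pool stays free (x ≈ 0.53) and the
steady synthesis rate 11.86 sits just under the factor-limited ceiling
k2·[eIF4F]0 = 12. Dropping k4 to 0.1 flips β to 4.8: the rate becomes
recycling-limited (≈ k4·[60S]0 = 2.5) and the relaxation now passes
through three stages whose estimated transition times (0.21, 1.86, 9.13)
bracket the measured relaxation time 12.2.

The signature tables that discriminate mechanisms:

```bash
ribodyn signature --model nonlinear --out signature.tsv   # 4x4 table
ribodyn signature --model linear    --out linear.tsv      # 2x3 table
ribodyn scan --setting wt_inefficient --mechanism k4      # one scan TSV
ribodyn steady --fixture default                          # steady state
ribodyn report --fixture efficient                        # figures
```

For instance, under a wild-type cap with inefficient initiation,
suppressing k4 leaves the steady rate flat until k4 crosses the critical
value k2[eIF4F]0/[60S]0 = 0.48 and then cuts it proportionally, while the
relaxation time first rises ~30-fold and then falls back — the
"decreases after threshold / goes up and down" signature that no other
mechanism produces in that setting.

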