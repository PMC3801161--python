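# tcrtrigger

Kinetic-proofreading model of T-cell receptor (TCR) triggering with
explicit CD8 co-receptor kinetics, and the statistics of TCR degeneracy
over random ligand ensembles.

## The problem

A T-cell recognises peptide–MHC class I ligands (pMHCI) through its TCR,
helped by the co-receptor CD8, which binds pMHCI at a separate site and
(i) promotes TCR/pMHCI association, (ii) stabilises the bond, and
(iii) accelerates the ITAM phosphorylation cascade that converts an
engaged TCR/CD3 complex into a signalling one. Because a single TCR must
cover an astronomically large peptide universe, recognition is
*degenerate*: each receptor responds appreciably to a small but non-zero
fraction of random ligands. This package quantifies how the surface
density and binding strength of CD8 tune both the per-ligand *functional
sensitivity* and the overall degeneracy of a T-cell — the "ligand
focusing" mechanism.

## The model

Three layers, each exposed as a module:

1. **Equilibrium** (`solve_equilibrium`): the four binding states of a
   pMHCI (free / TCR-bound / CD8-bound / ternary) at detailed balance.
   With scaled free densities x (CD8) and r (TCR), occupancy fractions
   share the denominator `D = 1 + x + r + xr/γ_kin`, and conservation of
   CD8 and TCR gives two coupled equations solved by damped Newton with a
   bracketed-bisection fallback (residual < 1e-12).

2. **Triggering** (`triggering_rate`): a two-lane kinetic-proofreading
   chain of n phosphorylation steps. In units of the basal rate, the
   CD8-unbound lane competes forward rate n against dissociation α and
   CD8 association νx; the CD8-bound lane competes n/γ_R against
   γ_off·α and CD8 dissociation δ. Backward recursion from the absorbing
   boundary P_n = 1 yields the triggering probabilities P⁰₀, P*₀ and the
   scaled functional sensitivity

       w = α (ε P⁰₀ + ζ γ_off P*₀),

   with ε, ζ the equilibrium fractions of binary and ternary complexes.

3. **Degeneracy** (`degeneracy_curve`): ligand off-rates are log-normal
   (Gaussian dissociation energies via Arrhenius), ln α ~ N(μ, σ²), and
   degeneracy is the exceedance probability P(w > ω), integrated
   semi-analytically down to the 1e-8 probabilities that delimit the
   immunological operating band. CD8-affinity mutants of HLA A*0201
   (A245V, wild-type, Q115E, A2/α3kb) enter by rescaling K3 with the
   measured K_D ratio.

Independent oracles (`absorption_solve`, a first-step linear solve over
all chain states, and `simulate_chain`, a seeded jump-chain simulator)
cross-validate the recursion and are part of the public API.

## Worked example

```python
import tcrtrigger as tt

p = tt.get_preset("fig2").params.replace(alpha=2.5)   # reference scenario

res = tt.triggering_rate(p.replace(x_T=50.0))
print(res.w, res.P00, res.P0_star)
# 0.098637 0.089755 0.091862

x_min, w_min = tt.find_sensitivity_minimum(p)          # sweep + refine
print(x_min, w_min)
# 50.57 0.0986

ens = tt.get_preset("fig2").ensemble                   # ln(alpha) ~ N(2, 0.2^2)
for xT in (0.0, 50.0, 200.0):
    print(xT, tt.exceedance_probability(p.replace(x_T=xT), ens, 0.12))
# 0.0   1.696e-06
# 50.0  2.055e-10
# 200.0 7.914e-03
```

Reading: at the reference off-rate α = 2.5 the sensitivity w(x_T) has an
interior *minimum* near scaled CD8 density x_T ≈ 50 — intermediate CD8
levels make the cell least responsive, so shifting CD8 expression in
either direction re-tunes which ligands are agonists. The degeneracy
P(w > 0.12) spans four orders of magnitude across the same CD8 range,
dipping far below the 1e-8–1e-5 operating band at the minimum and rising
above it at high CD8.

The same is available from the shell:

```sh
tcrtrigger sweep --preset fig2 --var x_T --grid 1:200:400 --alpha 2.5 --out w.csv
tcrtrigger degeneracy --preset fig5 --mutants --out panel.csv --plot panel.png
tcrtrigger band --preset fig2 --omega-crit 0.12 --grid 1:200:60 --out band.csv
tcrtrigger validate
```

All CSV outputs carry a `#`-prefixed provenance header (parameter hash,
seed, version) sufficient to reproduce the run.

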