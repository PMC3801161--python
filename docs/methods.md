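# Methods

## Model

`tcrtrigger` implements a kinetic model of T-cell receptor (TCR) triggering
in the contact area between a T-cell and an antigen-presenting cell, with
explicit kinetics for the co-receptor CD8, and a statistical layer that
turns the per-ligand triggering rate into a measure of TCR degeneracy.

### Binding equilibrium

A pMHCI molecule can be free, bound to a TCR, bound to a CD8, or in a
ternary TCR/pMHCI/CD8 complex. The four association/dissociation reactions
are assumed fast relative to the triggering chain and are treated at
equilibrium. With free densities scaled by the two-dimensional dissociation
constants (x = X/K3 for CD8, r = R/K1 for TCR), detailed balance gives all
four occupancy fractions of pMHCI a common denominator

    D(x, r) = 1 + x + r + x r / gamma_kin,

where `gamma_kin = gamma_off/gamma_on = K4/K1 = K2/K3` is the net affinity
modulation exerted by CD8 on the TCR/pMHCI bond. The fractions are 1/D
(free), `eps = r/D` (TCR-bound), x/D (CD8-bound) and
`zeta = (x r/gamma_kin)/D` (ternary). Conservation of total CD8 and TCR
yields two coupled equations for (x, r):

    x_T = x + kappa m_T (x + x r/gamma_kin)/D
    r_T = r + m_T (r + x r/gamma_kin)/D

The solver uses a damped Newton iteration with the analytic 2x2 Jacobian,
iterates clipped to the box [0, x_T] x [0, r_T], absolute residual
tolerance 1e-12 and at most 200 iterations. On any failure it falls back
to nested bracketed root-finding (outer in x, inner in r), which is
guaranteed to converge because each equation is strictly increasing in its
own variable on the box. The tight tolerance is deliberate: the degeneracy
layer resolves probabilities near 1e-8, which inherit their accuracy from
the equilibrium fractions. Three degenerate cases are closed-form, not
limits: no ligand (m_T = 0), no CD8 (x_T = 0, a quadratic in r) and no TCR
(r_T = 0, a quadratic in x). The equilibrium depends only on
(m_T, x_T, r_T, kappa, gamma_kin); the solver never reads the kinetic
parameters, and a regression test asserts this.

### Two-lane proofreading chain

An engaged TCR/CD3 complex must complete n ITAM phosphorylations before it
signals; partially phosphorylated complexes reset on dissociation. The
chain runs in two lanes. In scaled units (rates divided by the basal
triggering rate lambda = 1/T_R):

| lane        | forward     | dissociation      | lane switch |
|-------------|-------------|-------------------|-------------|
| CD8 unbound | n           | alpha             | nu x        |
| CD8 bound   | n / gamma_R | gamma_off * alpha | delta       |

The per-state success probabilities satisfy a coupled backward recursion
from the absorbing boundary P_n = (1, 1). It is evaluated by n
matrix-vector products rather than a matrix power: every intermediate
quantity lies in [0, 1], so the iteration is numerically stable and O(n).
When the CD8-association probability is exactly zero the unbound lane
decouples into the classical single-lane proofreading chain and its
powers are computed in log space, avoiding underflow for large n or large
off-rates. The scaled functional sensitivity of a ligand is

    w = alpha (eps P_0^0 + zeta gamma_off P_0^*).

The degenerate input in which both lane-switch probabilities are 1 (the
complex can only oscillate between lanes) raises an error.

### Validation oracles

Two independent implementations guard the recursion. First, first-step
analysis over the explicit state space — 2(n+1) states, sparse direct
solve — which agrees with the recursion to better than 1e-12 over hundreds
of random rate draws with n up to 200. Second, stochastic simulation of
the embedded jump chain: absorption probabilities of a continuous-time
chain depend only on the ratios of competing rates, so categorical draws
over the embedded chain are distributionally exact for this purpose and
much cheaper than exponential clocks. Simulated success fractions agree
with the linear solve within three binomial standard errors at 1e5 trials.
The simulator is vectorised over trials, which keeps the full-size checks
in the test suite at a few seconds.

### Dimensional bridge

`DimensionalKinetics` carries the two-dimensional association rates
Lambda_1..Lambda_4 (cm^2/s), dissociation rates lambda_-1..lambda_-4
(1/s), total densities (1/cm^2) and the triggering thresholds T_R and
T_R* (s; default 7.5 s, inside the physiologic 5–15 s band). Construction
enforces the thermodynamic cycle condition K1 K2 = K3 K4 (K_i =
lambda_-i/Lambda_i); the `consistent()` factory derives lambda_-2 from the
other rates so randomised scenarios satisfy it exactly. `to_scaled`
produces the dimensionless parameter set; such sets automatically satisfy
delta/nu = gamma_kin. The dimensional triggering rate W is available in
both its association form (M lambda_1 P00 + M_X lambda_4 P0*) and its
dissociation form (M_R lambda_-1 P00 + M_XR lambda_-4 P0*); detailed
balance makes them equal at equilibrium and a test verifies this to 1e-10.

CD8-affinity variants of HLA A*0201 are modelled by taking the 2D
constant K3 proportional to the measured solution K_D (A245V 498 uM,
wild-type 137.1 uM, Q115E 97.94 uM, A2/a3kb 10.87 uM). The
proportionality constant — the confinement length relating 3D and 2D
affinities — is assumed common to all variants and therefore cancels:
only the ratio rho = K_D(variant)/K_D(reference) enters, rescaling
kappa -> kappa/rho, x_T -> x_T/rho, nu -> nu rho. Applying rho1 then rho2
equals applying rho1 rho2 (a group action), which is tested.

### Degeneracy statistics

The dissociation energy barrier of a TCR/ligand pair is modelled as a sum
of many interfacial contributions, hence Gaussian; through the Arrhenius
relation the scaled off-rate alpha is log-normal, ln(alpha) ~
N(mu, sigma^2) with mu > 0 (most random ligands dissociate well before
the chain completes). The ensemble captions "mean m and SD s" are read as
the mean and SD of ln(alpha): a linear-scale mean of 2 with SD 0.2 would
place essentially all ligands at dwell times comparable to the triggering
threshold, contradicting the stated rarity of agonists. Reference
ensembles: (mu, sigma) = (2, 0.2) for the CD8-density scenarios and
(5, 0.5) for the mutant panel.

Degeneracy is the exceedance probability P(w > omega). The default
evaluation is semi-analytic: w(alpha) is profiled on a 400-point grid of
ln(alpha) spanning mu +- 8 sigma (no unimodality assumption — robustness
over speed), every sign change of w - omega is bracketed and refined by
bisection to relative 1e-10, and the exact Gaussian mass of the resulting
super-level intervals is accumulated (an endpoint still above omega
extends into the corresponding Gaussian tail). This resolves probabilities
of order 1e-8 — the biologically meaningful operating band — which no
feasible Monte Carlo depth can reach; sampling (seeded, reproducible) is
retained as an independent cross-check where P > 1e-3. The default
threshold grid is 60 log-spaced points over [1e-4, 10] x max w.

The activation layer declares a T-cell activated when Z T_I w > W_act
(presentation level x interaction duration x sensitivity). The units
linking the triple to w are not pinned down by the scaled model, so the
critical threshold omega_crit is the primary input (e.g. 0.12) and
(Z, T_I, W_act) a convenience; band edges default to P = 1e-8 and 1e-5.
A band scan re-solves the equilibrium per CD8 density and flags each
point below/in/above the band. For the reference scenario the profile is
U-shaped with its minimum near x_T = 50, so the flags form up to five
contiguous runs (the profile can cross each band edge twice).

The ligand-universe count 20^m C(n-a, m) — an n-mer anchored at a
positions with m TCR-contacted residues — is exact integer arithmetic;
m = 0 returns 1 with a warning since the model's domain is 0 < m. The
source text introduces the contacted-residue count as c but uses m in the
formula; the formula is implemented as printed.

## What the generated ensembles do and do not emulate

The synthetic ligand ensembles vary only the TCR/pMHCI off-rate alpha;
on-rates, CD8 kinetics and presentation levels are held at their scenario
values. This mirrors the MHC-limited regime, where the off-rate dominates
triggering, and is the regime in which the mutant-panel ordering
(stronger pMHCI/CD8 binding -> more degenerate) holds; in a TCR-limited
regime the variant curves collapse. Passing tests therefore certify the
kinetic and statistical machinery, not any claim about a particular
peptide library: real ensembles correlate on- and off-rates, and real
presentation levels vary across ligands.

## Parameter-set caveat

The exploratory scenario presets treat delta, nu and gamma_kin as
independent dials. A single detailed-balanced kinetic scheme would force
delta/nu = gamma_kin, which the presets violate (e.g. the reference
scenario has delta/nu = 600 against gamma_kin = 0.5). The presets are
reproduced verbatim; `check_consistency` computes the ratio and warns, so
users deriving parameters from measured rates can tell the two situations
apart. `gamma_kin > gamma_off` (implying a CD8-mediated on-rate
*reduction*) is likewise accepted with a warning rather than rejected.

## Problem sizes

Default chain length n = 100; sweeps use 400-point grids refined by
golden-section search; semi-analytic curves use the 400-point profile
grid; Monte Carlo cross-checks use 1e5 samples/trials; randomized
conservation checks use 1000 draws. With the vectorised simulator the
full suite runs in a few seconds.

## Known limitations

- Equilibrium-only binding: no pre-equilibrium transients, no serial
  rebinding or spatial synapse dynamics (micro-domain localisation of
  kinases/phosphatases is outside the model).
- Full phosphorylation reset between encounters; no partial memory.
- Downstream signalling (ERK, NF-kB, NFAT) is out of scope; "triggered"
  means completion of the proofreading chain.
- Mutant scenarios rescale K3 only; any variant effect on TCR/pMHCI rates
  themselves is not modelled.
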