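# Methods

## Model

`pgpear` implements the mass-action kinetic model of P-gp-mediated
efflux across a transwell monolayer introduced by Tran and colleagues.
Five dynamic quantities are integrated: the aqueous drug concentrations
in the apical chamber, cytoplasm and basolateral chamber, and the free
and drug-bound P-gp concentrations.  Two auxiliary quadrature states
accumulate the effluxed amount and the amount removed by the
unexplained-loss rate `k_v`.

Assumptions inherited from the model:

- **Instantaneous leaflet equilibration.**  Each membrane leaflet is in
  equilibrium with the adjacent aqueous phase, so leaflet
  concentrations are algebraic (`C_IL = K_IL · C_CP` etc.) and each
  aqueous compartment carries an effective volume
  `V_tot = V + K · V_leaflet`.
- **Single-site mass-action binding.**  Drug in the apical inner
  leaflet binds free P-gp with `k_on·K_IL·C_CP·C_Pgp,free`; bound drug
  either dissociates (`k_off`) or is effluxed into the apical chamber
  (`k_e`).  No cooperativity or multiple binding sites.
- **Symmetric passive diffusion** per membrane (`P_AC = P_CA`,
  `P_BC = P_CB`), apical dosing only.
- **Drug-independent association**, `k_on = 1e8 /M/s`.
- The loss term applies to the effective compartment amounts
  (`k_v·V_tot·C`), i.e. drug partitioned into outer leaflets is subject
  to loss together with its aqueous compartment, exactly as the
  effective-volume formulation implies.

The bound-P-gp amount bookkeeping uses the apical inner-leaflet volume
`0.5·V_IL` (half of the total inner-leaflet volume): the instantaneous
efflux rate is `k_e·C_Pgp,bound·0.5·V_IL` (mol/s) and the same factor
enters the chamber balance equations.  Whether P-gp concentrations are
referenced to the leaflet or the cell is immaterial for the rEAR
statistic, which only needs consistent amount bookkeeping.

## Parameters

System constants (defaults of `SystemParams`) describe a standard
transwell insert with an MDCKII-MDR1-like monolayer: membrane surface
areas 2.26e-2 dm², apical/basolateral chamber volumes 0.5/1.5 mL,
cytoplasm 1 µL, outer-leaflet volumes 5e-10 dm³, total inner-leaflet
volume 1e-9 dm³, and `k_v = 1e-6 /s` (negligible loss).  Internal units
are dm/s/M throughout; the boundary constructors accept permeabilities
in nm/s (1 nm/s = 1e-8 dm/s) and concentrations in µM.

The drug library carries the literature parameterization of seven
P-gp substrates (kinetic constants fitted by Lumen and colleagues to
bidirectional transwell time courses; partition coefficients measured
in leaflet-mimetic liposomes).  The reference expression of 1000 µM
P-gp corresponds to the estimate for MDCKII-MDR1 cells; the default
scenario doses 1 µM apically and integrates for `t_end = 21600 s`.

## The rEAR statistic

Activity is defined as cumulative efflux over the horizon,
`A_eff,cum(t_end)`.  `rEAR_x%` is the percent ratio of `A_eff,cum`
at `x%` of the reference P-gp concentration to that at 100%.  The
reference simulation is computed once per curve and reused across
fractions, so `rEAR_100% = 100` holds exactly and no duplicated-work
drift can enter the ratio.

The linear/intermediate/non-linear labels returned by `classify_ear`
are an operational convenience (default cut-offs 60% and 85% on
rEAR_50%, configurable); the underlying behaviour is a continuum and
the thresholds carry no mechanistic meaning.

Efflux efficiency `k_off/k_e` — the number of binding events per
successful efflux — is the drug property that predicts EAR type:
inefficiently effluxed drugs (large ratio) respond linearly to
expression, efficiently effluxed drugs are capacity-limited elsewhere
(passive access to the cytoplasm) and respond non-linearly.

## Numerics

- **Stiffness.**  Binding relaxes at rates up to
  `k_on·K_IL·C_Pgp,tot` ≈ 1e10 /s against a 2.16e4 s horizon — more
  than 13 decades of time-scale separation.  The default integrator is
  scipy's BDF with the analytic 7×7 Jacobian, relative tolerance 1e-8
  and absolute tolerances 1e-12 M (concentrations) / 1e-18 mol
  (amounts).  BDF was chosen after systematic comparison: scipy's
  LSODA aborts at extreme sweep corners (k_off = 1e7 /s combined with
  1e5 µM P-gp) and its success depends on the absolute-tolerance
  choice, while BDF completes the entire default parameter space at
  the default tolerances and agrees with LSODA and Radau to better
  than four digits wherever all converge.  `method="LSODA"` and
  `"Radau"` remain selectable.
- **Quadrature states.**  Cumulative amounts are integrated by the
  solver itself, so read-outs are independent of the output grid
  (verified to 1e-8 relative between 11 and 10 001 output points) and
  no post-hoc trapezoidal bias enters the rEAR ratio.
- **Clipping.**  Negative concentrations within solver tolerance are
  clipped to zero for rate evaluation only; the stored state is
  untouched.  This protects the bilinear binding term from sign errors
  during stiff stepping and measurably does not alter results.
- **Determinism.**  There is no randomness anywhere; repeated runs are
  bit-identical.  CLI `--seed` is accepted for interface compatibility.
- **Failure handling.**  Integration failures raise `SimulationError`
  with solver diagnostics; sweep grid points that fail are recorded
  (NaN value plus a failure record) rather than dropped, and the CLI
  exits non-zero.

## Verification strategy

The test suite checks conservation laws rather than trusting the
solver: P-gp conservation (`C_free + C_bound = C_tot`, < 1e-6
relative), drug mass balance at every output time (compartment amounts
plus bound amount plus cumulative loss equal the dosed amount, < 1e-5
relative; efflux recycles drug to the apical chamber and removes
nothing), exact symbolic cancellation of the amount derivatives in the
right-hand side, a trapezoidal quadrature oracle for the cumulative
efflux (1e-4 relative on a 10 001-point grid), dose-proportionality in
the linear regime, and solver-tolerance robustness (rtol 1e-8 vs
1e-10 changes cumulative efflux by < 1e-4 relative).

End-to-end tests reproduce the headline panel statistics (rEAR_50% and
rEAR_300% of the seven substrates at the default condition, to ±1
percentage point after integer rounding), the monotonicity of rEAR in
expression fraction, the kinetic-plane trends (rEAR_50% is strictly
non-decreasing in k_e; along k_off the large-scale movement is strictly
towards the linear limit, but the model genuinely produces bounded
interior counter-movements — up to ~1.2 percentage points on the
audited grid, independent of solver and tolerance — so the k_off audit
bounds counter-movements at 1.5 points and checks that every slice
with meaningful dynamic range ends far below its maximum), the
weak-efflux
analytic limit (rEAR_50% → 50% when efflux is a negligible
perturbation and drug is in excess of P-gp), and the hybrid-drug
ordering (ampramil at least as non-linear as amprenavir, veravir at
least as linear as verapamil).

## Problem sizes

The virtual-drug sweep defaults to 25 log-spaced points per kinetic
axis (k_off over [1e2, 1e7] /s, k_e over [0.03, 30] /s) × doses
{0.1, 1, 10, 100} µM × reference P-gp {1e1…1e5} µM; grid density is
configurable and the qualitative conclusions are
resolution-independent.  The test suite exercises a reduced 5×5
kinetic grid × 2 doses × 2 expression levels (200 grid points, 400
integrations, a few minutes on one CPU), which already contains the
monotonicity structure and the analytic weak-efflux corner.

## Limitations

- All conclusions are conditional on the kinetic model and its
  assumptions; simulations are not experimental proof.  Whether `k_on`
  is truly drug-independent, and whether the fitted constants are
  uniquely identifiable rather than a correlated combination, are open
  questions of the underlying estimation work.
- The model equates total P-gp with efflux-active P-gp in the apical
  inner leaflet; in real monolayers with microvilli only a fraction of
  transporter may be efflux-active, so mapping the model's µM
  expression onto proteomic expression measures (fmol/µg protein) is
  not addressed here.
- Basolateral dosing, dosing schedules, saturable/cooperative binding
  and embedding in PBPK frameworks are out of scope, as are efflux
  ratios from bidirectional assays and parameter estimation for new
  compounds.
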