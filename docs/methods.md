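# Methods

## Model structure

Five compounds are tracked: irinotecan (CPT-11), SN-38, SN-38G, NPC and
APC.  Hepatic conversions are CPT-11 → SN-38 (CES2, clearance `CL_CES1`),
CPT-11 → APC (CYP3A4, `CL_3A4_1`), CPT-11 → NPC (CYP3A4, `CL_3A4_2`),
NPC → SN-38 (CES2, `CL_CES2`) and SN-38 → SN-38G (UGT1A, `CL_UGT`).  The
metabolic graph is a DAG; conversion is 1:1 in dose-equivalent mass units
(amounts are expressed in μg per kg body weight with no molecular-weight
correction, matching how the objective data normalise metabolites to the
administered CPT-11 amount).

Each compound moves through 23 compartments: venous blood, arterial blood,
lung, and 13 perfused tissues (heart, brain, muscle, adipose, skin, bone,
kidney, spleen, pancreas, stomach, small intestine, large intestine,
liver), plus three biliary transit compartments, the small- and
large-intestinal lumen, and the absorbing urine and feces sinks.

Tissue exchange is perfusion-limited (blood-flow-limited): a tissue with
volume `V` (ml/kg), blood flow `Q` (ml/min/kg) and partition coefficient
`Kp` receives `Q·C_in` and releases `Q·C/Kp` with `C = amount/V`.  This
form is forced by the parameterisation — each organ carries exactly
(Q, V, Kp).  Topology:

* venous pool → lung → arterial pool → organs in parallel;
* spleen, pancreas, stomach and both intestines drain into the liver inlet
  together with the hepatic artery (flow-weighted mixing); the liver
  releases at its total (artery + portal) flow;
* renal elimination `CL_r·C_kidney/Kp_kidney` → urine; biliary elimination
  `CL_bile·C_liver/Kp_liver` → bile transit 1 → 2 → 3 → small-intestinal
  lumen at `k_bile`; lumenal drug is reabsorbed into the liver at `k_a`
  (enterohepatic circulation, portal shortcut) or passed on at `k_li` to
  the colonic lumen and excreted at `k_feces`;
* clearances act on organ *outflow* plasma (well-stirred convention).

**Deconjugation.** Gut-flora β-glucuronidase regenerates SN-38 from
lumenal SN-38G.  No separate deconjugation rate exists among the 105
parameters, so the model folds deconjugation into absorption: lumenal
SN-38G absorbed at `k_a(SN-38G)` enters the liver as SN-38.  The fecal
objective reports SN-38 + SN-38G jointly, so it is insensitive to where
exactly the conversion happens; the urinary SN-38/SN-38G split is the one
output that would notice a different convention.

**Dosing.** Zero-order infusion of CPT-11 into venous blood over 90 min.
Venous Cmax per compound is read off a ≤ 1-min grid spanning four infusion
durations (360 min); "serum" is equated with venous blood.  With extreme
rate-constant combinations the enterohepatic loop could in principle
produce a later secondary peak that this window misses; within the
estimation bounds the primary peak dominates.

**Flow rebalancing.** Printed per-organ flows are rounded to
0.1 ml/min/kg, so the lung flow and the total liver flow do not close
exactly against their summands (closure error up to ~0.8 ml/min/kg in this
cohort).  Validation accepts imbalances up to 1 ml/min/kg; internally the
simulator recomputes `liver_total = artery + splanchnic` and
`lung = Σ venous returns`, which makes a spatially uniform concentration
an exact equilibrium of the distribution-only system (checked to 1e-4
relative in the tests).

## Numerical solution

All kinetics are first-order, so the state equation is linear and
time-invariant within each infusion phase: `dx/dt = M x + rate(t)·u` with
115 states.  Columns of `M` sum to zero by construction (every transfer is
a paired loss/gain), so total mass equals the infused amount to machine
precision — the mass-balance test asserts < 1e-6 × dose.

The default propagator is the matrix exponential: one `expm` of the
(n+1)-augmented system yields both the 1-min homogeneous propagator and
the unit-input response; the 360-min fine grid is stepped minute by
minute, and the remainder to the 30 240-min horizon (21 days — terminal
excretion flux is negligible by then anywhere inside the bounds) is
covered by binary powers of the propagator.  This is exact for a linear
system regardless of stiffness and costs ~5 ms per simulation, which is
what makes ensemble estimation with thousands of forward runs practical
on one CPU.  An implicit BDF route (`method="bdf"`, rtol 1e-6, atol
1e-9 × dose, integration split at the infusion stop) is retained and
cross-checked against the exponential propagator to 1e-4 relative in the
test suite.

## Cluster Newton Method

The solver is generic over the forward function.  One iteration:

1. **Surrogate.** Least-squares affine fit `y ≈ A w + b` of the evaluated
   observables against the free working coordinates `w` over all
   successful points.  Working coordinates are log-parameters by default
   (`sampling="log"`): all 105 parameters are positive scale parameters
   with 2–3-decade ranges, so steps are multiplicative and positivity is
   structural.  A linear-coordinate mode exists for the affine-map oracle
   tests.
2. **Step.** Every point moves by the minimum-norm solution of
   `A s = y*_j − y_j`, where `y_j` are the point's *evaluated* observables
   and `y*_j = y* ∘ (1 + u_j)` is its private target
   (`u_j ~ U(−η, η)` componentwise, η = 0.1, drawn once at the start and
   kept — the cluster then settles into an ensemble of near-solutions of
   slightly different problems, which is the diversity mechanism).  The
   new point is `w_j + (1 − dS)·s_j` with dS = 0.2; dS = 0 recovers the
   full-step original method, dS = 1 freezes the cluster.  Points are
   clipped to the bounds (in log space, with a final natural-space clip to
   keep box membership exact to the ulp); fixed coordinates are never
   touched; failed evaluations are resampled log-uniformly.
3. **Scaling and truncation.** With relative-residual SSR
   `Σ((y_k − y*_k)/y*_k)²` the Newton solve is row-scaled by the target
   (solve on `y/y*`), so the μg/ml Cmax objectives count as the SSR counts
   them instead of being drowned by the %-scale excretion ratios.  For a
   full-row-rank consistent system this scaling provably does not change
   the minimum-norm solution; it matters only where the singular-value
   truncation acts.  Singular values below 2e-2 of the largest are
   truncated: the global surrogate over a wide cluster carries fit noise,
   and smaller singular values amplify that noise into bound-to-bound
   jumps along sloppy directions.  Convergence diagnostics over 12 seeds
   put the stage-1 final minimum SSR at 0.012–0.028 with the 2e-2 cutoff
   versus 0.018–0.084 with cutoffs of 1e-10 or 1e-1.
4. **Evaluation.** All points are re-evaluated serially (bitwise
   reproducibility under the seed); SSR is always measured against the
   unperturbed target.

A converged cluster loses numerical rank along directions the data no
longer constrain; the surrogate fit warns but continues (minimum-norm
coefficients, zero residuals, truncated step directions make this safe).
Fewer successful points than free parameters + 1 remains a hard error.

## Three-step pipeline

Stage 1 runs 10 iterations with all 105 parameters free; parameter sets
with SSR ≤ 0.03 (inclusive) are pooled across patients and the per-index
median of the 70 Kp coordinates becomes the constraint mask; stage 2 runs
15 iterations with fresh log-uniform initial sampling (restarting from the
stage-1 cluster is available as an option) and the 35 remaining parameters
free.  Per-patient seeds are derived by keyed splitting
(`SeedSequence([seed, stage, patient_index])`), so results are independent
of cohort ordering and the whole pipeline is bitwise reproducible under
one seed.

The coefficient of variation is computed per free parameter over the
successful points of the final cluster, on the linear scale, with the
sample (n−1) standard deviation, and no SSR pre-filtering.  CV ≤ 0.3
(inclusive) marks strong convergence.  Age-group summaries pool the final
clusters of each group (below 70 / 70 and over) and report quartiles.

At the reduced preset (300 points) on the packaged cohort, exactly the
renal clearance of CPT-11 (#71), its biliary clearance (#76) and its
CYP3A4 clearance to APC (#83) converge strongly in all seven patients,
and all three distribute lower in the 70-and-over group — the package's
tests assert the reproducible single-patient core of this behaviour.

## Synthetic studies

The generator draws virtual patients by perturbing the across-patient
means of the packaged per-kg organ volumes and flows with independent
mean-one lognormal factors (CV 15%, a typical inter-individual spread for
organ composition), then derives the lung and total liver flows from their
summands so the circulatory closure holds exactly.  Anthropometrics are
uniform over the cohort's observed ranges (weight 55–110 kg, height
160–190 cm, age 50–75 y) with a 1400 μg/kg, 90-min infusion.  Ground-truth
parameter vectors are drawn log-uniformly from the central 80% (log scale)
of each estimation range, so the truth is strictly interior; objective
vectors come from forward simulation, optionally multiplied by mean-one
lognormal observation noise.  By default all virtual patients share one
truth — the regime the Kp-consolidation step assumes.

What this does *not* emulate: correlated organ-size variation (all factors
are independent), assay error structure of real excretion balance studies,
within-patient occasion variability, or model misspecification — a passing
recovery test shows the estimation machinery works when the model is
correct, not that the model is correct for real patients.

## Problem sizes and runtime

The package's default study sizes: `paper` preset — 1000-point clusters,
10/15 iterations; `reduced` preset — 300-point clusters, same iterations.
The reduced preset is used throughout the test suite and the acceptance
script; a full single-patient three-step run takes ~40 s and the
seven-patient cohort ~4 min on one CPU.  The CNM is stochastic: at the
reduced scale the stage-1 minimum SSR for patient 1 lands in 0.012–0.028
across seeds, and roughly 1–4 of 300 points clear the 0.03 selection
threshold (at the 1000-point preset, ~1% of points do, consistent with
the scale of the source analysis).

## Known limitations

* No protein binding, blood:plasma partitioning, transporter saturation or
  Michaelis–Menten nonlinearity: every process is first-order, which is
  precisely what makes the exact linear propagator available.
* The urinary SN-38G/SN-38 split depends on the
  deconjugation-on-absorption convention (see above).
* Cmax is searched within 4 infusion durations only.
* The dividing-point orientation (`x + (1−dS)·s`) is fixed by requiring
  that dS = 0 reproduce the original full-step method; other readings of
  the dividing-ratio phrasing exist.
* η (target-perturbation half-width) is not identified by the source
  description; 0.1 reproduces the reported ensemble behaviour and is
  configurable.
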