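# Methods

## Models

**Saturation binding.** Specific binding follows the rectangular hyperbola
`B = B_MAX·F/(K_D + F)` in free radioligand concentration `F`. Replicates
are averaged per concentration, nonspecific (excess-atropine) wells are
subtracted, bound dpm are converted to molar via the specific activity
(dpm → Ci → mmol → M at the assay volume), and `F = added − bound`
(first-order ligand depletion; no quadratic isotherm). Points with averaged
nonspecific above total are excluded with a warning; a non-positive free
concentration anywhere is a hard error. pK_D is reported as −log10 M and
B_MAX as pmol of sites per mg membrane protein.

**Competition binding.** One-site `y = 100 − 100·x/(x + IC50)` and its
two-site extension with the percentage of low-affinity sites `f_low` are
both fitted to percent-of-control data; the two-site model is retained only
when the extra-sum-of-squares F-test rejects the one-site model at
p < 0.05 (matching the study's global α — no selection rule is otherwise
canonical). `f_low` is parameterised through a logit restricted to
[1, 99]% so the optimiser cannot collapse onto the boundary, and the
separation between the two pIC50s is constrained non-negative. Each IC50 is
converted with Cheng–Prusoff, `pK_I = pIC50 + log10(1 + [D]/K_D)`, with
[D] = 1 nM radioligand by default. A bottom plateau above 20% of control
triggers an "incomplete inhibition" warning — the agonists this pipeline is
designed around displace the radioligand completely.

**Functional response.** Data are fold over basal (blank-subtracted, basal
≡ 1). The Hill fit `y = 1 + (E′_MAX − 1)·x^nH/(EC50^nH + x^nH)` keeps the
bottom fixed at 1 and constrains `E′_MAX ≥ 1`, `nH > 0`. A curve is called
"no response" when the Hill model does not beat a constant in an
extra-sum-of-squares F-test at α = 0.05 (the same flat test detects the
absence of cAMP coupling at receptor–Gα16 fusions); such curves are
reported with τ = 0 and no pK_A.

**Operational model.** The printed operational equation has no basal term,
but the data it is fitted to have bottom 1. The package therefore uses the
re-based form

    y = 1 + (E_MAX − 1)·τ·x / (K_A + (τ + 1)·x)

as its default forward and fitting model, and exposes a "plain" variant
(`y_max = E_MAX·τ/(τ+1)`, `τ = E′_MAX/(E_MAX − E′_MAX)`) because published
parameter tables for this receptor panel are internally consistent under
the plain convention (e.g. 30.7·1.41/2.41 = 17.96 ≈ the printed apparent
maximum 18, with E′_MAX inclusive of basal). Both conventions share
`pEC50 = pK_A + log10(1+τ)`. The closed-form Hill↔operational transform is
only applied for |nH − 1| ≤ 0.2; outside that window only τ/K_A-level
quantities are meaningful.

## The two-step fit and E_MAX identifiability

Step 1 fits all internal-standard curves (carbachol, oxotremorine,
pilocarpine by default) of one (receptor, pathway) simultaneously with a
single shared E_MAX and per-curve (τ, pK_A); step 2 fixes E_MAX and fits
each individual experiment, summarising τ and pK_A as mean ± SD across
independent experiments.

A structural caveat that the fitter surfaces instead of hiding: for
unit-slope curves the shared-E_MAX likelihood is **exactly flat** above the
largest apparent maximum. Any ceiling E_MAX > E′_MAX reproduces a given
Hill-shaped curve perfectly through the compensating reparameterisation
τ = (E′_MAX−1)/(E_MAX−E′_MAX), K_A = EC50·(1+τ); this holds for every curve
in the panel simultaneously, so adding agonists does not break the ridge
(numerically, the profile SSE is constant to 13 digits from E_MAX = 25 to
100 on simulated standards). Functional data alone therefore only bound the
system ceiling from below. `fit_system_emax` scans the E_MAX profile
explicitly on a log grid, returns the smallest statistically adequate
ceiling (the knee of the profile, within one residual-variance unit of the
flat minimum) and sets a `ridge_flat` diagnostic; a single-agonist panel,
or standards whose mean apparent maxima differ by less than 5%, are
refused outright. When the study design states the system ceiling — as the
two-step protocol assumes when step 2 "fixes E_MAX" — the pipeline uses
that value directly; the profile knee is the fallback and should be read
as a lower bound, not an estimate of the true ceiling.

## Bias quantification

Relative intrinsic activity is oriented so that a more potent or more
efficacious test agonist exceeds 1:

    RA_i = (E′_MAX,a/EC50,a) / (E′_MAX,ref/EC50,ref)
         = (τ_a/K_A,a) / (τ_ref/K_A,ref)

The two routes coincide exactly for unit slopes under the plain-ceiling
convention (τ/(1+τ) = E′_MAX/E_MAX); under the re-based convention the
τ/K_A route tracks (E′_MAX−1)/EC50 instead, so small route discrepancies
are expected on real tables and the package reports which route produced
each value. SDs are propagated to RA_i by the delta method on log RA_i.
Non-responding agonists (τ = 0) get RA_i = 0; a missing reference is an
error.

Between-receptor bias for one ligand and pathway is
`Δlog(τ/K_A) = [log10 τ + pK_A]_ligand − [⋯]_reference` per receptor,
`ΔΔlog = Δlog_A − Δlog_B`, reported as the factor `10^ΔΔlog`
(antisymmetric: factor(A,B)·factor(B,A) = 1; undefined when τ = 0
anywhere). Bias factors are computed only between receptors for the same
ligand — the design has a single functional pathway per construct.

**Rankings.** Receptors are ordered by descending RA_i; adjacent pairs are
merged into a tie group when a pooled-variance two-sample t-test on the
across-experiment summaries (mean, SD, n = 3) does not separate them at
α = 0.05. Pooled rather than Welch degrees of freedom are used: with n = 3
per group Welch df collapse toward 2 and the test loses the power the
underlying ANOVA+Tukey analysis has; the pooled test reproduces all the
published subtype orderings for this panel. Without dispersion information
a relative difference below 10% declares a tie. Rankings computed from a
parameter table prefer the table's own across-experiment RA_i ± SD columns
(within-experiment normalisation cancels shared error, so those SDs are
much tighter than anything reconstructable from τ/pK_A SDs).

**Group comparisons.** One-way ANOVA gates Tukey HSD at α = 0.05;
concentration-like parameters (pK_I, pEC50, pK_A) are compared on the log
scale. Flags are withheld (with a warning) below 3 estimates per group.

## Synthetic experiments

The generator emulates the study designs: saturation at 63, 125, 250, 500,
1000, 2000 pM in quadruplicate with a linear nonspecific component (~20% of
total at 1 nM free by default — nonspecific magnitude is a design choice,
not a measured value) and exact depletion bookkeeping (the free
concentration solves `free = added − bound(free)` in closed form);
competition against 1 nM radioligand on an 11-point half-log grid;
functional IPx curves on 9-point half-log grids centred on the true pEC50
in triplicate, generated at the dpm level over a basal drawn uniformly in
the 2–3% band of incorporated radioactivity (arbitrary dpm scale — fold
over basal is scale-free) and normalised by the measured basal replicate
mean; cAMP as a descending Gi/o component (submicromolar IC50) plus an
ascending Gs component (micromolar EC50) at wild type, flat at fusions.

Noise is multiplicative Gaussian with per-point CV (5% functional, 3%
binding by default — count-proportional scatter is the natural model for
radiometric assays, and these CVs produce across-experiment SDs of the
magnitude seen in published panels). Three independent experiments per
condition. All randomness derives from one integer seed through spawned
`numpy` SeedSequences; the same seed reproduces every well bit-identically.

What the simulator does **not** emulate: inter-experiment systematic
shifts beyond basal renormalisation, plate-position effects, non-Gaussian
outliers, receptor-expression drift, or slope heterogeneity (all functional
truths are unit-slope). Passing recovery tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to every artefact of real plate data.

## Numerical choices

All fitters use bounded trust-region least squares
(`scipy.optimize.least_squares`, xtol = ftol = 1e-12) with multi-start
(±1 log-unit perturbations of closed-form starting values derived from the
Hill fit or curve heuristics). Concentration-like parameters are optimised
as negative log10 molar and τ as log10 τ; saturation residuals are
normalised by the maximal specific binding so that picomolar-scale
magnitudes do not defeat optimizer tolerances. Standard errors come from
the Gauss–Newton covariance `(JᵀJ)⁻¹·SSE/(n−p)`. Degenerate inputs have
defined outcomes: perfectly constant series are "no coupling" (p = 1);
E′_MAX at or above E_MAX makes the closed-form transform raise rather than
return an unbounded τ; a zero-SSE complex model yields p = 0 in the nested
F-test, and a complex model that fails to improve yields p = 1.

Test and acceptance problem sizes are chosen to make the statistical
checks sharp while keeping the whole suite in the minutes range:
model-selection calibration at 1000 simulated datasets (binomial 3σ band
around the nominal 5%), flat-test power at 500 datasets, end-to-end
recovery over 100 seeded studies, and grid-search oracles at 0.001-step
resolution for 1–2-parameter fitters (with the Hill oracle on a coarser
3-D grid plus an SSE-dominance check).

## Known limitations

* System E_MAX is not estimable from unit-slope functional data (see
  above); reported τ values inherit the ceiling choice, and only τ/K_A
  ratios and RA_i are invariant to it in the plain convention.
* No transducer-slope generalisation of the operational model; curves with
  |nH − 1| > 0.2 get Hill parameters only.
* Biphasic (bell-shaped) cAMP responses are simulated and flat-tested but
  not parameterised — the wild-type M2/M4 result in this design is
  descriptive.
* No kinetic binding, allosteric ternary-complex, or β-arrestin models;
  competition assumes full displacement at one or two sites.
* Across-experiment summaries assume experiments are exchangeable; the SD
  reflects within-study scatter, not between-lab reproducibility.
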