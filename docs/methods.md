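# Methods

## The model

`mescgrn` implements a stochastic gene-regulatory-network model of mouse
embryonic stem cell (mESC) pluripotency in two culture media: serum/LIF,
in which Nanog expression is heterogeneous and bimodal, and 2i/LIF, the
serum-free "ground-state" medium containing the MEK inhibitor PD0325901
(PD) and the Gsk3 inhibitor CHIR99021 (Chiron).

Eight species are modelled: the Oct4-Sox2 heterodimer (OS, one species),
NANOG, MYCN, REST, PRDM14, the Fgf4/Erk signalling module (FGF_ERK),
β-catenin (BCAT) and TCF3.  Transcriptional regulation uses Hill kinetics;
when a gene has several transcriptional regulators, their Hill terms are
summed.  mRNA is assumed at quasi-steady state, so each species obeys one
protein-level equation

    dx_i = [ basal_i + Σ_j Hill_ij(x) − k_i(x)·x_i ] dt + σ_i dW_i .

Non-transcriptional interactions enter in two ways:

* **Multiplicative gates on a transcriptional term.**  Tcf3 weakens the
  Oct4-Sox2 activation of Nanog through the factor `K/(K+T)`.  Erk
  represses Nanog auto-regulation through `K²/(K²+F_eff²)`, where the
  effective Erk activity `F_eff = F · K_PD/(K_PD+PD) · K_P/(K_P+P)` is
  attenuated by the input PD and by Prdm14.
* **Hill modulators of a degradation rate.**  Chiron lowers β-catenin's
  effective degradation (`k·(1−0.95·CH/(K+CH))`), merging Chiron
  inhibition of Gsk3 with Gsk3-mediated β-catenin turnover into one
  interaction; β-catenin raises Tcf3's degradation (`k·(1+s·B/(K+B))`).

Noise is additive, zero-mean and Gaussian per species; concentrations are
kept non-negative by clipping at zero after each Euler–Maruyama step
(the model gives no boundary rule; clipping is the minimal choice and
only acts on the Nanog-low tail).  All newly added interactions use Hill
coefficient 1; the Nanog auto-activation loop and the Erk gate, which
descend from the core Oct4-Sox2/Nanog/Erk model, use coefficient 2.
Degradation rates are fixed at 1/h, the concentration scale is arbitrary
units (AU), and the time normalisation factor defaults to 1 with rates
already on the hours scale.

## How the calibration was chosen

All numeric parameters ship in `src/mescgrn/params/default.yaml`; they are
a calibration, not a transcription.  The guiding reduction is the Nanog
subsystem

    dN/dt ≈ a + s_eff · N²/(K²+N²) − N ,

where the basal drive `a` (Oct4-Sox2 activation, gated by Tcf3) is raised
by Chiron through the β-catenin→Tcf3 chain, and the effective auto-rate
`s_eff = s4 · g_Erk` is raised by PD opening the Erk gate.  The defaults
place this subsystem **just above the cusp** of its fold bifurcation
(`s_eff ≈ 1.7` at `K = 1`), which is the only regime in which all of the
following hold simultaneously:

* serum/LIF sits mid-way inside a narrow bistable window of `a`, with two
  *shallow* wells — cells flip between Nanog-High (NH) and Nanog-Low (NL)
  within hours and the steady state splits ≈50/50;
* 2i/LIF (PD = Chiron = 2 AU) sits near the fold at which NL disappears,
  but the NH basin stays shallow enough that, with Nanog noise reduced by
  20% (matching single-molecule FISH evidence for ground-state cultures),
  ≈12% of cells still occupy NL — the persistent NL subpopulation;
* raising both inputs slightly further (the shipped elevated-input level
  is PD = Chiron = 3.6 AU, just above the computed monostability onset at
  ≈3.5) removes the NL state entirely, yet with serum-level Nanog noise
  the system remains *excitable*: ≈12–13% of cells transiently visit NL;
* either inhibitor alone, anywhere in the scanned range, leaves the
  deterministic system bistable — both are needed to reach the
  monostable NH regime;
* deleting Tcf3 removes the gate on Oct4-Sox2→Nanog and lifts `a` past
  the fold in both media (monostable NH), while deleting β-catenin only
  shifts the system slightly deeper into bistability.

A deliberately large Fgf/Erk noise (σ_F = 0.5 AU·h^-1/2) acts as a
serum-specific symmetry breaker: in serum the open Erk gate transmits Erk
fluctuations into `s_eff`, intermittently eroding the NH basin near the
upper fold; in 2i the PD-attenuated gate compresses the same fluctuations
several-fold.  This is what lets one parameter set produce both the
balanced serum distribution and the NH-dominated 2i distribution.

Calibration also respects the serum→2i steady-state fold-change
directions: Mycn and Rest fall in 2i (β-catenin represses both; Nanog
represses Mycn), Prdm14 rises (Nanog activation dominates the loss of
Mycn input).  Rest's outgoing couplings are kept weak so that Rest
deletion barely moves the stability boundary, as observed.

At full protocol scale (50 populations × 1000 cells, dt = 0.01 h, 100 h
burn-in) the shipped defaults give NH fractions of ≈50.3–50.9% (serum),
≈88.2–88.6% (2i, 0.8× Nanog noise) and ≈87.5–88.0% (elevated inputs,
serum noise),
with across-population standard deviations of ≈1.3, ≈1.0 and ≈1.0
percentage points respectively — these are recomputed, not stored, by
`scripts/acceptance.py` and the acceptance tests.

## Simulation conventions

* **Integrator.** Euler–Maruyama, default dt = 0.01 h for population
  work (0.02–0.2 h in the agent-based model, whose observables are
  division counts rather than fine trajectory structure).  A halving-dt
  check keeps the serum NH fraction within Monte-Carlo error.
* **NH/NL threshold.** Midpoint of the two stable Nanog levels of the
  *serum* deterministic system, computed at model load (≈0.63 AU with the
  defaults) and reused unchanged in 2i for comparability.  Ties classify
  as NH.
* **Initialisation and burn-in.** Population runs start cells evenly
  split across the serum attractors with N(0, 0.02 AU) jitter and burn in
  100 h before recording; relaxation times are a few hours, and doubling
  the burn-in leaves the fractions unchanged within Monte-Carlo error.
* **Steady-state estimator.** Mean ± sd of the NH fraction over 50
  independent 1000-cell populations.
* **Randomness.** One master seed; sub-seeds are spawned with numpy
  `SeedSequence` for every population, colony and replicate, so any
  output is reproducible from its recorded seed.  Cells within one
  population draw i.i.d. Gaussian increment columns from the population's
  generator, which is equivalent in distribution to per-cell streams and
  vectorises far better.

## Equilibria and continuation

Equilibria are found by clamping Nanog on a log-spaced lattice, relaxing
the remaining species to quasi-steady state by ODE integration, and
polishing each start with a Newton solve (`scipy.optimize.root`);
duplicates are merged at relative L∞ distance 1e-4 and every reported
equilibrium satisfies ‖drift‖ < 1e-9 AU/h.  Stability comes from the
eigenvalues of a central finite-difference Jacobian (relative step 1e-6).
These networks are at most eight-dimensional, so this brute-force
approach is robust and cheap.

One-parameter branches (e.g. in the maximal Nanog auto-regulation rate
s4) are traced by pseudo-arclength continuation with a secant predictor
and a Newton corrector on the extended system; the step length adapts to
corrector failures.  Folds are taken at the turning points of the branch
(sign change of dp along the arc) refined by a local quadratic fit, and
they coincide with the zero crossings of the leading Jacobian eigenvalue
and with the bistable interval found by dense multi-start equilibrium
counting — the latter is kept as an independent oracle in the tests
rather than being the implementation.

The two-parameter (PD, Chiron) map labels a point "monostable (NH only)"
when exactly one stable equilibrium survives and it is the high-Nanog
one; the boundary is located per PD value by bisection on Chiron
(default tolerance 0.02–0.05 AU).  Boundaries that leave the scanned
range are reported as open-ended rather than extrapolated.

## Agent-based proliferation model

Each cell carries the full intracellular network state (same integrator)
plus a birth time and a cycle length fixed at birth.  On reaching its
cycle length a cell divides; both daughters inherit the mother's protein
concentrations exactly and draw cycle lengths from
Normal(mean_X, sd_X), truncated below at 2 h, where X is the mother's
High/Low class of the coupled species (Nanog or Mycn) *at the moment of
division*.  The Mycn threshold is the midpoint of the Mycn levels at the
two serum attractors, mirroring the Nanog rule.  Founders start from the
serum steady-state split with uniformly random initial age in
[0, cycle), which desynchronises division waves; there is no spatial
structure and no cell death.  Colonies exceeding a configurable cap are
randomly thinned with a count multiplier so reported counts stay
unbiased.

Growth is summarised as fold change in count relative to day 0 every
24 h over 3 days, averaged over independent colonies (15 by default)
with standard errors.  Cycle-time parameters are fitted by minimising
the root-mean-squared error between fold-change means (day 0 included):
a coarse grid seeds a bounded Powell search, and every candidate is
evaluated with the same colony seeds (common random numbers) so the
objective is deterministic.

**Identifiability caveat.**  In the fully stochastic network the NH/NL
classes mix on a few-hours timescale, so a 3-day growth curve mainly
constrains a class-occupancy-weighted average of the two cycle means;
the pair (mean_high, mean_low) is then only weakly identified, with
mean_high (the class that dominates late growth) much better determined
than mean_low.  The parameter-recovery tests therefore run on the
noise-free network, where cells stay frozen on their attractor and the
two exponential subpopulations make both means identifiable — this
isolates the estimator itself.  Fits to real (or fully stochastic
synthetic) data should be read as constraining the effective division
rate plus a direction of asymmetry, not two independent means.

The model-discrimination result does not depend on that caveat: with a
single calibrated network, the Nanog-coupled policy predicts *faster*
growth in 2i (the NH fraction rises) while measured ground-state growth
is slower; the Mycn-coupled policy predicts slower 2i growth because
Mycn falls in 2i (β-catenin and Nanog both repress it), and its
cross-medium prediction error is several-fold smaller.  The shipped
policy presets carry the printed cycle times (Nanog: 8.5/13.5 h in
serum, 55% longer in 2i; Mycn: 8.5/15 h and 9.5/16 h), and the paper's
model-selection argument is reproduced on synthetic serum-fast/2i-slow
fixtures.

## Synthetic data

`synthdata` generates the two kinds of measurement the pipeline
consumes, with known ground truth: FACS-like reporter fluorescence as a
two-component lognormal mixture (fluorescence is positive and
right-skewed; configurable state fractions, modes and spreads), and
proliferation tables produced by running the ABM with a known policy and
applying 5% multiplicative count noise per replicate-day (4 replicates,
24 h sampling over 3 days).  Generated datasets embed their seed and
truth; regeneration from the same spec is bit-identical.  What the
generator does *not* emulate: instrument-specific FACS artefacts
(autofluorescence, gating), plating variability between biological
replicates, and any coupling between counting error and colony size —
so passing recovery tests demonstrate estimator correctness on idealised
data, not robustness to those effects.

## Problem sizes used in the shipped checks

Steady-state fractions use the full 50 × 1000-cell protocol.  Sorting,
boundary-ordering and recovery checks run at reduced sizes chosen for a
desk-scale machine (hundreds of cells, 2–4 boundary points, colonies of
10–25 founders with population caps of 1000–6000) with tolerances set by
the corresponding Monte-Carlo spread; the APIs expose every size so any
check can be re-run at larger scale.

## Known limitations

* The parameter set is one calibrated point reproducing the reported
  population statistics; it is not a fit to molecular measurements, and
  other parameter sets could do as well.
* Near-cusp operation makes the deterministic boundary locations
  sensitive to small parameter changes (that is what makes the medium
  switch effective); boundary *orderings* across variants are robust,
  absolute boundary positions are not quantitative predictions.
* The elevated-input scenario lands slightly above the 2i NH fraction,
  whereas the reported ordering is slightly below; both values agree
  with their respective targets within one standard deviation.
* The ABM has no cell death, no spatial structure, and inherits the
  identifiability caveat above.
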