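# Methods

## The model

The circuit is two identical, independently regulated reporter genes (GFP
and RFP) in one cell.  Each module `i` has four reactions — transcription,
translation, mRNA decay, protein decay — with copy numbers `m_i`, `P_i`,
degradation rates `d_m`, `d_p`, and gene dose `g_i` treated as a
deterministic constant.  The two modules interact only through shared,
finite expression machinery: RNA polymerases at transcription (capacity
`J_g`, in gene-dose units) and ribosomes at translation (capacity `J_p`, in
mRNA copies).  Sharing is modelled with a saturating law

    transcription_i = k_m * g_i / (1 + (g_1+g_2)/J_g)
    translation_i   = k_p * m_i / (1 + (m_1+m_2)/J_p)

which has the properties any such law must have: the unlimited-resource
(UR) mass-action model is recovered as the capacities diverge; a module's
rate falls when the other module loads the pool; and an orthogonal-resource
(OR) variant is obtained by dropping the cross term while keeping the
self-saturation, `k*x_i/(1+x_i/J)`.  Because gene doses are constants,
`J_g` shapes means only; all stochastic cross-talk flows through
translation.

A fourth variant, FROZEN_CROSS, replaces the opposing mRNA inside each
translation propensity by a constant (its stationary mean).  It has exactly
the competitive (RC) model's mean field but no cross-mRNA fluctuation
channel, which is what lets the resource-competitive noise component be
isolated cleanly.

Assumptions inherited from this construction: no extrinsic fluctuations in
polymerase/ribosome copy numbers, no transcriptional bursting, no growth
dilution or cell division, no protein folding/maturation kinetics, and
cost-free orthogonal machinery.

## Noise decomposition

Around a stable fixed point the linear-noise approximation (LNA) gives the
stationary covariance from the Lyapunov equation `A C + C A^T + D = 0`
(`A` the drift Jacobian, `D` the diffusion matrix assembled from
propensities and stoichiometries; solved with SciPy's dense Lyapunov
solver, residual checked at 1e-10).  Because the two mRNAs are independent
birth-death processes upstream of the proteins, the GFP noise squared
(CV², `η² = σ²/mean²`) splits exactly into three parts:

    η_total² = 1/P1                                    (birth/death)
             + (σ_m1²/M1²) · H21² · (1/τ2)/(1/τ1+1/τ2)  (own mRNA)
             + (σ_m2²/M2²) · H23² · (1/τ2)/(1/τ3+1/τ2)  (cross mRNA, η_RC²)

with static susceptibilities `H2j = −∂ln f1/∂ln m_j` of the GFP translation
propensity and lifetimes `τ = 1/degradation rate`.  For the saturating law,

    H21 = −(J_p+m2*)/(J_p+m1*+m2*),   H23 = m2*/(J_p+m1*+m2*)   (RC)
    H21 = −1, H23 = 0 (UR);   H21 = −J_p/(J_p+m1*), H23 = 0 (OR)

The closed forms are verified against numerical and symbolic
differentiation in the test suite, and the three-term sum is checked
against the full Lyapunov CV² to 1e-8 in all four modes.  The mRNA
variances are taken from the LNA (here Poisson, since transcription is
state-independent) rather than assumed, so the split survives model
variants with state-dependent transcription.  "Noise" always means the
coefficient of variation; "RC noise fraction" means the variance fraction
`η_RC²/η_total²`.

## Calibration and parameter regimes

Noise comparisons are only meaningful at matched means, so rate constants
are rescaled per variant by inverting the stationary balance (closed form:
the balance is linear in `k_m`, `k_p`).  Time is measured in mRNA
lifetimes (`d_m = 1`).  Three regimes are used:

- **default** — mRNA mean 10, protein mean 100 per module, `J_p = 10`,
  `J_g = 20`, `d_p = 0.1`.  The workhorse for the capacity sweeps and the
  decomposition checks; translation runs at 1/3 of its unlimited rate.
- **strong competition** — `J_p = 2`, protein mean 1000.  Here protein
  birth/death noise is negligible and the propagated, resource-coupled
  components dominate: the LNA reporter correlation is ≈ −0.81, and this
  is the base circuit for trajectory-level anticorrelation and for all
  controller analyses (feedback can only reduce what dominates).
- **reduced** — mRNA mean 3, protein mean 6, `J_p = 3`, `d_p = 1`.  Chosen
  so the four-species master equation stays at ~2.5–5×10⁵ states; used for
  exact cross-validation only.

For the RC-versus-OR comparison the constants are calibrated once in the
OR model and reused verbatim in the RC model, making the two circuits
literally identical at RFP dose zero (their noise curves share that
anchor point) and letting competition emerge as the dose grows.  Dose
sweeps never retune module-1 constants — the uncompensated coupling is the
object of study.

## Stochastic simulation and statistics

The Gillespie direct method samples the exact jump process; every run
requires an explicit seed (NumPy `default_rng`), and identical seed plus
network reproduces the event sequence bit for bit.  Stationary statistics
are time-weighted — states are step functions, and event-weighted averages
would bias toward fast-firing regions — with Monte-Carlo standard errors
from ≥ 20 equal-time batch means.  Default horizons are 50 protein
lifetimes of burn-in and thousands of lifetimes of sampling; the stored-
trajectory statistics refuse horizons under 100 protein lifetimes.

## Master equation

The truncated CME generator is assembled on a box of copy numbers
(default caps: 5–6× the deterministic means), with transitions leaving the
box reflected so probability is conserved; the stationary vector comes
from a direct solve (small systems) or uniformised power iteration started
at a product-Poisson guess (large systems), with residual `‖Gπ‖∞ < 1e-10`
and a boundary-mass diagnostic (< 1e-6 required of production runs).
Distribution widths are full widths at half maximum with linear
interpolation between lattice points; multimodal inputs are flagged, not
rejected.  Increasing the caps by 50% moves reported moments by < 0.1%.

## Controllers

Twelve negative-feedback configurations: three types × four placements.
Placements select the mediator (mRNA or protein) and the target
(transcription or translation): MIX, PIX, MIL, PIL.  All types act through
an explicit inhibitor species — an sgRNA or repressor molecule — produced
at rate `α_s·d_s·(mediator)` and degraded at `d_s = 1`, so it tracks
`α_s ×` mediator with a one-mRNA-lifetime lag and its own birth/death
noise:

- **local** — each module's inhibitor represses that module;
- **global** — one shared inhibitor, produced from both mediators,
  represses both modules;
- **NCR** (negatively competitive regulation) — each module's sgRNA must
  bind a conserved dCas9 pool (`dcas_total = 50` copies, binding scale
  `K_b`); the bound complex `c_i = dcas·(s_i/K_b)/(1+s_1/K_b+s_2/K_b)`
  represses module `i`.  The partition is treated at quasi-steady state
  (the complex is a function of the sgRNA levels, in the LNA and in the
  SSA alike), and the pool is a conserved parameter, not a species.

Repression is non-cooperative: the targeted propensity is multiplied by
`1/(1 + S_c·E/K_e)`.  Scales are resolved once per analysis at a reference
dose: `α_s` so the inhibitor sits at 30 copies (inhibitory RNAs are sparse
species; their shot noise matters, and matters equally across placements),
`K_b` at the sgRNA mean, and `K_e` at the effector mean — so every
configuration represses its target by exactly `1/(1+S_c)` at the
reference, making the dimensionless strength `S_c` comparable across the
whole family.  `S_c = 0` reproduces the uncontrolled circuit exactly.

Controlled circuits are **mean-matched**: after attaching the feedback,
the targeted rate constants are divided by the repression factor at the
uncontrolled fixed point, which restores that fixed point exactly.
Normalised noise is then a pure comparison of noise structure at identical
means — without it, the repressed means inflate the 1/P term and every
feedback looks harmful.  The deterministic dose-response curves instead
mean-match once, at a chosen reference dose, and sweep the RFP dose with
constants fixed; the controllers' GFP-versus-RFP slopes then fan out
around the common point, and a shallower slope marks weaker residual
resource coupling.

Aggregate efficacy is the average noise reduction coefficient: the mean of
`1 − (normalised total system noise)` over a grid of doses placed at
deciles of the achieved RFP mean × logarithmically spaced strengths in
[0.2, 20] (the `S_c = 0` row is the reference, not a sample).  Total
system noise is the Pythagorean sum of the two reporters' CVs.
Coefficients are only compared across controllers computed on the
identical grid.

Known limitation: with these defaults the NCR-PIL configuration reduces
noise mildly at low RFP dose instead of amplifying it; the other eleven
configurations' qualitative behaviours (consistent moderate reduction for
MIX/PIX, strong high-dose reduction but low-dose amplification for MIL,
globally harmful shared feedback, the local/NCR efficacy crossover, and
the orthogonal system's preference for transcription-targeting
controllers) all reproduce.

## What the synthetic data does and does not emulate

The sampler generates exactly the statistical structure the analytics
assume: Poissonian mRNA statistics, translation coupled through a shared
finite capacity (hence anticorrelated reporters), and controller species
with their own shot noise.  It does not emulate extrinsic noise,
bursting, growth feedback or replicate-to-replicate parameter variation,
so passing tests validate the internal consistency of the model chain
(SSA ↔ CME ↔ LNA) and the qualitative mechanism, not quantitative
agreement with any particular in vivo measurement.

## Numerical choices

Fixed points: closed form for uncontrolled circuits; damped Newton with
the analytic Jacobian (residual < 1e-10) for controlled ones, started
from the uncontrolled point with inhibitors at their tracking means.
Stability is verified (all Jacobian eigenvalues in the left half-plane)
before any LNA quantity is reported.  Grid cells whose fixed point cannot
be located are flagged as missing rather than aborting a sweep.  Problem
sizes in the shipped analyses (trajectory horizons of 2×10³–10⁵ time
units, CME boxes up to ~5×10⁵ states, 8–10-point dose grids) were chosen
to keep each figure-level experiment in the seconds-to-minutes range on a
single core while leaving Monte-Carlo errors well inside the assertion
tolerances.
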