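# Methods

This note documents the models implemented in `alphadose`, the defaults and
why they were chosen, and what the synthetic generators do and do not
emulate.

## Decay chain and alpha energy per transformation

²²⁵Ac (t½ 9.92 d) heads a short serial chain: ²²¹Fr (4.9 min), ²¹⁷At
(32.3 ms), ²¹³Bi (45.6 min), then either ²¹³Po (4.2 µs, via the 98% beta
branch) or ²⁰⁹Tl (2.2 min, via the 2% alpha branch), merging at ²⁰⁹Pb
(3.25 h) and ending at stable ²⁰⁹Bi — four net alpha particles per parent
decay. Half-lives and mean alpha energies per decay are packaged constants
following ICRP Publication 107 nuclear data
(`src/alphadose/data/ac225_decay_chain.json`, replaceable at load time). The
²¹³Bi split is carried as exactly 0.98/0.02, the branch weighting
conventionally quoted for this chain; ²¹³Bi's own small alpha emission is
included as a branch-averaged 0.117 MeV per decay, while the ²⁰⁹Tl/²⁰⁹Pb
beta steps contribute no alpha energy.

The mean alpha energy per parent transformation is

Δ = Σᵢ wᵢ · Ēα,ᵢ,

with wᵢ the cumulative branch probability of reaching nuclide *i* and Ēα,ᵢ
its branch-averaged alpha energy per decay. The packaged chain gives
Δ = 4.403 × 10⁻¹² J/(Bq·s). Beta and photon energy are excluded throughout:
for alpha dosimetry with locally deposited energy they are a second-order
contribution, and including them would require absorbed-fraction modeling
out of scope here.

Activities of chain members are available from an analytic branch-weighted
Bateman solver (path enumeration with the standard λ-degeneracy guard:
equal decay constants perturbed by 1e-9 relative). The solver exists to
*verify* the secular-equilibrium assumption the dosimetry relies on — all
alpha daughters are within 0.5% of their branch-weighted equilibrium
activity within ten ²¹³Bi half-lives (~7.6 h), short against the 9.92-d
parent — not to drive the dose computation itself, which assumes
equilibrium and in-situ daughter decay.

## Biodistribution

Organ uptake is carried as decay-corrected %IA/g (percent of injected
activity per gram, referenced to injection time), the standard currency of
gamma-counted biodistribution studies. Count-ratio conversion assumes
sample and standard are both counted at secular equilibrium, so only parent
physical decay between counting sessions is corrected; the `count_delay`
parameter expresses either convention for when the standard was counted.
Group summaries use the sample SD (n−1); single-animal groups report sd = 0
with a log warning rather than an error, since small-n femur/marrow groups
are routine. Organ labels pass through a small controlled vocabulary
("Marrow, red" → marrow, "Heart wall" → heart, …) before any phantom or
weighting join.

## Dosimetry pipeline

The absorbed dose per organ follows the MIRD formalism for an alpha emitter
whose daughters decay where the parent decays:

D = Ã · Δ · ϕ, ϕ = 1,

with Ã the cumulated activity concentration (Bq·s/kg per MBq injected).
The stages, each separately exposed and tested:

1. **Mouse → human scaling** (relative organ-mass method): each organ's
   %IA is scaled by the ratio of fractional organ masses between species and
   reconverted to per-gram concentration. The organ masses cancel
   algebraically, so human %IA/g = mouse %IA/g × (mouse body mass / human
   body mass) identically across organs — an enforced, tested property.
   Consequently the packaged phantom organ masses (an ICRP-89-style 60-kg
   adult female and a 25-g mouse) matter only for organ coverage and
   %IA-per-organ reporting, not for per-gram doses.
2. **Time–activity curves**: %IA/g is un-decay-corrected (× e^(−λt)) to the
   activity actually present at sampling; 1 %IA/g per MBq injected is
   10⁷ Bq/kg at t = 0.
3. **Cumulated activity**: trapezoidal integration over the samples, plus a
   head segment from t = 0 to the first sample (held constant at the first
   value by default; a linear ramp from zero is available) and an analytic
   tail after the last sample in which biological retention is frozen and
   only physical decay proceeds: tail = a_last/λ. This is the maximally
   conservative extrapolation to infinity — any continued biological
   clearance would only reduce Ã — and the tail's share of Ã is recorded
   for audit. Trapezoid error converges as O(Δt²) on smooth curves.
4. **Doses**: equivalent dose = absorbed dose × RBE (default 5 for alpha
   particles) on the mGy/mSv scale; effective-dose scalars are
   tissue-weighted sums of organ equivalent doses under two packaged,
   replaceable weighting schemes — the older scheme for the "effective dose
   equivalent" and the newer one for the "effective dose". Organs without
   an explicit weight share the scheme's remainder weight uniformly. Blood
   is integrated and reported as its own compartment but excluded from the
   effective-dose sums; heart dose is computed from the heart measurement
   as recorded, with no blood-content correction.

Daughter translocation (e.g. free ²¹³Bi accumulating in kidney) is a
documented non-goal: all daughters decay in the organ where the parent
decayed, which can underestimate kidney dose.

## Radiochemistry QC

Plain arithmetic, validated for domain constraints: specific activity =
input activity × yield / antibody mass; purity = bound/(bound+free);
chelates per antibody = (conjugate − native mass)/adduct mass, reported to
one decimal. The DOTA adduct mass is a parameter because it depends on the
conjugation chemistry.

## Therapy statistics

Survival uses the Kaplan–Meier product-limit estimator (via lifelines) with
standard tie handling (deaths before censorings). Animals euthanized for
disease-attributable humane endpoints — hind-limb paralysis, >20% weight
loss, morbidity — count as events; scheduled termination and
disease-unrelated deaths are censored. The attribution set is a parameter
because censoring conventions vary between studies. The median is the first
time S(t) ≤ 0.5 and is reported as not determinable when fewer than half
the subjects have events. Cohorts are compared with the Mantel–Cox log-rank
test.

Tumor burden is analyzed on the log scale: per-subject BLI series are
normalized to the first imaging time point (which changes intercepts, never
slopes — a tested identity), and growth rates are OLS slopes of log₁₀ flux
versus day over a half-open window, default days [10, 20) after cell
injection. Cohort slopes are compared by one-way ANOVA with pairwise t
contrasts; per-subject slopes (rather than a pooled interaction regression)
keep each animal as the experimental unit. Weight trajectories are compared
per day with Welch tests, uncorrected by default to match per-timepoint
reporting conventions, with an optional Holm adjustment.

## Synthetic data generators

The biodistribution generator emulates intact-antibody pharmacokinetics in
the mouse. Blood is bi-exponential, C(t) = A·e^(−αt) + B·e^(−βt) with
defaults A = 8, B = 38 %IA/g, α = 0.094/h, β = 0.0032/h, calibrated so the
cohort mean is ≈43 %IA/g at 4 h and ≈15 %IA/g at 12 d. Other organs follow
uptake–washout curves peak·(1−e^(−3t/t_peak))·e^(−k_w·t) calibrated to the
ranges typical of these studies (kidney 8–11, liver 10–15, marrow 6–12
%IA/g declining); a tumor-bearing scenario reproduces the high tumor
(≈28 %IA/g) and spleen (≈31 %IA/g) and low liver (≈7 %IA/g) uptake of
CD20-targeted antibody at 7 d. Noise is multiplicative log-normal (organ
data are strictly positive) and mean-preserving (exp(σZ − σ²/2)), default
σ = 0.14 so cohort SDs match reported ±SD spreads (≈±6 on a mean of 43).
Default sampling: 4 h and 1, 2, 4, 7, 10, 12 d, four animals per timepoint,
destructive sampling (one animal contributes all organs at one time).

The therapy simulator is phenomenological: exponential burden growth
N(t) = N₀e^(gt) with N₀ = 10⁶ cells and g = 0.44/d, BLI flux proportional
to burden, an instantaneous cohort-dependent log₁₀ kill at the treatment
day (day 8), and Bernoulli regrowth of residual disease (relapse). Events
occur when burden crosses a hind-limb-paralysis threshold (10¹⁰ cells) or
weight drops >20% from baseline; survivors are censored at day 200.
Untreated animals cross the threshold at a median of ≈21 d (ln(10⁴)/g),
within the 19–23 d band across seeds. Per-subject variability is log-normal
on g (σ = 0.06) and N₀ (σ = 0.2). A transient weight dip (nadir ~day 27,
recovery by ~day 52) emulates dose-dependent systemic toxicity in treated
survivors.

What the generators do *not* emulate: real inter-animal covariance between
organs, dechelation and free-actinium liver accumulation, daughter
redistribution, mechanistic radiobiology of alpha killing (the log-kill is
an effect size, not a dose-response model), imaging saturation, or the
actual timepoint structure of any particular study. Passing tests therefore
demonstrate that the pipeline and statistics behave correctly on data with
the right structure and calibrated first moments — not that they reproduce
any specific animal dataset. In particular, published organ-dose tables
depend on the originating study's raw biodistribution file and its phantom
and weighting choices; with synthetic inputs the dose pipeline is validated
by its algebraic properties (linearity in uptake, Δ, ϕ and RBE;
body-mass-ratio scaling; tail conservatism; trapezoid convergence) and by
hand-computed single-organ oracles rather than by matching printed tables.

## Numerical choices

- Bateman solver: analytic path enumeration; equal decay constants
  perturbed by 1e-9 relative; daughter activities clamped at exact zero for
  t = 0 and nonnegative elsewhere (cancellation guard).
- Trapezoid integration uses the sample grid as given; accuracy is the
  caller's schedule choice (200 points per half-life gives <1% error on a
  pure exponential, and the default biodistribution schedule errs on the
  conservative side via the head/tail policies).
- Degenerate statistics inputs: zero-variance ANOVA returns F = 0, p = 1;
  single-sample summary groups report sd = 0; slope estimation requires two
  positive-flux points inside the window and excludes zero-flux points
  (they carry no burden signal on the log scale).
- Problem sizes in tests were chosen for tight Monte-Carlo bounds at
  interactive runtimes: 2000 null pairs for log-rank type-I error, 500
  replicate seeds for survival-band and ANOVA calibration, 50 animals per
  timepoint for generator calibration checks.

## Known limitations

- Alpha-only dosimetry; no beta/photon cross-dose, no voxel or Monte-Carlo
  transport, no bone-surface vs. marrow microdosimetry.
- No daughter translocation kinetics (kidney dose from free ²¹³Bi is
  underestimated by construction).
- The packaged phantoms and tissue-weight sets are reasonable defaults, not
  a reproduction of any particular published model; both are replaceable
  via configuration.
- The therapy simulator's relapse model is qualitative (a regrowth
  probability per arm), sufficient to exercise the statistics but not to
  model dose–response of relapse timing.
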