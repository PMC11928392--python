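# Methods

This note documents the models, numerical choices and limitations of
`rptdose`. It is the package's own account of its science; every
number quoted here is computed by the test suite or the acceptance
script.

## Time-activity model and fitting

Organ activity concentration after injection (t = 0, hours) is modelled
as

* mono-exponential washout: c(t) = A·e^(−λt), or
* uptake–washout bi-exponential: c(t) = A₁·e^(−λ₁t) − A₂·e^(−λ₂t),
  λ₂ > λ₁, A₁ > 0, A₂ ≥ 0,

with concentrations decay-corrected to acquisition time, i.e. physical
decay included. Every admissible rate therefore satisfies
λ ≥ λ_phys = ln2/159.5 h⁻¹ (biological clearance cannot be negative);
rates are capped at 10 h⁻¹, faster than anything resolvable from scans
hours apart.

Fitting is nonlinear least squares with variable projection: for fixed
rates the amplitudes are the linear least-squares solution, and the
rates are optimized by `scipy.optimize.least_squares` over
(log(λ₁−λ_phys), log(λ₂−λ₁)), which enforces the ordering and lower
bound by construction. The slow rate is seeded by log-linear regression
on the last two positive samples; the fast rate is multi-started at
5·λ₁ and at 0.15, 0.5 and 1.5 h⁻¹, spanning uptake phases peaking from
minutes to about a day, with early exit once an interpolating fit is
found. A requested bi-exponential falls back to mono-exponential when
the fit is degenerate: negative amplitude, collapsed rates
(λ₂−λ₁ < 10⁻³·λ₁), non-positive total integral, or an RSS reduction
below 1% relative to the mono fit (including the case where the mono
fit already explains the data to numerical noise).

**Effective half-life.** A bi-exponential has no single half-life; we
use the terminal-phase definition T_eff = ln2/λ₁ by default, because
the single-time-point eligibility window concerns late washout. An
area-equivalent alternative (ln2·Ã/c_peak, which reduces to the same
value for mono-exponentials) is available via `teff_kind="area"`.

**Identifiability caveat.** On the default SPECT-like grid
{3, 24, 48, 72} h the uptake pair (A₂, λ₂) is constrained by a single
pre-peak sample: for fast uptake (λ₂ ≳ 0.5 h⁻¹) the day-1–3 samples
carry no information about it, leaving a one-parameter family of
near-interpolating fits whose integrals differ by a few percent. The
terminal rate — and hence T_eff — is unaffected. Recovery of the dose
to better than 1% therefore requires early sampling that resolves the
uptake phase (the dense-grid configuration used in the recovery tests);
with the default 4-point grid the median noiseless dose error is ~0.3%
with worst cases near 2–8%.

## Absorbed dose

Both methods convert a time-integrated concentration Ã (MBq·h/g) to
dose under **local energy deposition**:

    K = 3.6·10⁹ decays/(MBq·h) · Ē[MeV] · 1.602·10⁻¹³ J/MeV · 10³ g/kg
      = 0.0848 Gy per MBq·h/g at Ē = 0.147 MeV.

Ē defaults to 0.147 MeV, the mean electron (beta + conversion + Auger)
energy per ¹⁷⁷Lu decay from standard nuclear data; it is configurable
via `NuclideSpec`. This replaces voxel Monte-Carlo transport, which is
reasonable for ¹⁷⁷Lu's ~mm beta range at organ scale; cross-organ
photon dose (a few percent of the self-dose) is deliberately ignored.
Tissue density defaults to 1.0 g/mL and only matters when
concentrations are supplied per millilitre.

* **MTPD**: Ã = ΣᵢAᵢ/λᵢ from the fitted curve (closed form). A
  numerical cross-check integrates the observed samples with the
  pharmacokinetic lin-up/log-down trapezoid rule (log-trapezoid is
  exact for exponential decay between samples) plus a closed-form head
  and a terminal-rate tail.
* **STPD**: Ã ≈ c(t)·2t/ln2 from one scan. For mono-exponential truth
  STPD/MTPD = 2^(1−x)·x with x = t/T_eff: zero error at x = 1, maximum
  +6.15% at x = 1/ln2, −10.81% at x = 0.75 and −11.61% at x = 2.5.
  Scans are eligible only for 0.75·T_eff < t < 2.5·T_eff (strict
  bounds, matching the stated inequality), which bounds the
  mono-exponential error to ±11.6%.

The window uses the organ-wise **population** T_eff (median over all
fitted curves of that organ), mirroring a cohort-level quality-control
step; a per-patient option exists. When several scans pass, the one
closest to T_eff is used, since that minimizes the analytic error law.
Note the built-in tension this reproduces: with tumor T_eff ≈ 45 h a
day-1 scan (~24 h) is below the window and STPD must use day 2–3,
while marrow (T_eff ≈ 30 h) accepts day-1 scans.

Cumulative doses are running sums over cycles per patient × organ ×
method; the final sums are the MTPD_total/STPD_total covariates.

## Voxel mask rules

On (z, y, x)-indexed SUV grids: the marrow mask is bone AND
SUV ≤ 0.5·max (voxels *above* 50% of the whole-body maximum are
treated as tumor-infiltrated and excluded; boundary voxels stay in
marrow), and the tumor mask is the iso-contour SUV > f·max,
0 < f < 1. Both are invariant to uniform SUV rescaling, and marrow and
hot bone partition the bone mask exactly. A corollary of the literal
rule: a uniform positive SUV map leaves no marrow, since every voxel
is "above 50% of maximum". No registration, partial-volume or
physiologic-uptake exclusion is modelled.

## Discrepancy metrics

With MTPD as reference and pairs matched by patient within organ ×
cycle (cumulative doses by default, per-cycle switchable):

* RMSE = √(mean (Sᵢ−Mᵢ)²) in Gy,
* MPE = mean((Sᵢ−Mᵢ)/Mᵢ)·100,
* RPD per pair = (Sᵢ−Mᵢ)/((Sᵢ+Mᵢ)/2)·100, tabulated as the arithmetic
  mean over pairs (matching MPE's printed form).

Pairs whose STPD was removed by the window filter are dropped from
that cycle's metrics and counted in an attrition log. With scan time
pinned at x = t/T_eff on noiseless mono-exponential kinetics, MPE
equals 100·(2^(1−x)·x − 1) exactly — the link between the metrics and
the analytic law that the tests assert.

## Outcome statistics

* PSA decline rate (PSA_t − PSA₀)/PSA₀ per cycle; ≤ −0.5 (a decrease
  of at least 50%, inclusive) defines a good response.
* CTCAE v5.0 anemia from hemoglobin (default LLN 13 g/dL): grade 1 in
  [10, LLN), 2 in [8, 10), 3 below 8; grades 4–5 only via explicit
  clinical flags.
* Spearman correlation (scipy, average ranks, t-approximation p) of
  cycle-level cumulative dose with the same cycle's endpoint, pooled
  across patients (~100 observations for 20 patients × up to 6
  cycles); patient-level pooling is possible by pre-aggregating.
* Fisher Z comparison of the two methods' correlations using the
  independent-samples formula. Strictly, the two correlations share
  their observations; the independent form is kept as the default
  (consistent with how such comparisons are usually reported) and
  Steiger's dependent-correlation test is available via
  `dependent_fisher=True` / `steiger_z_compare`. The independent form
  is conservative here: with strongly correlated dose methods the true
  null variance of z₁−z₂ is smaller than assumed, so non-significance
  statements are not inflated.
* Mann–Whitney U between responder classes: exact distribution for
  ≤ 20 untied observations, normal approximation with tie correction
  otherwise (scipy).
* Univariate Cox regression: own Newton–Raphson maximization of the
  Breslow partial likelihood with step halving, covariate centering
  and overflow-safe risk-set sums. Monotone likelihood (perfect
  separation) is detected exactly — the log partial likelihood is
  concave, so a non-vanishing score at the admissible boundary
  (|β| = 20) proves the maximizer lies at or beyond it — and flagged
  with a warning, with β capped. Without tied event times (the
  simulated setting) Breslow coincides with Efron, and the estimates
  match lifelines to ~10⁻⁵ in tests. The Cox subset is patients with
  at least 5 cycles (reading "more than 4 cycles" literally),
  switchable via `min_cycles_for_cox`; log-dose covariates exclude
  zero doses with a warning.
* Kaplan–Meier via lifelines, with a median split on total MTPD.
* All p-values two-sided; no multiplicity correction is applied.

## Synthetic cohort generator

What it emulates: 20 patients × up to 6 cycles of 7.2 ± 0.3 GBq;
per-patient organ T_eff lognormal around the population values (tumor
45.05 h, marrow 29.86 h, kidneys 35.11 h, liver 38.40 h, spleen
34.02 h) with CV 20% — an assumed inter-patient spread, as no
population variance is available; uptake amplitudes calibrated so the
expected cycle-1 dose per unit activity equals the organ targets
(kidneys 0.36, liver 0.12, spleen 0.09, marrow 0.45, tumor 2.02
Gy/GBq) with lognormal inter-patient CVs (0.37–1.0, widest for marrow
and tumor where uptake is metastasis-driven); a fast uptake rate drawn
log-uniformly in [0.5, 2] h⁻¹, putting the concentration peak at
roughly 2–7 h, consistent with a first scan at 2–4 h being near peak;
scan grid {3, 24, 48, 72} h with ±2 h jitter; multiplicative lognormal
measurement noise, CV 10% by default (SPECT quantification error is
scale-proportional).

Outcomes: PSA decline rate = a·(cumulative tumor dose) + Gaussian
noise truncated at −1 (PSA cannot fall below zero), with a = −0.004
per Gy and noise SD 0.35 — sized so that cycle-level dose–response
rank correlations land in the |ρ| ≈ 0.3–0.5 range typical of such
cohorts; hemoglobin declines by 0.08 g/dL per Gy of cumulative marrow
dose; survival is exponential with log-hazard proportional to log
total tumor dose (default log-HR = log 3.41 per log-Gy — higher-dose
patients fare *worse*, reflecting that total dose tracks tumor burden
in observational data), with independent uniform censoring at
400–1200 days. Patients may stop after 4–5 cycles (probability 0.3).
Same seed → byte-identical outputs.

What it does **not** emulate — and what passing tests therefore do not
show about real data: image reconstruction, registration and
segmentation errors (the dominant real-world sources of
single-time-point discrepancy, especially for marrow); kinetics that
deviate from bi-exponential form; inter-cycle kinetic drift from
treatment response; correlated organ uptakes; informative censoring.
In particular, STPD errors in the simulator stay close to the analytic
mono-exponential bound, so the simulated method agreement is tighter
than observed clinically; conclusions about error *tolerance* transfer,
conclusions about error *magnitude* do not.

## Problem sizes and numerical tolerances

Recovery tests run the default 20 × 6 cohort (≈ 565 curves, a few
seconds per cohort); effective-half-life recovery is judged against
the realized cohort truth (the drawn per-patient values), since with
20 patients the realized population median sits several percent from
the configured value by sampling alone. Dose recovery to 1% uses the
dense early-sampling grid (see the identifiability caveat). The Cox
hazard-ratio recovery uses 500 patients; null calibration of the
correlation machinery uses 1000 replicates of n = 95. Optimizer
tolerances are 10⁻¹⁴ (curve fits) and 10⁻¹⁰ relative (Cox Newton);
fits recover noiseless generating parameters to ~10⁻⁶ relative or
better.

## Known limitations

Organ-mean kinetics only (no voxel-wise fitting); no photon cross-dose
or marrow cellularity model; no radiobiological (BED/EQD2) modelling —
dose–response is summarized by rank correlation only; anemia grading
from hemoglobin alone caps at grade 3; the Fisher comparison's
independent-samples default understates power for dependent
correlations (use the Steiger option when that matters).
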