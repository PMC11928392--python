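# rptdose

Single- vs multi-time-point absorbed-dose estimation for
¹⁷⁷Lu-PSMA-617 radiopharmaceutical therapy, and the question that
matters clinically: **do the errors of a simplified one-scan dosimetry
protocol degrade the correlation of absorbed dose with treatment
outcome?**

The package is aimed at medical-physics and nuclear-medicine
researchers who want a tested, reusable reference implementation of
this comparison — curve fitting, dose conversion, error metrics and the
outcome statistics — together with a synthetic-cohort generator with
known ground truth, so every stage runs and is testable without patient
data.

## The methods in brief

**Kinetics.** Serial SPECT activity concentrations c(t) (MBq/g) per
organ and cycle are fitted by least squares as mono-exponential washout
c(t) = A·e^(−λt) or uptake–washout bi-exponential
c(t) = A₁·e^(−λ₁t) − A₂·e^(−λ₂t) with λ₂ > λ₁. The effective half-life
is the terminal one, T_eff = ln2/λ₁, bounded by the physical decay of
¹⁷⁷Lu (159.5 h).

**Multi-time-point dose (MTPD).** The time-integrated concentration
Ã = ∫₀^∞ c(t) dt (closed form, ΣᵢAᵢ/λᵢ term-wise) is converted to
absorbed dose under local energy deposition,

    D = Ã × 3.6·10⁹ decays/(MBq·h) × Ē × 1.602·10⁻¹³ J/MeV × 10³ g/kg,

with Ē ≈ 0.147 MeV per decay for ¹⁷⁷Lu's electrons — appropriate
because the beta range is small against organ size; cross-organ photon
dose is neglected.

**Single-time-point dose (STPD, Hänscheid approximation).** One scan at
time t surrogates the integral as Ã ≈ c(t)·2t/ln2, exact at t = T_eff
for mono-exponential washout. Scans are eligible only inside
0.75·T_eff < t < 2.5·T_eff, where the analytic error law
STPD/MTPD = 2^(1−x)·x (x = t/T_eff) bounds the mono-exponential error
to −10.8%…+6.2%…−11.6% across the window. The window uses the organ's
*population* T_eff, and among eligible scans the one closest to T_eff
is used.

**Comparison and outcome statistics.** Per organ and cycle the paired
cumulative doses give RMSE, mean percentage error (MPE) and mean
relative percentage difference (RPD). Cycle-level cumulative tumor dose
is correlated (Spearman) with that cycle's PSA decline rate
(PSA_t − PSA₀)/PSA₀, and marrow dose with CTCAE anemia grade; the two
methods' correlations are compared with the Fisher Z-transformed test
z = atanh(ρ), Z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3)). Overall survival is
analyzed with univariate Cox regression (Breslow partial likelihood,
Newton–Raphson) on total tumor dose (raw and log) and Kaplan–Meier
curves split at the median total dose; responder groups (PSA decline
≥ 50%) are contrasted with the Mann–Whitney U test.

**Synthetic cohorts.** `generate_cohort` draws per-patient kinetics
around published population values (T_eff: tumor 45.05 h, marrow
29.86 h, kidneys 35.11 h, liver 38.40 h, spleen 34.02 h; cycle-1 dose
per activity: kidneys 0.36, liver 0.12, spleen 0.09, marrow 0.45,
tumor 2.02 Gy/GBq), ~7.2 GBq per cycle for up to 6 cycles, lognormal
measurement noise, and outcomes stochastically linked to cumulative
dose — with the generating truth returned for recovery tests.

## Worked example

```
rptdose report --seed 1 --out run/
```

simulates the default 20-patient cohort, fits all curves, computes both
dose sets, and prints the statistics block:

```
PSA decline rate vs tumor dose: MTPD rho = -0.48 (p = 5.8e-08), STPD rho = -0.48 (p = 6.4e-08); Fisher Z = -0.01, p = 0.99 (n = 113/113)
Anemia grade vs bone-marrow dose: MTPD rho = 0.42 (p = 4.4e-06), STPD rho = 0.43 (p = 1.9e-06); Fisher Z = -0.13, p = 0.89 (n = 113/113)
U-test tumor MTPD by PSA response: U = 1337.0, p = 0.00016
U-test tumor STPD by PSA response: U = 1340.0, p = 0.00014
Cox OS ~ MTPD_total: HR = 1.01 (beta = 0.011, se = 0.006, p = 0.0469)
Cox OS ~ log_MTPD_total: HR = 2.05 (beta = 0.718, se = 0.593, p = 0.226)
Cox OS ~ STPD_total: HR = 1.01 (beta = 0.013, se = 0.006, p = 0.0438)
Cox OS ~ log_STPD_total: HR = 2.06 (beta = 0.721, se = 0.623, p = 0.247)
```

Reading: both dose methods correlate negatively with PSA decline
(higher tumor dose → larger decline) and positively with anemia grade,
and the Fisher comparison finds no significant difference between the
two methods' correlations — the one-scan protocol loses accuracy
(`run/metrics.csv` holds the per-organ RMSE/MPE/RPD table; e.g. marrow
STPD runs ~5–9% below MTPD here) but not predictive association.
`run/doses.csv`, `run/pd_series.csv` and `run/report.txt` hold the full
dose table, the per-cycle percentage-difference series, and the text
report; each stage also writes a manifest with input digests so reruns
are reproducible.

The same stages are available as Python functions (`generate_cohort`,
`fit_all`, `run_dosimetry`, `metric_report`, `run_comparison_analysis`)
and as separate subcommands (`simulate`, `fit`, `dose`, `compare`,
`correlate`).

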