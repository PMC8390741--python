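# Methods

## Dose model

All kinetics are single exponentials. For a region r_k with activity
`A_k(t) = A_k(0)·e^(−λ_k t)` (λ_k the effective decay constant, physical +
biological, in h⁻¹), the cumulated activity from injection to infinity is
`Ã_k = A_k(0)/λ_k` in MBq·h. The general MIRD engine
(`organ_dose_mird`) evaluates `D = Σ_s Ã_s·DF(target ← s)` with dose
factors in mGy/(MBq·s) (cumulated activities are converted ×3600); a
missing (source, target) pair raises rather than contributing zero.

For ¹⁷⁷Lu the absorbed dose to kidneys, liver, spleen and tumors is
dominated by the non-penetrating β self-term, so the working route is the
mass-scaled self-dose

    D = Ã · Θ_k / m_k,

where Θ_k lumps the equilibrium dose constant and self-absorbed fraction
(mGy·kg/(MBq·h)) and m_k is the *patient's* VOI mass (volume × density,
density 1.0 g/cc by default and configurable; clinical reports rarely state
the value used). Tumor Θ comes from a sphere-model table interpolated
piecewise-linearly in mass; queries outside the tabulated range are
refused, since extrapolating absorbed fractions has no physical basis.

Bone marrow combines the blood self-term with a remainder-of-body
cross-term:

    D(BM) = (a_blood(0)/λ_blood)·Θ_BM,BM + (c_RM(0)/λ_RM)·Θ_BM,RM,

with both time-integrated concentrations expressed in mCi·h/cc. The two
couplings are treated as opaque fitted constants in mGy/(mCi·h/cc): any
marrow-to-blood concentration ratio, and the fixed factor between
activity-per-mass and concentration-per-cc at unit density, are absorbed
into them. This is why the package applies the same mCi/cc convention in
the standard marrow dose and in the regression composite — one convention,
one conversion point.

## Kinetic fitting

`fit_monoexponential` is unweighted ordinary least squares of ln(value) on
time. The fit is exact for two points; zero or negative values are rejected
before the log transform; a fitted λ ≤ 0 raises a non-decaying-kinetics
error carrying the offending parameters. Nonlinear least squares was
considered and rejected as the default: log-OLS is the simplest scheme
consistent with mono-exponential fitting, is exactly invertible on
noiseless data, and is unbiased for λ under multiplicative lognormal noise
(verified by a 200-replicate Monte-Carlo in the tests).

Cycles after the first are imaged once (~24 h). Their dose uses
`Ã = A(t_s)·e^(λ t_s)/λ` with the *same patient's* cycle-1 λ per region —
the unchanged-effective-half-life assumption. If a region has no cycle-1
fit the calculation fails loudly; borrowing a population λ is known to
produce ≥30% errors and is deliberately not offered.

## Single-time-point regression

Writing the self-dose in terms of the measured concentration
`conc(t_s) = S·C(t_s)/V` gives `ln D = ln K + ln conc + λ·t_s` exactly, for
a region-specific constant K. The trained model

    ln D = α₀ + α₁·ln conc + α₂·t_s

is plain OLS (no regularisation, no robust loss) on standard-protocol
doses; α₂ estimates the population's effective decay constant, which the
parameter-recovery tests assert. The time regressor stays in the design
even for single-time training tags: acquisition times vary patient to
patient (±2 h at t₁ up to ±12 h at t₃), which keeps the column
non-degenerate; a truly constant column raises a singular-design error.
Rows with zero measured activity cannot be log-transformed and are dropped
with a logged warning. The reported r² is the coefficient of determination
of the fit in log space.

The marrow model first estimates (Θ_BM,BM, Θ_BM,RM) by **non-negative**
least squares through the origin of the standard marrow dose on its two
time-integrated terms. Neither an intercept nor a sign constraint is
dictated by convention here; the origin-through, non-negative choice
encodes that both source compartments can only deposit dose, and is
documented as an assumption. The same estimated pair is embedded in the
coefficient object and reused at prediction time. Note that when the
standard marrow dose is itself computed from the same fitted terms, the
regression is exactly identified; noise on the dose side (independent
replicate measurements) degrades recovery, and the test tolerances for that
case were fixed by a 500-replicate Monte-Carlo (worst-case relative errors
6.4% for the blood coupling, 29% for the remainder coupling at n = 40, 5%
noise).

Unit contract: concentrations in mCi/cc, time in hours, dose in mGy.
Internal units are MBq/cc; division by 37 happens exactly once, at the
regression boundary, and estimators refuse unit strings they do not know.
Coefficient files are JSON with full-precision floats, so serialisation
changes no prediction at all.

### Protocol combinations

The headline protocol trains on all first-cycle times and predicts at t₃
after cycle 1, then switches to t₁-trained equations applied at t₁ for
every later cycle. Using one coefficient set for both positions would
extrapolate the marrow model ~140 h outside its training time support and
visibly biases later-cycle doses, so `run_study` trains separate sets per
cycle position (configurable via `StudyConfig`). The sweep utility
enumerates 4 solid training tags × 3 first-cycle prediction times × 3
marrow training tags = 36 combinations, pairing the marrow prediction time
with the solid one (t₂ maps to t₃ — no blood sample exists at t₂).

## Management rules

"Expected" cumulative dose after one more cycle = cumulative + arithmetic
mean of completed-cycle doses. The mean is the minimal defensible
estimator and is isolated in one function so a clinic-specific rule (e.g.
scaling by planned injected activity) can be substituted. "Exceed" is
strict: exactly 25.000 Gy continues.

The early classification projects the mean per-cycle dose to the planned
series and buckets patients by the fractional cycle count x at which the
trajectory crosses the threshold: x ≥ 4 → four cycles safe; 3.5 ≤ x < 4 →
consider a fourth; 3 ≤ x < 3.5 → three cycles safe; 2 ≤ x < 3 → consider a
third; otherwise (or cumulative already above threshold) → stop now. The
half-cycle boundary is a reconstruction — the upstream clinical algorithm
is not public — chosen so that a trajectory that only just overshoots the
planned total is flagged for review rather than hard-stopped a cycle early.
Decisions are advisory; multidisciplinary override is out of scope.

## Synthetic cohort

The generator emulates the study conditions the models were built for:

| parameter | default | note |
|---|---|---|
| injected activity | 7300 ± 500 MBq per cycle | reported treatment activity |
| λ kidneys/liver/spleen/tumor | 0.0129 / 0.0098 / 0.0095 / 0.0082 h⁻¹ | population means, lognormal, CV 20% |
| imaging times | 24 ± 2, 96 ± 8, 168 ± 12 h | cycle 1; later cycles t₁ only |
| blood sampling | t₁ and t₃ (cycle 1), t₁ later | concentration in MBq/cc |
| measurement noise | 5% CV, multiplicative lognormal | unbiased in log space |
| cycles per patient | P(1..4) = .125/.0625/.28/.53 | matches a treated population |
| marrow couplings (truth) | Θ_BM,BM = 1889, Θ_BM,RM = 315 | published t₃ estimates |
| train/test split | 40/72 proportional | training patients first |

Uptake fractions (kidneys 2%, liver 4.5%, spleen 1.2%, tumor 2%, remainder
40%, blood 10% of injected) and VOI volumes are plausible placeholders —
the underlying clinical distributions are not published — and only shape
the dose magnitudes, not the model structure. All randomness flows from
one seed; patient i uses the substream (seed, i), so cohorts are
bit-reproducible and patients individually regenerable.

Ground truth is closed-form: every organ dose is `A₀Θ/(mλ)` and the marrow
dose the two-term coupling formula, so the noiseless pipeline must agree to
better than 10⁻⁹ relative (it agrees to ~10⁻¹⁴; the slack covers the
log-OLS round trip).

`model_matched()` produces the degenerate variant under which the log-log
models are *exact*: zero λ and volume spread per region, blood and
remainder sharing one decay constant (so the composite marrow model has a
single λ_BM), zero noise. On that cohort training returns r² = 1, α₁ = 1,
α₂ = λ to machine precision and the two protocols make identical decisions
for every patient — the closure the acceptance checks assert. What passing
those checks does **not** show: real patients have multi-compartment
kinetics, imperfect VOI delineation, partial-volume effects and
inter-cycle kinetic drift, none of which the generator models (per-cycle λ
jitter exists as an option, default off, for robustness experiments).

## Packaged data

`mlr_coefficients_published.json` transcribes the published coefficient
sets per target and training tag; a test asserts cell-for-cell fidelity.
`dose_factors_synthetic.json` and `sphere_theta_synthetic.json` are
synthetic stand-ins (proprietary phantom S-value libraries cannot be
redistributed): self couplings follow the ¹⁷⁷Lu mean β energy
(≈134 keV → Θ ≈ 0.0773 mGy·kg/(MBq·h), absorbed fraction ≈ 1), phantom
masses and photon cross-terms are illustrative. Absolute synthetic doses
are therefore realistic in magnitude (≈3 Gy/cycle kidneys, ≈0.3 Gy/cycle
marrow) but not clinically calibrated.

## Numerical choices and limitations

- OLS via `numpy.linalg.lstsq` with an explicit rank check
  (tolerance 10⁻¹² × largest design entry) → `SingularDesignError`;
  statsmodels serves only as an independent oracle in the test suite.
- NNLS via `scipy.optimize.nnls`.
- Agreement statistics: relative differences use the standard protocol as
  denominator (model/standard − 1); Bland–Altman limits are mean ±
  1.96·SD with the n−1 denominator; the angular coefficient is the OLS
  slope of model on reference with intercept; no multiplicity correction
  is applied (the statistics are descriptive).
- Binomial power uses the zero-discordance null, under which any observed
  discordance rejects and power = 1 − (1 − p)ⁿ; this is the unique null
  reproducing the printed design power and is stated as such.
- Under measurement noise the marrow slope β₁ attenuates toward ~0.5–0.8:
  the single-sample composite regressor carries the full measurement error
  while the dose derives from the two-point blood fit (classical
  errors-in-variables). This is a property of the design, visible in the
  published training quality as well, and is not corrected for.
- Problem sizes in tests and the acceptance script (72-patient cohorts,
  500-replicate Monte-Carlos run offline to fix tolerances, 10⁴-point
  equivalence grids) keep the full suite under a few seconds while leaving
  the statistical assertions well-powered.
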