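# Methods

## Flow quantification

A cine PC acquisition is a voxel grid of through-plane velocity (cm/s) over
8 cardiac bins. Quantification follows the standard workflow:

1. **Background phase correction.** Per bin, the mean velocity over the
   static-tissue mask is subtracted everywhere (constant model, default), or
   a first-order plane fitted to static voxels is removed (`planar`). The
   corrected static mean is 0 (±1e-9) and the operation is idempotent. The
   constant model is the simplest one consistent with a slab of
   uniform-offset error; the planar option covers linear shim-like fields.
2. **Vessel flow.** Per bin, flow = (mean velocity over the ROI) × (ROI
   pixel count × pixel area) × 60, in mL/min; the cycle mean is the
   unweighted mean of the 8 bins (retrospective gating yields equal-duration
   bins). This is algebraically identical to summing per-pixel flux over
   the ROI, which a unit test asserts exactly.
3. **Total CBF and nCBF.** The four neck vessels (L/R ICA, L/R VA) sum to
   total CBF; nCBF = CBF / brain mass × 100, with mass = (GM + WM volume) ×
   1.06 g/mL. Units are fixed: cm/s, cm², mL/min, mL/100 g/min.

## Session analysis

**Placement reconciliation.** Slice placement 1 is chosen orthogonal to the
carotids; placement 2 to whichever vessels placement 1 cuts obliquely
(typically vertebrals). An oblique cut under-reads flow, so per vertebral
artery we regress placement-2 on placement-1 steady-state flow across the
whole group (OLS; residual SD = √(SSE/(n−2))) and flag a session's vessel
when observed p2 − predicted p2 exceeds 1.96 × residual SD at any
steady-state timepoint. Flagged vessels take their placement-2 values in
*every* phase of that session; carotid values are never substituted. A
configurable floor (default 1 mL/min) on the residual SD prevents a
degenerate zero threshold; the 1.96 multiplier and the per-vessel vs pooled
model are options. The threshold is interpreted as a multiple of the
*residual standard deviation* of the fit — the only reading that has flow
units.

**Steady-state CBF.** Per phase, carotid flows are the mean over the
placement-1 steady acquisitions (two for stimulus phases, one for the
recovery baseline); phase physiology is the mean of the same acquisitions'
window summaries. End-tidal gases and ventilation are averaged over each
scan's half-open window [start, start+duration) — half-open so adjacent
scans never share a sample; SpO2 and heart rate use the sample nearest the
scan start, matching how pulse-oximeter values are logged. Placement-1
physiology is used even when vessel flows were substituted: both placements
sample the same physiological state within ~1–2 min.

**CVR and the CO2 correction.** Hypercapnic and hypoxic CVR follow the
equations in the README; the initial baseline (not the recovery baseline)
is the reference throughout. The hypoxic signs are flipped so vasodilation
under falling O2 is positive. Because CO2 clamping during hypoxia is
imperfect, the session's hypercapnic CVR converts the measured ΔPETCO2 into
an nCBF contribution which is subtracted from the hypoxic change; corrected
metrics are reported alongside, never instead of, the uncorrected ones, and
are unavailable when the session has no hypercapnia phase. The correction
operates on nCBF deltas (mass cancels, so CBF deltas give the same CVR).

**Response classification.** The meaningful-change threshold is the median
absolute nCBF difference between back-to-back steady-state repetitions
pooled over phases and sessions; |Δ| below it is *minimal*, otherwise the
sign gives *increase*/*decrease*.

## Reliability statistics

* **ICC.** One-way random-effects, complete-case subject × session
  matrices. Both forms are computed: single-measure ICC(1) = (MSB−MSW) /
  (MSB+(k−1)MSW) and average-measures ICC(1,k) = (MSB−MSW)/MSB. Published
  agreement coefficients for session-mean CVR metrics correspond to the
  average-measures form: with inter-subject SD σb and inter-session SD σe,
  ICC(1,k) = kρ/(1+(k−1)ρ), ρ = σb²/(σb²+σe²), and plugging the reported
  hypercapnic components (1.13, 1.37, k=3) gives 0.67 exactly — likewise
  0.43 and 0.55 for the two hypoxic metrics — so the average-measures ICC
  is what the package uses when comparing with published reliability
  values, while ICC(1) remains the default elsewhere and both appear in
  every report.
* **Variance components.** One-way ANOVA method of moments: σ̂b² =
  (MSB−MSW)/k0 with the harmonic-adjusted group size k0 for unbalanced
  data; negative estimates truncate to 0 with a flag; σ̂e = √MSW.
* **Wilcoxon signed rank.** Zeros dropped, midranks for ties; the exact
  two-sided p for n ≤ 25 comes from the full null distribution of the
  positive-rank sum built by subset-sum dynamic programming (identical to
  enumerating all 2ⁿ sign assignments, and tested against that enumeration
  for n ≤ 10); larger n uses the normal approximation with continuity and
  tie corrections. Used for back-to-back steady-state verification and the
  phase comparisons.
* **Phase comparisons.** Six variables (PETCO2, PETO2, VE, SpO2, HR, nCBF)
  × three phases against the initial baseline = 18 paired tests, flagged at
  the family-wise Bonferroni threshold 0.05/18 = 0.00278; hypercapnia is
  additionally compared with the recovery baseline at the same threshold.
* **Mixed-model R².** Random-intercept regression y = α + βx + b_subject +
  ε fitted by ML, profiling λ = σb²/σε²: at each λ the GLS solution is a
  closed-form least-squares problem on within-group deviations plus
  reweighted group means, and a 1-D bounded search maximizes the profiled
  likelihood. Reported is the marginal R² = β²Var(x) / (β²Var(x)+σb²+σε²),
  the variance share of the fixed slope. The fit matches statsmodels
  MixedLM (ML) to ~6 decimals in tests; with singleton groups it reduces
  exactly to OLS R².

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth, at two fidelity levels (per-vessel flows, or rendered
velocity cines).

**Latent structure.** Per subject: brain volume (1166 ± 110 mL, chosen so
mean mass ≈ 1236 g and 779 mL/min ↔ 63 mL/100 g/min), baseline nCBF
(63 ± 9), PETCO2 (41.0 ± 2.6 mmHg), PETO2 (112.3 ± 8.8 mmHg), SpO2 (98 ±
1 %), HR (67 ± 8 bpm), VE (9.2 ± 2.5 L/min). CVR_HC ~ N(4.33, 1.13²) at the
subject level with N(0, 1.37²) session deviations; CVR_HX is folded
positive — N(0.10, 0.07²) in magnitude — with N(0, 0.14²) session
deviations, and a `paradox_fraction` (default 0.15, within the observed
5–24 % per-session range) of subjects get a negative subject-level value.
Responder class follows the subject-level sign and the 2 mL/100 g/min
minimal-change criterion at a nominal ~51 mmHg PETO2 drop. The two
reactivities are drawn independently: the generator does not model shared
"overall vascular responsiveness", so cross-stimulus R² on synthetic
cohorts is near zero by construction (a published cohort shows ~0.3–0.5);
the R² machinery is exercised against its own analytic oracle instead.

**Gas targets and traces.** Hypercapnia achieves PETCO2 +6 mmHg (the
protocol target) ± 0.5 session-to-session; hypoxia achieves PETO2 61.6 ±
3.6 mmHg regardless of the 55–70 target window, plus a session-specific
unintentional PETCO2 perturbation of −0.4 ± 0.9 mmHg. SpO2 during hypoxia
couples linearly to the PETO2 drop (slope 0.158 %/mmHg — the value that
maps the group-mean PETO2 drop onto the group-mean SpO2 drop of 98→90 —
plus 1 % noise); the true coupling is unknown, so this is an explicit
modeling choice. Traces are piecewise-constant at the phase targets on a
1-s grid with linear transitions and per-channel sample noise.

**Flows.** Steady-state hypoxic nCBF = baseline × (1 + CVR_HX/100 ×
PETO2 drop + CVR_HC/100 × ΔPETCO2): the CO2 perturbation couples into
hypoxic flow through the session's *true* hypercapnic CVR, which is exactly
the confound the correction removes (and why zero-noise recovery is exact).
Per-acquisition noise of SD 2.1 mL/100 g/min (nCBF scale) is added before
splitting the total across vessels as 0.38/0.38/0.12/0.12 (ICAs/VAs, a
typical physiological split): the difference of two such measurements has
SD 2.1√2 and median |Δ| = 2.1√2 × 0.6745 ≈ 2.0 mL/100 g/min, matching the
empirically observed threshold. Placement non-orthogonality is
phenomenological: with probability 0.2 a vertebral vessel's placement-1
flows are multiplied by α ~ U(0.70, 1.0) for the whole session (α = 1 at
placement 2).

**Schedule.** Each session is BL → transition → HX → transition → RBL →
transition → HC; stimulus phases end with three steady acquisitions
(placements 2, 1, 1), hypoxia and hypercapnia open with two
transition-labelled placement-1 scans that are generated but excluded from
CVR, and the recovery baseline has one steady scan. The default schedule
uses 540/600/240/480-s phases with 60-s scans; `Schedule.compact()`
(180/240/90/180-s phases, 30-s scans) preserves the acquisition structure
and all steady-state statistics and is what the analysis drivers, heavy
tests and the acceptance script use to keep runtimes in seconds — only the
trace length changes, not the cohort statistics.

**Image fidelity.** Each acquisition can be rendered as a 96×96×8 cine
(0.5 mm pixels): vessels are discs (ICA radius 12 px, VA 10 px) with
parabolic profiles whose analytic integral equals the requested per-bin
flow, modulated by a unit-mean raised-cosine waveform with peak/mean 1.6
(only the cycle mean matters downstream), plus a constant background phase
offset and voxel noise. Discretization keeps pixel-sum flow within 2 % of
the request for disc diameters ≥ 20 px. No k-space simulation, velocity
aliasing, motion, or gating artifacts are modeled.

**What passing tests show.** Synthetic traces are stationary within phases,
clocks are perfectly aligned, ROIs are exact, and noise is Gaussian and
independent across acquisitions. Tests therefore validate the *estimators*
(exact parameter recovery at zero noise; calibrated thresholds, ICC and
variance-component recovery at realistic noise), not robustness to motion,
segmentation error, drift, or non-Gaussian physiology.

## Numerical choices and edge cases

* Half-open acquisition windows; ≥2 samples required per window.
* CVR is undefined (raises) when the stimulus delta is exactly zero;
  sessions without a baseline phase are skipped with a warning; sessions
  without hypercapnia yield hypoxic-only outputs with corrected metrics
  marked unavailable.
* ICC requires ≥2 complete rows; variance components truncate negative
  subject-variance estimates to zero with a flag.
* The profiled-λ search runs on log λ over a coarse grid refined by bounded
  minimization (xatol 1e-8); λ is bounded within [1e-8, 1e4].
* Study serialization round-trips bit-exactly (CSV via round-trip float
  parsing, JSON, float64 NIfTI); cohort generation is deterministic for a
  fixed seed via a single `numpy.random.default_rng` stream with fixed draw
  order.

## Known limitations

* The hypoxic dose–response is linear in the PETO2 drop; the real response
  is curvilinear and the generator does not model graded stimuli.
* No clock drift between the gas recording and the scanner: alignment is
  assumed exact.
* The generator's vessel split, SpO2 coupling, pulsatility waveform and
  attenuation model are plausible conventions, not fitted quantities; all
  are configurable.
* Crossed subject × session random effects are simplified to subject-only
  random intercepts (session variance absorbed into the residual) in the
  variance-component and R² models.
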