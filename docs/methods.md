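# Methods

`pvloop` reimplements, at desk scale, the hemodynamic analysis of a chronic
pulmonary-hypertension experiment: pressure–volume (PV) loop indices per
beat, load-varying regressions over caval-occlusion beat families, derived
arterio-ventricular coupling and vascular-resistance panels, and the
crossover dose–response statistics. Because no animal data are available,
the package ships a physiologically structured simulator that emulates the
study — six control and five pulmonary-artery-banded (PAB) pigs, each
receiving incremental norepinephrine and dobutamine infusions in a
randomised crossover with washout — and the analysis chain is validated by
parameter recovery against that simulator's ground truth.

## Beat analysis

**Segmentation.** The source experiments used commercial conductance-lab
software whose cycle-detection rules are proprietary; we declare our own.
Systolic upstrokes are dP/dt peaks of at least 50% of the global dP/dt
maximum, pruned to a quasi-periodic train: of any two peaks closer than 60%
of the median inter-peak spacing, the weaker is dropped. This rejects both
noise spikes and the rapid-filling wave, whose dP/dt can rival the systolic
upstroke in a weak, stiff ventricle. Each beat boundary is then the last
sample before dP/dt exceeds 10% (`threshold_frac`) of the global maximum
ahead of its systolic peak — the onset of isovolumic contraction, taken as
end-diastole. Derivatives are central differences by default; for noisy
recordings a Savitzky–Golay derivative (cubic; default window 101 samples =
50.5 ms at 2 kHz) is used via `RunConfig.smooth_window`, chosen so that
additive pressure noise of a few tenths of a mmHg at 2 kHz does not create
false boundaries while the systolic upstroke (≈100–300 ms) is preserved.

**End-systole.** Detected as the maximum of P/(V − V0_ref) over the beat —
the standard conductance-laboratory convention, exact for a time-varying
elastance ventricle when V0_ref equals the true volume intercept.
`fit_occlusion` uses V0_ref = 0 for a first pass, fits the ESPVR, and
refines once with V0_ref set to the fitted intercept (skipped when the
intercept is not safely below the smallest volume in the trace).

**Indices.** Pmax/Pmin are extrema, Pmean the sample mean over the beat
(uniform sampling makes this the duration-weighted mean; reported values
are beat-averaged, then stage-averaged). EF = (EDV − ESV)/EDV. HR comes
from the PV-trace period; the source protocol derived HR from the arterial
pressure curve, equivalent in steady rhythm. Stroke work is the absolute
shoelace (polygon) area of the closed loop, so traversal direction is
irrelevant. Tau (Weiss method) is −1/slope of the least-squares line
through (t, ln P) from the dP/dt minimum to the first subsequent sample
with P ≤ EDP; the window anchor uses a 21-sample smoothed derivative so a
single noise spike cannot hijack it, while the regression runs on raw
pressures (exact mono-exponentials are recovered to machine precision).
The Weiss formulation assumes decay toward zero pressure; beats whose
window is too short (high heart rates), contains non-positive pressures,
or does not decay are flagged with `tau = NaN` and a reason, never
silently dropped.

## Occlusion regressions

ESPVR (ESP on ESV; slope Ees, x-intercept V0), PRSW (stroke work on EDV)
and EDPVR (EDP on EDV) are ordinary least squares with volume as the
regressor — the regression direction is a declared convention, matching
how V0 is defined as an x-intercept. Preprocessing drops the first 2 beats
after occlusion onset (transient), truncates once EDV falls below 60% of
the first retained beat's EDV (reflex-contamination guard; both constants
configurable), and enforces a strictly decreasing EDV sequence by keeping
the longest strictly-decreasing subsequence — tolerant of single upward
noise blips where a greedy filter is not. Families with less than 5% total
EDV excursion (e.g. no actual occlusion) skip the monotone filter and are
flagged `low_range` instead of erroring. Fewer than 5 surviving beats is
an error.

## Derived panel

BSA = 0.0734·kg^0.656 (a juvenile-pig power law; the source protocol cites
a formula without reproducing it, so the coefficients are configurable).
SVRI = 80·(MAP − CVP)/CO and PVRI = 80·(RV Pmean − LV Pmin)/CO. The source
text writes both formulas per kilogram, but the tabulated magnitudes match
the un-indexed form; `index_by_weight` therefore defaults OFF and both
behaviours are available. Ea = ESP/SV. Coupling is reported in both
directions (Ees/Ea and Ea/Ees) because text and table use opposite
conventions; neither is privileged. Percent contrasts between groups are
ratios of group means rounded to integers — the convention under which the
reported contrast integers reproduce exactly; per-animal mean-of-ratios
remains available through the stage table.

## Simulator

Each simulated animal carries two independent single-ventricle circuits
(RV + pulmonary Windkessel, LV + systemic Windkessel) sharing a pacing
rate. Chamber pressure is

    P(V, t) = [Emin + (Emax − Emin)·e(t)]·(V − V0)
              + (1 − e(t))·ks·max(V − V_passive, 0)

with activation e(t) rising as a half-cosine to 1 at `t_peak` and decaying
exponentially with `relax_tau`. Two properties are built in deliberately:
at the activation peak the working point lies exactly on the end-systolic
line Emax·(V − V0), so logged ES points recover the generating ESPVR to
float precision; and the diastolic floor at end-systolic volumes is kept
near zero in the recovery-benchmark configuration, so the zero-asymptote
Weiss tau is an unbiased estimate of `relax_tau` (measured bias ≤ ~1.5% at
zero noise). The default RV/LV parameter sets have larger diastolic floors
for realism; their Weiss tau reads a few percent high, which is
inconsequential for the within-animal dose–response contrasts they feed.
Integration is explicit Euler at dt = 0.5 ms (matching 2 kHz output); all
system time constants are ≥ 50 ms, so this is comfortably stable, and
fixed-step integration keeps traces exactly aligned with the sampling
grid. Ejection is suppressed below a 3 ml volume floor: a linear ESPVR
extrapolated to a negative intercept would otherwise let a strongly
stimulated chamber empty completely. Steady state is declared when
consecutive beats' stroke volumes agree within 1% (error after 50 beats).

**Occlusion.** Caval occlusion lowers the venous pressure linearly per
beat. The study generator scales the ramp to 2.2%/beat (LV) and 1.6%/beat
(RV) of the prevailing venous pressure over 22 beats, shedding roughly a
quarter of EDV — deep enough for well-conditioned fits, shallow enough to
keep volumes physiological at every dose.

**Banding.** The PAB transform multiplies pulmonary peripheral resistance
(×1.6) and RV Emax (compensatory hypertrophy, ×1.7) and reduces LV filling
pressure (×0.57) as a septal-shift surrogate. These three numbers were
calibrated once against the phenotype the transform must reproduce —
PVRI ratio ≈ 2.9 (target band 2–3.2), LV EDV −28%, CO −22%, RV Pmax +57% —
and then frozen.

**Drugs.** Each gain g maps dose d to a multiplier 1 + g·d/(d + EC50)
(identity at zero dose, saturating at 1 + g). Norepinephrine is modelled
as a vasopressor with venous-tone recruitment (Rp_gain 0.40, Pven_gain
1.00, modest inotropy 0.35, HR 0.30; EC50 0.15 µg/kg/min over doses
0.05–0.5); dobutamine as an inodilator (Emax_gain 0.70, HR_gain 0.35,
Rp_gain −0.20; EC50 3 µg/kg/min over doses 1–10). The resistance effect on
the pulmonary circuit is attenuated to 40% of the systemic gain. These are
phenomenological coefficients tuned once to the qualitative pharmacology —
equal cardiac-index improvement in banded animals via opposite mechanisms
(preload recruitment vs. inotropy), arterial pressures favouring
norepinephrine, RV arterio-ventricular coupling improved chiefly by
dobutamine — and are not claimed to be physiological constants.

**Noise and variability.** Additive white Gaussian noise on pressure
(0.2 mmHg) and volume (0.5 ml) per sample; multiplicative lognormal
inter-subject jitter (σ = 0.05) on the physiologically variable
parameters; a small lognormal washout drift (σ = 0.02) on the second arm's
state. All randomness flows from one integer seed; a study specification
regenerates byte-identically. What the generator does *not* emulate:
baroreflexes, ventilation–perfusion coupling, an explicit septum,
conductance-catheter calibration error, band-limited (coloured) noise, or
arrhythmia. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under the stated model, not robustness
to every artefact of real catheter laboratory data.

**Protocol.** Per subject: baseline, four dose steps of the first drug, a
post-washout second baseline, four dose steps of the second drug — ten
measurement points, with steady traces and occlusion runs for both
ventricles at each, plus a systemic panel (arterial pressures from the
systemic Windkessel, CO from the LV, SvO2 from a Fick relation with an
assumed VO2, CVP from the right-sided filling pressure). NT-proBNP and
lactate are sampled once per subject as group-shifted scalars and carried
passively.

## Statistics

Baseline group contrasts use a two-tailed pooled-variance Student's t
(Welch behind a flag) when both samples pass a Shapiro–Wilk gate at
α = 0.05 — an automated stand-in for the visual normality checks of the
original workflow — and the Wilcoxon rank-sum test otherwise.

The dose–response analysis is a repeated-measures two-way ANOVA by the
classical sums-of-squares decomposition, with each within-subject effect
tested against its own subject-by-effect interaction (the convention of
the usual commercial packages; mixed-model likelihood estimation is out of
scope). Two layouts are supported and must be chosen explicitly: both
factors within subject (treatment × dose; the pipeline default), or group
as a between-subject factor (group × dose). Post-hoc per-dose contrasts
are paired (or two-sample) t-tests, Bonferroni-adjusted with m = the
number of dose levels (4); the original analysis does not state m.

The baseline-shift rule compares the two baselines by paired t; when they
differ at α = 0.05, responses are analysed as relative changes from each
arm's own baseline. The pipeline always reports dose responses as relative
changes (the crossover convention) and keeps absolute values in the stage
table. Calibration, measured by simulation: the treatment F-test under a
pure subject-plus-noise null rejects at 5.2% (2000 runs) and reaches >99%
power at a 3-SD additive effect; Bonferroni-adjusted per-dose contrasts
run conservative (~1.6% per contrast). One caveat found during
development: when the baseline-shift rule fires *spuriously* (no true
drift), normalising by the noisy baseline measurement injects an arm-level
artifact and inflates the omnibus treatment test to ~6–7% — an intrinsic
property of this fallback procedure worth knowing when
interpreting borderline omnibus p-values.

## Problem sizes and numerical choices

The shipped analyses use 8-beat steady stages and 22-beat occlusion runs
at 2 kHz, 11 subjects × 10 stages × 2 ventricles for the full study, a
3×3 (Emax, R_periph) grid for parameter recovery, and 2000/500 simulation
replicates for type-I/power calibration — sizes chosen so the entire
validation suite completes in a couple of minutes on one core while
keeping Monte-Carlo error well below the decision margins. Degenerate
inputs fail loudly: traces shorter than 3 samples, flat pressure, volumes
at or below the ES-detection reference, zero-variance regressors,
incomplete ANOVA designs and unpaired baselines all raise typed errors
with context rather than returning numbers.

## Known limitations

* Single-ventricle circuits with a preload surrogate for septal shift; no
  true biventricular interaction, so RV and LV stroke volumes need not
  match.
* Linear ESPVR/EDPVR throughout; curvilinear end-systolic relations and
  exponential diastolic stiffness are out of scope (the EDPVR unit printed
  as a slope implies the linear reading).
* The Weiss tau is undefined at the highest simulated heart rates in some
  subjects (diastole shorter than the fit window); the pipeline flags and
  excludes those stage values, which can leave a response variable without
  a complete ANOVA cube — reported as an explicit error, not imputed.
* Drug and banding coefficients reproduce directions and approximate
  magnitudes of group contrasts, not per-animal values; simulator
  population variance is only loosely calibrated to the reference SDs.
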