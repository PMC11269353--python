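# Methods

## Build-up model and fitting

Each proton's STD amplification factor η(t) = (I₀ − I_STD)/I₀ · ε is fitted
to the saturating mono-exponential η(t) = STD_max(1 − exp(−k_sat t)) by
unweighted nonlinear least squares (scipy's trust-region-reflective solver,
bounds STD_max ∈ (0, ε], k_sat ∈ (0, 100] s⁻¹, tolerances 1e−10, at most
10 000 model evaluations). The bound STD_max ≤ ε is structural: η cannot
exceed ε when I_STD ≥ 0. Initialization uses the largest observed η for the
plateau and the first-point slope η(t₁)/(STD_max⁰ t₁), clipped to
[1e−3, 10] s⁻¹, for the rate — robust for curves that visibly saturate over
the 0.5–6 s schedule. Negative η values (possible under noise) are retained
in the fit rather than clipped, to avoid biasing the plateau; a warning is
attached to the result. Solutions landing on a parameter bound are flagged
non-converged rather than reported as clean numbers.

STD₀ = STD_max · k_sat is the initial slope of the build-up curve; its
standard error comes from first-order propagation of the full fit covariance
(including the strongly negative STD_max/k_sat covariance term, without which
se(STD₀) would be badly overestimated). The epitope map normalizes STD₀ of
converged fits to the per-ligand maximum (100% exactly); ties at the maximum
break toward the lowest chemical shift so output is deterministic. Protons
flagged for resonance overlap, with all η below the detection floor (default
1e−3), or with non-converged fits are excluded from the normalization and
listed as undetermined.

## Competition and site assignment

Attenuation is quantified per proton as 100 · STD₀(with probe)/STD₀(without),
from full refits of the build-up curve in each condition. Per probe the
determined ratios are aggregated by the median (robust to single-proton
outliers; the mean is available as an option). The probe with the smallest
median marks the main site; another probe also marks its site as secondary
when its median falls below 90% (tolerance 10 points under 100). The verdict
is ambiguous when the two smallest medians differ by fewer than 10 percentage
points — a threshold comfortably below the ≥ 15-point separations seen in
practice for clearly single-main-site ligands. Ratios above 100% are retained
with a warning; they never indicate competition. The probe→site mapping is
configuration (defaults: warfarin → Sudlow site I, diazepam → site II), not
hard-coded chemistry.

WaterLOGSY classification is ordinal: sign inversion between the free and
with-protein spectra → binder; same sign but attenuated → weak or ambiguous;
unchanged → non-binder.

## Equilibria and thermodynamics

Concentrations are µM internally; the dialysis reader converts µg/mL with a
caller-supplied molar mass. The 1:1 free-ligand concentration is the positive
root of the mass-action quadratic, evaluated in the cancellation-free branch.
The two-site model treats the sites as independent (no cooperativity; the
ligand simply distributes over both pockets) with a probe competing at
exactly one site; for a trial free-ligand value the free probe has a closed
form, so the ligand mass balance is a bracketed one-dimensional root solved
with Brent's method to near machine precision. Mass balances are verified to
1e−9 relative and the solver raises rather than returning partial output.

Binding degree is 100 · (D_t − D_f)/D_t, computed as 100(1 − D_f/D_t) so the
fully-bound and fully-free boundaries are exact in floating point. A
measurement with D_f > D_t is rejected as an analytical error, never clipped.
Note the formula gives the *bound* percentage; the unbound ("free fraction")
convention is its complement.

ΔG ↔ Kd conversion uses Kd = exp(ΔG/RT) with R = 1.9872 × 10⁻³
kcal mol⁻¹ K⁻¹, T defaulting to 298 K, at the 1 M standard state (the
convention under which docking energies are reported); the round trip is
exact to 1e−12.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes, at
the standard experimental conditions: schedule {0.5, 1, 1.5, 2, 3, 4, 5, 6} s,
20 µM protein with 800 µM ligand (ε = 40), 800 µM probe when competing, and
shipped ligand templates carrying the observed proton sets of the two CMC
isomers (shifts are labels only). Template plateaus and rates are chosen so
the aromatic ring dominates the epitope map with the methyls trailing near
35–45%, the pattern typical of these ligands; per-proton site weights lean
toward site II. The default dialysis system uses physiological albumin
(600 µM), a trace drug dose and Kd = 150 µM, i.e. a bound fraction of ~80%,
the regime reported for these cathinones; note 600/(600+150) = 0.8, which is
also why micromolar-range constants and ~80% binding are mutually consistent.

Intensity noise is multiplicative Gaussian (default cv 0.02) applied
independently to the two peaks an STD measurement records: the off-resonance
peak and the difference-spectrum peak I₀ − I_STD (STD spectra are acquired by
internal subtraction, so the difference peak carries its own proportional
error; putting the noise on the raw on-resonance peak instead would give η an
absolute error ∝ cv·(ε − η) ≈ 0.8 at these conditions and swamp the signal —
not how the measurement behaves). To first order η then has relative error
√2·cv, which is what the delta-method checks in the tests assert.
Concentration noise for dialysis is multiplicative with cv 0.01, matching the
sub-point replicate scatter typical of such determinations.

Competition is modelled as occupancy scaling: each proton's STD_max is scaled
by the probe-induced change in its site-weight-averaged bound-ligand
concentration, with k_sat unchanged — the simplest mechanism consistent with
probe-induced STD attenuation. The recorded ground-truth main site is the
site with the larger occupancy-weighted transfer contribution in the
probe-free system. All randomness flows from one `numpy.random.default_rng`
stream per generator call; identical seed and configuration give bit-identical
datasets.

Not emulated: lineshapes, chemical-shift overlap (beyond an explicit overlap
flag), spin-diffusion/relaxation-matrix effects on the build-up, dialysis
kinetics and membrane binding, or multi-protein plasma. Passing tests
therefore demonstrate correctness of the analysis chain under its own model
assumptions, not robustness to those real-data effects.

## Problem sizes and numerical checks

Stochastic recovery is scored on 500 replicate datasets at cv 0.02 (median
relative STD₀ error ≈ 2%, 2·se coverage ≈ 95%); noiseless round trips on 100
random parameter draws recover parameters to ≲ 1e−11 relative; solver/oracle
comparisons use 1 000 (1:1) and 50 (two-site) random systems against
brute-force bisection; site-assignment accuracy uses 100 random competitive
systems.

## Limitations

Ordinal competition assignment presumes the probes can displace the ligand:
if the ligand binds its main site more tightly than the probe binds it, the
probe's attenuation underreports that site and even noise-free data can point
to the wrong main site. The synthetic accuracy studies therefore draw ligand
site affinities from the micromolar regime (13–190 µM, the range implied by
the docking energies at 298 K) and probe affinities from the low-micromolar
regime typical of warfarin and diazepam; outside that regime the experiment
itself, not the analysis, is uninformative. The independent-sites equilibrium
ignores cooperativity, and competition ratios are taken from full refits —
whether single-time-point comparisons would behave identically is not
addressed.
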