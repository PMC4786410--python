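# Methods

phasekit implements four analysis stages used to characterize how multivalent
arginine-rich motifs in nucleophosmin (NPM1) binding partners drive
liquid-liquid phase separation: proteome-scale motif scanning, NMR
chemical-shift titration fitting, model-free relaxation analysis, and
small-angle scattering analysis. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## R-motif scanning (`phasekit.rmotif`)

**Model.** An R-motif is a maximal run of arginines in which consecutive
arginines are separated by at most `max_inner_gap` = 2 other residues.
Detection is greedy and maximal: arginine positions are chained while the
inter-arginine gap is ≤ 2; chains with ≥ 2 arginines are motifs. A protein is
*multivalent* when two consecutive motifs are separated by at most
`max_motif_gap` = 20 residues, the gap being counted strictly between the
last arginine of one motif and the first arginine of the next (for the rpL5
peptide `RRRREGKTDYYARKRLV`, motifs [1–4] and [13–15], gap = 8).

Maximal-motif-first semantics matter: a literal reading of the nested pattern
R X≤2 R X≤20 R X≤2 R would call a single run of four arginines
(`RRRR`) multivalent, but a poly-R tract is one long motif, not two — it
binds with high affinity yet does not cross-link. Building maximal motifs
first and then requiring two distinct motifs reproduces the observed
divalent/monovalent behaviour of the reference peptides.

Only `R` counts as arginine; the ambiguity codes `X`, and any nonstandard
letters, never match (records containing letters outside the 20 standard
codes plus `X` are rejected). Coordinates are 1-based inclusive everywhere.

**Enrichment.** Proportions of multivalent proteins in two sets are compared
with a two-sided Fisher exact test on the 2×2 table (scipy); a chi-square
variant with continuity correction is available. The test is validated in
the suite against a full hypergeometric enumeration oracle.

**NoLS overlap.** Externally predicted nucleolar-localization-signal
intervals are intersected with motif spans at single-residue resolution;
intervals that extend past the sequence are clipped with a logged warning.
The NoLS predictor itself is out of scope — its output intervals are
consumed, not reproduced.

## Two-state titration fitting (`phasekit.binding`)

**Model.** In fast exchange the observed ¹⁵N shift change of a resonance is
proportional to the bound fraction of the protein, with ligand depletion
treated exactly:

    fb(Pt, Lt, K_D) = (Pt + Lt + K_D − sqrt((Pt + Lt + K_D)² − 4 Pt Lt)) / (2 Pt)
    Δω(Lt) = Δω_max · fb(Pt, Lt, K_D)

Only the single-site two-state model is implemented. Multi-site or
cooperative models are deliberately out of scope: isotherms that show
multiple independent transitions should not be fed to this fitter.

**Isotherm selection.** Two stages: (1) keep series whose final |Δω| exceeds
0.15 ppm — smaller total shifts carry too little signal; (2) normalize the
last five points of each survivor by its final shift, fit a straight line
against titration-point index, and keep series whose end slope is strictly
below the mean slope of the stage-1 survivors — a flat tail means the
resonance has effectively saturated, which is what makes Δω_max (and hence
K_D) identifiable. Ties at exactly the mean are excluded (strict
inequality); the slope is fitted against point index rather than
concentration so the criterion is scale-free. The mean is taken over stage-1
survivors only.

**Global fit.** One shared K_D, one Δω_max per accepted isotherm. The fit
uses variable projection: for any trial K_D each Δω_max has a closed-form
least-squares solution, so the nonlinear search is one-dimensional in K_D
(bounded (0, 10⁴] µM, three log-spaced starts). This is algebraically
identical to the joint minimization over all parameters but far cheaper,
which matters for the Monte-Carlo loop.

**Errors.** The dominant experimental uncertainty is the absolute ligand
concentration. Each of the 500 (default) Monte-Carlo replicates multiplies
the ligand axis by a single factor drawn from Normal(1, 0.10) — a scale
error shifts points along the abscissa — then refits; the SD over replicates
is the reported error. Independent per-point perturbation is available as an
option. `mc_reps = 0` returns the point estimate with NaN errors.

## Model-free relaxation analysis (`phasekit.relax`)

**Observables.** Peak-intensity decays are fitted to I(t) = I₀·exp(−R·t)
(bounded least squares, log-linear initialization); with exactly two delay
points the closed form R = ln(I₁/I₂)/(t₂ − t₁) is used with analytically
propagated error. Monte-Carlo errors (default 1000 runs) resample the
intensities from Normal(I, noise SD). The exchange-free transverse
cross-correlated rate is η_xy = (R₂,α − R₂,β)/2 with error
sqrt(σα² + σβ²)/2.

**Spectral density.** The Lipari–Szabo model-free form

    J(ω) = 2/5 [ S² τc / (1 + (ω τc)²) + (1 − S²) τi / (1 + (ω τi)²) ],
    1/τi = 1/τc + 1/τf

with the local variant (local-MF) obtained at τf = 0 and a residue-specific
τc,local. Rate predictions use the standard DD/CSA conventions with the
dipolar constant d = (µ0/4π)ħγH|γN|/r³ (r_NH = 1.04 Å), ¹⁵N CSA
Δσ = −162 ppm, CSA/bond angle θ = 17°:

    R1   = d²/4 [J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + (ωN Δσ/√3)² J(ωN)
    η_xy = (d ωN |Δσ| / 6) P₂(cos θ) [4J(0) + 3J(ωN)]

Magnitudes are used for γN and Δσ so that η_xy > 0 for a macromolecule
(R₂,α being the fast-relaxing anti-TROSY component). All constants live in
`PhysicalConstants` and are overridable, so any convention difference
against other software is auditable. Rotational anisotropy is not modelled.
Predicted rates for a ~54 ns tumbler at 800 MHz fall in the 0.1–0.3 s⁻¹
band for R1, the expected magnitude for a particle of this size.

**Grid search.** Per residue, χ² = Σ((obs − calc)/σ)² is minimized
exhaustively over S² ∈ [0.6, 1.0] step 0.01, τf ∈ [0, 1 ns] step 100 ps,
τc ∈ [40, 80 ns] step 1 ns (fully vectorized; ~18,000 nodes). Missing rate
SDs fall back to unit weights with a warning.

**Global tumbling time.** Residues with similar grid τc (grouping tolerance
± 3 ns) and grid τf of 0 or 100 ps are refined jointly: one shared τc plus
per-residue S². Two points deserve emphasis:

* *τf is not a free continuous parameter in this refinement.* With η_xy at
  three fields and R1 at one, the map (S², τf, τc) → rates has a
  quasi-degenerate valley — lowering S² below the folded-core range while
  raising τc and adjusting τf by tens of ps reproduces all observables to
  ~0.1%. A free τf therefore lets the joint τc drift arbitrarily upward
  under any noise. Instead the refinement alternates: (i) continuous joint
  fit of τc and the S² values with each τf held at its grid assignment;
  (ii) re-assignment of every τf on its grid with τc fixed at the new
  value; iterated to a fixed point (typically ≤ 3 rounds).
* *S² is bounded to the core window [0.6, 1.0]*, the same range the grid
  spans. Core residues are selected for rigidity in the first place, and
  this window is what blocks the degenerate valley.

The lower bound on τc comes from a rigid-rotor treatment of the η_xy data
(S² = 1, τf = 0: η_xy is monotone in τc, so the rigid-rotor τc reproducing
an observed η_xy bounds the true τc from below; the largest such bound over
the group, minus a 1 ns numerical margin, is used). Monte-Carlo errors
resample every rate from Normal(value, σ) and redo one joint fit per
replicate with the τf assignments frozen at the solution.

**Per-residue model selection.** Candidates are (a) LS-MF with the global τc
fixed, fitting (S², τf), with a nested F-test at 95% deciding whether τf is
warranted over τf = 0; and (b) local-MF fitting (τc,local, S²). The two
families are not nested, so the cross-family choice falls back to the lower
χ² and is flagged in the output. Candidate fits are run with S² allowed up
to 2 so that unrealistic solutions are *detected* (any candidate converging
to S² ≥ 1 is rejected) rather than silently pinned at 1; if every candidate
is rejected the residue is flagged unanalyzable.

**Back-calculation.** Observed vs predicted rates are summarized per rate
type by the Pearson correlation coefficient (NaN below three points).

**Stoichiometry.** The Stokes–Einstein hydrated radius
r_H = (3 V M / 4π N_A)^{1/3} + r_w (V = partial specific volume, default
0.73 ml/g; r_w = hydration shell, default 2 Å) predicts
τc(M₂)/τc(M₁) = (r_H(M₂)/r_H(M₁))³. With r_w = 0 this reduces exactly to
M₂/M₁. For 73.4 → 95.6 kDa the predicted ratio is 1.28 — a 28% increase,
the signature of two peptides bound per protomer.

## Small-angle scattering (`phasekit.sans`)

Units throughout: q in Å⁻¹, I in cm⁻¹ (absolute scale), lengths in Å,
scattering length densities in cm⁻², concentration accepted in mg/mL and
converted to g/cm³ internally.

**Guinier.** ln I vs q² is fitted over a window iterated to self-consistency
with q·R_g ≤ 1.3 (the conventional limit; at 1.3 the systematic error on a
sphere is below 2%). A non-negative slope (no decay) is an error, not a
number.

**P(r).** The pair-distance distribution solves the regularized indirect
Fourier transform I(q) = 4π ∫ P(r) sinc(qr) dr on a 101-point r grid over
[0, D_max], with P(0) = P(D_max) = 0 imposed exactly by construction
(endpoint basis functions removed) and a second-derivative smoothness
penalty. The penalty weight α is chosen by an L-curve corner criterion over
a log-spaced scan (10⁻¹⁰–10⁻², 25 points) unless fixed by the caller.
Negative excursions are permitted but logged. Real-space invariants:
R_g² = ∫r²P dr / (2∫P dr), I(0) = 4π∫P dr. The transform is validated
against the closed-form sphere P(r) = r²(1 − 3u/2 + u³/2), u = r/2R, at 3%
RMS, and against Guinier R_g/I(0) at 2% — it is not intended to reproduce
any particular regularization package's perceptual criteria.

**Mass.** M = I(0)·N_A / (c·(Δρ·v̄)²) with Δρ = ρ_prot − ρ_solv. With the
study's inputs (c = 3 mg/mL, ρ_prot = 3.0×10¹⁰ cm⁻², ρ_D2O = 6.404×10¹⁰
cm⁻², v̄ = 0.73 ml/g) I(0) = 0.2344 cm⁻¹ gives 76 kDa (a pentamer of
14.6 kDa subunits) and 0.2744 cm⁻¹ gives 89 kDa. `i0_from_mass` is the
exact inverse and is what the generator uses.

**Broad peak.** I(q) = A/qⁿ + C/(1 + (|q − q0|ξ)^m) + B, the empirical
power-law-plus-Lorentzian form used for weakly ordered dense phases, fitted
by weighted least squares (lmfit) with automatic initial guesses (peak
position from the maximum of q·I) unless supplied. The peak position maps to
a correlation distance d₀ = 2π/q₀. A vanishing Lorentzian amplitude is
flagged as degenerate, with the power law still recovered.

**Gaussian peaks.** A sum of Gaussians plus an optional linear baseline;
initial centers are seeded from the most prominent local maxima of the
detrended curve. Centers are reported sorted with d_i = 2π/q_i.

## Synthetic data (`phasekit.synthdata`)

Every generator drives the exact forward model its analysis stage inverts
and emits its ground truth, so recovery tests are self-contained:

* **sequences** — background drawn from the 19 non-arginine residues (plus
  optional isolated arginines at a set frequency); planted proteins receive
  two independent random motifs separated by 3–20 residues, wrapped in an
  arginine-free buffer so plants never merge with background. Truth lists
  the planted spans.
* **titration** — the exact two-state quadratic plus Normal(0, 0.01 ppm)
  shift noise (typical ¹⁵N shift measurement precision), nine additions to
  a 3:1 ligand:protein ratio at Pt = 284 µM by default.
* **relaxation** — rates from the model-free predictor (η_xy at 600/800/
  1000 MHz, R1 at 800 MHz) with relative Gaussian noise, or exponential
  decay curves at chosen delay schedules. Core cohorts draw S² and τf on
  the search grid so noiseless recovery is exact.
* **sans** — sphere form factor P(q) = [3(sin x − x cos x)/x³]², x = qR,
  scaled to a target I(0); the broad-peak model; or Gaussian peaks. Errors
  mimic counting statistics (σ ∝ sqrt(I·I_max) + floor).

One top-level seed fans out to per-stage RNGs through
`SeedSequence([seed, stage_id])`; identical specs give identical data.

**What the generators do not emulate:** spectral overlap and peak-picking
errors, chemical exchange line broadening, rotational anisotropy,
polydispersity, inter-particle structure factors beyond the empirical peak
models, instrument smearing, and real proteome composition biases (planted
sequences have uniform background composition). Passing recovery tests
therefore demonstrates correctness of the estimators under their own model
assumptions, not robustness to every artifact of real data.

## Problem sizes used by the test suite

The suite's simulation studies use sizes chosen to exercise the estimators
meaningfully while staying quick on one CPU: scanner–oracle equivalence on
10⁴ random sequences (length ≤ 200); global K_D recovery from 18 isotherms
with 500 Monte-Carlo replicates; tumbling-time recovery from 8–10-residue
cohorts at two tumbling times (53.6 and 67.8 ns) across three fields;
scattering round trips on 300–400-point curves.

## Known limitations

* The η_xy/R1 prefactor conventions, while standard, are one of several in
  the literature; absolute printed rates from other pipelines may differ by
  fixed factors. All constants are centralized and overridable.
* The per-residue three-parameter grid is quasi-degenerate at realistic
  noise (see above); single-residue τc estimates should not be trusted —
  use the grouped global fit.
* The F-test applies only to nested reductions; the LS-MF vs local-MF
  choice is by χ², which at equal parameter counts is a likelihood
  comparison without a significance level.
* P(r) quality depends on D_max: values below π/q_max are flagged but not
  refused.
* The titration fitter assumes fast exchange and a shared ligand schedule
  across isotherms in the global fit.
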