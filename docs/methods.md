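# Methods

This note records the models implemented in `nlsbind`, the conventions
and defaults chosen where the underlying methodology left them open, and
what the synthetic-data generators do and do not emulate.

## Peptide properties

Average molecular masses use a standard 3-decimal average residue-mass
table plus one water (18.015 Da); the N-acetyl cap adds +42.04 Da and the
C-amide cap −0.98 Da relative to free termini. Monoisotopic masses are
deliberately not used: synthesis QC and the tabulated values are average
masses. Cysteine contributes its reduced mass and no cystine absorbance
term — the peptides modeled here were designed Cys-free (Cys→Ser) to
avoid disulfides. One caveat is recorded in `presets`: the tabulated
3697.16 Da for PADI1-NLS1 matches the wild-type Cys546 sequence, while
the synthesized Cys546Ser variant computes ≈16.07 Da lighter; the
package always reports the mass of the sequence as given.

Extinction coefficients are additive per residue: 5500 (Trp) and
1490 (Tyr) M⁻¹cm⁻¹ at 280 nm. For Trp/Tyr-free peptides quantification
falls back to phenylalanine absorbance at 258 nm; the per-Phe
coefficient defaults to 200 M⁻¹cm⁻¹ and is configurable, since published
per-Phe values vary with the tabulation used. A zero coefficient is
legal but warns when used for quantification.

The annotated-sequence parser accepts caret-superscript
(`K^520^...W^549^`) and plain-digit (`K520...W549`) numbering; residues
after the trailing index (e.g. a tyrosine appended for quantification)
become un-numbered "extra" residues, reported at synthetic positions
continuing past the span.

## Hydrodynamics

The decay functional form is the standard Stejskal–Tanner
mono-exponential in squared gradient strength with the (Δ − δ/3)
correction; acquisition defaults are γ(¹H) = 26752 rad s⁻¹ G⁻¹,
δ = 2 ms, Δ = 100 ms, gradients 2–60 G cm⁻¹ over 16 points. Flat or
rising traces are rejected before fitting (no silent D = 0).

Radii come from two independent routes. (i) Internal reference:
R_h = 2.12 Å · D_dioxane/D_solute; temperature and viscosity cancel in
the ratio, so no explicit Stokes–Einstein evaluation is performed, and
the dioxane trace is always fit from the same dataset. (ii) Random-coil
scaling law R_h = (0.027 ± 0.01)·MW^(0.50 ± 0.01) nm. All uncertainties
propagate by first-order quadrature. Note that propagating the stated
±0.01 on the prefactor yields ≈±6 Å on a 3.5 kDa peptide — considerably
wider than the ±2 Å such tables usually print; the propagation formula
is reported as-is and the measured-vs-predicted consistency check
(intervals overlap: |R_m − R_p| ≤ σ_m + σ_p) accepts caller-supplied
uncertainties. Polydisperse or multi-component diffusion is out of
scope.

## NMR disorder

Conformational shifts are Δδ = δ_obs − δ_rc(corrected) for Hα protons.
The random-coil reference ships as a packaged CSV (data, not code) of
Wishart-style base shifts; the single neighbor correction encoded is the
dominant one, +0.11 ppm on the Hα of a residue immediately preceding
proline. This is an abridged correction scheme: full i±1/i±2 tables can
be swapped in by replacing the CSV. Residues without a reference entry
are excluded with a warning and counted.

The disorder verdict is strict: random-coil iff **every** assigned
residue has |Δδ| ≤ 0.1 ppm, inclusive at the boundary. An
isolated-outlier-tolerant variant would be defensible (assignments can
be noisy); strictness was chosen so that a "structured" verdict always
names the offending residues and the caller decides. NOE summaries
classify j−i = 1 as sequential, 2–4 as medium, >4 as long range;
coil-consistent means ≥1 sequential and zero medium/long. Temperature
and pH are provenance metadata only; no re-referencing is applied.

## Fluorescence binding

The titration fit uses the exact two-state mass-balance quadratic
(ligand depletion): with receptor fixed at P_T ≈ K_d the hyperbolic
approximation is biased, and the quadratic costs nothing. The
discriminant (P_T+L_T+K_d)² − 4P_T·L_T ≥ K_d² algebraically; it is
clipped at zero purely against float rounding. ΔF_max is unconstrained
in sign (binding may quench). K_d is fit on a log scale; residuals are
unweighted by default with an optional weight vector.

Identifiability: the fitted K_d is flagged untrustworthy when it falls
outside [P_T/10, 10·max(L_T)] (boundary counts as outside) or when its
covariance uncertainty exceeds the estimate. The ×10/÷10 window is a
documented convention, not a statistical test. The inner-filter
correction is the standard half-absorbance form F·10^((A_ex+A_em)/2).
Spectra are resampled by linear interpolation onto the finer common
grid for addition/comparison; Trp/Tyr deconvolution and CD
secondary-structure analysis are non-goals.

## ITC

Concentrations follow the overflow-dilution product form exactly;
V₀ = 200.3 µL (Auto-iTC200 nominal cell) is the default and every
tabulated-number computation is V₀-independent. The apparent
stoichiometry n multiplies the cell protein (binding-competent
fraction). Internal equilibrium arithmetic runs in molar units (K_a in
M⁻¹); the public surface is micromolar, with conversions centralized.

The fit estimates (K_a, ΔH, n, Q_d) by nonlinear least squares with K_a
on a log scale. **Known limitation (low-c identifiability):** at
c = K_a·[P]·n ≈ 1 — the regime of the ~10 µM K_d cells titrated at
10 µM protein — the four-parameter likelihood surface has a weak-binding
ridge along which ΔH → large, n → 0 with ΔH·n·K_a nearly invariant, and
with realistic heat noise (σ ≈ 0.3 kcal/mol) that ridge is often the
global optimum; a Cramér–Rao computation at that design gives
σ(ln K_a) ≈ 0.9, i.e. K_d determined only to a factor of ~2 even by an
ideal unbiased estimator. The fit therefore detects ridge collapse
(n < 0.1) or a K_a bound hit and raises an explicit c-value-degeneracy
failure rather than reporting a number. At c ≈ 6 (the ~1 µM cells) the
same fit recovers K_d with ≈13–18% median error under the same noise.
Restoring identifiability at low c requires fixing n from outside
information, which this package does not silently do.

The optional thermogram layer generates one exponential power peak per
injection (τ = 4 s, 150 s spacing) whose trapezoidal integral returns
the injection heat; peak shape is a simulator convention, and real
baseline correction is out of scope. ΔG = −RT·ln K_a with
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹; "entropically driven" means ΔH > 0 and
−TΔS < 0.

## BLI

Association and dissociation segments are fit separately with linear
drift terms signed and subtracted exactly as the segment models define
them; the association form is structurally zero at t₀ = 180 s and the
dissociation form equals R₁ at t₀ = 300 s (asserted identities). The
segment schedule defaults to 30/120/30/120/120 s
(baseline/load/baseline/association/dissociation). k_obs values from ≥3
distinct concentrations go into an ordinary least-squares line; the
slope is k_on (µM⁻¹ s⁻¹, since concentrations enter in µM) and the
intercept k_off. A negative intercept is reported raw and floored at
zero only in the derived K_d. K_d uncertainty is first-order quadrature
of the relative rate errors. A two-state (single on/off path) mechanism
is assumed and recorded on every result; multi-state models and global
multi-concentration fits are out of scope.

The simulator's equilibrium response is 1:1 Langmuir,
R_eq(c) = R_max·c/(c + K_d) — a convention, since only k_obs and the
segment shapes matter to the fits. The analyte channel is zero through
baseline and load segments (reference-subtracted convention) and
continuous across every boundary, with R₁ taken from the association
value at the dissociation start.

## Synthetic data

Every generator evaluates the exact forward model of its consumer and
adds Gaussian noise (absolute or relative σ, seeded NumPy generator);
σ = 0 reproduces the forward model pointwise, and identical
(parameters, seed) give identical output. Defaults are the study
designs: titrations at P_T = 3 µM with L_T on 0–30 µM (16 points); ITC
as 19 × 2 µL of 100 µM ligand into 10 µM protein; BLI at 1–10 µM
analyte with 1% noise and small per-segment drift; DOSY always paired
with a dioxane reference trace. The generators do **not** emulate
instrument artifacts (spikes, buffer-mismatch peaks, biosensor
depletion, baseline wander beyond linear drift), photobleaching, or
assignment ambiguity in shift tables; passing recovery tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to raw-instrument pathology. The disorder generator and
classifier share the same random-coil table, so coil-mode consistency
checks validate the classification logic, not the reference values.

## Problem sizes

Recovery studies use 100 replicates for ITC noise studies, 20 for BLI,
and 1,000 random parameter draws for the forward-model/oracle
equivalence check (tolerance 10⁻⁸ kcal/mol against a bracketed
mass-balance solver inside a stepwise dilution simulator) — sizes chosen
to make medians stable while keeping the whole suite quick on one CPU.
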